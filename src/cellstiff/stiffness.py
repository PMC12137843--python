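"""From classifier probabilities to Young's modulus.

The stiff-class softmax probability p (the "stiffness range", in [0, 1])
rises monotonically with cell stiffness. Calibrating it against
AFM-measured moduli uses a one-phase-decay (single-exponential
saturation) curve

    p(E) = plateau + (p0 - plateau) * exp(-k_decay * E),

fitted by nonlinear least squares, whose analytic inverse

    E(p) = -(1/k_decay) * ln((p - plateau) / (p0 - plateau))

converts a stiffness range into a predicted modulus in pascals.
Agreement with reference measurements is summarized by the absolute
percentage error (APE) and the coefficient of variation (CV).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class CalibrationCurve:
    """One-phase-decay parameters linking modulus E (Pa) to range p."""

    p0: float  # range at E = 0
    plateau: float  # asymptotic range as E -> infinity
    k_decay: float  # rate constant, 1/Pa
    fit_rss: float = 0.0
    n_points: int = 0

    def __post_init__(self):
        if self.k_decay <= 0:
            raise ValueError("k_decay must be positive")
        if self.p0 == self.plateau:
            raise ValueError("p0 == plateau gives a flat, non-invertible curve")

    def predict_range(self, modulus_pa):
        """Forward map E -> p; strictly monotone in E."""
        e = np.asarray(modulus_pa, dtype=float)
        out = self.plateau + (self.p0 - self.plateau) * np.exp(
            -self.k_decay * e)
        return float(out) if out.ndim == 0 else out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class APERecord:
    true_pa: float
    pred_pa: float
    ape_percent: float


def one_phase_decay(e, p0, plateau, k_decay):
    return plateau + (p0 - plateau) * np.exp(-k_decay * np.asarray(e, float))


def stiffness_range(probabilities, stiff_index: int = 1) -> float | np.ndarray:
    """Extract the stiff-class probability from softmax output(s)."""
    p = np.asarray(probabilities, dtype=float)
    if not -p.shape[-1] <= stiff_index < p.shape[-1]:
        raise IndexError(f"stiff_index {stiff_index} out of bounds "
                         f"for {p.shape[-1]} classes")
    out = p[..., stiff_index]
    return float(out) if out.ndim == 0 else out


def fit_one_phase_decay(modulus_pa, p) -> CalibrationCurve:
    """Nonlinear least-squares fit of p(E) = plateau + (p0-plateau)e^(-kE).

    Initialization is parameter-free: p0 from the p observed at the
    lowest E, plateau from the highest E, k = 1/median(E). Requires at
    least 4 distinct moduli; all-equal p is rejected as degenerate.
    """
    e = np.asarray(modulus_pa, dtype=float)
    p = np.asarray(p, dtype=float)
    if e.shape != p.shape or e.ndim != 1:
        raise ValueError("need matching 1-D arrays of E and p")
    if len(np.unique(e)) < 4:
        raise ValueError("need at least 4 distinct modulus values")
    if np.allclose(p, p[0]):
        raise ValueError("all stiffness ranges equal: degenerate fit")

    order = np.argsort(e)
    p0_init = float(p[order[0]])
    plateau_init = float(p[order[-1]])
    if p0_init == plateau_init:
        plateau_init += 1e-3
    k_init = 1.0 / float(np.median(e))
    try:
        popt, _ = curve_fit(one_phase_decay, e, p,
                            p0=[p0_init, plateau_init, k_init],
                            bounds=([-np.inf, -np.inf, 1e-12],
                                    [np.inf, np.inf, np.inf]),
                            maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"one-phase-decay fit did not converge: {err}")
    resid = p - one_phase_decay(e, *popt)
    return CalibrationCurve(p0=float(popt[0]), plateau=float(popt[1]),
                            k_decay=float(popt[2]),
                            fit_rss=float(np.sum(resid ** 2)),
                            n_points=len(e))


def range_to_modulus(p, cal: CalibrationCurve, eps: float = 1e-6,
                     e_max: float = 1e4):
    """Invert the calibration: E = -(1/k) ln((p - plateau)/(p0 - plateau)).

    p outside the open interval between p0 and plateau is clipped inward
    by ``eps`` (with a warning); the asymptote side is additionally
    capped at ``e_max`` Pa.
    """
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    lo = min(cal.p0, cal.plateau) + eps
    hi = max(cal.p0, cal.plateau) - eps
    if np.any(p_arr < lo) or np.any(p_arr > hi):
        warnings.warn("stiffness range outside calibration interval; "
                      "clipped inward", stacklevel=2)
        p_arr = np.clip(p_arr, lo, hi)
    ratio = (p_arr - cal.plateau) / (cal.p0 - cal.plateau)
    e = -np.log(ratio) / cal.k_decay
    capped = e > e_max
    if np.any(capped):
        warnings.warn(f"predicted modulus capped at {e_max:g} Pa near the "
                      "calibration asymptote", stacklevel=2)
        e = np.minimum(e, e_max)
    e = np.maximum(e, 0.0)
    return float(e[0]) if np.isscalar(p) or np.asarray(p).ndim == 0 else e


def absolute_percentage_error(true_pa, pred_pa):
    """APE = 100 * |pred - true| / true, in percent."""
    t = np.asarray(true_pa, dtype=float)
    if np.any(t <= 0):
        raise ValueError("true modulus must be positive")
    out = 100.0 * np.abs(np.asarray(pred_pa, float) - t) / t
    return float(out) if out.ndim == 0 else out


def coefficient_of_variation(values) -> float:
    """CV = 100 * sd / mean, with the sample (n-1) standard deviation."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(100.0 * v.std(ddof=1) / mean)


def ape_table(true_pa, pred_pa) -> list[APERecord]:
    apes = absolute_percentage_error(true_pa, pred_pa)
    return [APERecord(float(t), float(p), float(a))
            for t, p, a in zip(np.atleast_1d(true_pa), np.atleast_1d(pred_pa),
                               np.atleast_1d(apes))]
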