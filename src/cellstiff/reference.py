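"""Reference single-cell stiffness measurements.

AFM: Young's modulus from force-versus-indentation curves via the
Hertz-family contact model. For a conical (Sneddon) indenter with
half-angle theta and Poisson ratio nu,

    F(delta) = (2/pi) * tan(theta) * E / (1 - nu^2) * delta^2,

which is linear in E, so given the contact point the fit is an exact
linear least squares in delta^2. The contact point, if unknown, is found
by a two-segment (flat baseline + quadratic) change-point search.
Per-cell moduli average repeated indentations (three per cell in
standard practice).

Deformability cytometry: a cell is tracked through a microfluidic
constriction by thresholded intensity centroids; the transit time
between entering and leaving the first constriction region, at known
frame rate, indicates stiffness once cells are compared within similar
diameter bins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .synthetic import DCSequence, ForceCurve, hertz_force


@dataclass
class HertzFitResult:
    modulus_pa: float
    contact_point_m: float
    rss: float  # N^2
    n_points: int

    def __post_init__(self):
        if self.modulus_pa <= 0:
            raise ValueError("fitted modulus must be positive")


@dataclass
class TransitRecord:
    cell_id: str
    diameter_px: float
    entry_frame: int
    exit_frame: int
    fps: float

    def __post_init__(self):
        if self.exit_frame <= self.entry_frame:
            raise ValueError("exit frame must follow entry frame")

    @property
    def transit_s(self) -> float:
        return (self.exit_frame - self.entry_frame) / self.fps


# ---------------------------------------------------------------------------
# Hertz fitting


def _hertz_coeff(half_angle: float, poisson_ratio: float) -> float:
    return (2.0 / np.pi) * math.tan(half_angle) / (1.0 - poisson_ratio ** 2)


def _fit_modulus_known_contact(delta, force, half_angle, poisson_ratio):
    """E by linear least squares of F on delta^2 (exact, no iteration)."""
    d2 = np.asarray(delta, float) ** 2
    f = np.asarray(force, float)
    c = _hertz_coeff(half_angle, poisson_ratio)
    denom = np.sum(d2 * d2)
    if denom == 0:
        raise ValueError("zero indentation range")
    e = float(np.sum(d2 * f) / denom / c)
    resid = f - c * e * d2
    return e, float(np.sum(resid ** 2))


def fit_hertz(curve: ForceCurve, contact_point_m: float | None = None,
              ) -> HertzFitResult:
    """Fit the conical Hertz model to a force curve.

    With a known contact point the modulus is a closed-form linear
    least-squares solution. Otherwise each sample index is tried as a
    change point between a flat baseline and the quadratic contact
    regime, and the split with the lowest total residual wins.
    """
    delta = curve.indentation
    force = curve.force
    if np.max(np.abs(force)) == 0.0:
        raise ValueError("all-zero force curve")

    if contact_point_m is not None:
        post = delta >= contact_point_m
        if post.sum() < 10:
            raise ValueError("fewer than 10 points past the contact point")
        e, rss = _fit_modulus_known_contact(
            delta[post] - contact_point_m, force[post],
            curve.probe_half_angle, curve.poisson_ratio)
        return HertzFitResult(modulus_pa=e, contact_point_m=contact_point_m,
                              rss=rss, n_points=int(post.sum()))

    n = len(delta)
    best = None
    for split in range(0, n - 10):
        c0 = delta[split]
        baseline = force[:split]
        rss_base = float(np.sum((baseline - baseline.mean()) ** 2)) \
            if split > 1 else 0.0
        try:
            e, rss_post = _fit_modulus_known_contact(
                delta[split:] - c0, force[split:],
                curve.probe_half_angle, curve.poisson_ratio)
        except ValueError:
            continue
        if e <= 0:
            continue
        total = rss_base + rss_post
        if best is None or total < best[0]:
            best = (total, e, float(c0), rss_post, n - split)
    if best is None:
        raise ValueError("no valid contact point found (negative modulus?)")
    _, e, c0, rss, npts = best
    return HertzFitResult(modulus_pa=e, contact_point_m=c0, rss=rss,
                          n_points=npts)


def cell_modulus(fits: list[HertzFitResult]) -> float:
    """Per-cell modulus: arithmetic mean over repeated indentations."""
    if not fits:
        raise ValueError("no fits to average")
    if len(fits) != 3:
        warnings.warn(f"averaging {len(fits)} fits; standard practice is 3 "
                      "measurements per cell", stacklevel=2)
    return float(np.mean([f.modulus_pa for f in fits]))


# ---------------------------------------------------------------------------
# deformability cytometry


def extract_transit_times(seq: DCSequence, intensity_threshold: float = 100.0,
                          cell_id: str = "cell0", min_area: int = 9,
                          ) -> TransitRecord:
    """Track the cell and time its passage through the constriction.

    Per-frame centroids come from thresholded intensity moments; frames
    with two or more well-separated blobs are rejected (one cell per
    sequence). Entry is the first frame with centroid x >= x_start, exit
    the first with centroid x >= x_end; the diameter is the
    equivalent-circle diameter averaged over pre-entry frames.
    """
    from skimage.measure import label as cc_label

    x_start, x_end = seq.constriction_x
    centroids = np.full(len(seq.frames), np.nan)
    areas = np.full(len(seq.frames), np.nan)
    for t, frame in enumerate(seq.frames):
        mask = frame.astype(float) > intensity_threshold
        if mask.sum() < min_area:
            continue
        labels = cc_label(mask)
        sizes = np.bincount(labels.ravel())[1:]
        big = np.flatnonzero(sizes >= min_area)
        if len(big) > 1:
            raise ValueError(f"frame {t}: multiple cells detected; "
                             "sequences must contain one cell")
        ys, xs = np.nonzero(labels == big[0] + 1)
        centroids[t] = xs.mean()
        areas[t] = len(xs)

    if np.all(np.isnan(centroids)):
        raise ValueError("cell never detected above the intensity threshold")
    past_start = np.flatnonzero(centroids >= x_start)
    past_end = np.flatnonzero(centroids >= x_end)
    if past_start.size == 0 or past_end.size == 0:
        raise ValueError("cell never exits the constriction region")
    entry, exit_ = int(past_start[0]), int(past_end[0])

    pre = areas[:entry]
    pre = pre[np.isfinite(pre)]
    area = float(pre.mean()) if pre.size else float(areas[entry])
    diameter = 2.0 * math.sqrt(area / math.pi)
    return TransitRecord(cell_id=cell_id, diameter_px=diameter,
                         entry_frame=entry, exit_frame=exit_, fps=seq.fps)


def bin_by_diameter(records: list[TransitRecord], bin_width_px: float = 1.0,
                    min_count: int = 3) -> list[dict]:
    """Group transit records into half-open diameter bins [k*w, (k+1)*w).

    Returns per-bin summaries (n, median and IQR of transit time); bins
    with fewer than ``min_count`` records are flagged.
    """
    if not records:
        raise ValueError("no records to bin")
    if bin_width_px <= 0:
        raise ValueError("bin width must be positive")
    bins: dict[int, list[TransitRecord]] = {}
    for r in records:
        bins.setdefault(int(np.floor(r.diameter_px / bin_width_px)), []
                        ).append(r)
    out = []
    for k in sorted(bins):
        ts = np.array([r.transit_s for r in bins[k]])
        q1, med, q3 = np.percentile(ts, [25, 50, 75])
        out.append({"bin_lo_px": k * bin_width_px,
                    "bin_hi_px": (k + 1) * bin_width_px,
                    "n": len(ts), "median_transit_s": float(med),
                    "iqr_transit_s": float(q3 - q1),
                    "low_count": len(ts) < min_count})
    return out
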