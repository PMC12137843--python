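"""Seeded phantom data: single-cell images, AFM force curves, DC sequences.

Real phase-contrast images of soft cells show a bright peripheral halo
(rounded, tall cells refract light at their rim) while stiff cells show
heterogeneous intracellular texture. The phantom renderer reduces a cell
to exactly these two cues, controlled by a single dimensionless stiffness
parameter ``s`` in [0, 1]:

* halo amplitude falls linearly with ``s`` (soft cells halo strongly),
* interior speckle standard deviation rises linearly with ``s``,
* the boundary is an ellipse with a radial sinusoidal perturbation whose
  amplitude grows with ``s`` (stiff cells are more irregular).

``s`` maps to a ground-truth Young's modulus by log-linear interpolation
over the 200 Pa – 3 kPa range typical of cultured mesenchymal stromal
cells, so every phantom carries a physically meaningful label.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

E_MIN_PA = 200.0
E_MAX_PA = 3000.0


# ---------------------------------------------------------------------------
# domain types


@dataclass
class PhantomParams:
    """Rendering parameters for one phantom cell.

    ``s`` is the dimensionless stiffness parameter in [0, 1]; intensity
    gains are in 8-bit units.
    """

    s: float = 0.5
    crop_size: int = 100
    cell_radius: float = 30.0
    halo_gain: float = 70.0
    texture_gain: float = 45.0
    boundary_irregularity: float = 0.12
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"stiffness parameter s={self.s} outside [0, 1]")
        if self.cell_radius >= self.crop_size / 2:
            raise ValueError(
                f"cell_radius {self.cell_radius} must be < crop_size/2 "
                f"({self.crop_size / 2}) to fit the halo in the crop")
        if self.boundary_irregularity < 0:
            raise ValueError("boundary_irregularity must be >= 0")


@dataclass
class CellImage:
    """An 8-bit single-cell image with optional ground truth."""

    pixels: np.ndarray
    label: str | None = None  # "soft" | "stiff" | None
    modulus_pa: float | None = None
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("pixel intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.label not in (None, "soft", "stiff"):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def grayscale(self) -> np.ndarray:
        """2-D view; channel-replicated images collapse to one channel."""
        if self.pixels.ndim == 3:
            return self.pixels[..., 0]
        return self.pixels

    def as_rgb(self) -> np.ndarray:
        g = self.grayscale
        return np.repeat(g[..., None], 3, axis=-1)


@dataclass
class ForceCurve:
    """AFM force-versus-indentation samples with probe geometry."""

    indentation: np.ndarray  # m, non-negative, strictly increasing
    force: np.ndarray  # N
    probe_half_angle: float = math.radians(18.0)  # rad
    poisson_ratio: float = 0.5
    true_modulus_pa: float | None = None

    def __post_init__(self):
        self.indentation = np.asarray(self.indentation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.indentation.shape != self.force.shape:
            raise ValueError("indentation and force must have equal length")
        if self.indentation.size < 10:
            raise ValueError("force curve needs at least 10 samples")
        if np.any(np.diff(self.indentation) <= 0):
            raise ValueError("indentation must be strictly increasing")
        if np.any(self.indentation < 0):
            raise ValueError("indentation must be non-negative")


@dataclass
class DCSequence:
    """A deformability-cytometry recording of one cell with ground truth."""

    frames: np.ndarray  # (T, H, W) uint8
    fps: float = 250.0
    constriction_x: tuple[int, int] = (100, 140)  # [x_start, x_end)
    truth_entry_frame: int = 0
    truth_exit_frame: int = 0
    truth_diameter: float = 0.0  # px

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        x0, x1 = self.constriction_x
        if not 0 <= x0 < x1 <= self.frames.shape[2]:
            raise ValueError(f"constriction {self.constriction_x} outside "
                             f"frame width {self.frames.shape[2]}")
        if not (self.truth_entry_frame < self.truth_exit_frame
                < len(self.frames)):
            raise ValueError("need entry < exit < number of frames")


# ---------------------------------------------------------------------------
# stiffness parameter <-> modulus


def stiffness_from_param(s, e_min: float = E_MIN_PA,
                         e_max: float = E_MAX_PA):
    """Map s in [0,1] to Young's modulus by log-linear interpolation.

    s=0 gives ``e_min`` (200 Pa), s=1 gives ``e_max`` (3 kPa), s=0.5 the
    geometric mean; strictly increasing in s.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("s must lie in [0, 1]")
    out = e_min * (e_max / e_min) ** s  # exact at both endpoints
    return float(out) if out.ndim == 0 else out


def param_from_stiffness(modulus_pa, e_min: float = E_MIN_PA,
                         e_max: float = E_MAX_PA):
    """Inverse of :func:`stiffness_from_param`."""
    e = np.asarray(modulus_pa, dtype=float)
    if np.any(e <= 0):
        raise ValueError("modulus must be positive")
    out = (np.log(e) - np.log(e_min)) / (np.log(e_max) - np.log(e_min))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# phantom cell rendering

_BACKGROUND = 28.0
_INTERIOR = 105.0
_N_BOUNDARY_MODES = (3, 5, 7)


def _boundary_radius(theta: np.ndarray, params: PhantomParams,
                     rng: np.random.Generator) -> np.ndarray:
    """Angle-dependent cell radius: ellipse + sinusoidal perturbation.

    Both the ellipticity and the perturbation amplitude scale with s, so
    soft cells render near-circular and stiff cells irregular.
    """
    ecc = 1.0 - 0.12 * params.s * rng.uniform(0.0, 1.0)
    phi0 = rng.uniform(0, 2 * np.pi)
    r = params.cell_radius * np.sqrt(
        ecc * np.cos(theta - phi0) ** 2 + (1 / ecc) * np.sin(theta - phi0) ** 2)
    amp = params.boundary_irregularity * params.s
    for m in _N_BOUNDARY_MODES:
        phase = rng.uniform(0, 2 * np.pi)
        r *= 1.0 + amp / len(_N_BOUNDARY_MODES) * np.sin(m * theta + phase)
    return r


def generate_phantom_cell(params: PhantomParams,
                          label_threshold: float | None = 0.5,
                          channels: int = 1) -> CellImage:
    """Render one phantom cell; deterministic for a fixed seed.

    Low ``s``: bright peripheral annulus, smooth interior, near-circular
    boundary. High ``s``: faint halo, speckled interior, irregular
    boundary. ``label_threshold=None`` leaves the image unlabeled.
    """
    rng = np.random.default_rng(params.seed)
    n = params.crop_size
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    cy = cx = (n - 1) / 2.0
    dy, dx = yy - cy, xx - cx
    rad = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    r_b = _boundary_radius(theta, params, rng)
    inside = rad <= r_b

    img = np.full((n, n), _BACKGROUND)
    img[inside] = _INTERIOR

    # halo: Gaussian radial band just inside the rim, fading with s
    halo_sigma = 0.075 * params.cell_radius
    halo = (params.halo_gain * (1.0 - params.s)
            * np.exp(-0.5 * ((rad - 0.9 * r_b) / halo_sigma) ** 2))
    img += halo

    # interior speckle: low-pass filtered noise, sd growing with s
    speckle = rng.normal(0.0, 1.0, size=(n, n))
    speckle = gaussian_filter(speckle, sigma=1.5)
    speckle *= params.texture_gain * params.s / max(speckle[inside].std(), 1e-9)
    img[inside] += speckle[inside]

    img += rng.normal(0.0, params.noise_sd, size=(n, n))
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    if channels == 3:
        img = np.repeat(img[..., None], 3, axis=-1)

    label = None
    if label_threshold is not None:
        label = "soft" if params.s < label_threshold else "stiff"
    return CellImage(pixels=img, label=label,
                     modulus_pa=stiffness_from_param(params.s),
                     source_id=f"phantom_s{params.s:.3f}_seed{params.seed}")


def halo_contrast(img: CellImage, cell_radius: float) -> float:
    """Mean intensity over the peripheral halo band minus the interior mean.

    The band is the radial interval [0.825, 0.975] * ``cell_radius``
    (one halo sigma either side of the rendered halo center at 0.9 R);
    the interior is everything within 70% of the radius. Both regions
    lie inside the cell, so the difference isolates the halo.
    """
    g = img.grayscale.astype(float)
    n = g.shape[0]
    cy = cx = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    rad = np.hypot(yy - cy, xx - cx)
    annulus = (rad >= 0.825 * cell_radius) & (rad <= 0.975 * cell_radius)
    interior = rad <= 0.7 * cell_radius
    return float(g[annulus].mean() - g[interior].mean())


def interior_variance(img: CellImage, cell_radius: float) -> float:
    """Intensity variance within 70% of the nominal cell radius."""
    g = img.grayscale.astype(float)
    n = g.shape[0]
    cy = cx = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    rad = np.hypot(yy - cy, xx - cx)
    return float(g[rad <= 0.7 * cell_radius].var())


def generate_phantom_dataset(n_soft: int, n_stiff: int,
                             s_soft: tuple[float, float] = (0.0, 0.2),
                             s_stiff: tuple[float, float] = (0.8, 1.0),
                             seed: int = 0,
                             params: PhantomParams | None = None,
                             ) -> list[CellImage]:
    """Draw s uniformly within each class interval and render the cells.

    Per-image seeds are derived from the master seed, so the call is
    fully deterministic. Overlapping class intervals are allowed but
    produce ambiguous labels, hence a warning.
    """
    if n_soft < 0 or n_stiff < 0:
        raise ValueError("counts must be non-negative")
    for lo, hi in (s_soft, s_stiff):
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"interval ({lo}, {hi}) not within [0, 1]")
    if s_soft[1] > s_stiff[0]:
        warnings.warn("soft and stiff s-intervals overlap; labels ambiguous",
                      stacklevel=2)
    base = params or PhantomParams()
    rng = np.random.default_rng(seed)
    images: list[CellImage] = []
    for count, (lo, hi), label in ((n_soft, s_soft, "soft"),
                                   (n_stiff, s_stiff, "stiff")):
        for i in range(count):
            s = float(rng.uniform(lo, hi))
            child_seed = int(rng.integers(0, 2 ** 31 - 1))
            p = PhantomParams(
                s=s, crop_size=base.crop_size, cell_radius=base.cell_radius,
                halo_gain=base.halo_gain, texture_gain=base.texture_gain,
                boundary_irregularity=base.boundary_irregularity,
                noise_sd=base.noise_sd, seed=child_seed)
            img = generate_phantom_cell(p, label_threshold=None)
            img.label = label
            img.source_id = f"{label}_{i:05d}_s{s:.4f}"
            images.append(img)
    return images


def generate_phantom_spectrum(n: int, s_range: tuple[float, float] = (0.0, 1.0),
                              seed: int = 0,
                              params: PhantomParams | None = None,
                              ) -> list[CellImage]:
    """Unlabeled phantoms with s drawn uniformly across ``s_range`` —
    the synthetic analog of untreated, intermediate-stiffness cells."""
    base = params or PhantomParams()
    rng = np.random.default_rng(seed)
    images = []
    for i in range(n):
        s = float(rng.uniform(*s_range))
        child_seed = int(rng.integers(0, 2 ** 31 - 1))
        p = PhantomParams(
            s=s, crop_size=base.crop_size, cell_radius=base.cell_radius,
            halo_gain=base.halo_gain, texture_gain=base.texture_gain,
            boundary_irregularity=base.boundary_irregularity,
            noise_sd=base.noise_sd, seed=child_seed)
        img = generate_phantom_cell(p, label_threshold=None)
        img.source_id = f"wt_{i:05d}_s{s:.4f}"
        images.append(img)
    return images


def place_cells_in_field(cells: list[CellImage], field_shape=(400, 520),
                         positions: list[tuple[int, int]] | None = None,
                         background: float = _BACKGROUND,
                         seed: int = 0) -> CellImage:
    """Paste phantom crops into a larger field (max-blend, non-overlap not
    enforced); used to exercise the field-image cropping stage."""
    rng = np.random.default_rng(seed)
    field = np.full(field_shape, background)
    field += rng.normal(0, 2.0, size=field_shape)
    for k, cell in enumerate(cells):
        g = cell.grayscale.astype(float)
        h, w = g.shape
        if positions is not None:
            y0, x0 = positions[k]
        else:
            y0 = int(rng.integers(0, field_shape[0] - h))
            x0 = int(rng.integers(0, field_shape[1] - w))
        patch = field[y0:y0 + h, x0:x0 + w]
        np.maximum(patch, g, out=patch)
    return CellImage(pixels=np.clip(np.round(field), 0, 255).astype(np.uint8),
                     source_id="field")


# ---------------------------------------------------------------------------
# AFM force curves


def hertz_force(indentation, modulus_pa: float,
                half_angle: float = math.radians(18.0),
                poisson_ratio: float = 0.5):
    """Conical-indenter (Sneddon) force: F = (2/pi) tan(theta) E/(1-nu^2) d^2."""
    d = np.asarray(indentation, dtype=float)
    return (2.0 / np.pi) * np.tan(half_angle) * modulus_pa \
        / (1.0 - poisson_ratio ** 2) * d ** 2


def generate_force_curve(modulus_pa: float,
                         half_angle: float = math.radians(18.0),
                         poisson_ratio: float = 0.5,
                         max_indentation: float = 1e-6,
                         n_points: int = 100,
                         noise_sd: float = 0.0,
                         seed: int = 0) -> ForceCurve:
    """Synthesize a force-indentation curve from the Hertz/Sneddon model
    with additive Gaussian force noise (N)."""
    if modulus_pa <= 0:
        raise ValueError("modulus must be positive")
    if max_indentation <= 0:
        raise ValueError("max_indentation must be positive")
    delta = np.linspace(0.0, max_indentation, n_points)
    force = hertz_force(delta, modulus_pa, half_angle, poisson_ratio)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        force = force + rng.normal(0.0, noise_sd, size=force.shape)
    return ForceCurve(indentation=delta, force=force,
                      probe_half_angle=half_angle,
                      poisson_ratio=poisson_ratio,
                      true_modulus_pa=modulus_pa)


# ---------------------------------------------------------------------------
# deformability-cytometry sequences


def generate_dc_sequence(diameter: float = 24.0,
                         speed_px_per_frame=2.0,
                         constriction_x: tuple[int, int] = (100, 140),
                         frame_shape: tuple[int, int] = (128, 256),
                         fps: float = 250.0,
                         start_x: float = 0.0,
                         noise_sd: float = 0.0,
                         seed: int = 0,
                         intensity: float = 200.0) -> DCSequence:
    """Render one bright cell traversing the channel left to right.

    ``speed_px_per_frame`` may be a constant or a callable of the frame
    index. Inside the constriction the cell is rendered as an elongated
    ellipse of equal area. Ground-truth entry/exit frames follow the
    definition used by the extractor: first frame with centroid x >=
    x_start and first frame with centroid x >= x_end.
    """
    h, w = frame_shape
    x0, x1 = constriction_x
    speed = speed_px_per_frame if callable(speed_px_per_frame) \
        else (lambda t, v=float(speed_px_per_frame): v)
    rng = np.random.default_rng(seed)

    # center trajectory: advance until the cell leaves the field of view
    xs = [float(start_x)]
    t = 0
    while xs[-1] <= w - 1 + diameter / 2 and t < 100000:
        v = float(speed(t))
        if v <= 0:
            raise ValueError("speed must stay positive")
        xs.append(xs[-1] + v)
        t += 1
    xs_arr = np.array(xs[:-1]) if xs[-1] > w - 1 + diameter / 2 else np.array(xs)
    n_frames = len(xs_arr)

    cy = h / 2.0
    r = diameter / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    frames = np.zeros((n_frames, h, w), dtype=np.uint8)
    centroids = np.full(n_frames, np.nan)
    for ti in range(n_frames):
        cx = xs_arr[ti]
        if x0 <= cx < x1:
            ax, ay = r * 1.4, r / 1.4  # elongate along flow, conserve area
        else:
            ax = ay = r
        mask = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
        if mask.any():
            centroids[ti] = xx[mask].mean()
        frame = np.zeros((h, w))
        frame[mask] = intensity
        if noise_sd > 0:
            frame += rng.normal(0.0, noise_sd, size=(h, w))
        frames[ti] = np.clip(np.round(frame), 0, 255).astype(np.uint8)

    # truth from the rendered centroid — the same quantity the extractor
    # measures — so noiseless extraction matches exactly
    past_start = np.flatnonzero(centroids >= x0)
    past_end = np.flatnonzero(centroids >= x1)
    if past_start.size == 0 or past_end.size == 0:
        raise ValueError("cell never reaches the constriction exit")
    entry, exit_ = int(past_start[0]), int(past_end[0])
    return DCSequence(frames=frames, fps=fps, constriction_x=(x0, x1),
                      truth_entry_frame=entry, truth_exit_frame=exit_,
                      truth_diameter=diameter)


# ---------------------------------------------------------------------------
# on-disk interchange


def write_dataset(images: list[CellImage], out_dir: str | Path,
                  fmt: str = "png") -> Path:
    """Write crops plus a manifest CSV (source_id, label, modulus_pa)."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source_id", "path", "label", "modulus_pa"])
        for i, img in enumerate(images):
            name = f"cell_{i:05d}.{fmt}"
            iio.imwrite(out / name, img.pixels)
            writer.writerow([img.source_id, name, img.label or "",
                             "" if img.modulus_pa is None else img.modulus_pa])
    return manifest


def write_force_curve(curve: ForceCurve, csv_path: str | Path) -> None:
    """Two-column CSV (indentation_m, force_n) + JSON metadata sidecar."""
    path = Path(csv_path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["indentation_m", "force_n"])
        for d, f in zip(curve.indentation, curve.force):
            writer.writerow([repr(float(d)), repr(float(f))])
    meta = {"probe_half_angle_rad": curve.probe_half_angle,
            "poisson_ratio": curve.poisson_ratio,
            "true_modulus_pa": curve.true_modulus_pa}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_force_curve(csv_path: str | Path) -> ForceCurve:
    path = Path(csv_path)
    data = np.genfromtxt(path, delimiter=",", skip_header=1)
    kwargs = {}
    meta_path = path.with_suffix(".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        kwargs = {"probe_half_angle": meta["probe_half_angle_rad"],
                  "poisson_ratio": meta["poisson_ratio"],
                  "true_modulus_pa": meta["true_modulus_pa"]}
    return ForceCurve(indentation=data[:, 0], force=data[:, 1], **kwargs)


def write_dc_sequence(seq: DCSequence, tiff_path: str | Path) -> None:
    """Multi-page TIFF + JSON sidecar carrying fps and ground truth."""
    import tifffile

    path = Path(tiff_path)
    tifffile.imwrite(path, seq.frames)
    meta = {"fps": seq.fps, "constriction_x": list(seq.constriction_x),
            "truth_entry_frame": seq.truth_entry_frame,
            "truth_exit_frame": seq.truth_exit_frame,
            "truth_diameter": seq.truth_diameter}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_dc_sequence(tiff_path: str | Path) -> DCSequence:
    import tifffile

    path = Path(tiff_path)
    frames = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return DCSequence(frames=frames, fps=meta["fps"],
                      constriction_x=tuple(meta["constriction_x"]),
                      truth_entry_frame=meta["truth_entry_frame"],
                      truth_exit_frame=meta["truth_exit_frame"],
                      truth_diameter=meta["truth_diameter"])
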