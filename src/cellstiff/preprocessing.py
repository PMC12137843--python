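"""Field-image cropping, 50x50 resizing, normalization, augmentation,
and train/validation/test partitioning.

Model inputs follow a fixed contract: crops are resized to 50x50 px and
intensities mapped affinely from [0, 255] to [-1, 1]
(v -> 2*(v/255 - 0.5)). Datasets are split 60/20/20 by default,
optionally stratified by class label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, rotate as nd_rotate
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.transform import resize

from .synthetic import CellImage

INPUT_SIDE = 50


@dataclass
class NormalizedInput:
    """A 50x50 real-valued model input with every value in [-1, 1]."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[:2] != (INPUT_SIDE, INPUT_SIDE):
            raise ValueError(f"expected {INPUT_SIDE}x{INPUT_SIDE}, "
                             f"got {self.values.shape}")
        if self.values.min() < -1.0 - 1e-9 or self.values.max() > 1.0 + 1e-9:
            raise ValueError("normalized values must lie in [-1, 1]")


@dataclass
class DatasetSplit:
    train_ids: list = field(default_factory=list)
    val_ids: list = field(default_factory=list)
    test_ids: list = field(default_factory=list)
    ratios: tuple = (0.6, 0.2, 0.2)
    seed: int = 0

    def __iter__(self):
        return iter((self.train_ids, self.val_ids, self.test_ids))


# ---------------------------------------------------------------------------


def crop_single_cells(field_img: CellImage, min_area: float = 100.0,
                      margin: int = 8, max_cells_per_crop: int = 1,
                      ) -> list[CellImage]:
    """Detect cells in a field image and return single-cell crops.

    Candidate regions come from Otsu thresholding of the
    background-subtracted intensity followed by connected components and
    an area filter; a candidate bounding box is rejected when it contains
    zero or more than ``max_cells_per_crop`` detected cells (overlapping
    cells merge into one oversized component and are dropped by the
    area/solidity screen below).
    """
    from scipy.ndimage import distance_transform_edt
    from skimage.feature import peak_local_max

    g = field_img.grayscale.astype(float)
    if g.size == 0:
        return []
    bg = np.median(g)
    signal = g - bg
    if signal.max() <= 1.0:  # featureless field
        return []
    thr = threshold_otsu(signal)
    mask = signal > thr
    labels = cc_label(mask)
    props = [p for p in regionprops(labels) if p.area >= min_area]
    if not props:
        return []

    def count_cells(component_mask: np.ndarray) -> int:
        """Cells inside one component = distance-transform peaks; two
        touching cells merge into one component but keep two peaks."""
        dist = distance_transform_edt(component_mask)
        r_est = max(int(round(0.7 * dist.max())), 1)
        peaks = peak_local_max(dist, min_distance=r_est,
                               threshold_abs=0.5 * dist.max(),
                               exclude_border=False)
        return max(len(peaks), 1)

    crops = []
    for p in props:
        y0, x0, y1, x1 = p.bbox
        y0 = max(0, y0 - margin)
        x0 = max(0, x0 - margin)
        y1 = min(g.shape[0], y1 + margin)
        x1 = min(g.shape[1], x1 + margin)
        sub = labels[y0:y1, x0:x1]
        n_cells = 0
        for v in np.unique(sub):
            if v == 0 or (labels == v).sum() < min_area:
                continue
            n_cells += count_cells(labels == v)
        if n_cells == 0 or n_cells > max_cells_per_crop:
            continue
        crops.append(CellImage(
            pixels=field_img.grayscale[y0:y1, x0:x1].copy(),
            label=field_img.label, modulus_pa=field_img.modulus_pa,
            source_id=f"{field_img.source_id}_crop{len(crops)}"))
    return crops


def resize_crop(crop: CellImage, side: int = INPUT_SIDE) -> CellImage:
    """Bilinear resize to ``side`` x ``side``, anti-aliased on downscale."""
    g = crop.grayscale
    if g.size == 0 or min(g.shape) == 0:
        raise ValueError("cannot resize an empty crop")
    if g.shape == (side, side):
        out = g.copy()
    else:
        resized = resize(g.astype(float), (side, side), order=1,
                         anti_aliasing=min(g.shape) > side,
                         preserve_range=True)
        out = np.clip(np.round(resized), 0, 255).astype(np.uint8)
    return CellImage(pixels=out, label=crop.label,
                     modulus_pa=crop.modulus_pa, source_id=crop.source_id)


def normalize_intensity(img: CellImage | np.ndarray) -> NormalizedInput:
    """Map 8-bit intensities to [-1, 1]: v -> 2*(v/255 - 0.5)."""
    g = img.grayscale if isinstance(img, CellImage) else np.asarray(img)
    g = g.astype(float)
    if g.min() < 0 or g.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return NormalizedInput(values=2.0 * (g / 255.0 - 0.5))


def denormalize_intensity(norm: NormalizedInput | np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`normalize_intensity` on the continuous scale."""
    v = norm.values if isinstance(norm, NormalizedInput) else np.asarray(norm)
    return (v / 2.0 + 0.5) * 255.0


_AUGMENT_OPS = ("rotation", "flip", "gaussian_blur")


def augment(img: CellImage, ops=("rotation", "flip", "gaussian_blur"),
            rotation_angles=(90.0, 180.0, 270.0), random_rotation: bool = False,
            blur_sd: float = 1.0, seed: int = 0) -> list[CellImage]:
    """Produce augmented copies (rotations, horizontal flip, Gaussian
    blur); labels and moduli are copied unchanged. Deterministic under
    ``seed`` (which only matters when ``random_rotation`` is set)."""
    for op in ops:
        if op not in _AUGMENT_OPS:
            raise ValueError(f"unknown augmentation op {op!r}; "
                             f"choose from {_AUGMENT_OPS}")
    rng = np.random.default_rng(seed)
    g = img.grayscale.astype(float)
    out: list[CellImage] = []

    def emit(arr, tag):
        out.append(CellImage(
            pixels=np.clip(np.round(arr), 0, 255).astype(np.uint8),
            label=img.label, modulus_pa=img.modulus_pa,
            source_id=f"{img.source_id}_{tag}"))

    if "rotation" in ops:
        angles = list(rotation_angles)
        if random_rotation:
            angles.append(float(rng.uniform(0.0, 360.0)))
        for a in angles:
            if a % 90 == 0:
                emit(np.rot90(g, k=int(a // 90) % 4), f"rot{a:g}")
            else:
                emit(nd_rotate(g, a, reshape=False, order=1,
                               mode="nearest"), f"rot{a:g}")
    if "flip" in ops:
        emit(g[:, ::-1], "flip")
    if "gaussian_blur" in ops:
        emit(gaussian_filter(g, sigma=blur_sd), f"blur{blur_sd:g}")
    return out


def split_dataset(ids, ratios=(0.6, 0.2, 0.2), labels=None,
                  seed: int = 0) -> DatasetSplit:
    """Disjoint, exhaustive train/val/test partition of unique ids.

    Counts use floor for val and test with the remainder assigned to
    train, so realized fractions match ``ratios`` to within rounding.
    Passing ``labels`` (one per id) stratifies the split per class.
    """
    ids = list(ids)
    if len(set(map(id, ids))) != len(ids) and len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios {ratios} must sum to 1")
    if len(ratios) != 3 or any(r < 0 for r in ratios):
        raise ValueError("need three non-negative ratios")

    rng = np.random.default_rng(seed)

    def partition(group):
        group = list(group)
        order = rng.permutation(len(group))
        n = len(group)
        n_val = int(np.floor(ratios[1] * n))
        n_test = int(np.floor(ratios[2] * n))
        n_train = n - n_val - n_test
        shuffled = [group[i] for i in order]
        return (shuffled[:n_train],
                shuffled[n_train:n_train + n_val],
                shuffled[n_train + n_val:])

    if labels is None:
        tr, va, te = partition(ids)
    else:
        labels = list(labels)
        if len(labels) != len(ids):
            raise ValueError("labels must align with ids")
        tr, va, te = [], [], []
        for lab in sorted(set(labels), key=str):
            group = [i for i, l in zip(ids, labels) if l == lab]
            a, b, c = partition(group)
            tr += a
            va += b
            te += c
    return DatasetSplit(train_ids=tr, val_ids=va, test_ids=te,
                        ratios=tuple(ratios), seed=seed)


def images_to_tensor(images: list[CellImage]) -> np.ndarray:
    """Resize + normalize a list of crops into an (N, 50, 50, 1) tensor."""
    arrs = [normalize_intensity(resize_crop(im)).values for im in images]
    return np.stack(arrs)[..., None]
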