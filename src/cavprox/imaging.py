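"""Front–rear polarity and proximity-ligation image quantification.

Implements the image statistics used to characterise caveolae rear
localisation in migrating cells:

- :func:`estimate_polarity_axis` — principal axis of a cell mask with
  the rear pole assigned to the brighter half (or a manual hint);
- :func:`rear_localization_index` — background-subtracted mean rear
  intensity over an equal-sized front region;
- :func:`quadrant_profile` — intensity profile along a wide line scan
  from rear to front, averaged into four equal quadrants (rear,
  centre rear, centre front, front);
- :func:`count_pla_dots` — proximity-ligation dots per cell as
  area-filtered connected components of a smoothed, thresholded image;
- :func:`rear_fraction_of_dots` — fraction of dots in the rear
  quadrant (or half);
- :func:`pearson_colocalization` — Pearson r over in-mask pixels.

Conventions: row-major arrays, origin top-left, pixel centres at
integer coordinates; areas in pixels with ``pixel_size_um`` recorded
separately where physical units are needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage import measure

from .proteomics import ConfigError, InputError


class AmbiguousAxisError(ValueError):
    """Mask too isotropic to define a front–rear axis without a hint."""


class UndefinedIndexError(ZeroDivisionError):
    """Front mean is zero; rear/front ratio undefined."""


@dataclass(frozen=True)
class PolarityAxis:
    """Front–rear axis of one cell.

    ``vector`` is the unit (row, col) direction pointing from front
    to rear; ``centroid`` is the mask centroid; ``rear_pole`` and
    ``front_pole`` are the extreme mask pixels along the axis.
    """

    vector: tuple[float, float]
    centroid: tuple[float, float]
    rear_pole: tuple[float, float]
    front_pole: tuple[float, float]
    axis_ratio: float

    def project(self, coords: np.ndarray) -> np.ndarray:
        """Signed coordinate along the axis (positive toward the rear),
        relative to the centroid. ``coords`` is (N, 2) in (row, col)."""
        d = np.asarray(coords, dtype=float) - np.asarray(self.centroid)
        return d @ np.asarray(self.vector)


def _cell_coords(mask: np.ndarray, label: int) -> np.ndarray:
    coords = np.argwhere(mask == label)
    if len(coords) == 0:
        raise InputError(f"no pixels with label {label}")
    return coords


def estimate_polarity_axis(
    mask: np.ndarray,
    image: np.ndarray | None = None,
    rear_hint: tuple[float, float] | None = None,
    label: int = 1,
    min_axis_ratio: float = 1.05,
    min_pixels: int = 100,
) -> PolarityAxis:
    """Principal axis of the mask's second moments, rear pole assigned.

    The axis direction is the major principal axis of the labelled
    region. The rear is the pole whose half of the cell has the higher
    mean intensity — the side of maximal bait signal — unless
    ``rear_hint`` (a point near the rear, in (row, col)) overrides it.
    Raises :class:`AmbiguousAxisError` for near-isotropic masks
    (axis ratio < ``min_axis_ratio``) without a hint.
    """
    coords = _cell_coords(mask, label)
    if len(coords) < min_pixels:
        raise InputError(f"cell region has {len(coords)} px; need >= {min_pixels}")
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    cov = centred.T @ centred / len(coords)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    axis_ratio = float(np.sqrt(evals[1] / max(evals[0], 1e-12)))
    vec = evecs[:, 1]

    proj = centred @ vec
    if rear_hint is not None:
        hint_proj = (np.asarray(rear_hint, dtype=float) - centroid) @ vec
        if hint_proj < 0:
            vec = -vec
            proj = -proj
    else:
        if axis_ratio < min_axis_ratio:
            raise AmbiguousAxisError(
                f"axis ratio {axis_ratio:.3f} < {min_axis_ratio}; supply rear_hint"
            )
        if image is None:
            raise InputError("need an intensity image or rear_hint to orient the axis")
        vals = image[coords[:, 0], coords[:, 1]]
        if vals[proj > 0].mean() < vals[proj < 0].mean():
            vec = -vec
            proj = -proj

    rear_pole = coords[np.argmax(proj)]
    front_pole = coords[np.argmin(proj)]
    return PolarityAxis(
        vector=(float(vec[0]), float(vec[1])),
        centroid=(float(centroid[0]), float(centroid[1])),
        rear_pole=(float(rear_pole[0]), float(rear_pole[1])),
        front_pole=(float(front_pole[0]), float(front_pole[1])),
        axis_ratio=axis_ratio,
    )


def rear_front_halves(
    mask: np.ndarray, axis: PolarityAxis, label: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-pixel-count rear and front regions along the axis.

    Mask pixels are ranked by their axis coordinate; the most rear-ward
    floor(N/2) pixels form the rear region and the most front-ward
    floor(N/2) the front region, guaranteeing equal size (±1 via the
    shared middle pixel at odd N being excluded).
    """
    coords = _cell_coords(mask, label)
    proj = axis.project(coords)
    order = np.argsort(proj, kind="stable")
    half = len(coords) // 2
    front_idx = coords[order[:half]]
    rear_idx = coords[order[-half:]]
    rear = np.zeros(mask.shape, dtype=bool)
    front = np.zeros(mask.shape, dtype=bool)
    rear[rear_idx[:, 0], rear_idx[:, 1]] = True
    front[front_idx[:, 0], front_idx[:, 1]] = True
    return rear, front


def rear_localization_index(
    image: np.ndarray,
    rear_region: np.ndarray,
    front_region: np.ndarray,
    background: float = 0.0,
) -> float:
    """Rear/front mean-intensity ratio after background subtraction.

    Regions must have (near-)equal pixel counts; intensities are
    floored at zero after subtracting ``background``. The index is
    invariant to global intensity scaling.
    """
    n_rear, n_front = int(rear_region.sum()), int(front_region.sum())
    if abs(n_rear - n_front) > 1:
        raise ConfigError(
            f"regions must have equal pixel counts (got {n_rear} vs {n_front})"
        )
    corrected = np.clip(np.asarray(image, dtype=float) - background, 0, None)
    front_mean = corrected[front_region].mean()
    if front_mean == 0:
        raise UndefinedIndexError("front mean intensity is zero")
    return float(corrected[rear_region].mean() / front_mean)


def quadrant_profile(
    image: np.ndarray,
    mask: np.ndarray,
    axis: PolarityAxis,
    line_width_px: float = 50.0,
    label: int = 1,
    background: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float, float]]:
    """Wide line-scan profile from rear to front, plus quadrant means.

    A line of width ``line_width_px`` runs along the polarity axis
    through the centroid. In-mask pixels within half the width of the
    line are binned by their (1 px wide) axis coordinate; the profile
    is the mean background-subtracted intensity per bin, ordered
    rear -> front. The profile is then split into four equal-length
    segments — rear, centre rear, centre front, front — and averaged
    within each.

    Returns (positions, profile, quadrant_means).
    """
    coords = _cell_coords(mask, label)
    proj = axis.project(coords)  # positive toward rear
    perp = np.abs(
        (coords - np.asarray(axis.centroid))
        @ np.array([-axis.vector[1], axis.vector[0]])
    )
    inside = perp <= line_width_px / 2.0
    coords, proj = coords[inside], proj[inside]
    span = proj.max() - proj.min()
    if span < 4:
        raise ConfigError(f"axis span {span:.1f} px too short to quadrant")

    # rear -> front means decreasing axis coordinate
    s = (proj.max() - proj) / span  # 0 at rear pole, 1 at front pole
    vals = np.clip(image[coords[:, 0], coords[:, 1]].astype(float) - background, 0, None)
    n_bins = max(int(np.ceil(span)), 4)
    bins = np.minimum((s * n_bins).astype(int), n_bins - 1)
    sums = np.bincount(bins, weights=vals, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    positions = (np.arange(n_bins) + 0.5) * span / n_bins

    edges = [0.0, 0.25, 0.5, 0.75, 1.0]
    quad_means = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (s >= lo) & (s < hi) if hi < 1 else (s >= lo)
        quad_means.append(float(vals[sel].mean()) if sel.any() else float("nan"))
    return positions, profile, tuple(quad_means)


@dataclass(frozen=True)
class DotDetectionParams:
    """PLA dot detection: Gaussian smoothing sigma (px), threshold at
    in-mask mean + threshold_k * sd, and an area window in px."""

    sigma: float = 1.0
    threshold_k: float = 4.0
    min_area: int = 3
    max_area: int = 400


def count_pla_dots(
    image: np.ndarray,
    mask: np.ndarray,
    params: DotDetectionParams = DotDetectionParams(),
) -> tuple[dict[int, int], np.ndarray, np.ndarray]:
    """Count proximity-ligation dots per labelled cell.

    The image is Gaussian-smoothed, thresholded at the in-mask
    mean + k*sd, and dots are 8-connected components within the area
    window. Each dot is assigned to the cell whose label contains its
    centroid; dots whose centroid falls outside every cell are
    discarded.

    Returns (per-cell counts for every mask label, binary dot mask,
    centroids of the accepted dots as an (n, 2) array).
    """
    img = np.asarray(image, dtype=float)
    smoothed = ndimage.gaussian_filter(img, params.sigma) if params.sigma > 0 else img
    in_mask = mask > 0
    if not in_mask.any():
        raise InputError("empty cell mask")
    mu, sd = smoothed[in_mask].mean(), smoothed[in_mask].std()
    binary = smoothed > mu + params.threshold_k * sd

    labels = measure.label(binary, connectivity=2)
    dot_mask = np.zeros(img.shape, dtype=bool)
    counts = {int(lab): 0 for lab in np.unique(mask) if lab > 0}
    centroids = []
    for region in measure.regionprops(labels):
        if not (params.min_area <= region.area <= params.max_area):
            continue
        r, c = region.centroid
        cell = int(mask[int(round(r)), int(round(c))])
        if cell <= 0:
            continue
        counts[cell] += 1
        centroids.append((r, c))
        dot_mask[labels == region.label] = True
    return counts, dot_mask, np.array(centroids).reshape(-1, 2)


def rear_fraction_of_dots(
    dot_centroids: np.ndarray,
    axis: PolarityAxis,
    mask: np.ndarray,
    label: int = 1,
    boundary: str = "quadrant",
) -> float | None:
    """Fraction of dots rear-ward of the stated boundary.

    ``boundary = "quadrant"`` uses the rear quarter of the axis span
    (matching the rear quadrant of :func:`quadrant_profile`);
    ``"half"`` uses the centroid plane. Returns None (undefined) when
    there are no dots.
    """
    pts = np.asarray(dot_centroids, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return None
    coords = _cell_coords(mask, label)
    proj_cell = axis.project(coords)
    proj_dots = axis.project(pts)
    if boundary == "half":
        cut = 0.0
    elif boundary == "quadrant":
        cut = proj_cell.max() - 0.25 * (proj_cell.max() - proj_cell.min())
    else:
        raise ConfigError(f"unknown boundary {boundary!r}")
    return float(np.mean(proj_dots > cut))


def pearson_colocalization(
    image_a: np.ndarray, image_b: np.ndarray, mask: np.ndarray
) -> float:
    """Pearson correlation of two channels over in-mask pixels."""
    a, b = np.asarray(image_a, float), np.asarray(image_b, float)
    if a.shape != b.shape or a.shape != mask.shape:
        raise InputError("channel and mask shapes differ")
    sel = mask > 0
    if sel.sum() < 2:
        raise InputError("need >= 2 in-mask pixels")
    av, bv = a[sel], b[sel]
    if av.std() == 0 or bv.std() == 0:
        raise InputError("zero-variance channel inside the mask")
    return float(stats.pearsonr(av, bv)[0])
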