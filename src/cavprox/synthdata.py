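"""Seeded synthetic-data generators with known ground truth.

Four generators emulate the study's data modalities so that every
downstream stage is testable without downloads:

- :func:`simulate_lfq_experiment` — 4 groups x 3 replicates of
  log-normal LFQ intensities with planted interactor classes and
  detection-limit (MNAR) missingness;
- :func:`simulate_polarized_cell_image` — elliptical cells with a
  planted rear/front intensity fold;
- :func:`simulate_pla_image` — Gaussian-profile proximity-ligation
  dots at recorded positions;
- :func:`simulate_tracks` — 2-D persistent random walks
  (Ornstein–Uhlenbeck velocity process) at a stated speed scale.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .proteomics import CONDITIONS, ConfigError, IntensityTable, SampleDesign

# Planted interactor classes and their log2 enrichment over the NES
# reference per condition. core_caveolar mirrors the caveolar coat
# (Cav1/Cav2/cavin1/EHD2): strongly enriched at rest (NT) and after
# recovery (REC), lost under hypo-osmotic shock (HYPO).
DEFAULT_EFFECT_SIZES: dict[str, dict[str, float]] = {
    "core_caveolar": {"NT": 3.0, "HYPO": 0.0, "REC": 3.0},
    "nt_rec_specific": {"NT": 2.0, "HYPO": 0.0, "REC": 2.0},
    "hypo_specific": {"NT": 0.0, "HYPO": 2.0, "REC": 0.0},
    "hypo_rec_specific": {"NT": 0.0, "HYPO": 2.0, "REC": 2.0},
    "background": {"NT": 0.0, "HYPO": 0.0, "REC": 0.0},
}

# Fractions roughly mirror the reported interactome proportions
# (~350 significant of ~1500 quantified; HYPO-only the largest class).
DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    "core_caveolar": 0.02,
    "nt_rec_specific": 0.02,
    "hypo_specific": 0.05,
    "hypo_rec_specific": 0.01,
    "background": 0.90,
}


@dataclass(frozen=True)
class SynthProteomeConfig:
    """Design and noise model of the simulated LFQ experiment.

    log2 intensities: baseline ~ N(baseline_mean, baseline_sd^2) per
    protein, plus the class effect for the sample's condition (Cav1
    baits only), plus N(0, replicate_sd^2) per measurement. Values
    below ``detection_limit`` (log2 units) are censored to missing
    (MNAR); ``mcar_rate`` adds uniform random dropout for robustness
    tests.
    """

    n_proteins: int = 1500
    n_replicates: int = 3
    groups: tuple[tuple[str, str], ...] = (
        ("Cav1", "NT"),
        ("Cav1", "HYPO"),
        ("Cav1", "REC"),
        ("NES", "NT"),
    )
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    effect_sizes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECT_SIZES.items()}
    )
    baseline_mean: float = 27.0
    baseline_sd: float = 2.0
    replicate_sd: float = 0.5
    detection_limit: float = 24.0
    mcar_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class_fractions sum to {total}, expected 1")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        if self.replicate_sd <= 0:
            raise ConfigError("replicate_sd must be > 0")
        unknown = set(self.class_fractions) - set(self.effect_sizes)
        if unknown:
            raise ConfigError(f"classes without effect sizes: {sorted(unknown)}")


def simulate_lfq_experiment(
    config: SynthProteomeConfig,
) -> tuple[IntensityTable, pd.DataFrame]:
    """Simulate a proteinGroups-style LFQ table with planted truth.

    Returns the raw-scale :class:`IntensityTable` and a truth frame
    indexed by protein id with the class label and the true log2
    effect per condition.
    """
    rng = np.random.default_rng(config.seed)
    design = SampleDesign.from_layout(config.groups, config.n_replicates)

    classes = list(config.class_fractions)
    counts = _apportion(config.n_proteins, [config.class_fractions[c] for c in classes])
    labels = np.repeat(classes, counts)
    rng.shuffle(labels)

    protein_ids = pd.Index(
        [f"P{i:05d}" for i in range(config.n_proteins)], name="protein_id"
    )
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_proteins)

    truth = pd.DataFrame({"class": labels}, index=protein_ids)
    for cond in CONDITIONS:
        truth[f"effect_{cond}"] = [
            config.effect_sizes[c][cond] for c in labels
        ]

    log2 = {}
    for _, row in design.table.iterrows():
        mean = baseline.copy()
        if row["bait"] == "Cav1":
            mean = mean + truth[f"effect_{row['condition']}"].to_numpy()
        log2[row["sample_id"]] = mean + rng.normal(
            0.0, config.replicate_sd, config.n_proteins
        )
    log2 = pd.DataFrame(log2, index=protein_ids)

    censored = log2.where(log2 >= config.detection_limit)
    if config.mcar_rate > 0:
        drop = rng.random(censored.shape) < config.mcar_rate
        censored = censored.mask(drop)
    raw = np.exp2(censored)

    flags = pd.DataFrame(
        {"contaminant": False, "reverse": False, "only_by_site": False},
        index=protein_ids,
    )
    return IntensityTable(raw, flags, design), truth


def _apportion(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder split of n items into the given fractions."""
    raw = np.asarray(fractions) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base.tolist()


# ---------------------------------------------------------------------------
# images


@dataclass(frozen=True)
class EllipseGeometry:
    """Elliptical cell mask: centre (row, col), semi-axes in px, angle.

    ``angle`` is the direction of the major axis in radians, measured
    from the +col (x) axis toward +row; the rear pole lies at
    centre + a * (cos angle, sin angle) in (col, row) terms.

    Default centres sit on half-integer coordinates so that for an
    axis-aligned ellipse no pixel lies exactly on the minor-axis
    plane: the rear and front halves then have exactly equal pixel
    counts and a planted step fold is recovered exactly.
    """

    center: tuple[float, float] = (127.5, 127.5)
    semi_major: float = 100.0
    semi_minor: float = 40.0
    angle: float = 0.0


@dataclass
class SynthImageTruth:
    rear_fold: float | None = None
    axis_angle: float | None = None
    dot_centres: list[tuple[float, float]] = field(default_factory=list)

    @property
    def dot_count(self) -> int:
        return len(self.dot_centres)


def _ellipse_mask(shape: tuple[int, int], geom: EllipseGeometry) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - geom.center[0]
    dc = cc - geom.center[1]
    # coordinates along / across the major axis
    u = dc * np.cos(geom.angle) + dr * np.sin(geom.angle)
    v = -dc * np.sin(geom.angle) + dr * np.cos(geom.angle)
    return (u / geom.semi_major) ** 2 + (v / geom.semi_minor) ** 2 <= 1.0


def _axis_coordinate(shape: tuple[int, int], geom: EllipseGeometry) -> np.ndarray:
    """Signed distance along the major axis; positive toward the rear pole."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - geom.center[0]
    dc = cc - geom.center[1]
    return dc * np.cos(geom.angle) + dr * np.sin(geom.angle)


def simulate_polarized_cell_image(
    shape: tuple[int, int] = (256, 256),
    mask_geometry: EllipseGeometry | None = None,
    rear_fold: float = 8.0,
    noise_model: Literal["none", "poisson", "gaussian"] = "none",
    seed: int | None = 0,
    front_level: float = 100.0,
    gaussian_sd: float = 5.0,
    profile: Literal["step", "ramp"] = "step",
) -> tuple[np.ndarray, np.ndarray, SynthImageTruth]:
    """Elliptical cell with a planted rear/front intensity fold.

    With ``profile="step"`` the rear half of the mask (along the major
    axis) has mean intensity ``rear_fold * front_level`` and the front
    half ``front_level``, so the rear/front mean ratio equals
    ``rear_fold`` exactly before noise. ``"ramp"`` interpolates
    linearly between the pole intensities instead.

    Returns (image float64, mask uint16 with label 1, truth).
    """
    if rear_fold <= 0:
        raise ConfigError("rear_fold must be > 0")
    geom = mask_geometry or EllipseGeometry(
        center=((shape[0] - 1) / 2, (shape[1] - 1) / 2),
        semi_major=min(shape) * 0.4,
        semi_minor=min(shape) * 0.16,
    )
    mask = _ellipse_mask(shape, geom)
    if not mask.any():
        raise ConfigError("mask does not intersect the image")
    if (
        geom.center[0] - geom.semi_major < -0.5
        or geom.center[0] + geom.semi_major > shape[0] - 0.5
    ) and (
        geom.center[1] - geom.semi_major < -0.5
        or geom.center[1] + geom.semi_major > shape[1] - 0.5
    ):
        raise ConfigError("mask larger than image")

    u = _axis_coordinate(shape, geom)
    image = np.zeros(shape, dtype=float)
    if profile == "step":
        rear = mask & (u > 0)
        front = mask & (u <= 0)
        image[rear] = front_level * rear_fold
        image[front] = front_level
    else:
        frac = np.clip((u + geom.semi_major) / (2 * geom.semi_major), 0, 1)
        image[mask] = front_level * (1 + (rear_fold - 1) * frac[mask])

    rng = np.random.default_rng(seed)
    if noise_model == "poisson":
        image = rng.poisson(image).astype(float)
    elif noise_model == "gaussian":
        image = image + rng.normal(0.0, gaussian_sd, shape)

    truth = SynthImageTruth(rear_fold=rear_fold, axis_angle=geom.angle)
    return image, mask.astype(np.uint16), truth


class PlacementError(RuntimeError):
    """Could not place the requested dots within the retry cap."""


def simulate_pla_image(
    shape: tuple[int, int] = (256, 256),
    mask_geometry: EllipseGeometry | None = None,
    n_dots: int = 12,
    dot_radius: float = 2.0,
    min_separation: float = 10.0,
    background: float = 10.0,
    amplitude: float = 200.0,
    noise_sd: float = 2.0,
    seed: int | None = 0,
    max_attempts: int = 10_000,
) -> tuple[np.ndarray, np.ndarray, SynthImageTruth]:
    """Proximity-ligation-assay fixture: Gaussian dots on a noisy background.

    Dot centres are drawn by rejection sampling inside the mask with a
    pairwise ``min_separation`` constraint (retry cap
    ``max_attempts``); the truth records the centres.
    """
    geom = mask_geometry or EllipseGeometry(
        center=((shape[0] - 1) / 2, (shape[1] - 1) / 2),
        semi_major=min(shape) * 0.4,
        semi_minor=min(shape) * 0.25,
    )
    mask = _ellipse_mask(shape, geom)
    rng = np.random.default_rng(seed)

    centres: list[tuple[float, float]] = []
    attempts = 0
    # keep centres a dot-radius clear of the mask edge so the full
    # Gaussian footprint stays inside the cell
    inner = EllipseGeometry(
        geom.center,
        max(geom.semi_major - 2 * dot_radius, 1.0),
        max(geom.semi_minor - 2 * dot_radius, 1.0),
        geom.angle,
    )
    inner_mask = _ellipse_mask(shape, inner)
    candidates = np.argwhere(inner_mask)
    if n_dots > 0 and len(candidates) == 0:
        raise PlacementError("mask too small for any dot")
    while len(centres) < n_dots:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed {len(centres)}/{n_dots} dots in {max_attempts} attempts"
            )
        attempts += 1
        r, c = candidates[rng.integers(len(candidates))] + rng.random(2) - 0.5
        if all(np.hypot(r - r0, c - c0) >= min_separation for r0, c0 in centres):
            centres.append((float(r), float(c)))

    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    image = np.full(shape, background, dtype=float)
    for r0, c0 in centres:
        image += amplitude * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * dot_radius**2)
        )
    if noise_sd > 0:
        image += rng.normal(0.0, noise_sd, shape)
    image = np.clip(image, 0, None)

    truth = SynthImageTruth(axis_angle=geom.angle, dot_centres=centres)
    return image, mask.astype(np.uint16), truth


# ---------------------------------------------------------------------------
# tracks


@dataclass(frozen=True)
class SynthTrackTruth:
    """Persistent-random-walk parameters.

    ``speed`` is the stationary RMS speed S (µm/min) and
    ``persistence`` the velocity correlation time P (min); the
    ensemble MSD follows the Fürth form
    2 S^2 P (t - P (1 - exp(-t/P))).
    Default speed matches the observed ~0.4 µm/min translocation
    rate of RPE1 cells.
    """

    speed: float = 0.4
    persistence: float = 10.0
    frame_interval: float = 5.0
    n_frames: int = 61

    def __post_init__(self) -> None:
        if self.speed < 0 or self.persistence <= 0 or self.frame_interval <= 0:
            raise ConfigError("require speed >= 0, persistence > 0, interval > 0")

    def furth_msd(self, lag: np.ndarray | float) -> np.ndarray | float:
        lag = np.asarray(lag, dtype=float)
        P = self.persistence
        return 2 * self.speed**2 * P * (lag - P * (1 - np.exp(-lag / P)))


def simulate_tracks(
    n_tracks: int,
    truth: SynthTrackTruth = SynthTrackTruth(),
    seed: int | None = 0,
) -> pd.DataFrame:
    """Simulate 2-D persistent random walks.

    Velocity follows a stationary Ornstein–Uhlenbeck process with
    per-component variance S^2/2 and correlation time P. Velocity and
    displacement over each frame are drawn from their exact joint
    Gaussian (integrated-OU) distribution, so the sampled positions
    carry no time-discretisation bias.

    Returns a tidy frame (track_id, frame, t_min, x_um, y_um).
    """
    if n_tracks < 1:
        raise ConfigError("n_tracks must be >= 1")
    rng = np.random.default_rng(seed)
    P = truth.persistence
    dt = truth.frame_interval
    sigma2 = truth.speed**2 / 2.0  # per-component stationary velocity variance

    x = dt / P
    mu = np.exp(-x)
    one_m_mu = -np.expm1(-x)       # 1 - e^-x without cancellation
    one_m_mu2 = -np.expm1(-2 * x)  # 1 - e^-2x
    var_v = sigma2 * one_m_mu2
    # x - 2(1-mu) + (1-mu^2)/2 ~ x^3/3 for x << 1; series guard keeps
    # the covariance positive semidefinite deep in the ballistic regime
    f = x - 2 * one_m_mu + one_m_mu2 / 2
    if x < 1e-4:
        f = x**3 / 3 - x**4 / 4
    var_x = 2 * sigma2 * P**2 * f
    cov_xv = sigma2 * P * one_m_mu**2
    cov = np.array([[var_x, cov_xv], [cov_xv, var_v]])
    chol = np.linalg.cholesky(cov + 1e-300 * np.eye(2))

    records = []
    for tid in range(n_tracks):
        v = rng.normal(0.0, np.sqrt(sigma2), size=2)
        pos = np.zeros(2)
        for frame in range(truth.n_frames):
            records.append(
                (tid, frame, frame * dt, pos[0], pos[1])
            )
            noise = chol @ rng.standard_normal((2, 2))  # (x/v) x (2 components)
            pos = pos + v * P * (1 - mu) + noise[0]
            v = v * mu + noise[1]
    return pd.DataFrame(
        records, columns=["track_id", "frame", "t_min", "x_um", "y_um"]
    )


# ---------------------------------------------------------------------------
# writers


def write_image(image: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint16))


def write_tracks(tracks: pd.DataFrame, path: str | Path) -> None:
    tracks.to_csv(path, index=False)


def write_truth(truth, path: str | Path) -> None:
    """Serialise any of the truth objects (or a truth DataFrame) to JSON."""
    if isinstance(truth, pd.DataFrame):
        payload = json.loads(truth.to_json(orient="index"))
    else:
        payload = asdict(truth)
    Path(path).write_text(json.dumps(payload, indent=1))
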