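"""Cell-migration track statistics: speed, displacement, MSD, PRW fits.

Tracks are tidy frames (track_id, frame, t_min, x_um, y_um), one row
per observation, as produced by manual nucleus tracking. Statistics
follow the common track-analysis conventions:

- speed = path length / duration (frame-to-frame polyline); the mean
  instantaneous step speed is also exposed since tracking packages
  differ on the default;
- MSD(tau) pools all overlapping ordered pairs at each lag across
  tracks (ensemble-time average), with pair counts reported;
- persistent-random-walk parameters (S, P) are recovered by nonlinear
  least squares on the Fürth form
  MSD(tau) = 2 S^2 P (tau - P (1 - exp(-tau/P))).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .proteomics import ConfigError, InputError

TRACK_COLUMNS = ["track_id", "frame", "t_min", "x_um", "y_um"]

P_UPPER_BOUND = 1e4  # min; fits hitting this bound are flagged ballistic


def read_tracks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"track table missing columns: {sorted(missing)}")
    return df[TRACK_COLUMNS]


def _per_track(tracks: pd.DataFrame):
    for tid, g in tracks.groupby("track_id", sort=True):
        g = g.sort_values("t_min")
        if not g["t_min"].is_monotonic_increasing or g["t_min"].duplicated().any():
            raise InputError(f"track {tid}: times not strictly increasing")
        yield tid, g


def normalize_tracks_to_origin(tracks: pd.DataFrame) -> pd.DataFrame:
    """Translate each track so its first sample is at (0, 0)."""
    out = []
    for _, g in _per_track(tracks):
        g = g.copy()
        g["x_um"] -= g["x_um"].iloc[0]
        g["y_um"] -= g["y_um"].iloc[0]
        out.append(g)
    return pd.concat(out, ignore_index=True)


@dataclass(frozen=True)
class TrackStats:
    track_id: object
    duration_min: float
    displacement_um: float
    path_length_um: float
    speed_um_per_min: float          # path length / duration
    mean_step_speed_um_per_min: float  # mean of per-step speeds
    straightness: float | None       # displacement / path length; None if stationary


def track_statistics(track: pd.DataFrame) -> TrackStats:
    """Summary statistics of one track (>= 2 samples required)."""
    if len(track) < 2:
        raise InputError("track needs >= 2 samples")
    g = track.sort_values("t_min")
    t = g["t_min"].to_numpy(float)
    xy = g[["x_um", "y_um"]].to_numpy(float)
    duration = t[-1] - t[0]
    if duration <= 0:
        raise InputError("track duration is zero")
    steps = np.diff(xy, axis=0)
    step_len = np.hypot(steps[:, 0], steps[:, 1])
    dts = np.diff(t)
    path = float(step_len.sum())
    disp = float(np.hypot(*(xy[-1] - xy[0])))
    return TrackStats(
        track_id=g["track_id"].iloc[0],
        duration_min=float(duration),
        displacement_um=disp,
        path_length_um=path,
        speed_um_per_min=path / duration,
        mean_step_speed_um_per_min=float(np.mean(step_len / dts)),
        straightness=(disp / path) if path > 0 else None,
    )


def all_track_statistics(tracks: pd.DataFrame) -> pd.DataFrame:
    rows = [vars(track_statistics(g)) for _, g in _per_track(tracks)]
    return pd.DataFrame(rows)


def msd(
    tracks: pd.DataFrame,
    max_lag: int | None = None,
    min_track_length: int = 3,
) -> pd.DataFrame:
    """Ensemble-time-averaged mean squared displacement.

    Requires a uniform frame interval within each track (shared across
    tracks). MSD at lag tau_j = j * dt averages |r(t+tau) - r(t)|^2
    over all overlapping ordered pairs of all tracks. Tracks shorter
    than ``min_track_length`` frames are excluded (their count is in
    ``.attrs["n_excluded"]``).

    Returns a frame (lag_min, msd_um2, n_pairs) including lag 0.
    """
    dt = None
    used = excluded = 0
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for tid, g in _per_track(tracks):
        t = g["t_min"].to_numpy(float)
        steps = np.diff(t)
        if len(steps) and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise InputError(
                f"track {tid}: non-uniform frame interval; resample before msd()"
            )
        if len(g) < min_track_length:
            excluded += 1
            continue
        if dt is None:
            dt = float(steps[0])
        elif not np.isclose(steps[0], dt, rtol=1e-6):
            raise InputError("tracks have differing frame intervals")
        used += 1
        xy = g[["x_um", "y_um"]].to_numpy(float)
        n = len(xy)
        top = n - 1 if max_lag is None else min(max_lag, n - 1)
        for j in range(1, top + 1):
            d = xy[j:] - xy[:-j]
            sums[j] = sums.get(j, 0.0) + float(np.sum(d[:, 0] ** 2 + d[:, 1] ** 2))
            counts[j] = counts.get(j, 0) + (n - j)
    if used == 0:
        raise InputError("no track long enough for MSD")
    lags = sorted(sums)
    out = pd.DataFrame(
        {
            "lag_min": [0.0] + [j * dt for j in lags],
            "msd_um2": [0.0] + [sums[j] / counts[j] for j in lags],
            "n_pairs": [0] + [counts[j] for j in lags],
        }
    )
    out.attrs["n_excluded"] = excluded
    return out


def furth_msd(lag: np.ndarray, speed: float, persistence: float) -> np.ndarray:
    """Fürth MSD of a 2-D persistent random walk."""
    lag = np.asarray(lag, dtype=float)
    P = persistence
    return 2 * speed**2 * P * (lag - P * (1 - np.exp(-lag / P)))


@dataclass(frozen=True)
class FurthFit:
    speed: float
    persistence: float
    residual_rms: float
    at_bound: bool  # persistence hit its upper bound (ballistic regime)


def fit_furth(msd_curve: pd.DataFrame) -> FurthFit:
    """Least-squares fit of the Fürth form to an MSD curve.

    Needs >= 5 positive-lag points with positive MSD. A persistence
    estimate at the documented upper bound (1e4 min) indicates the
    ballistic regime and is flagged rather than trusted.
    """
    pos = msd_curve[msd_curve["lag_min"] > 0]
    if len(pos) < 5 or not (pos["msd_um2"] > 0).any():
        raise ConfigError("need >= 5 positive lags with positive MSD")
    lag = pos["lag_min"].to_numpy(float)
    y = pos["msd_um2"].to_numpy(float)
    # moment-based start: slope at large lag ~ 2 S^2 P
    s0 = max(np.sqrt(y[-1] / max(lag[-1], 1e-9)), 1e-3)
    try:
        popt, _ = curve_fit(
            furth_msd,
            lag,
            y,
            p0=[s0, max(lag[1], 1.0)],
            bounds=([1e-9, 1e-6], [np.inf, P_UPPER_BOUND]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"Fürth fit did not converge on {len(lag)} lags "
            f"(msd range {y.min():.3g}–{y.max():.3g} µm²): {exc}"
        )
    speed, pers = float(popt[0]), float(popt[1])
    resid = float(np.sqrt(np.mean((furth_msd(lag, *popt) - y) ** 2)))
    return FurthFit(speed, pers, resid, at_bound=pers >= 0.99 * P_UPPER_BOUND)
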