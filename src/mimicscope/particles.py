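"""Group localizations into particles and summarize each cluster.

Clustering is flat-kernel mean shift on (x, y): every seed (occupied cell
of a bandwidth-sized grid) climbs to the mean of the points within one
bandwidth until it stops moving; modes closer than bandwidth/2 are merged
(highest-support mode wins) and every localization is assigned to its
nearest mode, so the clusters partition the input.

Within a cluster, consecutive-frame runs of localizations are linked into
binding events: a run of length k spans k·exposure of bright time, and
the gaps between runs are the dark times.  Cluster summaries report mean
and standard deviation of bright times, dark times, peak and centroid
wavelengths, spatial and spectral photons, the event count, a size
estimate (2·√2 × the RMS member-to-centroid distance — unbiased for a
uniformly sampled disc) and the aspect ratio √(λ₁/λ₂) of the position
covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "ParticleCluster",
    "mean_shift",
    "mean_shift_cluster",
    "link_events",
    "summarize_cluster",
    "clusters_to_frame",
]


@dataclass
class ParticleCluster:
    """One particle: member spectral fits plus summary statistics."""

    id: int
    members: pd.DataFrame = field(repr=False)
    centroid_nm: tuple[float, float] = (np.nan, np.nan)
    diameter_nm: float = np.nan
    aspect_ratio: float = np.nan
    n_events: int = 0
    bright_ms: tuple[float, float] = (np.nan, np.nan)  # mean, sd
    dark_ms: tuple[float, float] = (np.nan, np.nan)
    peak_nm: tuple[float, float] = (np.nan, np.nan)
    centroid_wavelength_nm: tuple[float, float] = (np.nan, np.nan)
    photons_spatial: tuple[float, float] = (np.nan, np.nan)
    photons_spectral: tuple[float, float] = (np.nan, np.nan)
    validated: bool = False
    single_member: bool = False

    @property
    def n_localizations(self) -> int:
        return len(self.members)


def mean_shift(
    xy: np.ndarray,
    bandwidth: float,
    max_iter: int = 300,
    tol_factor: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Flat-kernel mean shift.  Returns (modes, labels).

    Seeds are the means of occupied bandwidth-sized grid cells.  Modes
    within bandwidth/2 of a stronger (more supported) mode are merged.
    """
    xy = np.asarray(xy, float)
    if xy.size == 0:
        return np.empty((0, 2)), np.empty(0, int)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    tree = cKDTree(xy)
    cells = np.floor(xy / bandwidth).astype(np.int64)
    _, first = np.unique(cells, axis=0, return_index=True)
    seeds = np.stack([
        xy[(cells == cells[i]).all(axis=1)].mean(axis=0) for i in np.sort(first)
    ])
    tol = tol_factor * bandwidth
    modes = []
    support = []
    for seed in seeds:
        center = seed
        for _ in range(max_iter):
            idx = tree.query_ball_point(center, bandwidth)
            new = xy[idx].mean(axis=0)
            if np.linalg.norm(new - center) < tol:
                center = new
                break
            center = new
        modes.append(center)
        support.append(len(tree.query_ball_point(center, bandwidth)))
    modes = np.asarray(modes)
    order = np.argsort(support)[::-1]
    kept: list[np.ndarray] = []
    for i in order:
        if all(np.linalg.norm(modes[i] - m) >= bandwidth / 2 for m in kept):
            kept.append(modes[i])
    kept_arr = np.asarray(kept)
    _, labels = cKDTree(kept_arr).query(xy)
    # relabel so cluster ids are contiguous and ordered by first appearance
    used, labels = np.unique(labels, return_inverse=True)
    return kept_arr[used], labels


def mean_shift_cluster(fits: pd.DataFrame, bandwidth_nm: float = 100.0) -> list[ParticleCluster]:
    """Cluster QC-passed spectral fits into particles.

    Accepts a spectral-fit table (only rows with ``passed_qc`` are used if
    the column is present); returns unsummarized clusters partitioning
    the input localizations.
    """
    data = fits[fits["passed_qc"]] if "passed_qc" in fits.columns else fits
    if data.empty:
        return []
    modes, labels = mean_shift(data[["x_nm", "y_nm"]].to_numpy(), bandwidth_nm)
    clusters = []
    for k in range(len(modes)):
        members = data.iloc[np.nonzero(labels == k)[0]].copy()
        clusters.append(ParticleCluster(id=k, members=members))
    return clusters


def link_events(
    frames: np.ndarray, max_gap_frames: int = 0, exposure_ms: float = 50.0
) -> tuple[list[float], list[float]]:
    """Bright and dark times from member frame numbers.

    Runs of frames with inter-frame gaps ≤ max_gap_frames form one event
    whose bright time is (last − first + 1)·exposure; the gaps between
    events are the dark times.
    """
    f = np.unique(np.asarray(frames, int))
    if f.size == 0:
        return [], []
    breaks = np.nonzero(np.diff(f) > max_gap_frames + 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [f.size - 1]])
    bright = [(f[e] - f[s] + 1) * exposure_ms for s, e in zip(starts, ends)]
    dark = [
        (f[starts[i + 1]] - f[ends[i]] - 1) * exposure_ms for i in range(len(starts) - 1)
    ]
    return bright, dark


def _mean_sd(values) -> tuple[float, float]:
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return (np.nan, np.nan)
    if v.size == 1:
        return (float(v[0]), 0.0)
    return (float(v.mean()), float(v.std(ddof=1)))


def summarize_cluster(
    cluster: ParticleCluster,
    exposure_ms: float = 50.0,
    max_gap_frames: int = 0,
    min_events: int = 5,
) -> ParticleCluster:
    """Fill all summary statistics of a cluster in place (and return it)."""
    m = cluster.members
    xy = m[["x_nm", "y_nm"]].to_numpy()
    centroid = xy.mean(axis=0)
    cluster.centroid_nm = (float(centroid[0]), float(centroid[1]))
    r2 = ((xy - centroid) ** 2).sum(axis=1)
    cluster.diameter_nm = float(2.0 * np.sqrt(2.0) * np.sqrt(r2.mean()))
    cluster.single_member = len(m) < 2
    if len(m) >= 2:
        cov = np.cov(xy.T)
        ev = np.sort(np.linalg.eigvalsh(cov))
        cluster.aspect_ratio = float(np.sqrt(ev[1] / ev[0])) if ev[0] > 0 else np.inf
    else:
        cluster.aspect_ratio = 1.0
    bright, dark = link_events(m["frame"].to_numpy(), max_gap_frames, exposure_ms)
    cluster.n_events = len(bright)
    cluster.bright_ms = _mean_sd(bright)
    cluster.dark_ms = _mean_sd(dark)
    if "peak_nm" in m:
        cluster.peak_nm = _mean_sd(m["peak_nm"])
    if "centroid_nm" in m:
        cluster.centroid_wavelength_nm = _mean_sd(m["centroid_nm"])
    if "photons" in m:
        cluster.photons_spatial = _mean_sd(m["photons"])
    if "photons_spectral" in m:
        cluster.photons_spectral = _mean_sd(m["photons_spectral"])
    cluster.validated = cluster.n_events >= min_events
    return cluster


def clusters_to_frame(clusters: list[ParticleCluster]) -> pd.DataFrame:
    """One row per cluster with every summary field (CSV-ready)."""
    rows = []
    for c in clusters:
        rows.append(
            {
                "cluster_id": c.id,
                "x_nm": c.centroid_nm[0],
                "y_nm": c.centroid_nm[1],
                "diameter_nm": c.diameter_nm,
                "aspect_ratio": c.aspect_ratio,
                "n_localizations": c.n_localizations,
                "n_events": c.n_events,
                "bright_mean_ms": c.bright_ms[0],
                "bright_sd_ms": c.bright_ms[1],
                "dark_mean_ms": c.dark_ms[0],
                "dark_sd_ms": c.dark_ms[1],
                "peak_mean_nm": c.peak_nm[0],
                "peak_sd_nm": c.peak_nm[1],
                "centroid_mean_nm": c.centroid_wavelength_nm[0],
                "centroid_sd_nm": c.centroid_wavelength_nm[1],
                "photons_spatial_mean": c.photons_spatial[0],
                "photons_spatial_sd": c.photons_spatial[1],
                "photons_spectral_mean": c.photons_spectral[0],
                "photons_spectral_sd": c.photons_spectral[1],
                "validated": c.validated,
            }
        )
    return pd.DataFrame(rows)
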