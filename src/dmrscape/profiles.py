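"""Global methylome summaries: per-feature and windowed mean methylation,
methylation-level category proportions, sample ordination and centroid
distances."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .config import AnalysisConfig, DEFAULT_CONFIG
from .genome_io import ChromSizes, MethylationTrack, merge_intervals

log = logging.getLogger(__name__)


def mean_methylation_over_intervals(intervals: pd.DataFrame,
                                    track: MethylationTrack) -> float:
    """Unweighted mean CpG methylation over a feature set.

    The intervals are merged first, so a CpG under overlapping features
    counts exactly once. Returns NaN when no CpG is covered.
    """
    merged = merge_intervals(intervals)
    if merged.empty:
        return float("nan")
    levels = []
    for chrom, sub in merged.groupby("chrom", sort=False):
        track_sub = track.cpgs[track.cpgs["chrom"] == chrom]
        if track_sub.empty:
            continue
        pos = track_sub["pos"].to_numpy()
        lv = track_sub["level"].to_numpy()
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            lo, hi = np.searchsorted(pos, [s, e])
            if hi > lo:
                levels.append(lv[lo:hi])
    if not levels:
        log.warning("no CpG covered by the interval set for %s", track.sample_id)
        return float("nan")
    return float(np.concatenate(levels).mean())


def methylation_category_proportions(track: MethylationTrack,
                                     config: AnalysisConfig = DEFAULT_CONFIG) -> dict:
    """Fractions of CpGs that are lowly (< 30%), intermediately (30%-70%)
    and highly (> 70%) methylated, plus the genome-wide mean level."""
    lv = track.cpgs["level"].to_numpy()
    if lv.size == 0:
        raise ValueError("empty methylation track")
    low = float(np.mean(lv < config.meth_low))
    high = float(np.mean(lv > config.meth_high))
    return {"low": low, "intermediate": 1.0 - low - high, "high": high,
            "mean": float(lv.mean())}


def build_window_matrix(tracks: dict[str, MethylationTrack],
                        chrom_sizes: ChromSizes, width: int = 1000) -> pd.DataFrame:
    """Windows x samples matrix of mean CpG methylation.

    Non-overlapping windows of ``width`` bp tile every chromosome; windows
    that no sample's track covers with a CpG are absent. The index is a
    (chrom, start) MultiIndex.
    """
    cols = {}
    for sid, track in tracks.items():
        parts = []
        for chrom, sub in track.cpgs.groupby("chrom", sort=False):
            if chrom not in chrom_sizes:
                continue
            win = sub["pos"].to_numpy() // width * width
            parts.append(pd.Series(sub["level"].to_numpy(),
                                   index=pd.MultiIndex.from_arrays(
                                       [np.repeat(chrom, len(sub)), win]))
                         .groupby(level=[0, 1]).mean())
        cols[sid] = pd.concat(parts) if parts else pd.Series(dtype=float)
    mat = pd.DataFrame(cols)
    mat.index.names = ["chrom", "start"]
    return mat.sort_index()


def _scale_windows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop zero-variance windows, then center and scale each window across
    samples (rows become mean 0, sd 1)."""
    values = matrix.to_numpy(float)
    sd = values.std(axis=1, ddof=0)
    keep = sd > 0
    values = values[keep]
    scaled = (values - values.mean(axis=1, keepdims=True)) / sd[keep, None]
    return pd.DataFrame(scaled, index=matrix.index[keep], columns=matrix.columns)


def centroid_distances(matrix: pd.DataFrame, group_labels: dict[str, str]):
    """Per-sample Euclidean distance to its group centroid in PC space.

    Zero-variance windows are dropped, each window is centered and scaled
    across samples, samples are projected onto principal components (all of
    them, so distances are rotation-invariant), group centroids are the
    per-component group means, and distances are taken over all components.

    Returns ``(distances, explained_variance_ratio)`` where ``distances`` is
    a frame with sample/group/distance/degenerate (True for singleton
    groups, whose distance is 0 by construction).
    """
    scaled = _scale_windows(matrix)
    X = scaled.to_numpy().T  # samples x windows
    n_comp = min(X.shape)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    samples = list(scaled.columns)
    groups = pd.Series([group_labels[s] for s in samples], index=samples)
    rows = []
    for g, idx in groups.groupby(groups).groups.items():
        sel = [samples.index(s) for s in idx]
        centroid = scores[sel].mean(axis=0)
        for s, i in zip(idx, sel):
            dist = float(np.linalg.norm(scores[i] - centroid))
            rows.append((s, g, dist, len(sel) == 1))
    out = pd.DataFrame(rows, columns=["sample", "group", "distance", "degenerate"])
    if out["degenerate"].any():
        log.warning("singleton group(s) present; their distances are 0 by construction")
    return out.set_index("sample").loc[samples].reset_index(), pca.explained_variance_ratio_


def sample_correlation_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation distance (1 - r) between all sample pairs across
    windows; zero-variance samples get NaN entries with a warning."""
    corr = matrix.corr(method="pearson")
    sd = matrix.std(ddof=0)
    flat = sd[sd == 0].index
    if len(flat):
        log.warning("zero-variance samples %s: correlation undefined", list(flat))
    arr = (1.0 - corr).to_numpy()
    np.fill_diagonal(arr, 0.0)
    return pd.DataFrame(arr, index=corr.index, columns=corr.columns)
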