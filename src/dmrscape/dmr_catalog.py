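"""Sample-comparison enumeration, DMR call ingestion, Q-threshold calibration,
and the position-stable recurrence catalogue.

The catalogue merges the union of all called 500-bp bins into blocks of
genomically adjacent bins and assigns each bin a two-part identifier
``B<block>.<position-within-block>``. Identifiers depend only on the set of
called bins, never on the order in which comparisons are ingested.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig, DEFAULT_CONFIG, chrom_sort_key
from .genome_io import BinGrid, MethylationTrack, SampleRecord

log = logging.getLogger(__name__)

CALL_COLUMNS = ["comparison_id", "chrom", "bin", "start", "end", "q_value", "direction"]


@dataclass(frozen=True)
class ComparisonSpec:
    """An ordered pair of samples submitted to the upstream DMR caller.

    ``kind``: "matched" (same patient, normal vs tumor), "normal_normal"
    (unordered normal pair in canonical order), or "cross" (normal and tumor
    from different patients).
    """

    comparison_id: str
    sample_ref: SampleRecord
    sample_alt: SampleRecord
    kind: str

    @property
    def patient_id(self) -> str:
        """Patient whose tumor drives a matched comparison."""
        return self.sample_alt.patient_id


def enumerate_comparisons(manifest: list[SampleRecord],
                          include_matched_in_cross: bool = False) -> list[ComparisonSpec]:
    """Enumerate matched, normal-normal, and cross sample comparisons.

    matched: one per patient with both a normal and a tumor sample;
    normal_normal: all unordered pairs of normals; cross: all
    (normal, tumor) pairs from different patients. With
    ``include_matched_in_cross`` the cross set is all normal x tumor pairs.
    """
    normals = sorted((r for r in manifest if r.malignancy == "normal"),
                     key=lambda r: r.sample_id)
    tumors = sorted((r for r in manifest if r.malignancy == "tumor"),
                    key=lambda r: r.sample_id)
    by_patient_normal = {}
    for r in normals:
        if r.patient_id in by_patient_normal:
            raise ValueError(f"patient {r.patient_id} has two normal samples")
        by_patient_normal[r.patient_id] = r
    specs: list[ComparisonSpec] = []
    for t in tumors:
        n = by_patient_normal.get(t.patient_id)
        if n is not None:
            specs.append(ComparisonSpec(f"matched:{t.patient_id}", n, t, "matched"))
    for a, b in itertools.combinations(normals, 2):
        specs.append(ComparisonSpec(f"nn:{a.sample_id}|{b.sample_id}", a, b, "normal_normal"))
    for n, t in itertools.product(normals, tumors):
        if not include_matched_in_cross and n.patient_id == t.patient_id:
            continue
        specs.append(ComparisonSpec(f"cross:{n.sample_id}|{t.sample_id}", n, t, "cross"))
    return specs


def load_dmr_calls(path, comparison_id: str,
                   config: AnalysisConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Load one comparison's DMR call table (chrom, start, end, q[, stat]).

    Bins must be exactly ``bin_width`` wide; a call whose interval is the
    right width but off-grid is snapped to the nearest bin with a warning,
    anything else is rejected with a warning. The optional signed statistic
    gives a provisional direction (positive = gain in the alt sample), which
    :func:`assign_direction` overrides when methylation tracks are available.
    """
    from .genome_io import normalize_chrom

    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "q_value", "stat"],
                     usecols=range(5), dtype={0: str},
                     skip_blank_lines=True).dropna(subset=["chrom", "start", "end", "q_value"])
    width = config.bin_width
    rows = []
    n_rej = 0
    for r in df.itertuples(index=False):
        start, end = int(r.start), int(r.end)
        if end - start != width:
            n_rej += 1
            continue
        if start % width != 0:
            start = int(round(start / width)) * width
            log.warning("%s: off-grid call snapped to bin starting %d", path, start)
        q = float(r.q_value)
        if not (0.0 <= q <= 1.0):
            raise ValueError(f"{path}: q value {q} outside [0, 1]")
        stat = float(r.stat) if pd.notna(r.stat) else np.nan
        direction = "unset"
        if np.isfinite(stat) and stat != 0:
            direction = "hyper" if stat > 0 else "hypo"
        rows.append((comparison_id, normalize_chrom(r.chrom), start // width,
                     start, start + width, q, direction))
    if n_rej:
        log.warning("%s: rejected %d calls with width != %d bp", path, n_rej, width)
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def _bin_means(track: MethylationTrack, chrom: str, bins: np.ndarray,
               width: int) -> np.ndarray:
    """Mean CpG methylation per requested bin; NaN where the track has no CpG."""
    sub = track.cpgs[track.cpgs["chrom"] == chrom]
    if sub.empty:
        return np.full(len(bins), np.nan)
    idx = sub["pos"].to_numpy() // width
    means = pd.Series(sub["level"].to_numpy()).groupby(idx).mean()
    return means.reindex(bins).to_numpy()


def assign_direction(calls: pd.DataFrame, track_ref: MethylationTrack,
                     track_alt: MethylationTrack,
                     config: AnalysisConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Direction of methylation change from the two samples' tracks.

    A bin whose mean CpG level in the alt (tumor) sample is below the ref
    (normal) sample is ``hypo``, above is ``hyper``, equal is ``ambiguous``.
    Also records ``delta`` = alt - ref mean. A bin with no CpG in either
    track is an error: such a bin should not exist on the grid.
    """
    calls = calls.copy()
    calls["delta"] = np.nan
    for chrom, sub in calls.groupby("chrom", sort=False):
        bins = sub["bin"].to_numpy()
        ref = _bin_means(track_ref, chrom, bins, config.bin_width)
        alt = _bin_means(track_alt, chrom, bins, config.bin_width)
        if np.isnan(ref).any() or np.isnan(alt).any():
            raise ValueError(f"call bin on {chrom} has no CpG in one of the tracks")
        calls.loc[sub.index, "delta"] = alt - ref
    delta = calls["delta"].to_numpy()
    calls["direction"] = np.select([delta < 0, delta > 0], ["hypo", "hyper"], "ambiguous")
    return calls


def filter_calls(calls: pd.DataFrame, config: AnalysisConfig = DEFAULT_CONFIG,
                 bin_grid: BinGrid | None = None) -> pd.DataFrame:
    """Apply the downstream inclusion rules to a combined call table.

    Keeps calls with q strictly below the threshold, drops the excluded
    chromosomes (Y), and drops blacklisted or CpG-free bins when a grid is
    supplied (i.e. restricts to the background universe).
    """
    if calls.empty:
        return calls.copy()
    keep = calls["q_value"].to_numpy() < config.q_threshold
    keep &= ~calls["chrom"].isin(config.excluded_dmr_chroms).to_numpy()
    if bin_grid is not None:
        keep &= np.array([bin_grid.is_background(c, b)
                          for c, b in zip(calls["chrom"], calls["bin"])])
    return calls[keep].reset_index(drop=True)


def calibrate_q_threshold(all_calls: pd.DataFrame, comparisons: list[ComparisonSpec],
                          tracks: dict[str, MethylationTrack] | None = None,
                          config: AnalysisConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Per-threshold diagnostics used to pick the working Q cutoff.

    For each grid threshold and matched comparison: the false-positive ratio
    (mean number of DMRs between that patient's normal and every other
    normal, divided by the number of patient-matched DMRs), the fraction of
    matched DMR instances whose bin is called in more than one matched
    comparison, and the fraction of matched DMRs whose absolute methylation
    change exceeds ``config.large_change`` (tracks required). A cohort-mean
    row per threshold is appended with comparison_id "cohort_mean".
    """
    matched = [c for c in comparisons if c.kind == "matched"]
    nn = [c for c in comparisons if c.kind == "normal_normal"]
    calls_by_comp = dict(tuple(all_calls.groupby("comparison_id", sort=False)))
    empty = all_calls.iloc[0:0]
    rows = []
    for thr in sorted(config.q_calibration_grid, reverse=True):
        per_comp = []
        # bins surviving the threshold per matched comparison
        surv = {}
        for c in matched:
            sub = calls_by_comp.get(c.comparison_id, empty)
            surv[c.comparison_id] = sub[sub["q_value"] < thr]
        bin_counts = pd.concat(
            [s[["chrom", "bin"]] for s in surv.values()], ignore_index=True
        ).value_counts() if any(len(s) for s in surv.values()) else pd.Series(dtype=int)
        for comp in matched:
            mine = surv[comp.comparison_id]
            n_matched = len(mine)
            normal_id = comp.sample_ref.sample_id
            nn_counts = []
            for other in nn:
                ids = {other.sample_ref.sample_id, other.sample_alt.sample_id}
                if normal_id in ids:
                    sub = calls_by_comp.get(other.comparison_id, empty)
                    nn_counts.append(int((sub["q_value"] < thr).sum()))
            fpr = (float(np.mean(nn_counts)) / n_matched) if (n_matched and nn_counts) else (
                0.0 if n_matched else np.nan)
            if n_matched:
                keys = list(zip(mine["chrom"], mine["bin"]))
                shared = float(np.mean([bin_counts.get(k, 0) > 1 for k in keys]))
            else:
                shared = np.nan
            large = np.nan
            if tracks is not None and n_matched:
                with_dir = assign_direction(
                    mine, tracks[comp.sample_ref.sample_id],
                    tracks[comp.sample_alt.sample_id], config)
                large = float(np.mean(np.abs(with_dir["delta"]) > config.large_change))
            per_comp.append((thr, comp.comparison_id, n_matched, fpr, shared, large))
        rows.extend(per_comp)
        arr = np.array([[r[3], r[4], r[5]] for r in per_comp], dtype=float)
        means = [float(np.nanmean(col)) if len(col) and np.isfinite(col).any() else np.nan
                 for col in (arr.T if len(arr) else np.empty((3, 0)))]
        rows.append((thr, "cohort_mean", int(sum(r[2] for r in per_comp)),
                     means[0], means[1], means[2]))
    return pd.DataFrame(rows, columns=["q_threshold", "comparison_id", "n_matched_dmrs",
                                       "fpr_ratio", "shared_fraction",
                                       "large_change_fraction"])


def build_catalog(filtered_calls: pd.DataFrame,
                  comparisons: list[ComparisonSpec] | None = None) -> "DMRCatalog":
    """Assign position-stable unique IDs and tabulate recurrence.

    The union of called bins is grouped into blocks of genomically adjacent
    bins; blocks are numbered 1..K in karyotype order and bins within a block
    5'->3'. Recurrence is counted per direction over matched comparisons.
    """
    bins = (filtered_calls[["chrom", "bin"]].drop_duplicates()
            .assign(_key=lambda d: d["chrom"].map(chrom_sort_key))
            .sort_values(["_key", "bin"]).drop(columns="_key").reset_index(drop=True))
    if bins.empty:
        catalog = pd.DataFrame(columns=["dmr_id", "chrom", "bin", "start", "end",
                                        "block_id", "block_pos"])
        obs = filtered_calls.iloc[0:0].assign(dmr_id=pd.Series(dtype=str))
        return DMRCatalog(catalog, obs.reindex(columns=["dmr_id", *CALL_COLUMNS]))
    new_block = np.ones(len(bins), dtype=bool)
    same_chrom = bins["chrom"].to_numpy()[1:] == bins["chrom"].to_numpy()[:-1]
    adjacent = bins["bin"].to_numpy()[1:] == bins["bin"].to_numpy()[:-1] + 1
    new_block[1:] = ~(same_chrom & adjacent)
    block_id = np.cumsum(new_block)
    pos = np.arange(len(bins)) - np.maximum.accumulate(
        np.where(new_block, np.arange(len(bins)), 0)) + 1
    width = int((filtered_calls["end"] - filtered_calls["start"]).iloc[0])
    catalog = bins.assign(
        block_id=block_id, block_pos=pos,
        dmr_id=[f"B{b}.{p}" for b, p in zip(block_id, pos)],
        start=bins["bin"] * width, end=(bins["bin"] + 1) * width,
    )[["dmr_id", "chrom", "bin", "start", "end", "block_id", "block_pos"]]
    id_map = {(c, b): i for c, b, i in zip(catalog["chrom"], catalog["bin"],
                                           catalog["dmr_id"])}
    obs = filtered_calls.copy()
    obs.insert(0, "dmr_id", [id_map[(c, b)] for c, b in zip(obs["chrom"], obs["bin"])])
    return DMRCatalog(catalog, obs, comparisons)


@dataclass
class DMRCatalog:
    """Unique DMRs plus their per-comparison observations.

    ``dmrs``: one row per unique DMR (dmr_id, chrom, bin, start, end,
    block_id, block_pos). ``observations``: one row per (DMR, comparison)
    call with direction. ``comparisons`` optionally carries the enumeration
    used, so recurrence can be restricted to matched comparisons.
    """

    dmrs: pd.DataFrame
    observations: pd.DataFrame
    comparisons: list[ComparisonSpec] | None = None

    def matched_observations(self) -> pd.DataFrame:
        obs = self.observations
        if self.comparisons is None:
            return obs[obs["comparison_id"].str.startswith("matched:")]
        matched_ids = {c.comparison_id for c in self.comparisons if c.kind == "matched"}
        return obs[obs["comparison_id"].isin(matched_ids)]

    def recurrence(self) -> pd.DataFrame:
        """Per (dmr_id, direction): number of matched comparisons calling it."""
        obs = self.matched_observations()
        obs = obs[obs["direction"].isin(["hypo", "hyper"])]
        rec = (obs.groupby(["dmr_id", "direction"])["comparison_id"]
               .nunique().rename("n_comparisons").reset_index())
        return rec

    def recurrence_histogram(self) -> pd.DataFrame:
        """Counts of unique DMRs by (direction, number of sharing patients)."""
        rec = self.recurrence()
        return (rec.groupby(["direction", "n_comparisons"]).size()
                .rename("n_dmrs").reset_index())

    def intervals(self) -> pd.DataFrame:
        return self.dmrs[["chrom", "start", "end", "dmr_id"]].copy()
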