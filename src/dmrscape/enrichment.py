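"""DMR annotation against features, repeats and chromatin states, with
log-odds-ratio enrichment statistics and repeat-evolution quantities.

All enrichments compare an observed overlap proportion among DMRs with a
background proportion (bins or base pairs) on the natural-log odds scale:
``lor = ln[(pD/(1-pD)) / (pB/(1-pB))]``. When a cell of the implied 2x2
table is zero, a Haldane-Anscombe +0.5 correction is applied to all four
cells so the LOR stays finite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig, DEFAULT_CONFIG
from .genome_io import MethylationTrack, merge_intervals, overlap_any, overlap_query

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentRecord:
    """Observed vs background overlap for one annotation unit."""

    unit_name: str
    dmr_count: int
    dmr_total: int
    background_measure: float
    background_total: float
    lor: float

    @property
    def dmr_fraction(self) -> float:
        return self.dmr_count / self.dmr_total

    @property
    def background_fraction(self) -> float:
        return self.background_measure / self.background_total


def _lor_from_counts(a: float, b: float, c: float, d: float) -> float:
    # a/b: DMR in/out, c/d: background in/out
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return math.log((a / b) / (c / d))


def log_odds_ratio(p_dmr: float, p_background: float) -> float:
    """LOR of two proportions; both must lie strictly inside (0, 1)."""
    return math.log((p_dmr / (1 - p_dmr)) / (p_background / (1 - p_background)))


def feature_lor(dmr_bins: pd.DataFrame, feature_intervals: pd.DataFrame,
                background_bins: pd.DataFrame, unit_name: str = "") -> EnrichmentRecord:
    """Bin-level enrichment of DMRs over a feature vs the background bins.

    ``dmr_bins`` and ``background_bins`` are interval frames of 500-bp bins;
    the proportion of each overlapping the feature set (>= 1 bp) forms the
    2x2 table.
    """
    if dmr_bins.empty:
        raise ValueError("empty DMR set")
    a = int(overlap_any(dmr_bins, feature_intervals).sum())
    c = int(overlap_any(background_bins, feature_intervals).sum())
    n_d, n_b = len(dmr_bins), len(background_bins)
    return EnrichmentRecord(unit_name, a, n_d, c, n_b,
                            _lor_from_counts(a, n_d - a, c, n_b - c))


def classify_exclusive_feature(dmrs: pd.DataFrame, promoters: pd.DataFrame,
                               genes: pd.DataFrame) -> pd.Series:
    """Mutually exclusive feature category per DMR.

    Precedence promoter > genic > intergenic; any 1-bp overlap counts.
    """
    in_prom = overlap_any(dmrs, promoters)
    in_gene = overlap_any(dmrs, genes)
    cat = np.where(in_prom, "promoter", np.where(in_gene, "genic", "intergenic"))
    return pd.Series(cat, index=dmrs.index, name="feature_category")


def repeat_class_composition(dmr_overlapping_repeats: pd.DataFrame,
                             all_repeats: pd.DataFrame,
                             by: str = "elements") -> pd.DataFrame:
    """Class distribution of repeats genome-wide vs those overlapping DMRs.

    ``by="elements"`` counts repeat copies; ``by="bases"`` weights by element
    length. Both distributions are normalised to sum to 1.
    """
    def dist(df: pd.DataFrame) -> pd.Series:
        if df.empty:
            return pd.Series(dtype=float)
        if by == "bases":
            w = (df["end"] - df["start"]).groupby(df["repeat_class"]).sum()
        else:
            w = df.groupby("repeat_class").size()
        return w / w.sum()

    genome = dist(all_repeats)
    dmr = dist(dmr_overlapping_repeats)
    if dmr.empty:
        log.warning("no DMR-overlapping repeats; DMR composition empty")
    out = pd.DataFrame({"genome": genome, "dmr": dmr}).fillna(0.0)
    out.index.name = "repeat_class"
    return out.reset_index()


def repeat_subfamily_lor(dmrs: pd.DataFrame, subfamily: str,
                         all_repeats: pd.DataFrame) -> EnrichmentRecord:
    """Enrichment of a DMR set over one repeat subfamily.

    Observed: fraction of DMRs overlapping >= 1 element of the subfamily.
    Background: the subfamily's share of total repeat length (bp). The
    background odds use the bp proportion directly; the continuity
    correction applies to the DMR counts when they are degenerate.
    """
    if dmrs.empty:
        raise ValueError("empty DMR set")
    elements = all_repeats[all_repeats["subfamily"] == subfamily]
    sub_bp = int((elements["end"] - elements["start"]).sum())
    tot_bp = int((all_repeats["end"] - all_repeats["start"]).sum())
    if sub_bp == 0:
        raise ValueError(f"subfamily {subfamily!r} has zero total length")
    k = int(overlap_any(dmrs, elements).sum())
    n = len(dmrs)
    p_b = sub_bp / tot_bp
    if k == 0 or k == n:
        p_d = (k + 0.5) / (n + 1.0)
    else:
        p_d = k / n
    return EnrichmentRecord(subfamily, k, n, sub_bp, tot_bp,
                            log_odds_ratio(p_d, p_b))


def subfamily_enrichment_table(dmrs_by_direction: dict[str, pd.DataFrame],
                               all_repeats: pd.DataFrame,
                               config: AnalysisConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """LOR per (subfamily, direction), reporting only subfamilies overlapping
    more than ``config.min_subfamily_dmrs`` DMRs in that direction."""
    rows = []
    for direction, dmrs in dmrs_by_direction.items():
        if dmrs.empty:
            continue
        hits = overlap_query(dmrs, all_repeats)
        if hits.empty:
            continue
        hits = hits.assign(subfamily=all_repeats["subfamily"].to_numpy()[hits["subject_index"]])
        counts = hits.groupby("subfamily")["query_index"].nunique()
        for subfamily, k in counts.items():
            if k <= config.min_subfamily_dmrs:
                continue
            rec = repeat_subfamily_lor(dmrs, subfamily, all_repeats)
            rows.append((direction, subfamily, rec.dmr_count, rec.dmr_total,
                         rec.background_fraction, rec.lor))
    return pd.DataFrame(rows, columns=["direction", "subfamily", "n_dmrs",
                                       "dmr_total", "bp_fraction", "lor"])


def jukes_cantor_distance(p):
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) for substitution
    proportion p; NaN (excluded, with a warning) where p >= 0.75."""
    p = np.asarray(p, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    out = np.full(p.shape, np.nan)
    valid = (p >= 0) & (p < 0.75)
    out[valid] = -0.75 * np.log1p(-4.0 * p[valid] / 3.0)
    n_bad = int((~valid & np.isfinite(p)).sum())
    if n_bad:
        log.warning("%d elements with substitution proportion >= 0.75 excluded", n_bad)
    return float(out[0]) if scalar else out


def subfamily_jukes_cantor(all_repeats: pd.DataFrame) -> pd.Series:
    """Median Jukes-Cantor distance per subfamily (elements lacking a
    divergence value, or diverged beyond the model's domain, are excluded)."""
    d = jukes_cantor_distance(all_repeats["subst_prop"].to_numpy())
    return (pd.Series(d, index=all_repeats["subfamily"].to_numpy())
            .dropna().groupby(level=0).median().rename("median_jc_distance"))


def subfamily_methylation_profile(subfamily: str, all_repeats: pd.DataFrame,
                                  tracks: dict[str, MethylationTrack],
                                  manifest=None,
                                  config: AnalysisConfig = DEFAULT_CONFIG):
    """Per-sample mean methylation over a subfamily's unique CpGs.

    CpGs shared by overlapping elements count once. Subfamilies covering
    fewer than ``config.min_subfamily_cpgs`` CpGs are excluded (returns
    None). When a manifest is given, also reports the median normal level,
    the median matched tumor-normal change, and the spread (standard
    deviation) of normal-sample means.
    """
    elements = merge_intervals(all_repeats[all_repeats["subfamily"] == subfamily])
    if elements.empty:
        return None
    any_track = next(iter(tracks.values()))
    cpg = any_track.cpgs[["chrom", "pos"]].copy()
    cpg["start"] = cpg["pos"]
    cpg["end"] = cpg["pos"] + 1
    inside = overlap_any(cpg, elements)
    if int(inside.sum()) < config.min_subfamily_cpgs:
        return None
    keys = set(map(tuple, cpg.loc[inside, ["chrom", "pos"]].to_numpy()))
    means = {}
    for sid, track in tracks.items():
        mask = [(c, p) in keys for c, p in zip(track.cpgs["chrom"], track.cpgs["pos"])]
        sel = track.cpgs.loc[mask, "level"]
        means[sid] = float(sel.mean()) if len(sel) else np.nan
    result = {"subfamily": subfamily, "n_cpgs": int(inside.sum()),
              "sample_means": means}
    if manifest is not None:
        by_id = {r.sample_id: r for r in manifest}
        normals = [v for k, v in means.items()
                   if k in by_id and by_id[k].malignancy == "normal"]
        result["normal_median"] = float(np.median(normals)) if normals else np.nan
        result["normal_spread"] = float(np.std(normals)) if normals else np.nan
        deltas = []
        tumors = {by_id[k].patient_id: v for k, v in means.items()
                  if k in by_id and by_id[k].malignancy == "tumor"}
        for k, v in means.items():
            r = by_id.get(k)
            if r and r.malignancy == "normal" and r.patient_id in tumors:
                deltas.append(tumors[r.patient_id] - v)
        result["change_median"] = float(np.median(deltas)) if deltas else np.nan
    return result


# ---------------------------------------------------------------------------
# chromatin states
# ---------------------------------------------------------------------------

ACTIVE_STATES = {"15-state": frozenset({1, 2, 3, 6, 7}),
                 "18-state": frozenset({1, 2, 3, 4, 7, 8, 9, 10, 11})}
TRANSCRIBED_STATES_18 = frozenset({5, 6})
POLYCOMB_STATES_18 = frozenset({14, 15, 16, 17})
N_STATES = {"15-state": 15, "18-state": 18}


def _state_number(state: str) -> int:
    head = str(state).split("_", 1)[0]
    if not head.isdigit():
        raise ValueError(f"unparseable chromatin state label {state!r}")
    return int(head)


def map_composite_state(state: str, model: str = "18-state") -> str:
    """Composite class of a ChromHMM state label such as ``14_TssBiv``.

    active_regulatory: states 1-3 and 6-7 (15-state) or 1-4 and 7-11
    (18-state); transcribed: 5-6 and polycomb: 14-17 (18-state model only);
    everything else is other.
    """
    if model not in N_STATES:
        raise ValueError(f"unknown ChromHMM model {model!r}")
    n = _state_number(state)
    if not 1 <= n <= N_STATES[model]:
        raise ValueError(f"state {state!r} outside the {model} vocabulary")
    if n in ACTIVE_STATES[model]:
        return "active_regulatory"
    if model == "18-state":
        if n in TRANSCRIBED_STATES_18:
            return "transcribed"
        if n in POLYCOMB_STATES_18:
            return "polycomb"
    return "other"


def chromhmm_composition(dmrs: pd.DataFrame, segmentation: pd.DataFrame,
                         background_bins: pd.DataFrame) -> pd.DataFrame:
    """Base-level ChromHMM state composition of a DMR set vs background.

    Per state: the fraction of DMR bases annotated with that state and the
    same fraction over background bins, with fold and LOR enrichment. Bases
    covered by no segment are reported as ``unannotated``; each side's
    proportions (including unannotated) sum to 1.
    """
    def base_counts(intervals: pd.DataFrame) -> tuple[pd.Series, int]:
        total = int((intervals["end"] - intervals["start"]).sum())
        hits = overlap_query(intervals, segmentation)
        if hits.empty:
            by_state = pd.Series(dtype=float)
        else:
            states = segmentation["state"].to_numpy()[hits["subject_index"]]
            by_state = hits.groupby(states)["overlap"].sum().astype(float)
        by_state["unannotated"] = total - float(by_state.sum())
        return by_state, total

    d, nd = base_counts(dmrs)
    b, nb = base_counts(background_bins)
    out = pd.DataFrame({"dmr_bases": d, "background_bases": b}).fillna(0.0)
    out["dmr_fraction"] = out["dmr_bases"] / nd
    out["background_fraction"] = out["background_bases"] / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        out["fold"] = out["dmr_fraction"] / out["background_fraction"]
    out["lor"] = [_lor_from_counts(a, nd - a, c, nb - c)
                  for a, c in zip(out["dmr_bases"], out["background_bases"])]
    out.index.name = "state"
    return out.reset_index()


def categorize_methylation_level(level: float,
                                 config: AnalysisConfig = DEFAULT_CONFIG) -> str:
    """hypomethylated (< 30%), intermediate (30%-70%, boundaries inclusive),
    or hypermethylated (> 70%)."""
    if not 0.0 <= level <= 1.0:
        raise ValueError("methylation level outside [0, 1]")
    if level < config.meth_low:
        return "hypomethylated"
    if level > config.meth_high:
        return "hypermethylated"
    return "intermediate"


def detect_promoter_switches(catalog, promoters: pd.DataFrame) -> pd.DataFrame:
    """Genes whose promoters carry both a hypoDMR and a hyperDMR in the same
    matched comparison (candidate promoter switching).

    Requires the gene to have more than one DMR-overlapping promoter.
    Returns gene_id/gene_name, the number of comparisons in which the
    combination holds, and a ``recurrent`` flag (> 1 comparison).
    """
    obs = catalog.matched_observations()
    obs = obs[obs["direction"].isin(["hypo", "hyper"])]
    if obs.empty:
        return pd.DataFrame(columns=["gene_id", "gene_name", "n_comparisons", "recurrent"])
    obs_iv = obs.reset_index(drop=True)
    hits = overlap_query(obs_iv[["chrom", "start", "end"]], promoters)
    if hits.empty:
        return pd.DataFrame(columns=["gene_id", "gene_name", "n_comparisons", "recurrent"])
    ann = pd.DataFrame({
        "comparison_id": obs_iv["comparison_id"].to_numpy()[hits["query_index"]],
        "direction": obs_iv["direction"].to_numpy()[hits["query_index"]],
        "dmr_id": obs_iv["dmr_id"].to_numpy()[hits["query_index"]],
        "transcript_id": promoters["transcript_id"].to_numpy()[hits["subject_index"]],
        "gene_id": promoters["gene_id"].to_numpy()[hits["subject_index"]],
        "gene_name": promoters["gene_name"].to_numpy()[hits["subject_index"]],
    })
    rows = []
    for (gene_id, gene_name), sub in ann.groupby(["gene_id", "gene_name"]):
        if sub["transcript_id"].nunique() < 2:
            continue
        n = 0
        for _, comp_sub in sub.groupby("comparison_id"):
            if {"hypo", "hyper"} <= set(comp_sub["direction"]):
                n += 1
        if n:
            rows.append((gene_id, gene_name, n, n > 1))
    return pd.DataFrame(rows, columns=["gene_id", "gene_name", "n_comparisons",
                                       "recurrent"])
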