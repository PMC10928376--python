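"""Clinicopathologic-category-exclusive DMRs with exhaustive permutation
nulls, multi-resolution DMR density, hotspot detection, and window-feature
correlation.

Exclusivity asks whether a DMR recurs (with the same direction) in enough
member patients of a category while being absent from every excluded
patient, ignoring patients whose status is unconfirmed. The null
distribution comes from exhaustively re-assigning the category labels over
the confirmed patients (e.g. all 15 ways of naming 2 of 6 patients
never-smokers) and recomputing the exclusive count under each assignment.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .config import AnalysisConfig, DEFAULT_CONFIG, chrom_sort_key
from .dmr_catalog import DMRCatalog
from .genome_io import BinGrid, MethylationTrack, overlap_any, overlap_bases, overlap_query

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CategoryRule:
    """Membership rule for one clinicopathologic category.

    ``min_members_with_dmr`` is the recurrence floor among members;
    ``lenient_patients`` are members exempt from the requirement (counted
    when present), and ``ignore_patients`` are neither required nor
    disqualifying (unconfirmed status).
    """

    label: str
    member_patients: tuple[str, ...]
    excluded_patients: tuple[str, ...]
    min_members_with_dmr: int
    ignore_patients: tuple[str, ...] = ()
    lenient_patients: tuple[str, ...] = ()

    def __post_init__(self):
        if set(self.member_patients) & set(self.excluded_patients):
            raise ValueError("member and excluded patient sets overlap")
        if self.min_members_with_dmr > len(self.member_patients):
            raise ValueError("min_members_with_dmr exceeds member count")


@dataclass
class SpecificityResult:
    """Observed category-exclusive count against its exhaustive null."""

    label: str
    direction: str
    observed: int
    permutation_counts: list[int]
    n_permutations: int

    @property
    def rank(self) -> int:
        """1-based rank of the observed count within the null (1 = max)."""
        return 1 + sum(c > self.observed for c in self.permutation_counts)

    @property
    def exceeds_null_max(self) -> bool:
        others = [c for i, c in enumerate(self.permutation_counts) if i > 0]
        return self.observed > max(others) if others else False


def _patient_sets(catalog: DMRCatalog) -> pd.DataFrame:
    """(dmr_id, direction) -> frozenset of patients observing it, from
    matched comparisons."""
    obs = catalog.matched_observations()
    obs = obs[obs["direction"].isin(["hypo", "hyper"])].copy()
    if obs.empty:
        return pd.DataFrame(columns=["dmr_id", "direction", "patients"])
    obs["patient"] = obs["comparison_id"].str.replace("matched:", "", regex=False)
    grouped = (obs.groupby(["dmr_id", "direction"])["patient"]
               .agg(frozenset).rename("patients").reset_index())
    return grouped


def find_exclusive_dmrs(catalog: DMRCatalog, rule: CategoryRule,
                        direction: str | None = None,
                        known_patients: set[str] | None = None) -> pd.DataFrame:
    """DMRs exclusive to a category under ``rule``.

    A DMR (per direction) qualifies when its strict members (members minus
    lenient) reach ``min(min_members_with_dmr, #strict members)`` presences,
    no excluded patient carries it in the same direction, and presence in
    ignored patients is disregarded.
    """
    if known_patients is not None:
        referenced = set(rule.member_patients) | set(rule.excluded_patients)
        unknown = referenced - known_patients
        if unknown:
            raise ValueError(f"rule references unknown patients {sorted(unknown)}")
    sets = _patient_sets(catalog)
    if direction is not None:
        sets = sets[sets["direction"] == direction]
    strict = set(rule.member_patients) - set(rule.lenient_patients)
    required = min(rule.min_members_with_dmr, len(strict))
    excluded = set(rule.excluded_patients)
    keep = []
    for row in sets.itertuples(index=False):
        pts = row.patients
        if len(pts & excluded):
            continue
        if len(pts & strict) >= required:
            keep.append((row.dmr_id, row.direction,
                         len(pts & set(rule.member_patients))))
    return pd.DataFrame(keep, columns=["dmr_id", "direction", "n_members_with_dmr"])


def enumerate_label_assignments(patients: list[str],
                                label_counts: dict[str, int]) -> list[dict[str, str]]:
    """All distinct assignments of a label multiset to patients.

    The number of assignments is the multinomial coefficient of the label
    counts; the first assignment is not guaranteed to be the identity.
    """
    if sum(label_counts.values()) != len(patients):
        raise ValueError("label multiset size does not match patient count")
    labels = sorted(label_counts)
    assignments = []

    def recurse(remaining: tuple[str, ...], partial: dict[str, str], idx: int):
        if idx == len(labels):
            assignments.append(dict(partial))
            return
        lab = labels[idx]
        k = label_counts[lab]
        for chosen in itertools.combinations(remaining, k):
            nxt = dict(partial)
            for p in chosen:
                nxt[p] = lab
            recurse(tuple(p for p in remaining if p not in chosen), nxt, idx + 1)

    recurse(tuple(patients), {}, 0)
    return assignments


def n_label_assignments(label_counts: dict[str, int]) -> int:
    n = sum(label_counts.values())
    out = math.factorial(n)
    for k in label_counts.values():
        out //= math.factorial(k)
    return out


def permutation_null(catalog: DMRCatalog, patients: list[str],
                     label_counts: dict[str, int], rule_factory,
                     direction: str | None = None,
                     true_assignment: dict[str, str] | None = None,
                     max_enumeration: int = 10 ** 6) -> SpecificityResult:
    """Exhaustive label-permutation null for a category-exclusive count.

    ``rule_factory(assignment)`` builds the :class:`CategoryRule` for one
    label assignment (a dict patient -> label). The observed count uses
    ``true_assignment`` (default: the first enumerated assignment must be
    supplied explicitly to mean anything). Enumerations larger than
    ``max_enumeration`` raise, pointing at sampling as a (non-exhaustive)
    fallback.
    """
    n_total = n_label_assignments(label_counts)
    if n_total > max_enumeration:
        raise ValueError(
            f"{n_total} label assignments exceed the enumeration cap "
            f"({max_enumeration}); use a sampled null instead (not exhaustive)")
    assignments = enumerate_label_assignments(patients, label_counts)
    counts = []
    observed = None
    ordered = assignments
    if true_assignment is not None:
        ordered = ([a for a in assignments if a == true_assignment]
                   + [a for a in assignments if a != true_assignment])
        if not ordered or ordered[0] != true_assignment:
            raise ValueError("true_assignment is not among the enumerated assignments")
    for assignment in ordered:
        rule = rule_factory(assignment)
        n = len(find_exclusive_dmrs(catalog, rule, direction=direction))
        counts.append(n)
        if observed is None:
            observed = n
    rule0 = rule_factory(ordered[0])
    return SpecificityResult(rule0.label, direction or "both", observed,
                             counts, len(counts))


def smoking_rule_factory(min_smokers: int = 3):
    """Rule factories for the smoking-status categories.

    Never-smoker-specific: present in both never-smokers, absent in all
    smokers; smoker-specific: present in >= ``min_smokers`` of the smokers,
    absent in both never-smokers. Unconfirmed patients are ignored by
    construction (they carry no label).
    """
    def never_rule(assignment: dict[str, str]) -> CategoryRule:
        members = tuple(sorted(p for p, l in assignment.items() if l == "never"))
        excluded = tuple(sorted(p for p, l in assignment.items() if l == "smoker"))
        return CategoryRule("never_smoker_specific", members, excluded,
                            min_members_with_dmr=len(members))

    def smoker_rule(assignment: dict[str, str]) -> CategoryRule:
        members = tuple(sorted(p for p, l in assignment.items() if l == "smoker"))
        excluded = tuple(sorted(p for p, l in assignment.items() if l == "never"))
        return CategoryRule("smoker_specific", members, excluded,
                            min_members_with_dmr=min(min_smokers, len(members)))

    return never_rule, smoker_rule


def normal_field_effect_dmrs(catalog: DMRCatalog, manifest) -> dict:
    """Categorise normal-vs-normal DMRs by the smoking status of the pair.

    Each unique DMR from normal_normal comparisons is tagged never-never,
    smoker-smoker, or never-smoker (mixed pairs win when a DMR appears in
    several categories they are all recorded). Returns per-DMR category
    sets, per-sample counts of DMRs against never-smokers and smokers, and
    the "example" tier: DMRs in >= 3 never-vs-smoker comparisons covering
    both never-smoker samples and absent from the never-never comparison.
    """
    status = {r.sample_id: r.smoking for r in manifest if r.malignancy == "normal"}
    obs = catalog.observations
    nn = obs[obs["comparison_id"].str.startswith("nn:")].copy()
    if nn.empty:
        return {"dmr_categories": pd.DataFrame(), "per_sample_counts": pd.DataFrame(),
                "example_tier": []}
    pair = nn["comparison_id"].str.replace("nn:", "", regex=False).str.split("|")
    nn["sample_a"] = pair.str[0]
    nn["sample_b"] = pair.str[1]
    nn["status_a"] = nn["sample_a"].map(status)
    nn["status_b"] = nn["sample_b"].map(status)

    def pair_category(a: str, b: str) -> str:
        pairset = {a, b}
        if pairset == {"never"}:
            return "never_never"
        if pairset == {"smoker"}:
            return "smoker_smoker"
        if pairset == {"never", "smoker"}:
            return "never_smoker"
        return "unconfirmed"

    nn["category"] = [pair_category(a, b) for a, b in zip(nn["status_a"], nn["status_b"])]
    dmr_categories = (nn.groupby("dmr_id")["category"].agg(lambda s: sorted(set(s)))
                      .rename("categories").reset_index())
    rows = []
    for sid in status:
        vs_never = nn[((nn["sample_a"] == sid) & (nn["status_b"] == "never")) |
                      ((nn["sample_b"] == sid) & (nn["status_a"] == "never"))]
        vs_smoker = nn[((nn["sample_a"] == sid) & (nn["status_b"] == "smoker")) |
                       ((nn["sample_b"] == sid) & (nn["status_a"] == "smoker"))]
        rows.append((sid, status[sid], vs_never["dmr_id"].nunique(),
                     vs_smoker["dmr_id"].nunique()))
    per_sample = pd.DataFrame(rows, columns=["sample_id", "smoking",
                                             "n_dmrs_vs_never", "n_dmrs_vs_smoker"])
    never_samples = {s for s, st in status.items() if st == "never"}
    example = []
    for dmr_id, sub in nn.groupby("dmr_id"):
        mixed = sub[sub["category"] == "never_smoker"]
        if len(mixed) < 3:
            continue
        nevers_seen = set(mixed["sample_a"]) | set(mixed["sample_b"])
        if not never_samples <= nevers_seen:
            continue
        if (sub["category"] == "never_never").any():
            continue
        example.append(dmr_id)
    return {"dmr_categories": dmr_categories, "per_sample_counts": per_sample,
            "example_tier": sorted(example)}


# ---------------------------------------------------------------------------
# density, hotspots, window features
# ---------------------------------------------------------------------------

def make_windows(bin_grid: BinGrid, width: int,
                 config: AnalysisConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Non-overlapping windows tiling the genome (chrY and chrM excluded),
    with the number of background-eligible 500-bp bins per window. Windows
    with zero eligible bins are dropped (density undefined there)."""
    rows = []
    for chrom, length in bin_grid.chrom_sizes.items():
        if chrom in config.excluded_window_chroms:
            continue
        eligible = (bin_grid.contains_cpg.get(chrom, np.zeros(0, bool))
                    & ~bin_grid.blacklisted.get(chrom, np.zeros(0, bool)))
        for start in range(0, length, width):
            end = min(start + width, length)
            lo, hi = start // bin_grid.width, -(-end // bin_grid.width)
            n_bins = int(eligible[lo:hi].sum())
            if n_bins:
                rows.append((chrom, start, end, n_bins))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpg_bins"])


def window_density(filtered_calls: pd.DataFrame, windows: pd.DataFrame,
                   bin_grid: BinGrid) -> pd.DataFrame:
    """DMR density per window, comparison, and direction.

    Density = called bins in the window / background-eligible bins in the
    window, so a window saturated with DMRs has density 1.
    """
    calls = filtered_calls[filtered_calls["direction"].isin(["hypo", "hyper"])]
    windows = windows.reset_index(drop=True)
    rows = []
    groups = calls.groupby(["comparison_id", "direction"], sort=False)
    for (comp, direction), sub in groups:
        counts = np.zeros(len(windows), dtype=int)
        for chrom, wsub in windows.groupby("chrom", sort=False):
            csub = sub[sub["chrom"] == chrom]
            if csub.empty:
                continue
            starts = csub["start"].to_numpy()
            idx = np.searchsorted(wsub["start"].to_numpy(), starts, side="right") - 1
            ok = (idx >= 0) & (starts < wsub["end"].to_numpy()[np.clip(idx, 0, None)])
            uniq, cnt = np.unique(idx[ok], return_counts=True)
            counts[wsub.index.to_numpy()[uniq]] += cnt
        dens = counts / windows["n_cpg_bins"].to_numpy()
        for i in range(len(windows)):
            rows.append((comp, direction, windows.at[i, "chrom"],
                         windows.at[i, "start"], windows.at[i, "end"],
                         int(counts[i]), float(dens[i])))
    return pd.DataFrame(rows, columns=["comparison_id", "direction", "chrom",
                                       "start", "end", "n_dmrs", "density"])


def genome_wide_density(filtered_calls: pd.DataFrame, bin_grid: BinGrid) -> pd.DataFrame:
    """Per comparison and direction: DMR count / background bin count."""
    n_bg = bin_grid.n_background
    out = (filtered_calls[filtered_calls["direction"].isin(["hypo", "hyper"])]
           .groupby(["comparison_id", "direction"]).size().rename("n_dmrs")
           .reset_index())
    out["density"] = out["n_dmrs"] / n_bg
    return out


def detect_hotspots(densities: pd.DataFrame,
                    config: AnalysisConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Flag hotspot windows per direction.

    A window is a hotspot when its density exceeds ``density_hotspot`` in
    more than one comparison (``recurrent`` clause) or ranks among the top
    ``hotspot_top_n`` windows by maximum density across comparisons
    (``top_n`` clause; ties at the boundary broken by genomic order). The
    returned frame carries both flags and their union.
    """
    out = []
    for direction, sub in densities.groupby("direction", sort=False):
        per_win = (sub.groupby(["chrom", "start", "end"])
                   .agg(n_above=("density", lambda d: int((d > config.density_hotspot).sum())),
                        max_density=("density", "max"))
                   .reset_index())
        per_win["recurrent"] = per_win["n_above"] >= 2
        order = per_win.assign(_k=per_win["chrom"].map(chrom_sort_key)).sort_values(
            ["max_density", "_k", "start"], ascending=[False, True, True],
            kind="mergesort")
        top_idx = order.index[:config.hotspot_top_n]
        per_win["top_n"] = per_win.index.isin(top_idx)
        per_win["hotspot"] = per_win["recurrent"] | per_win["top_n"]
        per_win.insert(0, "direction", direction)
        out.append(per_win.drop(columns=["n_above"]))
    if not out:
        return pd.DataFrame(columns=["direction", "chrom", "start", "end",
                                     "max_density", "recurrent", "top_n", "hotspot"])
    return pd.concat(out, ignore_index=True)


def window_feature_profile(windows: pd.DataFrame, cpgs: pd.DataFrame,
                           repeats: pd.DataFrame, transcripts: pd.DataFrame,
                           segmentation: pd.DataFrame | None = None,
                           normal_tracks: dict[str, MethylationTrack] | None = None
                           ) -> pd.DataFrame:
    """Covariate features per window.

    CpG density (CpGs/bp), repeat density (repeat bp/bp), gene and
    transcript densities overall and for protein-coding biotypes (count/bp),
    per-state base proportions of the segmentation, and the mean normal
    methylation over the window's CpGs (averaged over normal samples).
    """
    windows = windows.reset_index(drop=True)
    length = (windows["end"] - windows["start"]).to_numpy()
    out = windows.copy()

    cpg_iv = cpgs.assign(start=cpgs["pos"], end=cpgs["pos"] + 1)[["chrom", "start", "end"]]
    n_cpg = np.zeros(len(windows), dtype=int)
    for chrom, wsub in windows.groupby("chrom", sort=False):
        pos = cpgs.loc[cpgs["chrom"] == chrom, "pos"].to_numpy()
        pos.sort()
        lo = np.searchsorted(pos, wsub["start"].to_numpy())
        hi = np.searchsorted(pos, wsub["end"].to_numpy())
        n_cpg[wsub.index.to_numpy()] = hi - lo
    out["cpg_density"] = n_cpg / length
    out["repeat_density"] = overlap_bases(windows, repeats) / length

    tx_iv = transcripts.rename(columns={"tx_start": "start", "tx_end": "end"})[
        ["chrom", "start", "end", "gene_id", "biotype"]]
    gene_iv = (tx_iv.groupby(["chrom", "gene_id"])
               .agg(start=("start", "min"), end=("end", "max"),
                    biotype=("biotype", "first")).reset_index())
    for name, iv in (("transcript", tx_iv), ("gene", gene_iv)):
        for tag, sel in (("", iv), ("protein_coding_", iv[iv["biotype"] == "protein_coding"])):
            hits = overlap_query(windows, sel.reset_index(drop=True))
            counts = (hits.groupby("query_index").size()
                      .reindex(range(len(windows)), fill_value=0).to_numpy())
            out[f"{tag}{name}_density"] = counts / length

    if segmentation is not None and not segmentation.empty:
        hits = overlap_query(windows, segmentation)
        states = segmentation["state"].to_numpy()
        for state in sorted(set(states)):
            sub = hits[states[hits["subject_index"]] == state]
            bp = (sub.groupby("query_index")["overlap"].sum()
                  .reindex(range(len(windows)), fill_value=0).to_numpy())
            out[f"state_{state}"] = bp / length

    if normal_tracks:
        sums = np.zeros(len(windows))
        ns = np.zeros(len(windows))
        for track in normal_tracks.values():
            for chrom, wsub in windows.groupby("chrom", sort=False):
                tsub = track.cpgs[track.cpgs["chrom"] == chrom]
                pos = tsub["pos"].to_numpy()
                lv = tsub["level"].to_numpy()
                lo = np.searchsorted(pos, wsub["start"].to_numpy())
                hi = np.searchsorted(pos, wsub["end"].to_numpy())
                idx = wsub.index.to_numpy()
                for j, (a, b) in enumerate(zip(lo, hi)):
                    if b > a:
                        sums[idx[j]] += lv[a:b].mean()
                        ns[idx[j]] += 1
        with np.errstate(invalid="ignore"):
            out["mean_normal_methylation"] = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    return out


def correlate_density_features(profiles: pd.DataFrame, densities: pd.DataFrame,
                               config: AnalysisConfig = DEFAULT_CONFIG) -> dict:
    """Pearson correlation of window features with DMR-density summaries,
    plus an ordination of the feature space.

    Density summaries per window and direction: density in each individual
    comparison, the number of comparisons with density above the hotspot
    threshold, and the mean density across comparisons. Constant features
    yield NaN correlations (reported, not dropped). The ordination reports
    per-component variance shares and the correlation of each feature with
    the first three components.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 windows")
    feature_cols = [c for c in profiles.columns
                    if c not in ("chrom", "start", "end", "n_cpg_bins")]
    key = ["chrom", "start", "end"]
    rows = []
    for direction, sub in densities.groupby("direction", sort=False):
        wide = sub.pivot_table(index=key, columns="comparison_id",
                               values="density", fill_value=0.0)
        summary = pd.DataFrame({
            "mean_density": wide.mean(axis=1),
            "n_comparisons_above": (wide > config.density_hotspot).sum(axis=1),
        })
        merged = profiles.set_index(key).join(summary, how="inner")
        comp_cols = list(wide.columns)
        merged = merged.join(wide, how="left")
        for feat in feature_cols:
            x = merged[feat].to_numpy(float)
            for target in ["mean_density", "n_comparisons_above", *comp_cols]:
                y = merged[target].to_numpy(float)
                if np.std(x) == 0 or np.std(y) == 0:
                    r = np.nan
                else:
                    r = float(np.corrcoef(x, y)[0, 1])
                rows.append((direction, feat, str(target), r))
    corr = pd.DataFrame(rows, columns=["direction", "feature", "density_summary", "r"])

    X = profiles[feature_cols].to_numpy(float)
    sd = X.std(axis=0)
    usable = sd > 0
    if not usable.any():
        return {"correlations": corr, "feature_loadings": pd.DataFrame(),
                "variance_shares": np.array([])}
    Xs = (X[:, usable] - X[:, usable].mean(axis=0)) / sd[usable]
    n_comp = min(Xs.shape[0], Xs.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(Xs)
    loadings = {}
    for k in range(min(3, n_comp)):
        loadings[f"PC{k + 1}"] = [
            float(np.corrcoef(Xs[:, j], scores[:, k])[0, 1])
            if np.std(scores[:, k]) > 0 else np.nan
            for j in range(Xs.shape[1])]
    ordination = pd.DataFrame(loadings,
                              index=[f for f, u in zip(feature_cols, usable) if u])
    return {"correlations": corr, "feature_loadings": ordination,
            "variance_shares": pca.explained_variance_ratio_}


def comparison_exclusive_dmrs(catalog: DMRCatalog) -> pd.DataFrame:
    """DMRs observed in exactly one matched comparison (per direction)."""
    obs = catalog.matched_observations()
    obs = obs[obs["direction"].isin(["hypo", "hyper"])]
    counts = obs.groupby(["dmr_id", "direction"])["comparison_id"].agg(["nunique", "first"])
    solo = counts[counts["nunique"] == 1].reset_index()
    return solo.rename(columns={"first": "comparison_id"})[
        ["dmr_id", "direction", "comparison_id"]]


def exclusive_in_hotspots_fraction(catalog: DMRCatalog, densities: pd.DataFrame,
                                   config: AnalysisConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Fraction of each comparison's exclusive DMRs inside that comparison's
    high-density (> ``density_high``) windows, per direction. NaN when the
    comparison has no exclusive DMRs in that direction."""
    solo = comparison_exclusive_dmrs(catalog)
    dmr_pos = catalog.dmrs.set_index("dmr_id")[["chrom", "start", "end"]]
    rows = []
    for (comp, direction), sub in solo.groupby(["comparison_id", "direction"]):
        dense = densities[(densities["comparison_id"] == comp)
                          & (densities["direction"] == direction)
                          & (densities["density"] > config.density_high)]
        pos = dmr_pos.loc[sub["dmr_id"]]
        if pos.empty:
            rows.append((comp, direction, 0, np.nan))
            continue
        inside = overlap_any(pos.reset_index(drop=True),
                             dense[["chrom", "start", "end"]])
        rows.append((comp, direction, len(pos), float(np.mean(inside))))
    return pd.DataFrame(rows, columns=["comparison_id", "direction",
                                       "n_exclusive", "fraction_in_hotspots"])
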