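"""Self-contained synthetic dataset generator with planted ground truth.

Emulates the statistical structure the downstream analysis assumes: a small
multi-chromosome genome with CpG islands, transcripts, repeats, a chromatin
state mosaic and a blacklist; a cohort of matched normal/tumor methylomes
(17 tumors, 10 matched normals by default, mirroring the study cohort);
and per-comparison DMR call tables in which recurrent, smoking-status-
specific, repeat-targeted and hotspot-concentrated differential bins are
planted on top of a configurable false-positive rate.

Randomness is split into four independent streams (reference, truth,
methylomes, calls) spawned from one seed, so e.g. changing the cohort noise
never perturbs the reference genome.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import AnalysisConfig, DEFAULT_CONFIG
from .dmr_catalog import CALL_COLUMNS, ComparisonSpec, DMRCatalog, enumerate_comparisons
from .genome_io import (BinGrid, ChromSizes, MethylationTrack, SampleRecord,
                        build_bin_grid, overlap_any)

# (class, family, subfamily, mean length, milliDiv mean) for the repeat catalogue
DEFAULT_SUBFAMILIES = (
    ("SINE", "Alu", "AluY", 300, 40),
    ("SINE", "Alu", "AluSp", 300, 120),
    ("LINE", "L1", "L1M5", 900, 300),
    ("LTR", "ERV1", "LTR12C", 1200, 90),
    ("LTR", "ERV1", "MER57E3", 500, 180),
    ("DNA", "hAT-Charlie", "MER5A", 250, 250),
    ("Simple_repeat", "Simple_repeat", "(TA)n", 120, 10),
    ("Low_complexity", "Low_complexity", "A-rich", 100, 10),
)

CHROMHMM18_STATES = (
    "1_TssA", "2_TssFlnk", "3_TssFlnkU", "4_TssFlnkD", "5_Tx", "6_TxWk",
    "7_EnhG1", "8_EnhG2", "9_EnhA1", "10_EnhA2", "11_EnhWk", "12_ZNF/Rpts",
    "13_Het", "14_TssBiv", "15_EnhBiv", "16_ReprPC", "17_ReprPCWk", "18_Quies",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic dataset; defaults mirror the study conditions.

    Effect size 0.4, measurement noise sd 0.05 and caller false-positive
    rate 1e-3 per background bin reproduce the regime the recovery
    properties are calibrated to; planted calls get q ~ U(0, 1e-5) and
    false positives q ~ U(0, 1e-3).
    """

    chrom_lengths: tuple[tuple[str, int], ...] = (
        ("chr1", 2_000_000), ("chr2", 2_000_000),
        ("chrX", 1_000_000), ("chrY", 200_000))
    cpg_background_rate: float = 0.004
    islands_per_mb: float = 10.0
    island_length: int = 1000
    island_cpg_rate: float = 0.08
    n_transcripts: int = 300
    biotype_mix: tuple[tuple[str, float], ...] = (
        ("protein_coding", 0.70), ("lincRNA", 0.15),
        ("antisense", 0.10), ("processed_transcript", 0.05))
    promoter_cgi_fraction: float = 0.5
    n_repeats: int = 1500
    subfamilies: tuple = DEFAULT_SUBFAMILIES
    segment_mean_length: int = 5000
    quiescent_weight: float = 10.0
    blacklist_per_chrom: int = 3
    blacklist_length: int = 2000

    n_matched_patients: int = 10
    n_tumor_only: int = 7

    n_recurrent_hypo: int = 40
    n_recurrent_hyper: int = 40
    recurrence_min: int = 2
    recurrence_max: int = 6
    n_singleton: int = 60
    n_never_specific: int = 8
    n_smoker_specific: int = 8
    #: planted smoker-specific DMRs recur in this range of smokers
    smoker_specific_k: tuple[int, int] = (3, 4)
    n_subtype_specific: int = 6
    n_hotspot_windows: int = 2
    hotspot_window_width: int = 1_000_000
    hotspot_rate: float = 0.05
    hotspot_n_patients: int = 2
    te_target_subfamily: str = "LTR12C"
    n_te_targeted: int = 15

    delta: float = 0.4
    noise_sd: float = 0.05
    fpr: float = 1e-3
    q_planted_max: float = 1e-5
    q_fp_max: float = 1e-3
    baseline_cgi: float = 0.15
    baseline_repeat: float = 0.85
    baseline_other: float = 0.75
    tumor_repeat_shift: float = -0.05

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


DEFAULT_GENERATOR = GeneratorConfig()


@dataclass
class Reference:
    chrom_sizes: ChromSizes
    cpgs: pd.DataFrame          # chrom, pos
    cgis: pd.DataFrame          # chrom, start, end
    transcripts: pd.DataFrame
    repeats: pd.DataFrame       # rmsk-like element frame
    segmentation: pd.DataFrame  # chrom, start, end, state
    blacklist: pd.DataFrame


@dataclass
class SyntheticTruth:
    """Planted ground truth: one row per planted DMR bin in ``planted``
    (chrom, bin, start, end, direction, patients, category) plus the planted
    hotspot windows and the repeat subfamily targeted for hypomethylation."""

    planted: pd.DataFrame
    hotspot_windows: pd.DataFrame
    te_target_subfamily: str

    def planted_for(self, patient: str) -> pd.DataFrame:
        mask = self.planted["patients"].map(lambda ps: patient in ps).astype(bool)
        return self.planted[mask]

    def recurrent(self, min_patients: int = 2) -> pd.DataFrame:
        return self.planted[self.planted["patients"].map(len) >= min_patients]


def default_manifest(config: GeneratorConfig = DEFAULT_GENERATOR) -> list[SampleRecord]:
    """Cohort manifest mirroring the study: 10 matched patients (2 confirmed
    never-smokers, 4 confirmed smokers incl. the lenient Patient_4999, 4
    unconfirmed) plus 7 tumor-only patients."""
    matched = [f"Patient_{i:02d}" for i in range(1, config.n_matched_patients)]
    matched.append("Patient_4999")
    smoking = {"Patient_01": "never", "Patient_02": "never",
               "Patient_03": "smoker", "Patient_04": "smoker",
               "Patient_05": "smoker", "Patient_4999": "smoker"}
    stage = {"Patient_01": "1A", "Patient_02": "1", "Patient_03": "1A",
             "Patient_06": "1", "Patient_07": "1A",
             "Patient_04": "3A", "Patient_05": "3B", "Patient_08": "3A"}
    subtype = {"Patient_02": "acinar", "Patient_06": "acinar",
               "Patient_03": "adenosquamous", "Patient_4999": "adenosquamous"}
    records = []
    for p in matched:
        smk = smoking.get(p, "unconfirmed")
        stg = stage.get(p, "unconfirmed")
        sub = subtype.get(p, "adenocarcinoma")
        records.append(SampleRecord(f"{p}_N", p, "normal", smk, stg, sub, None))
        records.append(SampleRecord(f"{p}_T", p, "tumor", smk, stg, sub, 0.6))
    for i in range(config.n_tumor_only):
        p = f"Patient_T{i + 1:02d}"
        records.append(SampleRecord(f"{p}_T", p, "tumor", "unconfirmed",
                                    "unconfirmed", "adenocarcinoma", 0.6))
    return records


def confirmed_smoking(manifest: list[SampleRecord]) -> dict[str, str]:
    """Patient -> smoking label for matched patients with confirmed status."""
    out = {}
    for r in manifest:
        if r.malignancy == "normal" and r.smoking in ("never", "smoker"):
            out[r.patient_id] = r.smoking
    return out


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

def generate_reference(config: GeneratorConfig, rng: np.random.Generator) -> Reference:
    """Deterministic (given the stream) toy genome with all annotation layers."""
    chrom_sizes = ChromSizes(dict(config.chrom_lengths))
    cpg_rows, cgi_rows = [], []
    for chrom, length in chrom_sizes.items():
        n_islands = int(round(config.islands_per_mb * length / 1e6))
        starts = np.sort(rng.choice(
            max(length - config.island_length, 1), size=n_islands, replace=False))
        for s in starts:
            cgi_rows.append((chrom, int(s), int(s) + config.island_length))
            n = rng.poisson(config.island_cpg_rate * config.island_length)
            pos = np.unique(rng.integers(s, s + config.island_length, size=n))
            cpg_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
        n_bg = rng.poisson(config.cpg_background_rate * length)
        pos = np.unique(rng.integers(0, length, size=n_bg))
        cpg_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    cpgs = (pd.concat(cpg_rows, ignore_index=True)
            .drop_duplicates().sort_values(["chrom", "pos"]).reset_index(drop=True))
    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])

    # transcripts; a fraction of TSSs sit inside CpG islands
    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    biotypes, weights = zip(*config.biotype_mix)
    tx_rows = []
    for i in range(config.n_transcripts):
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        strand = "+" if rng.random() < 0.5 else "-"
        tx_len = int(rng.integers(2_000, 30_000))
        use_cgi = rng.random() < config.promoter_cgi_fraction
        chrom_cgis = cgis[cgis["chrom"] == chrom]
        if use_cgi and len(chrom_cgis):
            tss = int(chrom_cgis.iloc[rng.integers(len(chrom_cgis))]["start"]) + 100
        else:
            tss = int(rng.integers(0, chrom_sizes[chrom]))
        if strand == "+":
            start, end = tss, min(tss + tx_len, chrom_sizes[chrom])
        else:
            start, end = max(tss - tx_len, 0), tss
        if end - start < 200:
            continue
        gene_idx = i // 2  # roughly two isoforms per gene
        tx_rows.append((f"TX{i:05d}", f"G{gene_idx:05d}", f"GENE{gene_idx}",
                        biotypes[rng.choice(len(biotypes), p=np.array(weights))],
                        chrom, strand, start, end))
    transcripts = pd.DataFrame(tx_rows, columns=[
        "transcript_id", "gene_id", "gene_name", "biotype",
        "chrom", "strand", "tx_start", "tx_end"])

    sub_idx = rng.integers(0, len(config.subfamilies), size=config.n_repeats)
    rep_rows = []
    for k in range(config.n_repeats):
        cls, fam, name, mean_len, mdiv = config.subfamilies[sub_idx[k]]
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        length = max(50, int(rng.normal(mean_len, mean_len / 4)))
        start = int(rng.integers(0, max(chrom_sizes[chrom] - length, 1)))
        milli = float(np.clip(rng.normal(mdiv, mdiv / 5 + 5), 0, 900))
        rep_rows.append((chrom, start, start + length,
                         "+" if rng.random() < 0.5 else "-",
                         name, fam, cls, milli))
    repeats = pd.DataFrame(rep_rows, columns=[
        "chrom", "start", "end", "strand", "subfamily", "family",
        "repeat_class", "milli_div"])
    repeats["subst_prop"] = repeats["milli_div"] / 1000.0
    from .genome_io import TE_CLASSES
    repeats["is_TE"] = repeats["repeat_class"].isin(TE_CLASSES)
    repeats = repeats.sort_values(["chrom", "start"]).reset_index(drop=True)

    seg_rows = []
    weights18 = np.ones(len(CHROMHMM18_STATES))
    weights18[-1] = config.quiescent_weight
    weights18 = weights18 / weights18.sum()
    for chrom, length in chrom_sizes.items():
        pos = 0
        while pos < length:
            seg_len = max(200, int(rng.exponential(config.segment_mean_length)))
            state = CHROMHMM18_STATES[rng.choice(len(CHROMHMM18_STATES), p=weights18)]
            seg_rows.append((chrom, pos, min(pos + seg_len, length), state))
            pos += seg_len
    segmentation = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "state"])

    bl_rows = []
    for chrom, length in chrom_sizes.items():
        starts = rng.choice(max(length - config.blacklist_length, 1),
                            size=config.blacklist_per_chrom, replace=False)
        for s in np.sort(starts):
            bl_rows.append((chrom, int(s), int(s) + config.blacklist_length))
    blacklist = pd.DataFrame(bl_rows, columns=["chrom", "start", "end"])

    return Reference(chrom_sizes, cpgs, cgis, transcripts, repeats,
                     segmentation, blacklist)


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

def _bin_frame(bin_grid: BinGrid, chrom_bins: pd.DataFrame) -> pd.DataFrame:
    out = chrom_bins.copy()
    out["start"] = out["bin"] * bin_grid.width
    out["end"] = out["start"] + bin_grid.width
    return out


def generate_truth(reference: Reference, manifest: list[SampleRecord],
                   config: GeneratorConfig, rng: np.random.Generator,
                   analysis: AnalysisConfig = DEFAULT_CONFIG) -> SyntheticTruth:
    """Choose planted DMR bins, their directions, patients and categories."""
    bin_grid = build_bin_grid(reference.chrom_sizes, reference.cpgs,
                              reference.blacklist, analysis)
    background = bin_grid.background_bins()
    matched_patients = sorted({r.patient_id for r in manifest if r.malignancy == "normal"})
    smoking = confirmed_smoking(manifest)
    nevers = sorted(p for p, s in smoking.items() if s == "never")
    smokers = sorted(p for p, s in smoking.items() if s == "smoker")
    subtype_members: dict[str, list[str]] = {}
    for r in manifest:
        if r.malignancy == "normal" and r.subtype not in ("unconfirmed",):
            subtype_members.setdefault(r.subtype, []).append(r.patient_id)

    available = background.sample(frac=1.0, random_state=int(rng.integers(2 ** 31)))
    cursor = 0

    def take(n: int) -> pd.DataFrame:
        nonlocal cursor
        if cursor + n > len(available):
            raise ValueError("not enough background bins to plant the requested truth")
        out = available.iloc[cursor:cursor + n]
        cursor += n
        return out

    rows = []

    def plant(bins: pd.DataFrame, direction: str, patients_list, category: str):
        for (_, b), pats in zip(bins.iterrows(), patients_list):
            rows.append((b["chrom"], int(b["bin"]), int(b["start"]), int(b["end"]),
                         direction, tuple(sorted(pats)), category))

    def random_subsets(n: int, k_min: int, k_max: int, pool: list[str]):
        out = []
        for _ in range(n):
            k = int(rng.integers(k_min, min(k_max, len(pool)) + 1))
            out.append(rng.choice(pool, size=k, replace=False).tolist())
        return out

    for direction, count in (("hypo", config.n_recurrent_hypo),
                             ("hyper", config.n_recurrent_hyper)):
        bins = take(count)
        plant(bins, direction,
              random_subsets(count, config.recurrence_min, config.recurrence_max,
                             matched_patients), "recurrent")
    bins = take(config.n_singleton)
    singles = random_subsets(config.n_singleton, 1, 1, matched_patients)
    for row, pats in zip(bins.itertuples(index=False), singles):
        rows.append((row.chrom, int(row.bin), int(row.start), int(row.end),
                     "hypo" if rng.random() < 0.5 else "hyper",
                     tuple(pats), "singleton"))

    if nevers and config.n_never_specific:
        bins = take(config.n_never_specific)
        dirs = rng.random(len(bins)) < 0.5
        for (row, hypo) in zip(bins.itertuples(index=False), dirs):
            rows.append((row.chrom, int(row.bin), int(row.start), int(row.end),
                         "hypo" if hypo else "hyper", tuple(nevers), "never_specific"))
    if smokers and config.n_smoker_specific:
        bins = take(config.n_smoker_specific)
        k_lo, k_hi = config.smoker_specific_k
        for row in bins.itertuples(index=False):
            k = int(rng.integers(k_lo, min(k_hi, len(smokers)) + 1))
            pats = rng.choice(smokers, size=k, replace=False).tolist()
            rows.append((row.chrom, int(row.bin), int(row.start), int(row.end),
                         "hypo" if rng.random() < 0.5 else "hyper",
                         tuple(sorted(pats)), "smoker_specific"))
    if config.n_subtype_specific:
        members = subtype_members.get("adenosquamous", [])
        if len(members) >= 2:
            bins = take(config.n_subtype_specific)
            for row in bins.itertuples(index=False):
                rows.append((row.chrom, int(row.bin), int(row.start), int(row.end),
                             "hyper", tuple(sorted(members)), "subtype_adenosquamous"))

    # repeat-targeted hypomethylation: bins overlapping the target subfamily
    target = reference.repeats[reference.repeats["subfamily"] == config.te_target_subfamily]
    if config.n_te_targeted and not target.empty:
        taken = set(zip(available.iloc[:cursor]["chrom"], available.iloc[:cursor]["bin"]))
        cand = background[overlap_any(background[["chrom", "start", "end"]], target)]
        cand = cand[~cand.apply(lambda r: (r["chrom"], r["bin"]) in taken, axis=1)]
        n = min(config.n_te_targeted, len(cand))
        sel = cand.sample(n=n, random_state=int(rng.integers(2 ** 31)))
        plant(sel, "hypo",
              random_subsets(n, 2, min(4, len(matched_patients)), matched_patients),
              "te_targeted")
        taken_te = set(zip(sel["chrom"], sel["bin"]))
    else:
        taken_te = set()

    # hotspot windows: dense one-direction planting in a fixed patient pair
    hs_rows = []
    if config.n_hotspot_windows:
        eligible_windows = []
        for chrom, length in reference.chrom_sizes.items():
            if chrom in analysis.excluded_window_chroms:
                continue
            for start in range(0, length - config.hotspot_window_width + 1,
                               config.hotspot_window_width):
                eligible_windows.append((chrom, start, start + config.hotspot_window_width))
        sel_idx = rng.choice(len(eligible_windows),
                             size=min(config.n_hotspot_windows, len(eligible_windows)),
                             replace=False)
        used = set(zip(available.iloc[:cursor]["chrom"], available.iloc[:cursor]["bin"]))
        used |= taken_te
        for wi in sel_idx:
            chrom, start, end = eligible_windows[wi]
            inside = background[(background["chrom"] == chrom)
                                & (background["start"] >= start)
                                & (background["end"] <= end)]
            inside = inside[~inside.apply(
                lambda r: (r["chrom"], r["bin"]) in used, axis=1)]
            n_plant = int(round(config.hotspot_rate * len(inside)))
            if n_plant == 0:
                continue
            sel = inside.sample(n=n_plant, random_state=int(rng.integers(2 ** 31)))
            used |= set(zip(sel["chrom"], sel["bin"]))
            direction = "hypo" if rng.random() < 0.5 else "hyper"
            pats = rng.choice(matched_patients, size=config.hotspot_n_patients,
                              replace=False).tolist()
            plant(sel, direction, [pats] * n_plant, "hotspot")
            hs_rows.append((chrom, start, end, direction, tuple(sorted(pats))))

    planted = pd.DataFrame(rows, columns=["chrom", "bin", "start", "end",
                                          "direction", "patients", "category"])
    hotspots = pd.DataFrame(hs_rows, columns=["chrom", "start", "end",
                                              "direction", "patients"])
    return SyntheticTruth(planted, hotspots, config.te_target_subfamily)


# ---------------------------------------------------------------------------
# methylomes and calls
# ---------------------------------------------------------------------------

def generate_cohort_methylomes(reference: Reference, truth: SyntheticTruth,
                               manifest: list[SampleRecord],
                               config: GeneratorConfig,
                               rng: np.random.Generator
                               ) -> dict[str, MethylationTrack]:
    """Per-sample CpG methylation tracks over the reference CpG set.

    Normals: CpG-island CpGs low, repeat CpGs high, elsewhere
    intermediate-high, plus Gaussian noise, clipped to [0, 1]. Tumors:
    the same baseline shifted by +-delta at bins planted for that patient,
    plus an optional global repeat-level downshift.
    """
    cpgs = reference.cpgs
    iv = cpgs.assign(start=cpgs["pos"], end=cpgs["pos"] + 1)[["chrom", "start", "end"]]
    in_cgi = overlap_any(iv, reference.cgis)
    in_rep = overlap_any(iv, reference.repeats[["chrom", "start", "end"]])
    baseline = np.full(len(cpgs), config.baseline_other)
    baseline[in_rep] = config.baseline_repeat
    baseline[in_cgi] = config.baseline_cgi  # CGI wins over repeat

    width = DEFAULT_CONFIG.bin_width
    bin_key = pd.Series(list(zip(cpgs["chrom"], cpgs["pos"] // width)))
    planted_shift: dict[str, np.ndarray] = {}
    for patient in {r.patient_id for r in manifest if r.malignancy == "normal"}:
        mine = truth.planted_for(patient)
        shift = np.zeros(len(cpgs))
        if not mine.empty:
            sign = {(c, b): (1.0 if d == "hyper" else -1.0)
                    for c, b, d in zip(mine["chrom"], mine["bin"], mine["direction"])}
            hits = bin_key.map(sign)
            shift = hits.fillna(0.0).to_numpy() * config.delta
        planted_shift[patient] = shift

    tracks = {}
    for record in manifest:
        level = baseline.copy()
        if record.malignancy == "tumor":
            level = level + planted_shift.get(record.patient_id, 0.0)
            level[in_rep & ~in_cgi] += config.tumor_repeat_shift
        level = level + rng.normal(0.0, config.noise_sd, size=len(cpgs))
        level = np.clip(level, 0.0, 1.0)
        tracks[record.sample_id] = MethylationTrack(
            record.sample_id,
            pd.DataFrame({"chrom": cpgs["chrom"], "pos": cpgs["pos"], "level": level}))
    return tracks


def generate_dmr_calls(truth: SyntheticTruth, comparisons: list[ComparisonSpec],
                       bin_grid: BinGrid, config: GeneratorConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Per-comparison call tables emulating the upstream caller's output.

    Matched comparisons contain that patient's planted bins (q ~ planted
    model) plus background false positives at rate ``fpr``; normal-normal
    and cross comparisons contain false positives only. Directions ride on
    the signed-statistic convention (positive = gain in the alt sample).
    """
    background = bin_grid.background_bins()
    bg_keys = list(zip(background["chrom"], background["bin"]))
    rows = []
    for comp in comparisons:
        planted = (truth.planted_for(comp.patient_id)
                   if comp.kind == "matched" else truth.planted.iloc[0:0])
        planted_keys = set(zip(planted["chrom"], planted["bin"]))
        for r in planted.itertuples(index=False):
            q = float(rng.uniform(0.0, config.q_planted_max))
            rows.append((comp.comparison_id, r.chrom, int(r.bin),
                         int(r.start), int(r.end), q, r.direction))
        if config.fpr > 0:
            fp_mask = rng.random(len(background)) < config.fpr
            for i in np.flatnonzero(fp_mask):
                key = bg_keys[i]
                if key in planted_keys:
                    continue
                q = float(rng.uniform(0.0, config.q_fp_max))
                direction = "hypo" if rng.random() < 0.5 else "hyper"
                b = background.iloc[i]
                rows.append((comp.comparison_id, b["chrom"], int(b["bin"]),
                             int(b["start"]), int(b["end"]), q, direction))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    seed: int
    reference: Reference
    manifest: list[SampleRecord]
    truth: SyntheticTruth
    bin_grid: BinGrid
    comparisons: list[ComparisonSpec]
    tracks: dict[str, MethylationTrack] | None
    calls: pd.DataFrame


def generate_dataset(config: GeneratorConfig = DEFAULT_GENERATOR, seed: int = 0,
                     with_methylomes: bool = True,
                     comparison_kinds: tuple[str, ...] = ("matched", "normal_normal"),
                     analysis: AnalysisConfig = DEFAULT_CONFIG) -> SyntheticDataset:
    """Generate a full dataset from one seed (see module docstring for the
    stream discipline)."""
    streams = np.random.SeedSequence(seed).spawn(4)
    rng_ref, rng_truth, rng_meth, rng_calls = map(np.random.default_rng, streams)
    reference = generate_reference(config, rng_ref)
    manifest = default_manifest(config)
    truth = generate_truth(reference, manifest, config, rng_truth, analysis)
    bin_grid = build_bin_grid(reference.chrom_sizes, reference.cpgs,
                              reference.blacklist, analysis)
    comparisons = [c for c in enumerate_comparisons(manifest)
                   if c.kind in comparison_kinds]
    tracks = (generate_cohort_methylomes(reference, truth, manifest, config, rng_meth)
              if with_methylomes else None)
    calls = generate_dmr_calls(truth, comparisons, bin_grid, config, rng_calls)
    return SyntheticDataset(config, seed, reference, manifest, truth,
                            bin_grid, comparisons, tracks, calls)


def catalog_from_dataset(dataset: SyntheticDataset,
                         analysis: AnalysisConfig = DEFAULT_CONFIG,
                         use_tracks: bool = True) -> DMRCatalog:
    """Run the catalogue stage on a generated dataset: filter the calls,
    re-derive matched-call directions from the methylomes when available,
    and build the unique-DMR catalogue."""
    from .dmr_catalog import assign_direction, build_catalog, filter_calls

    filtered = filter_calls(dataset.calls, analysis, dataset.bin_grid)
    if use_tracks and dataset.tracks is not None:
        parts = []
        for comp in dataset.comparisons:
            sub = filtered[filtered["comparison_id"] == comp.comparison_id]
            if sub.empty:
                continue
            if comp.kind == "matched":
                sub = assign_direction(sub, dataset.tracks[comp.sample_ref.sample_id],
                                       dataset.tracks[comp.sample_alt.sample_id],
                                       analysis)
            parts.append(sub)
        filtered = (pd.concat(parts, ignore_index=True) if parts
                    else filtered.iloc[0:0])
    return build_catalog(filtered, dataset.comparisons)


# ---------------------------------------------------------------------------
# dataset directory I/O
# ---------------------------------------------------------------------------

def _safe_name(comparison_id: str) -> str:
    return comparison_id.replace(":", "__").replace("|", "--")


def write_dataset(dataset: SyntheticDataset, outdir, force: bool = False) -> Path:
    """Lay the dataset out as the CLI expects, with a machine-readable truth
    manifest and provenance (config + seed)."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)
    ref = dataset.reference
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom, length in ref.chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")
    ref.cpgs.assign(end=ref.cpgs["pos"] + 1)[["chrom", "pos", "end"]].to_csv(
        outdir / "cpgs.bed", sep="\t", header=False, index=False)
    ref.cgis.to_csv(outdir / "cgi.bed", sep="\t", header=False, index=False)
    ref.blacklist.to_csv(outdir / "blacklist.bed", sep="\t", header=False, index=False)
    ref.segmentation.to_csv(outdir / "segmentation.bed", sep="\t",
                            header=False, index=False)
    rmsk = pd.DataFrame({
        "genoName": ref.repeats["chrom"], "genoStart": ref.repeats["start"],
        "genoEnd": ref.repeats["end"], "strand": ref.repeats["strand"],
        "repName": ref.repeats["subfamily"], "repClass": ref.repeats["repeat_class"],
        "repFamily": ref.repeats["family"],
        "milliDiv": ref.repeats["milli_div"].round(0).astype(int)})
    rmsk.to_csv(outdir / "rmsk.tsv", sep="\t", index=False)
    ref.transcripts.to_csv(outdir / "transcripts.tsv", sep="\t", index=False)
    man = pd.DataFrame([dataclasses.asdict(r) for r in dataset.manifest])
    man["purity"] = man["purity"].fillna("")
    man.to_csv(outdir / "manifest.csv", index=False)
    if dataset.tracks is not None:
        meth = outdir / "meth"
        meth.mkdir(exist_ok=True)
        for sid, track in dataset.tracks.items():
            df = track.cpgs.assign(end=track.cpgs["pos"] + 1)
            df[["chrom", "pos", "end", "level"]].to_csv(
                meth / f"{sid}.bedgraph", sep="\t", header=False, index=False,
                float_format="%.4f")
    calls_dir = outdir / "calls"
    calls_dir.mkdir(exist_ok=True)
    for comp in dataset.comparisons:
        sub = dataset.calls[dataset.calls["comparison_id"] == comp.comparison_id]
        stat = np.where(sub["direction"] == "hyper", 1.0,
                        np.where(sub["direction"] == "hypo", -1.0, 0.0))
        out = sub[["chrom", "start", "end", "q_value"]].assign(stat=stat)
        out.to_csv(calls_dir / f"{_safe_name(comp.comparison_id)}.tsv",
                   sep="\t", header=False, index=False)
    truth = dataset.truth.planted.copy()
    truth["patients"] = truth["patients"].map(lambda ps: ",".join(ps))
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    hs = dataset.truth.hotspot_windows.copy()
    if not hs.empty:
        hs["patients"] = hs["patients"].map(lambda ps: ",".join(ps))
    hs.to_csv(outdir / "truth_hotspots.tsv", sep="\t", index=False)
    with open(outdir / "provenance.yaml", "w") as fh:
        yaml.safe_dump({"seed": dataset.seed,
                        "config": dataclasses.asdict(dataset.config)}, fh)
    return outdir


def validate_dataset(path) -> dict:
    """Check a dataset directory's inputs parse and are mutually consistent;
    returns a summary dict."""
    from .genome_io import (read_bed, read_chrom_sizes, read_manifest,
                            read_rmsk, read_transcripts)
    path = Path(path)
    sizes = read_chrom_sizes(path / "chrom.sizes")
    manifest = read_manifest(path / "manifest.csv")
    cpgs = read_bed(path / "cpgs.bed")
    for name in ("cgi.bed", "blacklist.bed"):
        read_bed(path / name)
    seg = read_bed(path / "segmentation.bed", kind="segmentation")
    repeats = read_rmsk(path / "rmsk.tsv")
    tx = read_transcripts(path / "transcripts.tsv")
    for df, label in ((cpgs, "cpgs"), (seg, "segmentation")):
        bad = [c for c in df["chrom"].unique() if c not in sizes]
        if bad:
            raise ValueError(f"{label} references unknown chromosomes {bad}")
    n_calls = len(list((path / "calls").glob("*.tsv"))) if (path / "calls").is_dir() else 0
    n_meth = len(list((path / "meth").glob("*.bedgraph"))) if (path / "meth").is_dir() else 0
    return {"n_chroms": len(list(sizes)), "n_samples": len(manifest),
            "n_cpgs": len(cpgs), "n_transcripts": len(tx),
            "n_repeats": len(repeats), "n_call_tables": n_calls,
            "n_methylomes": n_meth}


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------

def evaluate_recovery(catalog: DMRCatalog, truth: SyntheticTruth,
                      hotspot_flags: pd.DataFrame | None = None,
                      min_patients: int = 2) -> dict:
    """Score pipeline output against the planted truth.

    Recurrent detection: a planted bin with >= ``min_patients`` patients
    counts as recovered when the catalogue shows it with the same direction
    and recurrence >= ``min_patients``; precision is the share of such
    catalogue DMRs that were planted. Hotspot scoring uses the
    recurrent-density clause only (the top-N clause flags a fixed number of
    windows by construction and has no planted-truth analogue).
    """
    rec = catalog.recurrence()
    dmr_pos = catalog.dmrs.set_index("dmr_id")
    rec = rec.join(dmr_pos[["chrom", "bin"]], on="dmr_id")
    detected = set(zip(rec.loc[rec["n_comparisons"] >= min_patients, "chrom"],
                       rec.loc[rec["n_comparisons"] >= min_patients, "bin"],
                       rec.loc[rec["n_comparisons"] >= min_patients, "direction"]))
    truth_rec = truth.recurrent(min_patients)
    truth_keys = set(zip(truth_rec["chrom"], truth_rec["bin"], truth_rec["direction"]))
    tp = len(detected & truth_keys)
    out = {
        "recurrent_sensitivity": tp / len(truth_keys) if truth_keys else float("nan"),
        "recurrent_precision": tp / len(detected) if detected else float("nan"),
        "n_planted_recurrent": len(truth_keys),
        "n_detected_recurrent": len(detected),
    }
    if hotspot_flags is not None:
        flagged = hotspot_flags[hotspot_flags["recurrent"]]
        fkeys = set(zip(flagged["direction"], flagged["chrom"], flagged["start"]))
        hs = truth.hotspot_windows
        tkeys = set(zip(hs["direction"], hs["chrom"], hs["start"]))
        tp_h = len(fkeys & tkeys)
        out.update({
            "hotspot_sensitivity": tp_h / len(tkeys) if tkeys else float("nan"),
            "hotspot_false_discoveries": len(fkeys - tkeys),
            "n_planted_hotspots": len(tkeys),
        })
    return out
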