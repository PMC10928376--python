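"""Data model, readers, interval algebra, bin grids, and promoter derivation.

Interval containers are plain :class:`pandas.DataFrame` objects with at least
``chrom``/``start``/``end`` columns in 0-based half-open convention; payload
columns (state labels, transcript ids, ...) ride along. Overlap queries are
backed by :mod:`intervaltree`, whose half-open semantics match ours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .config import AnalysisConfig, DEFAULT_CONFIG, chrom_sort_key, normalize_chrom

log = logging.getLogger(__name__)

__all__ = [
    "ChromSizes",
    "SampleRecord",
    "MethylationTrack",
    "BinGrid",
    "read_manifest",
    "read_chrom_sizes",
    "read_bed",
    "read_rmsk",
    "read_transcripts",
    "read_methylation_bedgraph",
    "write_bed",
    "derive_promoters",
    "build_bin_grid",
    "merge_intervals",
    "overlap_query",
    "overlap_any",
    "overlap_bases",
]

#: RepeatMasker classes treated as transposable elements
TE_CLASSES = frozenset(
    {"DNA", "DNA?", "LINE", "LINE?", "LTR", "LTR?", "Other", "RC",
     "SINE", "SINE?", "Unknown", "Unknown?"}
)

_SMOKING_MAP = {
    "never": "never", "never-smoker": "never", "never_smoker": "never",
    "smoker": "smoker", "current": "smoker", "former": "smoker",
    "former-smoker": "smoker", "ever": "smoker",
}
_MALIGNANCY_TOKENS = {"normal", "tumor"}


@dataclass(frozen=True)
class ChromSizes:
    """Chromosome name -> length (bp) with karyotype-ordered iteration."""

    entries: dict[str, int]

    def __post_init__(self):
        clean = {}
        for name, length in self.entries.items():
            name = normalize_chrom(name)
            length = int(length)
            if length <= 0:
                raise ValueError(f"non-positive length for {name}")
            if name in clean:
                raise ValueError(f"duplicate chromosome {name}")
            clean[name] = length
        object.__setattr__(self, "entries", clean)

    def __getitem__(self, chrom: str) -> int:
        return self.entries[normalize_chrom(chrom)]

    def __contains__(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self.entries

    def __iter__(self):
        return iter(sorted(self.entries, key=chrom_sort_key))

    def items(self):
        return ((c, self.entries[c]) for c in self)


@dataclass(frozen=True)
class SampleRecord:
    """One profiled sample with its clinicopathologic annotations.

    ``smoking`` folds former smokers into the smoker category; any
    unparseable or missing covariate becomes ``"unconfirmed"``.
    """

    sample_id: str
    patient_id: str
    malignancy: str  # "normal" | "tumor"
    smoking: str = "unconfirmed"  # "never" | "smoker" | "unconfirmed"
    stage: str = "unconfirmed"
    subtype: str = "unconfirmed"
    purity: float | None = None


@dataclass
class MethylationTrack:
    """Per-CpG methylation levels for one sample.

    ``cpgs`` holds ``chrom`` / ``pos`` / ``level`` with levels as fractions in
    [0, 1], sorted by (chrom, pos) and unique per position.
    """

    sample_id: str
    cpgs: pd.DataFrame

    def __post_init__(self):
        df = self.cpgs
        if not {"chrom", "pos", "level"} <= set(df.columns):
            raise ValueError("track needs chrom/pos/level columns")
        lv = df["level"].to_numpy(float)
        if lv.size and (lv.min() < 0 or lv.max() > 1):
            raise ValueError("methylation levels must lie in [0, 1]")
        self.cpgs = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    def levels_at(self, chrom: str, start: int, end: int) -> np.ndarray:
        sub = self.cpgs[self.cpgs["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [start, end])
        return sub["level"].to_numpy()[lo:hi]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str,
                       keep_default_na=False, comment="#")


def read_manifest(path) -> list[SampleRecord]:
    """Parse the cohort sample manifest (CSV/TSV with a header).

    Required columns: sample_id, patient_id, malignancy, smoking, stage,
    subtype, purity. Unknown smoking/stage/subtype tokens map to
    ``unconfirmed``; an unknown malignancy token or duplicate sample_id is a
    hard error.
    """
    df = _read_table(path)
    required = {"sample_id", "patient_id", "malignancy", "smoking",
                "stage", "subtype", "purity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in manifest")
    records = []
    for row in df.itertuples(index=False):
        malignancy = row.malignancy.strip().lower()
        if malignancy not in _MALIGNANCY_TOKENS:
            raise ValueError(f"unknown malignancy token {row.malignancy!r}")
        smoking = _SMOKING_MAP.get(row.smoking.strip().lower(), "unconfirmed")
        stage = row.stage.strip() or "unconfirmed"
        subtype = row.subtype.strip() or "unconfirmed"
        purity_txt = row.purity.strip()
        purity = float(purity_txt) if purity_txt else None
        if purity is not None and not (0.0 <= purity <= 1.0):
            raise ValueError(f"purity outside [0,1] for {row.sample_id}")
        records.append(SampleRecord(row.sample_id.strip(), row.patient_id.strip(),
                                    malignancy, smoking, stage, subtype, purity))
    normals = [(r.patient_id,) for r in records if r.malignancy == "normal"]
    if len(normals) != len(set(normals)):
        raise ValueError("a patient has more than one normal sample")
    return records


def read_chrom_sizes(path) -> ChromSizes:
    entries = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, length = line.split()[:2]
        entries[name] = int(length)
    return ChromSizes(entries)


def read_bed(path, kind: str = "generic") -> pd.DataFrame:
    """Read BED3/BED4 into a sorted interval frame.

    ``kind="segmentation"`` keeps column 4 as ``state``; other kinds keep a
    ``name`` column when present. Lines with start >= end are skipped with a
    warning; non-integer coordinates are a hard error.
    """
    rows, skipped = [], 0
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: fewer than 3 BED fields")
        chrom = normalize_chrom(parts[0])
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: malformed coordinates") from exc
        if start >= end:
            skipped += 1
            continue
        row = {"chrom": chrom, "start": start, "end": end}
        if len(parts) > 3:
            row["state" if kind == "segmentation" else "name"] = parts[3]
        rows.append(row)
    if skipped:
        log.warning("%s: skipped %d lines with start >= end", path, skipped)
    if not rows:
        cols = ["chrom", "start", "end"]
        if kind == "segmentation":
            cols.append("state")
        return pd.DataFrame(columns=cols)
    return sort_intervals(pd.DataFrame(rows))


_RMSK_COLS = ["genoName", "genoStart", "genoEnd", "strand",
              "repName", "repClass", "repFamily", "milliDiv"]


def read_rmsk(path) -> pd.DataFrame:
    """Read a RepeatMasker rmsk-style table into a repeat element frame.

    Output columns: chrom/start/end/strand/subfamily/family/repeat_class,
    ``milli_div`` (NaN when absent), ``subst_prop`` = milli_div/1000, and
    ``is_TE`` from the transposable-element class vocabulary.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_RMSK_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"rmsk table missing columns: {sorted(missing)}")
    out = pd.DataFrame({
        "chrom": df["genoName"].map(normalize_chrom),
        "start": df["genoStart"].astype(int),
        "end": df["genoEnd"].astype(int),
        "strand": df["strand"],
        "subfamily": df["repName"],
        "family": df["repFamily"],
        "repeat_class": df["repClass"],
    })
    milli = pd.to_numeric(df["milliDiv"], errors="coerce")
    if ((milli < 0) | (milli > 1000)).any():
        raise ValueError("milliDiv outside [0, 1000]")
    out["milli_div"] = milli
    out["subst_prop"] = milli / 1000.0
    out["is_TE"] = out["repeat_class"].isin(TE_CLASSES)
    n_missing = int(milli.isna().sum())
    if n_missing:
        log.warning("%s: %d repeats lack milliDiv; excluded from divergence analyses",
                    path, n_missing)
    return sort_intervals(out)


_TX_COLS = ["transcript_id", "gene_id", "gene_name", "biotype",
            "chrom", "strand", "tx_start", "tx_end"]


def read_transcripts(path) -> pd.DataFrame:
    """Read the transcript model lookup table (TSV with a header)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_TX_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"transcript table missing columns: {sorted(missing)}")
    df = df.copy()
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["tx_start"] = df["tx_start"].astype(int)
    df["tx_end"] = df["tx_end"].astype(int)
    if (df["tx_start"] >= df["tx_end"]).any():
        raise ValueError("transcript with tx_start >= tx_end")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("transcript strand must be + or -")
    return df.reset_index(drop=True)


def read_methylation_bedgraph(path, sample_id: str) -> MethylationTrack:
    """Read a one-CpG-per-line bedGraph into a :class:`MethylationTrack`.

    The value scale is auto-detected: any value > 1 means the file is on the
    percent scale and everything is divided by 100. Values outside [0, 100]
    are a hard error. Unsorted input is sorted with a warning.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"],
                     dtype={0: str, 1: int, 2: int, 3: float})
    values = df["value"].to_numpy(float)
    if values.size and (values.min() < 0 or values.max() > 100):
        raise ValueError(f"{path}: methylation values outside [0, 100]")
    if values.size and values.max() > 1.0:
        values = values / 100.0
    out = pd.DataFrame({"chrom": df["chrom"].map(normalize_chrom),
                        "pos": df["start"].to_numpy(), "level": values})
    sorted_out = out.sort_values(["chrom", "pos"], kind="mergesort")
    if not sorted_out.index.equals(out.index):
        log.warning("%s: bedGraph not sorted; sorting", path)
    return MethylationTrack(sample_id, sorted_out.reset_index(drop=True))


def write_bed(df: pd.DataFrame, path, extra_cols: tuple[str, ...] = ()) -> None:
    cols = ["chrom", "start", "end", *extra_cols]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    chroms = sorted(df["chrom"].unique(), key=chrom_sort_key)
    rank = {c: i for i, c in enumerate(chroms)}
    order = np.lexsort((df["end"].to_numpy(), df["start"].to_numpy(),
                        df["chrom"].map(rank).to_numpy()))
    return df.iloc[order].reset_index(drop=True)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse an interval set to its minimal non-overlapping cover.

    Abutting intervals merge (bedtools-merge default). Payload columns are
    dropped; output sorted by (chrom, start).
    """
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    out = []
    for chrom in sorted(df["chrom"].unique(), key=chrom_sort_key):
        sub = df[df["chrom"] == chrom].sort_values(["start", "end"])
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlap or abut
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def overlap_query(query: pd.DataFrame, subject: pd.DataFrame) -> pd.DataFrame:
    """All (query, subject) pairs sharing >= 1 base, with shared-base counts.

    Half-open semantics: end-touching intervals do not overlap. Returns a
    frame with ``query_index`` / ``subject_index`` (positional indices into
    the inputs) and ``overlap`` in bp.
    """
    trees: dict[str, IntervalTree] = {}
    for j, row in enumerate(subject.itertuples(index=False)):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, j)
    hits = []
    for i, row in enumerate(query.itertuples(index=False)):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(row.start, row.end):
            shared = min(row.end, iv.end) - max(row.start, iv.begin)
            hits.append((i, iv.data, shared))
    out = pd.DataFrame(hits, columns=["query_index", "subject_index", "overlap"])
    return out.sort_values(["query_index", "subject_index"]).reset_index(drop=True)


def _merged_arrays(subject: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = merge_intervals(subject)
    return {chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
            for chrom, sub in merged.groupby("chrom", sort=False)}


def overlap_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: does it share >= 1 base with the subject set?"""
    arrays = _merged_arrays(subject) if not subject.empty else {}
    query = query.reset_index(drop=True)
    flags = np.zeros(len(query), dtype=bool)
    for chrom, sub in query.groupby("chrom", sort=False):
        if chrom not in arrays:
            continue
        starts, ends = arrays[chrom]
        qs = sub["start"].to_numpy()
        qe = sub["end"].to_numpy()
        # candidate merged interval: last one starting before the query end
        idx = np.searchsorted(starts, qe, side="left") - 1
        ok = idx >= 0
        hit = np.zeros(len(sub), dtype=bool)
        hit[ok] = ends[idx[ok]] > qs[ok]
        flags[sub.index.to_numpy()] = hit
    return flags


def overlap_bases(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Shared base count per query interval against the merged subject set."""
    arrays = _merged_arrays(subject) if not subject.empty else {}
    query = query.reset_index(drop=True)
    out = np.zeros(len(query), dtype=np.int64)
    for chrom, sub in query.groupby("chrom", sort=False):
        if chrom not in arrays:
            continue
        starts, ends = arrays[chrom]
        vals = np.zeros(len(sub), dtype=np.int64)
        for k, (qs, qe) in enumerate(zip(sub["start"].to_numpy(), sub["end"].to_numpy())):
            lo = np.searchsorted(ends, qs, side="right")
            hi = np.searchsorted(starts, qe, side="left")
            if hi > lo:
                vals[k] = np.sum(np.minimum(ends[lo:hi], qe) - np.maximum(starts[lo:hi], qs))
        out[sub.index.to_numpy()] = vals
    return out


# ---------------------------------------------------------------------------
# promoters and bin grids
# ---------------------------------------------------------------------------

def derive_promoters(transcripts: pd.DataFrame, chrom_sizes: ChromSizes,
                     config: AnalysisConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Promoter intervals around each transcript's TSS.

    On + the TSS is tx_start and the promoter is [TSS - upstream,
    TSS + downstream); on - the TSS is tx_end and the promoter is the mirror
    [TSS - downstream, TSS + upstream). Clipped to chromosome bounds.
    """
    plus = transcripts["strand"].to_numpy() == "+"
    tss = np.where(plus, transcripts["tx_start"].to_numpy(),
                   transcripts["tx_end"].to_numpy())
    up, down = config.promoter_upstream, config.promoter_downstream
    start = np.where(plus, tss - up, tss - down)
    end = np.where(plus, tss + down, tss + up)
    lengths = transcripts["chrom"].map(lambda c: chrom_sizes[c]).to_numpy()
    out = transcripts[["transcript_id", "gene_id", "gene_name", "biotype",
                       "chrom", "strand"]].copy()
    out["start"] = np.clip(start, 0, lengths)
    out["end"] = np.clip(end, 0, lengths)
    out = out[out["start"] < out["end"]]
    return out[["chrom", "start", "end", "strand", "transcript_id",
                "gene_id", "gene_name", "biotype"]].reset_index(drop=True)


@dataclass
class BinGrid:
    """Fixed-width bin tiling of the genome with CpG and blacklist flags.

    A bin is keyed ``(chrom, index)`` with ``index = floor(start / width)``.
    The background set comprises CpG-containing, non-blacklisted bins on the
    configured background chromosomes (autosomes + X) — the universe of
    potential DMRs.
    """

    width: int
    chrom_sizes: ChromSizes
    contains_cpg: dict[str, np.ndarray]
    blacklisted: dict[str, np.ndarray]
    background_chroms: tuple[str, ...]

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.width)

    def bin_interval(self, chrom: str, index: int) -> tuple[int, int]:
        start = index * self.width
        return start, min(start + self.width, self.chrom_sizes[chrom])

    def is_background(self, chrom: str, index: int) -> bool:
        if chrom not in self.background_chroms or chrom not in self.contains_cpg:
            return False
        return bool(self.contains_cpg[chrom][index] and not self.blacklisted[chrom][index])

    def background_bins(self) -> pd.DataFrame:
        """All background bins as a frame with chrom/bin/start/end."""
        frames = []
        for chrom in self.chrom_sizes:
            if chrom not in self.background_chroms:
                continue
            mask = self.contains_cpg[chrom] & ~self.blacklisted[chrom]
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            frames.append(pd.DataFrame({
                "chrom": chrom, "bin": idx,
                "start": idx * self.width,
                "end": np.minimum((idx + 1) * self.width, self.chrom_sizes[chrom]),
            }))
        if not frames:
            return pd.DataFrame(columns=["chrom", "bin", "start", "end"])
        return pd.concat(frames, ignore_index=True)

    @property
    def n_background(self) -> int:
        return sum(int((self.contains_cpg[c] & ~self.blacklisted[c]).sum())
                   for c in self.chrom_sizes if c in self.background_chroms)


def build_bin_grid(chrom_sizes: ChromSizes, cpg_positions: pd.DataFrame,
                   blacklist: pd.DataFrame | None = None,
                   config: AnalysisConfig = DEFAULT_CONFIG) -> BinGrid:
    """Tile the genome into ``config.bin_width`` bins and flag each bin.

    ``cpg_positions`` is a frame with chrom/pos (the union of CpGs across
    samples); ``blacklist`` is an interval frame. A bin is blacklisted if any
    base overlaps a blacklist interval.
    """
    width = config.bin_width
    contains_cpg, black = {}, {}
    for chrom, length in chrom_sizes.items():
        n = -(-length // width)
        contains_cpg[chrom] = np.zeros(n, dtype=bool)
        black[chrom] = np.zeros(n, dtype=bool)
    for chrom, sub in cpg_positions.groupby("chrom", sort=False):
        if chrom not in chrom_sizes:
            continue
        idx = sub["pos"].to_numpy() // width
        contains_cpg[chrom][np.unique(idx)] = True
    if blacklist is not None and not blacklist.empty:
        for chrom, sub in blacklist.groupby("chrom", sort=False):
            if chrom not in chrom_sizes:
                continue
            for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
                lo, hi = s // width, -(-e // width)
                black[chrom][lo:min(hi, len(black[chrom]))] = True
    return BinGrid(width, chrom_sizes, contains_cpg, black,
                   tuple(c for c in config.background_chroms if c in chrom_sizes))
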