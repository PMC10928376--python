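"""Analysis-wide constants and chromosome conventions.

All coordinates in this package are 0-based, half-open (BED semantics); a CpG
position is the offset of the C on the + strand. Chromosome names are stored
with the ``chr`` prefix and ordered in karyotype order (chr1..chr22, chrX,
chrY, chrM).
"""

from __future__ import annotations

from dataclasses import dataclass


CANONICAL_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
#: chromosomes eligible for the background bin set (autosomes + X)
DEFAULT_BACKGROUND_CHROMS = CANONICAL_AUTOSOMES + ("chrX",)


def normalize_chrom(name: str) -> str:
    """Accept chromosome names with or without the ``chr`` prefix."""
    name = str(name).strip()
    if not name:
        raise ValueError("empty chromosome name")
    if not name.startswith("chr"):
        name = "chr" + name
    # normalise mitochondrial aliases
    if name in ("chrMT", "chrMt"):
        name = "chrM"
    return name


def chrom_sort_key(name: str) -> tuple[int, int | str]:
    """Karyotype ordering: chr1..chr22 < chrX < chrY < chrM < everything else."""
    body = name[3:] if name.startswith("chr") else name
    if body.isdigit():
        return (0, int(body))
    special = {"X": 23, "Y": 24, "M": 25}
    if body in special:
        return (0, special[body])
    return (1, body)


def sort_chroms(names) -> list[str]:
    return sorted(set(names), key=chrom_sort_key)


@dataclass(frozen=True)
class AnalysisConfig:
    """Constants governing the downstream DMR analysis.

    Defaults follow the published workflow this package reimplements:
    500-bp analysis bins, promoters as [TSS-2000, TSS+500), a strict DMR
    Q-value cutoff of 1e-3 chosen from a 1e-2..1e-5 calibration grid,
    methylation-level categories at 30%/70%, and 1-Mb hotspot windows
    flagged above 1% DMR density.
    """

    bin_width: int = 500
    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    q_threshold: float = 1e-3
    q_calibration_grid: tuple[float, ...] = (1e-2, 1e-3, 1e-4, 1e-5)
    meth_low: float = 0.30
    meth_high: float = 0.70
    large_change: float = 0.10
    density_hotspot: float = 0.01
    density_high: float = 0.10
    hotspot_top_n: int = 15
    min_subfamily_cpgs: int = 10
    min_subfamily_dmrs: int = 5
    window_widths: tuple[int, ...] = (10_000, 100_000, 1_000_000, 10_000_000)
    background_chroms: tuple[str, ...] = DEFAULT_BACKGROUND_CHROMS
    excluded_dmr_chroms: tuple[str, ...] = ("chrY",)
    #: chromosomes excluded when building density windows
    excluded_window_chroms: tuple[str, ...] = ("chrY", "chrM")

    def __post_init__(self) -> None:
        if not (0.0 < self.meth_low < self.meth_high < 1.0):
            raise ValueError("need 0 < meth_low < meth_high < 1")
        if self.q_threshold not in self.q_calibration_grid:
            raise ValueError("q_threshold must be on the calibration grid")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


DEFAULT_CONFIG = AnalysisConfig()
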