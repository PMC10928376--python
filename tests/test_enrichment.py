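"""LOR enrichment, repeat statistics, Jukes-Cantor divergence, chromatin
state composition, and promoter-switch detection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmrscape.dmr_catalog import CALL_COLUMNS, build_catalog
from dmrscape.enrichment import (categorize_methylation_level,
                                 chromhmm_composition,
                                 classify_exclusive_feature, feature_lor,
                                 jukes_cantor_distance, log_odds_ratio,
                                 map_composite_state, repeat_class_composition,
                                 repeat_subfamily_lor,
                                 subfamily_methylation_profile)
from dmrscape.genome_io import MethylationTrack, SampleRecord
from conftest import intervals


# ---------------------------------------------------------------------------
# log-odds ratios
# ---------------------------------------------------------------------------

def bins(n, chrom="chr1", start=0):
    return intervals(*[(chrom, start + 500 * i, start + 500 * i + 500)
                       for i in range(n)])


def test_feature_lor_closed_form():
    """80/100 DMRs vs 500/1000 background bins overlap: odds 4 vs 1 -> ln 4."""
    dmrs = bins(100)
    background = bins(1000)
    feature = intervals(("chr1", 0, 80 * 500), ("chr1", 100 * 500, 520 * 500))
    rec = feature_lor(dmrs, feature, background)
    assert rec.dmr_count == 80 and rec.background_measure == 500
    assert rec.lor == pytest.approx(math.log(4), abs=1e-12)


def test_feature_lor_zero_cell_is_finite_negative():
    dmrs = bins(100, start=600_000)           # none overlap the feature
    background = bins(1000)
    feature = intervals(("chr1", 0, 500 * 500))
    rec = feature_lor(dmrs, feature, background)
    assert np.isfinite(rec.lor) and rec.lor < 0
    with pytest.raises(ValueError, match="empty"):
        feature_lor(dmrs.iloc[0:0], feature, background)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
def test_lor_identities(p, q):
    assert log_odds_ratio(p, p) == pytest.approx(0.0, abs=1e-12)
    assert log_odds_ratio(p, q) == pytest.approx(-log_odds_ratio(q, p), abs=1e-12)


def test_lor_converges_to_zero_for_uniformly_planted_dmrs():
    """DMRs drawn uniformly from the background have no enrichment: LOR -> 0
    as the planted count grows (10,000 draws, |LOR| < 0.1)."""
    rng = np.random.default_rng(0)
    n_bg = 20_000
    background = bins(n_bg)
    chosen = rng.choice(n_bg, size=10_000, replace=False)
    dmrs = background.iloc[chosen]
    feature = intervals(("chr1", 0, 500 * (n_bg // 3)))
    rec = feature_lor(dmrs, feature, background)
    assert abs(rec.lor) < 0.1


# ---------------------------------------------------------------------------
# exclusive feature classes
# ---------------------------------------------------------------------------

def test_classify_exclusive_feature_precedence():
    dmrs = intervals(("chr1", 0, 500),        # promoter + gene -> promoter
                     ("chr1", 5_000, 5_500),  # gene only -> genic
                     ("chr1", 50_000, 50_500))
    promoters = intervals(("chr1", 400, 900))
    genes = intervals(("chr1", 0, 10_000))
    assert classify_exclusive_feature(dmrs, promoters, genes).tolist() == [
        "promoter", "genic", "intergenic"]


# ---------------------------------------------------------------------------
# repeats
# ---------------------------------------------------------------------------

def repeat_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "subfamily",
                                       "family", "repeat_class"])


def test_repeat_class_composition_counts_elements():
    genome = repeat_frame([("chr1", i * 1000, i * 1000 + 100, "s", "f",
                            "SINE" if i < 50 else "LINE") for i in range(100)])
    dmr_overlap = pd.concat([genome.iloc[:8], genome.iloc[50:52]])
    out = repeat_class_composition(dmr_overlap, genome).set_index("repeat_class")
    assert out.loc["SINE", "genome"] == pytest.approx(0.5)
    assert out.loc["SINE", "dmr"] == pytest.approx(0.8)
    assert out.loc["LINE", "dmr"] == pytest.approx(0.2)
    assert out[["genome", "dmr"]].sum().tolist() == pytest.approx([1.0, 1.0])


def test_repeat_subfamily_lor_closed_form():
    """5/50 DMRs overlap a subfamily holding 1% of repeat bases:
    ln[(0.1/0.9)/(0.01/0.99)] ~ 2.398."""
    rows = [("chr1", i * 10_000, i * 10_000 + 100, "TARGET", "f", "LTR")
            for i in range(5)]
    rows += [("chr2", 0, 49_500, "OTHER", "f", "LINE")]
    repeats = repeat_frame(rows)
    dmrs = pd.concat([
        intervals(*[("chr1", i * 10_000, i * 10_000 + 500) for i in range(5)]),
        bins(45, chrom="chr3")], ignore_index=True)
    rec = repeat_subfamily_lor(dmrs, "TARGET", repeats)
    assert rec.background_fraction == pytest.approx(0.01)
    assert rec.lor == pytest.approx(
        math.log((0.1 / 0.9) / (0.01 / 0.99)), abs=1e-12)


def test_repeat_subfamily_lor_equal_proportions_is_zero():
    repeats = repeat_frame([("chr1", 0, 100, "A", "f", "LTR"),
                            ("chr2", 0, 100, "B", "f", "LTR")])
    dmrs = intervals(("chr1", 0, 500), ("chr3", 0, 500))  # 1/2 overlap, bp 1/2
    assert repeat_subfamily_lor(dmrs, "A", repeats).lor == pytest.approx(0.0)


def test_subfamily_reporting_threshold_excludes_at_most_five(dataset, config):
    from dmrscape.enrichment import subfamily_enrichment_table
    dmrs = {"hypo": bins(3)}
    table = subfamily_enrichment_table(dmrs, dataset.reference.repeats, config)
    # 3 DMRs can never exceed the >5 overlap requirement
    assert table.empty


# ---------------------------------------------------------------------------
# Jukes-Cantor
# ---------------------------------------------------------------------------

def test_jukes_cantor_closed_form_values():
    assert jukes_cantor_distance(0.0) == 0.0
    # closed form: -(3/4) ln(1 - 0.4/3) = 0.1073256...
    assert jukes_cantor_distance(0.1) == pytest.approx(0.1073256, abs=1e-6)
    assert np.isnan(jukes_cantor_distance(0.75))


def test_jukes_cantor_small_p_linearity_and_monotonicity():
    p = np.linspace(0.0, 0.74, 200)
    d = jukes_cantor_distance(p)
    assert (np.diff(d) > 0).all()
    small = np.array([1e-4, 1e-3, 1e-2])
    assert jukes_cantor_distance(small) == pytest.approx(small, rel=2e-2)
    assert jukes_cantor_distance(0.7499) > 3  # blows up near the domain edge


# ---------------------------------------------------------------------------
# chromatin states
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("state,model,expected", [
    ("1_TssA", "18-state", "active_regulatory"),
    ("5_Tx", "18-state", "transcribed"),
    ("14_TssBiv", "18-state", "polycomb"),
    ("18_Quies", "18-state", "other"),
    ("6_EnhG", "15-state", "active_regulatory"),
    ("14_ReprPCWk", "15-state", "other"),
])
def test_map_composite_state(state, model, expected):
    assert map_composite_state(state, model) == expected


def test_map_composite_state_rejects_unknown():
    with pytest.raises(ValueError):
        map_composite_state("19_Nope", "18-state")
    with pytest.raises(ValueError):
        map_composite_state("16_ReprPC", "15-state")  # outside 15-state range


def test_chromhmm_composition_base_counting_and_conservation():
    seg = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 1250],
                        "end": [1250, 5000], "state": ["1_TssA", "18_Quies"]})
    dmrs = intervals(("chr1", 1000, 1500))      # split 250/250 across states
    background = intervals(("chr1", 0, 5000), ("chr2", 0, 1000))
    out = chromhmm_composition(dmrs, seg, background).set_index("state")
    assert out.loc["1_TssA", "dmr_fraction"] == pytest.approx(0.5)
    assert out.loc["18_Quies", "dmr_fraction"] == pytest.approx(0.5)
    # chr2 background bases are unannotated; proportions still sum to 1
    assert out["dmr_fraction"].sum() == pytest.approx(1.0)
    assert out["background_fraction"].sum() == pytest.approx(1.0)
    assert out.loc["unannotated", "background_fraction"] == pytest.approx(1000 / 6000)


def test_chromhmm_composition_sums_to_one_on_synthetic_dmrs(dataset, catalog):
    background = dataset.bin_grid.background_bins()[["chrom", "start", "end"]]
    out = chromhmm_composition(catalog.intervals()[["chrom", "start", "end"]],
                               dataset.reference.segmentation, background)
    assert out["dmr_fraction"].sum() == pytest.approx(1.0)
    assert np.isfinite(out["lor"]).all()


# ---------------------------------------------------------------------------
# methylation categories
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("level,expected", [
    (0.25, "hypomethylated"),
    (0.30, "intermediate"),   # boundaries belong to the closed 30%-70% band
    (0.70, "intermediate"),
    (0.90, "hypermethylated"),
])
def test_categorize_methylation_level(level, expected):
    assert categorize_methylation_level(level) == expected


# ---------------------------------------------------------------------------
# subfamily methylation profile
# ---------------------------------------------------------------------------

def make_track(sid, positions, level):
    return MethylationTrack(sid, pd.DataFrame(
        {"chrom": "chr1", "pos": positions, "level": level}))


def test_subfamily_profile_min_cpg_filter_and_unique_counting(config):
    # two overlapping elements share CpGs: each unique CpG counts once
    repeats = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 50],
                            "end": [100, 150], "subfamily": ["S", "S"]})
    few = [10 * i for i in range(9)]        # 9 CpGs: below the 10-CpG floor
    enough = [10 * i for i in range(12)]
    tracks9 = {"n1": make_track("n1", few, [0.9] * 9)}
    assert subfamily_methylation_profile("S", repeats, tracks9, config=config) is None
    manifest = [SampleRecord("n1", "P1", "normal"), SampleRecord("n2", "P2", "normal"),
                SampleRecord("t1", "P1", "tumor")]
    tracks = {"n1": make_track("n1", enough, [0.9] * 12),
              "n2": make_track("n2", enough, [0.9] * 12),
              "t1": make_track("t1", enough, [0.5] * 12)}
    prof = subfamily_methylation_profile("S", repeats, tracks, manifest, config)
    assert prof["n_cpgs"] == 12
    assert prof["normal_median"] == pytest.approx(0.9)
    assert prof["normal_spread"] == pytest.approx(0.0)
    assert prof["change_median"] == pytest.approx(-0.4)


# ---------------------------------------------------------------------------
# promoter switching
# ---------------------------------------------------------------------------

def promoter_rows():
    return pd.DataFrame({
        "chrom": ["chr1", "chr1"], "start": [0, 10_000], "end": [2_500, 12_500],
        "strand": ["+", "+"], "transcript_id": ["TA", "TB"],
        "gene_id": ["G1", "G1"], "gene_name": ["GENE1", "GENE1"]})


def switch_calls(rows):
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return build_catalog(calls)


def test_promoter_switch_detected_and_tiered():
    cat = switch_calls([
        ("matched:P1", "chr1", 1, 500, 1000, 1e-9, "hyper"),
        ("matched:P1", "chr1", 21, 10_500, 11_000, 1e-9, "hypo"),
        ("matched:P2", "chr1", 1, 500, 1000, 1e-9, "hyper"),
        ("matched:P2", "chr1", 21, 10_500, 11_000, 1e-9, "hypo"),
    ])
    from dmrscape.enrichment import detect_promoter_switches
    out = detect_promoter_switches(cat, promoter_rows())
    assert len(out) == 1
    assert out.loc[0, "n_comparisons"] == 2 and bool(out.loc[0, "recurrent"])


def test_no_switch_when_directions_agree():
    cat = switch_calls([
        ("matched:P1", "chr1", 1, 500, 1000, 1e-9, "hyper"),
        ("matched:P1", "chr1", 21, 10_500, 11_000, 1e-9, "hyper"),
    ])
    from dmrscape.enrichment import detect_promoter_switches
    assert detect_promoter_switches(cat, promoter_rows()).empty
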