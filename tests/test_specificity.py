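"""Category-exclusive DMRs, permutation nulls, window densities, hotspots."""

import numpy as np
import pandas as pd
import pytest

from dmrscape.config import AnalysisConfig
from dmrscape.dmr_catalog import CALL_COLUMNS, build_catalog
from dmrscape.genome_io import ChromSizes, build_bin_grid
from dmrscape.specificity import (CategoryRule, detect_hotspots,
                                  enumerate_label_assignments,
                                  exclusive_in_hotspots_fraction,
                                  find_exclusive_dmrs, make_windows,
                                  n_label_assignments,
                                  normal_field_effect_dmrs, permutation_null,
                                  smoking_rule_factory, window_density)
from dmrscape.synthetic import default_manifest
from conftest import intervals


def catalog_from(obs_rows):
    """obs_rows: (patient, chrom, bin, direction)."""
    calls = pd.DataFrame(
        [(f"matched:{p}", c, b, b * 500, b * 500 + 500, 1e-9, d)
         for p, c, b, d in obs_rows], columns=CALL_COLUMNS)
    return build_catalog(calls)


NEVERS = ("N1", "N2")
SMOKERS = ("S1", "S2", "S3", "S4")


def never_rule(**kw):
    return CategoryRule("never_specific", NEVERS, SMOKERS, 2, **kw)


def smoker_rule(**kw):
    return CategoryRule("smoker_specific", SMOKERS, NEVERS, 3, **kw)


def test_never_smoker_specific_requires_both_and_excludes_smokers():
    cat = catalog_from([
        ("N1", "chr1", 2, "hypo"), ("N2", "chr1", 2, "hypo"),
        ("U1", "chr1", 2, "hypo"),  # unconfirmed presence is ignored
        ("N1", "chr1", 8, "hypo"),  # only one never-smoker
    ])
    out = find_exclusive_dmrs(cat, never_rule())
    assert out["dmr_id"].tolist() == ["B1.1"]


def test_smoker_specific_fails_on_any_never_presence():
    cat = catalog_from([
        ("S1", "chr1", 2, "hyper"), ("S2", "chr1", 2, "hyper"),
        ("S3", "chr1", 2, "hyper"), ("N1", "chr1", 2, "hyper"),
    ])
    assert find_exclusive_dmrs(cat, smoker_rule()).empty


def test_direction_must_agree_for_exclusivity():
    cat = catalog_from([
        ("S1", "chr1", 2, "hyper"), ("S2", "chr1", 2, "hyper"),
        ("S3", "chr1", 2, "hypo"),  # third smoker carries the other direction
    ])
    assert find_exclusive_dmrs(cat, smoker_rule()).empty


def test_lenient_member_is_exempt_but_counted():
    # subtype pair {A, L} with lenient L: presence in A alone qualifies
    rule = CategoryRule("subtype", ("A", "L"), ("B",), 2, lenient_patients=("L",))
    cat = catalog_from([("A", "chr1", 2, "hyper")])
    out = find_exclusive_dmrs(cat, rule)
    assert out["dmr_id"].tolist() == ["B1.1"]
    assert out["n_members_with_dmr"].tolist() == [1]
    # but presence in the excluded patient still disqualifies
    cat2 = catalog_from([("A", "chr1", 2, "hyper"), ("B", "chr1", 2, "hyper")])
    assert find_exclusive_dmrs(cat2, rule).empty


def test_rule_with_unknown_patient_is_an_error():
    cat = catalog_from([("A", "chr1", 2, "hyper")])
    with pytest.raises(ValueError, match="unknown patients"):
        find_exclusive_dmrs(cat, never_rule(), known_patients={"A"})


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_patients,label_counts,expected", [
    (6, {"never": 2, "smoker": 4}, 15),
    (10, {"in_pair": 2, "out": 8}, 45),
    (2, {"a": 1, "b": 1}, 2),
])
def test_enumeration_size_is_multinomial(n_patients, label_counts, expected):
    patients = [f"P{i}" for i in range(n_patients)]
    assignments = enumerate_label_assignments(patients, label_counts)
    assert len(assignments) == expected == n_label_assignments(label_counts)
    # all assignments distinct
    assert len({tuple(sorted(a.items())) for a in assignments}) == expected


def test_permutation_null_identity_reproduces_observed():
    cat = catalog_from([
        ("N1", "chr1", 2, "hypo"), ("N2", "chr1", 2, "hypo"),
        ("N1", "chr2", 4, "hyper"), ("N2", "chr2", 4, "hyper"),
        ("S1", "chr3", 6, "hypo"), ("S2", "chr3", 6, "hypo"),
    ])
    truth = {"N1": "never", "N2": "never", "S1": "smoker", "S2": "smoker",
             "S3": "smoker", "S4": "smoker"}
    never_factory, _ = smoking_rule_factory()
    res = permutation_null(cat, sorted(truth), {"never": 2, "smoker": 4},
                           never_factory, true_assignment=truth)
    assert res.n_permutations == 15
    assert res.observed == 2
    assert res.permutation_counts[0] == res.observed
    assert res.observed in res.permutation_counts


def test_permutation_cap_raises():
    cat = catalog_from([("A", "chr1", 2, "hyper")])
    patients = [f"P{i}" for i in range(30)]
    with pytest.raises(ValueError, match="sampled null"):
        permutation_null(cat, patients, {"a": 15, "b": 15},
                         lambda a: never_rule(), max_enumeration=100)


# ---------------------------------------------------------------------------
# normal-vs-normal field effects
# ---------------------------------------------------------------------------

def nn_catalog(rows):
    """rows: (sample_a, sample_b, chrom, bin)."""
    calls = pd.DataFrame(
        [(f"nn:{a}|{b}", c, i, i * 500, i * 500 + 500, 1e-9, "hypo")
         for a, b, c, i in rows], columns=CALL_COLUMNS)
    return build_catalog(calls)


def test_normal_field_effect_categories_and_example_tier():
    manifest = default_manifest()
    nevers = ["Patient_01_N", "Patient_02_N"]
    smokers = ["Patient_03_N", "Patient_04_N", "Patient_05_N"]
    cat = nn_catalog([
        # bin 2: 3 never-vs-smoker comparisons spanning both nevers -> example
        (nevers[0], smokers[0], "chr1", 2),
        (nevers[0], smokers[1], "chr1", 2),
        (nevers[1], smokers[2], "chr1", 2),
        # bin 8: also appears between the two nevers -> excluded from examples
        (nevers[0], smokers[0], "chr1", 8),
        (nevers[0], smokers[1], "chr1", 8),
        (nevers[1], smokers[2], "chr1", 8),
        (nevers[0], nevers[1], "chr1", 8),
        # bin 20: smoker-smoker only
        (smokers[0], smokers[1], "chr1", 20),
    ])
    out = normal_field_effect_dmrs(cat, manifest)
    cats = out["dmr_categories"].set_index("dmr_id")["categories"]
    assert cats["B1.1"] == ["never_smoker"]
    assert set(cats["B2.1"]) == {"never_never", "never_smoker"}
    assert cats["B3.1"] == ["smoker_smoker"]
    assert out["example_tier"] == ["B1.1"]
    counts = out["per_sample_counts"].set_index("sample_id")
    assert counts.loc["Patient_01_N", "n_dmrs_vs_smoker"] == 2


# ---------------------------------------------------------------------------
# window density and hotspots
# ---------------------------------------------------------------------------

def small_grid(config):
    sizes = ChromSizes({"chr1": 2_000_000})
    pos = np.arange(0, 2_000_000, 500) + 100   # every bin contains a CpG
    cpgs = pd.DataFrame({"chrom": "chr1", "pos": pos})
    return build_bin_grid(sizes, cpgs, None, config)


def test_window_density_is_dmr_bins_over_cpg_bins(config):
    grid = small_grid(config)
    windows = make_windows(grid, 1_000_000, config)
    assert windows["n_cpg_bins"].tolist() == [2000, 2000]
    calls = pd.DataFrame(
        [("matched:P1", "chr1", b, b * 500, b * 500 + 500, 1e-9, "hypo")
         for b in range(20)], columns=CALL_COLUMNS)
    dens = window_density(calls, windows, grid)
    first = dens[(dens["start"] == 0)].iloc[0]
    assert first["density"] == pytest.approx(20 / 2000)  # 1%
    second = dens[(dens["start"] == 1_000_000)].iloc[0]
    assert second["density"] == 0.0


def density_frame(rows):
    return pd.DataFrame(rows, columns=["comparison_id", "direction", "chrom",
                                       "start", "end", "n_dmrs", "density"])


def test_hotspot_recurrent_clause(config):
    dens = density_frame([
        ("c1", "hypo", "chr1", 0, 10 ** 6, 15, 0.015),
        ("c2", "hypo", "chr1", 0, 10 ** 6, 15, 0.015),   # > 1% in two patients
        ("c1", "hypo", "chr1", 10 ** 6, 2 * 10 ** 6, 20, 0.02),  # one patient only
    ])
    out = detect_hotspots(dens, config).set_index("start")
    assert bool(out.loc[0, "recurrent"])
    assert not bool(out.loc[10 ** 6, "recurrent"])


def test_hotspot_top_n_clause(config):
    # 40 windows at low density; the densest must still be flagged via top-15
    rows = [("c1", "hyper", "chr1", i * 10 ** 6, (i + 1) * 10 ** 6, 1, 0.005 - i * 1e-5)
            for i in range(40)]
    out = detect_hotspots(density_frame(rows), config)
    assert int(out["top_n"].sum()) == 15
    assert not out["recurrent"].any()
    flagged = out[out["hotspot"]]
    assert set(flagged["start"]) == {i * 10 ** 6 for i in range(15)}
    # a window at 2% in exactly one patient and rank 40 is not a hotspot
    assert not bool(out.set_index("start").loc[39 * 10 ** 6, "hotspot"])


def test_exclusive_in_hotspots_fraction(config):
    calls = pd.DataFrame(
        [("matched:P1", "chr1", b, b * 500, b * 500 + 500, 1e-9, "hypo")
         for b in range(100)]
        + [("matched:P2", "chr1", 5000, 2_500_000, 2_500_500, 1e-9, "hypo")],
        columns=CALL_COLUMNS)
    cat = build_catalog(calls)
    # P1's first 1-Mb window is above 10% density for P1 only
    dens = density_frame([
        ("matched:P1", "hypo", "chr1", 0, 10 ** 6, 100, 0.2),
        ("matched:P2", "hypo", "chr1", 0, 10 ** 6, 0, 0.0),
    ])
    out = exclusive_in_hotspots_fraction(cat, dens, config)
    by = out.set_index("comparison_id")
    assert by.loc["matched:P1", "fraction_in_hotspots"] == pytest.approx(1.0)
    assert by.loc["matched:P2", "fraction_in_hotspots"] == pytest.approx(0.0)
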