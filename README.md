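# dmrscape

Downstream analysis of differentially methylated regions (DMRs) in matched
normal/tumor methylome cohorts — the kind produced by MeDIP-seq + MRE-seq
profiling of non-small cell lung cancer, where per-CpG methylation levels
come from an integrative estimator (methylCRF) and 500-bp DMR calls from a
paired bin test (M&M). `dmrscape` takes those upstream outputs (call tables,
bedGraph methylation tracks, standard annotations) and produces:

- a **position-stable DMR catalogue**: the union of called 500-bp bins,
  merged into blocks of adjacent bins and identified as `B<block>.<pos>`,
  with per-direction recurrence across patient-matched comparisons;
- **Q-threshold calibration** diagnostics (false-positive ratio against
  normal–normal comparisons, shared fraction, large-methylation-change
  fraction) over a grid of candidate cutoffs;
- **enrichment statistics** on the natural-log odds scale,
  `LOR = ln[(p_D/(1−p_D)) / (p_B/(1−p_B))]`, for genomic features, repeat
  classes and subfamilies, and ChromHMM chromatin states, against the
  background of CpG-containing, non-blacklisted 500-bp bins;
- **repeat evolution summaries**: Jukes–Cantor distance
  `d = −(3/4)·ln(1 − 4p/3)` from RepeatMasker divergence, and per-subfamily
  methylation profiles over unique CpGs;
- **clinicopathologic specificity** with exhaustive label-permutation
  nulls: e.g. smoker-specific DMRs (present in ≥3 of 4 smokers, absent in
  both never-smokers) scored against all C(6,2)=15 relabelings of the six
  confirmed-status patients;
- **multi-resolution DMR density** and hotspot detection (1-Mb windows
  with >1% density in more than one patient, or among the top-15 densest);
- a **synthetic data generator** that emulates the full input stack —
  genome, CpG islands, transcripts, repeats, chromatin states, cohort
  methylomes and call tables — with planted recurrent, category-specific,
  repeat-targeted and hotspot-concentrated DMRs, so the entire pipeline is
  testable without any external download.

Methylation conventions: levels are fractions in [0,1]; a *hypoDMR* has
lower methylation in the tumor than in its matched normal, a *hyperDMR*
higher. Coordinates are 0-based half-open (BED semantics).

## Worked example

```python
from dmrscape import generate_dataset, catalog_from_dataset
from dmrscape.dmr_catalog import filter_calls
from dmrscape.specificity import (make_windows, window_density, detect_hotspots,
                                  permutation_null, smoking_rule_factory)
from dmrscape.synthetic import confirmed_smoking, evaluate_recovery

ds = generate_dataset(seed=7)            # 17 tumors, 10 matched normals
cat = catalog_from_dataset(ds)           # filter Q < 1e-3, direction from tracks
print(f"unique DMRs: {len(cat.dmrs)}")

filtered = filter_calls(ds.calls, bin_grid=ds.bin_grid)
matched = filtered[filtered.comparison_id.str.startswith("matched:")]
hot = detect_hotspots(window_density(matched, make_windows(ds.bin_grid, 1_000_000),
                                     ds.bin_grid))
labels = confirmed_smoking(ds.manifest)
_, smoker_rule = smoking_rule_factory()
res = permutation_null(cat, sorted(labels), {"never": 2, "smoker": 4},
                       smoker_rule, true_assignment=labels)
print(f"smoker-exclusive DMRs: observed {res.observed}, "
      f"null max {max(res.permutation_counts[1:])}")
print(evaluate_recovery(cat, ds.truth, hot))
```

prints

```
unique DMRs: 786
smoker-exclusive DMRs: observed 15, null max 10
{'recurrent_sensitivity': 1.0, 'recurrent_precision': 1.0,
 'n_planted_recurrent': 288, 'n_detected_recurrent': 288,
 'hotspot_sensitivity': 1.0, 'hotspot_false_discoveries': 0,
 'n_planted_hotspots': 2}
```

786 unique DMRs were catalogued from the planted + false-positive calls;
every planted DMR shared by ≥2 patients was recovered with the correct
direction (sensitivity and precision 1.0); both planted 1-Mb hotspot
windows were flagged by the recurrent->1%-density clause with no false
flags; and the 15 planted smoker-specific DMRs stand clear of the strongest
count (10) obtainable under any alternative smoking-label assignment.

The same stages are available from a shell:

```sh
dmrscape simulate --seed 7 --out data/
dmrscape validate data/
dmrscape catalog --dataset data/ --out results/
dmrscape density --dataset data/ --width 1000000 --out results/
```

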