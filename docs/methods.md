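# Methods

## Scope and data model

`dmrscape` implements the *downstream* half of a matched normal/tumor DNA
methylation study: it consumes per-comparison DMR call tables (500-bp bins
with Q values) and per-sample per-CpG methylation tracks, and produces
recurrence catalogues, enrichment statistics, clinicopathologic-specificity
tests, and density hotspot maps. The upstream machinery — read alignment,
MeDIP/MRE normalisation, the paired bin test that emits Q values, and the
CRF-based per-CpG methylation estimator — is out of scope; its outputs are
this package's inputs, and the synthetic generator emulates them directly.

Conventions: coordinates are 0-based half-open; a CpG position is the
offset of the C on the + strand; chromosome names carry the `chr` prefix
and sort in karyotype order (chr1..chr22, chrX, chrY, chrM). Methylation
levels are stored as fractions; bedGraph readers auto-detect percent-scaled
files (any value > 1 ⇒ divide by 100), since both scales occur in practice.

## The analysis grid and its background

All DMR arithmetic happens on a fixed 500-bp bin grid tiling each
chromosome (`bin = floor(start/500)`; the last bin may be short). The
*background* universe — the set of potential DMRs — is every bin on
chr1–chr22 + chrX that contains at least one CpG and does not overlap a
blacklist interval. DMR calls are kept when `q < 1e-3` (strictly; a call at
exactly the threshold is dropped), are removed on chrY (an all-female
cohort design), and are restricted to the background universe. The 1e-3
cutoff sits on a calibration grid {1e-2, 1e-3, 1e-4, 1e-5} for which the
package reports, per matched comparison: the false-positive ratio (mean
number of DMRs between that patient's normal and every other normal,
divided by the matched DMR count), the fraction of matched DMR instances
whose bin recurs in another matched comparison, and the fraction with
absolute mean-methylation change above 0.10.

## Catalogue identifiers

The union of all surviving called bins is merged into blocks of genomically
adjacent bins; blocks are numbered 1..K in karyotype order and bins within
a block 5′→3′, giving IDs `B<block>.<pos>`. The IDs are a pure function of
the called-bin set: ingesting comparisons in any order yields the same
catalogue (tested). Direction (hypo/hyper, relative to the tumor sample) is
taken from the methylation tracks — the sign of the tumor-minus-normal mean
over the bin's CpGs — with the caller's signed statistic used only as a
provisional direction when tracks are absent. A bin called hypo in one
comparison and hyper in another keeps both observations; recurrence is
counted per direction over matched comparisons.

## Enrichment statistics

All enrichments are natural-log odds ratios. For genomic features the unit
is the bin: `p_D` = fraction of DMR bins overlapping the feature set (≥1 bp),
`p_B` = the same fraction over background bins. For chromatin states the
unit is the base pair ("length of each DMR annotated with each state");
bases outside every segment count as `unannotated`, so each side's state
proportions sum to 1. For repeat subfamilies `p_D` is the fraction of DMRs
touching ≥1 element and `p_B` the subfamily's share of total repeat length;
subfamilies are reported only above 5 overlapping DMRs. A Haldane–Anscombe
+0.5 on all four cells is applied only when a cell is zero, leaving
non-degenerate LORs exactly at their closed-form values. The log base is
natural throughout.

Composite chromatin classes follow the standard 15-/18-state ChromHMM
vocabularies: active regulatory = states 1–3, 6–7 (15-state) or 1–4, 7–11
(18-state); transcribed = 5–6 and polycomb = 14–17 (18-state). Methylation
categories are hypomethylated < 30%, hypermethylated > 70%, with both
boundaries assigned to the closed intermediate band 30%–70%.

Repeat divergence uses the one-parameter substitution model
`d = −(3/4)·ln(1 − 4p/3)` with `p` = RepeatMasker milliDiv/1000; elements
with `p ≥ 0.75` (outside the model's domain) or missing divergence are
excluded with a warning, and subfamilies are summarised by the median.
Subfamily methylation means are taken over *unique* CpGs (a CpG under two
overlapping elements counts once), and subfamilies with fewer than 10 CpGs
are dropped.

## Ordination and methylome summaries

Feature-level mean methylation merges intervals before averaging, so every
covered CpG contributes exactly once. The windowed sample matrix uses
non-overlapping 1-kb windows restricted to CpG-containing windows. For
centroid distances, zero-variance windows are dropped, each window is
centred and scaled across samples, and samples are projected onto *all*
principal components; distances to the per-group component-mean centroid
are therefore identical (to rotation) to distances in the scaled original
space, which is what the oracle test checks to 1e-8. Variance shares are
reported per component. Sample similarity is 1 − Pearson r across windows.

## Specificity rules and exhaustive nulls

A category rule names member patients, excluded patients, a recurrence
floor, ignored patients (unconfirmed status), and lenient members. A DMR
(per direction — exclusivity requires direction agreement, with a toggle)
is category-exclusive when its non-lenient members reach
`min(floor, #non-lenient members)` presences and no excluded patient shows
it. The lenient mechanism reproduces the convention of counting a DMR as
subtype-exclusive when present in all *other* members of a category
containing the low-burden Patient_4999 analogue. Default floors: both of 2
never-smokers; 3 of 4 smokers; 4 of 5 low-stage; 3 of 3 high-stage; all
members for subtypes.

The null recomputes the exclusive count under every distinct assignment of
the label multiset to the confirmed patients — 15 assignments for
{2 never, 4 smoker} over 6 patients, 45 patient pairs for a two-member
subtype — via exhaustive multiset enumeration (capped at 1e6 assignments;
beyond that the code refuses and points at sampling, which is explicitly
not the exhaustive procedure). The identity assignment is always among the
enumerated ones, so the observed count lies in the null's support by
construction; rank and exceedance of the non-identity maximum are reported.

## Density, hotspots, window features

Window DMR density = called bins in the window / background-eligible bins
in the window, per comparison and direction, over 10-kb/100-kb/1-Mb/10-Mb
tilings that exclude chrY and chrM; windows with no eligible bin are
undefined and dropped. A 1-Mb window is a hotspot when (a) its density
exceeds 1% in ≥2 matched comparisons, or (b) it ranks in the top 15 by
maximum density across comparisons (ties at the boundary broken by genomic
order; the max — rather than mean — ranking is a documented, configurable
choice). Window covariates (CpG, repeat, gene/transcript densities,
chromatin-state proportions, mean normal methylation) are correlated with
per-comparison densities, the >1% recurrence count, and the mean density;
the feature space is also ordinated with per-component variance shares and
feature loadings on the first three components. The fraction of a
comparison's single-patient (exclusive) DMRs inside that comparison's
>10%-density windows is reported per direction.

## Synthetic data: what it emulates, and what it does not

The generator builds, from one seed split into four independent RNG streams
(reference / truth / methylomes / calls), a toy genome (default 5.2 Mb over
chr1, chr2, chrX, chrY) with Poisson background CpGs plus CpG-island
clusters, transcripts whose TSSs sit in islands half the time, a repeat
catalogue spanning SINE/LINE/LTR/DNA/simple classes with subfamily-specific
divergence, an 18-state chromatin mosaic dominated by the quiescent state,
and a blacklist. The cohort mirrors the study design: 10 matched patients
(2 confirmed never-smokers, 4 confirmed smokers including a lenient
Patient_4999 analogue, 4 unconfirmed; stage and subtype assignments giving
a 5-patient low-stage group, a 3-patient high-stage group and two
two-patient subtypes) plus 7 tumor-only patients.

Planted truth: recurrent DMRs in random 2–6-patient subsets, singletons,
never-smoker- and smoker-specific DMRs, subtype-specific DMRs,
hypomethylated bins concentrated on a target LTR subfamily (LTR12C
analogue), and 1-Mb hotspot windows where 5% of eligible bins are planted
in a fixed patient pair. Methylomes put island CpGs low (0.15), repeat CpGs
high (0.85), the rest at 0.75, shift planted bins by ±0.4 in the carrier
patients' tumors, optionally downshift tumor repeat methylation globally,
add Gaussian noise (sd 0.05) and clip to [0,1]. Call tables emit planted
bins with q ~ U(0, 1e-5) and false positives at rate 1e-3 per background
bin with q ~ U(0, 1e-3); normal–normal tables contain false positives
only. Calls are simulated directly rather than via a reimplemented bin
test, because the upstream statistic is defined outside this package;
q values are generative stand-ins with the right filtering behaviour
across the calibration grid (the false-positive ratio falls as the
threshold tightens, tested).

What passing tests therefore show: the bookkeeping (IDs, recurrence,
filtering, densities, exclusivity, nulls) is correct, and the pipeline
recovers planted structure at the stated effect size/noise/FPR regime.
What they do not show: performance on real methylomes with spatially
correlated noise, copy-number artefacts, purity variation, or a caller
whose errors are not independent across bins — none of which the generator
models.

## Evaluation choices

Recovery scoring treats a planted bin with ≥2 carrier patients as
recovered when the catalogue shows the same bin, same direction, with
recurrence ≥2. Hotspot recovery and false discovery are judged on the
recurrent->1%-density clause only: the top-N clause flags a fixed number
of windows by construction and so has no planted-truth interpretation on a
small genome; both flags are exposed separately. The
smoker-specific-exceedance property is checked in a scenario where the
planted effect is present in all four smokers and no other shared signal
is planted, which is the regime in which exceedance of the full null
maximum is the designed behaviour; with additional exchangeable recurrent
planting the null widens and the guarantee is distributional, not
per-seed. Null calibration is verified by the exchangeability test: with
no label-linked planting, the tie-randomised rank of the observed count
within the 15-assignment null is uniform (chi-square over 200 seeds).

Problem sizes in the shipped tests and acceptance script (5.2-Mb default
genome, 500-kb-per-chromosome variants for the 200-seed null-calibration
loop) were chosen so the full suite exercises every stage in under a
minute of compute; all thresholds above are the package's defaults, stored
in `AnalysisConfig` / `GeneratorConfig`.

## Known limitations

- Interval queries are backed by an interval tree per chromosome; fine at
  annotation scale, not tuned for hundreds of millions of intervals.
- `enumerate_label_assignments` is exhaustive by design; covariates with
  many confirmed patients need the (non-exhaustive) sampling route, which
  the package deliberately does not pretend is the same procedure.
- The generator's q values are draws from fixed uniform models, not
  p-values from a test statistic; calibration diagnostics on synthetic
  data are structurally, not numerically, comparable to real cohorts.
- Promoter-switch detection requires both directions among a gene's
  promoter DMRs in the same comparison and ≥2 distinct DMR-bearing
  promoters; genes whose isoform TSSs coincide within one promoter window
  cannot be flagged.
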