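# Methods

`leukomir` implements a blood-cell miRNome analysis: starting from
probe-level microarray signals for five sorted leukocyte subsets (CD3+ T
cells, CD14+ monocytes, CD15+ granulocytes, CD19+ B cells, CD56+ NK cells)
and whole blood, drawn from a control and a lung-cancer donor group, it
derives disjoint cell-type-specific miRNA sets, condition contrasts, a
per-donor whole-blood mixture model, LOOCV classification, hierarchical
clustering and pathway over-representation.  Because such studies rarely
deposit raw arrays, the package ships a ground-truthed synthetic cohort
generator and validates every stage by recovery of planted structure.

## Preprocessing

Replicate probe signals (40 per miRNA on the emulated array design) are
summed to one linear expression value per miRNA and sample.  Samples are
quantile-normalized together — every sample's sorted vector is replaced by
the across-sample mean of order statistics; tied values receive the mean of
the target order statistics over their tied ranks, matching the de-facto
standard implementation.  A `per_cell_type` normalization scope exists but
the default normalizes all arrays of a run jointly, because all samples are
clustered in one map downstream.  Values are then log2-transformed with a
floor of 1.0 so an undetected (zero) signal maps to the scale origin.

Detection is a strict threshold call on the linear aggregated signal
(`value > threshold`, default 0), overridden by the vendor detection flag
when the probe table carries one.  Microarray texts usually leave the
"detected" call undefined; both routes are supported and neither is claimed
canonical.

## Differential expression

Per-miRNA independent two-tailed t tests; Welch's unequal-variance form is
the default (the common default of the R environment such analyses use),
pooled-variance Student's t by option.  Rows constant in both groups get
t = 0, p = 1 when the constants agree; when they differ the statistic is
undefined but the evidence unbounded, so p is set to the machine minimum and
the row flagged.  P-values are Benjamini–Hochberg adjusted per contrast.

At n = 7 vs 7, BH-adjusted significance typically clears nothing, so
condition contrasts additionally report *candidates*: miRNAs with raw
p < 0.05 that are detected in every sample of at least one group.  The union
report tabulates candidates across the six condition contrasts (five subsets
plus whole blood) with per-miRNA overlap counts.

## Cell-type-specific sets

Within one condition, all C(5,2) = 10 pairwise subset contrasts are tested,
each BH-adjusted within its own family (per-comparison adjustment; a pooled
mode is configurable).  A cell type's candidates are the miRNAs with
adjusted p < 0.05 in *all four* of its pairwise comparisons; significance
alone qualifies, with an optional strict mode additionally requiring a
consistent direction.  Candidates claimed by more than one cell type are
removed from all ("disjointification"), leaving five mutually disjoint
specific sets.  Whole blood never participates.

The three grouped contrasts — myeloid (CD14, CD15) vs lymphoid (CD3, CD19,
CD56) progenitor origin, innate (CD14, CD15, CD56) vs adaptive (CD3, CD19)
defense, antigen-presenting (CD14, CD19) vs cytotoxic (CD3, CD56) function —
restrict the tested universe to miRNAs detected in every sample of at least
one side and report BH-adjusted significance, with the two conditions'
significant sets partitioned into exclusive / shared-same-direction /
shared-opposite-direction members.

## Whole-blood mixture model

Per donor, the whole-blood expression vector is regressed on the five subset
vectors across miRNAs (observations = miRNAs detected in at least one of the
donor's samples).  OLS with intercept is the default; NNLS constrains the
subset coefficients to be nonnegative; a linear-scale mode fits raw signals.
The default fits log2 normalized values — the scale of the rest of the
pipeline — although physical mixing is linear in raw signal.  That
deliberate mismatch, plus the hidden compartment, is why the log-scale
linear model is only approximately correct; the per-donor R² and the
min–max band of subset-vs-whole-blood Pearson correlations quantify it.

Presence discordance flags the compartment structure directly: `wb_only`
miRNAs are detected in every whole-blood sample of a condition and in no
subset sample (the footprint of erythrocytes, platelets, exosomes);
`subset_only` miRNAs are detected in more than 90% (configurable) of subset
samples and in no whole-blood sample (dilution below the detection limit).

## Classification

Linear SVM (C = 1), leave-one-out cross-validation, features standardized
with training-fold statistics, decision ties broken toward the control
class.  `as_published` mode fixes the feature list — the condition-contrast
candidates computed on *all* samples — before cross-validation; this
replicates the protocol behind published accuracy tables of this design and
leaks information, which the package demonstrates rather than hides:
on pure-noise cohorts `as_published` accuracy exceeds the leakage-safe
`nested` mode, which re-runs candidate selection inside every training
fold.  LOOCV with a deterministic solver makes the 20 "repetitions"
identical; the parameter is kept for protocol parity.

## Clustering and enrichment

The 50 miRNAs with the largest unbiased sample variance (ties broken by id)
feed complete-linkage hierarchical clustering on Euclidean distances, rows
and columns independently.  Trees are cut with the standard
exactly-n-clusters rule; purity is the majority-class fraction over
clusters.  "Whole blood separates" is formalized as: the 2-way cut of the
all-sample tree isolates exactly the whole-blood samples (whole blood may
itself split into sub-branches below that).

Over-representation is the one-sided hypergeometric upper tail of the
overlap between a miRNA set's pooled validated targets and each pathway,
against a reference universe = the union of targets of every miRNA on the
array (always supplied as a file, never a hard-coded genome), BH-adjusted
across pathways, and reported only for pathways containing at least 10%
(inclusive) of the query's target genes.

## Synthetic cohort generator

The generator emulates the study design the analysis assumes: 7 + 7 donors,
five subsets plus whole blood per donor, 1,205 miRNAs, 40 replicate probes.
All randomness flows from one seed through numpy's PCG64 generator.

Subset signal (log2) = baseline + marker boost + disease shift +
N(0, `noise_sd`).  Key parameters, defaults, and rationale:

| parameter | default | meaning |
|---|---|---|
| `n_donors_per_condition` | 7 | study scale |
| `n_mirna` | 1205 | array content |
| `n_markers_per_celltype` | 20 | planted cell-type markers |
| `marker_effect` | 4.0 log2 | marker boost in its own subset |
| `universal_effect` | +1.5 log2 | oncomiR-like shift, all subsets, cancer donors |
| `noise_sd` | 0.5 log2 | per-sample measurement noise |
| `mixture_weights` | 0.55/0.20/0.08/0.07/0.05 (CD15/CD3/CD14/CD19/CD56) | textbook leukocyte proportions |
| hidden weight | 1 − Σ weights = 0.05 | non-leukocyte compartment |
| `hidden_n_mirna` | 15 | miRNAs expressed in no subset |
| `detection_threshold` | 4 linear | censoring limit (log2 = 2) |
| `n_probe_replicates`, `probe_noise_cv` | 40, 0.10 | probe expansion |

Baselines are bimodal: ~35% of miRNAs are "expressed" (log2 baseline
N(4.5, 2)), the rest silent (N(−1, 1)), leaving a thin mass near the
detection limit — as in real blood miRNomes, where most array content is
never detected.  Marker baselines are floored at log2 = 7 (five log2 units
above the detection limit): a cell-type marker is by definition robustly
expressed in the cells it marks, and the floor prevents censoring from
turning a planted marker into an on/off artifact.  The censoring threshold
is deliberately low (log2 = 2) so the discontinuity censoring introduces
stays well below the 4-log2 marker amplitude; with a high threshold,
near-threshold miRNAs flicker between 0 and the threshold across samples
and would dominate the top-variance ranking with noise.

Default disease effects: one universal +1.5 log2 shift across all five
subsets, plus four single-subset effects per cell type (±1.5, alternating
sign) on fixed-baseline (log2 = 8) miRNAs.  Whole blood mixes the donor's
*observed* subset profiles on the linear scale plus the hidden profile, then
gets its own multiplicative noise; the universal effect reaches whole blood
undiluted through mixing because the hidden compartment does not express
that miRNA.  Values below the detection threshold are censored to zero, and
the pre-censoring mask is stored as detection truth.

Probe expansion splits each value into 40 probe signals with multiplicative
noise renormalized so the probe sum reproduces the value exactly —
aggregation is the exact inverse, by construction.

### What the generator does not emulate

No probe cross-hybridization or sequence effects, no batch or spatial
artifacts, no donor-level covariates (age, sex), no per-donor variation in
mixture weights, and no correlation structure among miRNAs beyond the
planted effects.  Passing recovery tests therefore shows the *procedures*
are correct and calibrated at the study's scale, not that real arrays of
this design would yield the published miRNA identities.

## Validation design and problem sizes

The test suite validates three ways: (1) brute-force oracle equivalence —
quantile normalization, BH, Welch t, hypergeometric ORA, complete-linkage
clustering and the set algebra each match an independent naive
implementation on 1,000 randomized small instances; (2) hand-computed
worked examples (e.g. BH on (0.01, 0.02, 0.03, 0.04) collapses to 0.04;
Welch on (1,2,3) vs (4,5,6) gives |t| ≈ 3.674, p ≈ 0.0214; the 20/5/10
hypergeometric instance gives p ≈ 0.01625; exact mixtures are recovered to
1e-8); (3) recovery simulations at full cohort scale — marker
precision/recall ≥ 0.9 per cell type over 20 seeds, zero BH discoveries and
empty specific sets on ≥ 90% of 50 null seeds, the universal miRNA selected
in all six contrasts on ≥ 90% of 20 seeds, mixture weights within ±0.05
under additive noise (σ = 0.2, 800 miRNAs), hidden-compartment recall
≥ 0.9, nested-LOOCV mean accuracy ≥ 0.9 on planted effects and chance level
on permuted labels, and the clustering properties above.
`scripts/acceptance.py` recomputes these quantities from scratch; replicate
counts per quantity (5–20 cohorts) were chosen to keep the script fast while
making rates meaningful.

## Known limitations

* The package reproduces the *analysis design*, not the published miRNA
  lists — the original raw arrays are not available.
* The whole-blood regression default (log2 scale, with intercept) is a
  declared choice; the scale the original analysis used is not stated in
  such papers' methods.
* BH adjustment universes (all miRNAs vs detected-only) and the
  direction-consistency requirement for specificity are configurable because
  the source protocols underdetermine them.
* Zero-variance rows with unequal constants receive the machine-minimum
  p-value; any downstream ranking treats them as maximally significant.
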