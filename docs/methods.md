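# Methods

This note documents the model, the statistical procedures, the numerical
choices, and what the synthetic-data experiments do and do not
demonstrate.

## The scoring model and its assumptions

The immunogenicity score of a 9mer `L` on MHC molecule `H` is
`S = Σ_p M(H,p) · I(p) · E(A(L,p))`. The model is deliberately linear
and position-agnostic in its amino-acid preferences: a single 20-vector
`E` shared across positions, weighted by a per-position scalar `I`.
Position-specific 20×9 score matrices would fit labelled sets of a few
hundred peptides per class only at a serious risk of overfitting, and are
out of scope here.

Assumptions worth stating explicitly:

- **Anchors are binding, not recognition.** Residues at anchor positions
  are assumed to reflect the MHC binding motif; they are masked from both
  training counts and scoring. For most HLA class I molecules the 9mer
  anchors are P1/P2/P9 (the default rule `{1, 2, last}`); the bundled
  mask table adds only HLA-B*08:01 (P2/P5/P9). When a per-position
  binding-impact profile is available for an allele, `derive_anchor_mask`
  masks the three highest-impact positions; a tie across the 3rd/4th rank
  makes the split ambiguous and is an error rather than silently broken,
  because the mask changes every downstream number.
- **Only 9mers.** Scores and weights are estimated from 9mer data;
  scoring an 8- or 10mer raises an error instead of applying an invented
  length-extension rule. `default_mask` itself accepts lengths ≥ 8 so
  mask tables for other lengths can still be expressed.
- **Importance weights are fixed at training time.** Re-estimating `E`
  per cross-validation fold while holding `I` at the reference values
  mirrors how the model is meant to be transported to new data: `I` is
  treated as a property of TCR–pMHC geometry, and is far noisier to
  estimate than `E`.

The bundled reference model (`data/published_model.json`) carries the
widely used log-enrichment scale and position weights of the reference
MHC-I immunogenicity predictor distributed through the IEDB analysis
resource, transcribed by the package authors; its JSON round-trips
bit-exactly through `write_model`/`read_model`, and a version field
guards against silent format drift.

## Estimation details

**Log-enrichment scores.** `E(a) = ln f_imm(a) − ln f_non(a)` on
non-anchor counts, with frequencies `(count + c) / (total + 20c)`. The
pseudocount `c` defaults to *auto*: 0 when all 40 counts are positive
(pure frequency ratio), 0.5 otherwise. This keeps scores finite on small
user sets without perturbing estimates on study-scale data, where counts
in the hundreds make ±0.5 negligible. A zero count with `c = 0` is an
error naming the amino acid.

**Positional importance.** Per position, amino acids are counted over
peptides for which that position is non-anchor; under the default-only
mask table, P1/P2/P9 accumulate nothing and are reported NA, entering
the model with weight 0. The divergence is
`D(imm ‖ non) = Σ p ln(p/q)` in nats, with 0.5 per-cell smoothing
(20-category profiles from a few hundred peptides always contain zeros).
The direction — describing the immunogenic profile with the
non-immunogenic one — matches the scientific question; the symmetrized
variant would change magnitudes but not the P4–P6 ranking. One known
limitation: for alleles whose mask leaves P1 unmasked (B*08:01-like),
P1 still contributes weight 0, because the bundled weights carry NA
there.

**Permutation test.** The null hypothesis is that both classes are
random draws from the source-protein background. Each permutation draws
`total_imm` and `total_non` residues from the background and compares
the absolute frequency difference of the focal amino acid against the
observed one (two-sided: depletion counts as much as enrichment). Only
the focal amino acid's count matters, so the multinomial draw reduces to
its exact binomial marginal, which vectorizes. The reported p is
`(k + 1)/(n_perm + 1)`. This is a parametric resampling from the
background, not a label permutation conditioning on combined counts; the
conditioning variant would hold the pooled count fixed and is easy to
add, but the background-based reading matches how the test is used
(Fig.-style bar comparisons against a background line).

**Q-values.** Benjamini–Hochberg step-up, optionally scaled by the
Storey π₀ point estimate at λ = 0.5 (`π₀ = min(1, #{p > 0.5}/(0.5 n))`).
The λ-smoother variant adds machinery without changing 20-test analyses
appreciably.

**Class tests.** Each physicochemical characteristic is tested once, by
a two-sided Fisher exact test opposing the class to its stated opposite
(large vs small, aromatic vs non-aromatic, acidic vs basic, charged vs
non-charged), exactly reproducing the published table's enrichments to
2 d.p. and p-values to printed precision from the published counts.
Histidine deliberately belongs to large, aromatic, charged and basic
simultaneously. A zero class count in the non-immunogenic set makes the
fold enrichment undefined; it is reported as `None`, not as infinity.

**Positional contingency test.** The 2×20 table (all-zero columns
dropped) is tested with the asymptotic chi-squared probability when the
Cochran conditions hold on the expected counts (no zero cell, ≥ 80 % of
cells ≥ 5); otherwise a Monte-Carlo p is computed from fixed-margin
tables (Patefield sampling via `scipy.stats.random_table`), with
add-one smoothing. On 2×2 sub-tables the Monte-Carlo path agrees with
the exact Fisher test to Monte-Carlo error.

**Redundancy reduction.** BLAST-style mapping is replaced by an exact
ungapped sliding-window scan: for ≤ 10mer queries at > 75 % identity a
gapped alignment cannot beat the best ungapped window, so the scan loses
nothing and removes an external-tool dependency; precomputed mapping
tables can be supplied instead. Thresholds are strict (> 75 % identity;
overlap > half of the shorter peptide's residues, counted on *matched*
residues only). The redundancy graph is resolved greedily in descending
entry-count order with a seeded shuffle among ties; each kept peptide
eliminates its remaining neighbours. The procedure is deterministic
given the seed, idempotent, and reports the fraction of keeps that were
decided by chance among equal priorities. The final model averages `E`
over repeated selections (default 100), which shrinks tie-break variance
roughly as 1/n.

**Evaluation.** AUC is the tie-corrected normalized Mann–Whitney U
statistic (verified in tests against pairwise-concordance enumeration);
ROC points come from the standard threshold sweep. Cross-validation uses
stratified folds (each class split independently, preserving the class
imbalance per fold), pools held-out scores within a repetition, and
averages repetitions vertically on a fixed 101-point FPR grid. The
decision threshold for "positive" is 0, matching the triage use case
(discard candidates with `S ≤ 0`). Affinity matching bins records at
edges {1, 4.7, 22.4, 106, 500} nM (log-spaced), with an implicit < 1 nM
bin, keeps the per-bin minimum of the two sets (seeded subsampling of
the larger side), and reports a rank-sum check on the matched values; a
variant scheme with edges log-spaced over 1–5 serves combined
binding+processing scores after the conventional +1.1625 offset.

## The synthetic-data generator

`generate_sets` emulates the statistical structure the enrichment
analysis assumes: non-anchor residues of non-immunogenic peptides are
i.i.d. background draws; immunogenic peptides draw from the background
exponentially tilted by a planted 20-vector `e*`, scaled by a
per-position signal `s(p)`; anchor positions carry a fixed motif.
Defaults mirror a typical study geometry: 600 vs 181 9mers, one
A*02:01-like allele, uniform background, signal on all six non-anchor
positions. Affinities, when requested, are log-uniform on 0.1–500 nM.

One subtlety is deliberate and documented: because the tilted
distribution renormalizes, the true population log-enrichment is
`e*(a)·s − ln Z(s)`, not `e*(a)` itself — planting `e*(W) = 1` on a
uniform background yields a population value of 0.918 for W and −0.082
for the rest. `GeneratorConfig.expected_log_enrichment()` returns this
exact closed form (pooled over non-anchor positions), and all recovery
tests compare estimates against it; at 2000 peptides per class the mean
absolute error is ≈ 0.05.

`generate_redundant_pool` plants clusters of ≤ 2-substitution variants
of a seed 9mer embedded in its own random protein, so that cluster
members are provably mutually redundant (≥ 7/9 matches to the seed
window, ≥ 5 shared matched positions) while clusters are independent.

What passing synthetic tests does **not** show about real data: real
peptide sets have non-uniform backgrounds, allele mixtures with
correlated motifs, label noise from assay thresholds, and database
redundancy far messier than clean substitution clusters. The synthetic
experiments validate the estimators and their statistical calibration,
not the biological effect sizes; the benchmark numbers on the original
supplementary data sets are reproduced by a dedicated test only when
those tables are supplied by the user (they are distributed as binary
spreadsheets and cannot be bundled as text).

## Numerical choices and study sizes

- Natural log throughout (`E`, KL); scores are sums of products of
  O(0.1–1) quantities, no overflow concerns.
- Permutation and Monte-Carlo p-values use add-one smoothing; defaults
  are 10 000 draws (2 000 in the faster test settings).
- The uniformity check of the permutation test uses coprime class totals
  (1847/809): with commensurable totals the folded two-sided statistic
  collapses onto a coarse lattice and the (valid, conservative) discrete
  p-values fail a strict KS-vs-uniform comparison.
- Cross-validation and generator studies in the test suite use
  400–2000 peptides per class and 3–5 repetitions — sizes at which every
  asserted property has comfortable margin while the whole suite stays
  fast.
- Ties: anchor derivation refuses boundary ties; redundancy tie-breaks
  are seeded-random and reported; rank-based statistics use standard
  midrank tie handling.

## Known limitations

- Only 9mers are scored; H-2-restricted 8mers in particular are out of
  scope, and murine anchor usage differs enough that the HLA-trained
  scale should not be assumed to transfer.
- The mask table ships with a single non-default allele (B*08:01);
  users with binding-impact profiles or motif knowledge should register
  their own masks (`--mask`, `AnchorMask.with_entry`,
  `derive_anchor_mask`).
- Binding affinities and per-position binding-impact profiles are
  consumed as inputs; the package does not predict MHC binding or
  antigen processing.
- The permutation test models sampling from the background, so it tests
  "differs from background sampling", not "classes differ conditionally
  on the pooled composition"; with strong compositional skew the two
  questions can part ways.
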