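# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations behind `grouprax`. It states no empirical result beyond
what the test suite and `scripts/acceptance.py` compute.

## Study design model

A study is a full factorial of substances × ordered dose levels × ordered
sampling times, plus substance-specific untreated controls
(`dose_level == "control"`). Exposure doses descend from each substance's
*equi-effective dose* — the nominal concentration causing 10% acute
immobilisation — in half-log10 steps (medium = high·10^−0.5,
low = high·10^−1). A substance that never immobilises the test organisms
has no measurable equi-effective dose and is assigned the maximum across
the responsive substances, the conservative (least-potent) anchor.

Treatment groups excluded in any one omics layer (acute losses at high
doses, quality-control removals) are removed from **all** layers before
profiles are built, so every layer's t-statistic matrix covers the
identical group set. Group order is fixed (substance, dose index, time
index), making every downstream matrix and dendrogram reproducible.

Batch is recorded in the sample metadata but does not enter the
statistics beyond control pairing; only substance-level control linkage is
used by default.

## Preprocessing

* **Transcript counts**: features with total count over all samples below
  `min_total` (default 10) are dropped; a per-sample-maximum variant is
  available (`mode="max"`). Counts are then normalised by median-of-ratios
  size factors (per-sample median, over features positive in every sample,
  of count / feature geometric mean) — the classical size-factor estimator
  of count-based differential-expression analysis, cross-checked in the
  tests against the pydeseq2 implementation. Note the estimator is
  equivariant to per-sample scaling only up to a common constant: scaling
  one sample by k also shifts every feature's geometric mean by k^(1/n).
* **Intensities**: log2 with offset = half the minimum positive value.
  Whether mass-spectrometry intensities should be transformed before
  t-testing is data-dependent; both modes are exposed (`transform`).
* **Outliers**: per substance, samples are projected on the first two
  principal components (full SVD — exact and deterministic; the randomised
  solver sklearn may otherwise select is not) and removed when Hotelling's
  T² = Σ score²/eigenvalue exceeds the F-based in-sample limit
  k(n−1)/(n−k)·F₀.₉₅(k, n−k). One removal pass per call.

## Bioactivity profiles

Independent two-sample t-tests (pooled variance by default, Welch by
option) compare each treated group's replicates with the substance's
controls, per feature; positive t = elevated in treated. Degenerate
features: zero variance in both groups with equal means gives t = 0,
p = 1 (flagged); zero variance with differing means has its standard error
floored at the smallest positive SE across features so the statistic stays
finite (flagged).

Pipeline order is fixed: **t → collapse → vector-normalise → cluster**.
The maximum-perturbation collapse keeps, per feature and (substance,
dose), the signed t of largest magnitude over available time points;
normalising after the collapse makes each feature's unit vector span
exactly the groups being clustered. Zero rows stay zero rather than being
dropped, keeping feature ids aligned across modes. Percent-significant
summaries (share of features with p < α, default α = 0.05) are
descriptive only; no multiple-testing correction is applied because
grouping uses the t-statistics themselves, not significance calls.

## Clustering and multiscale-bootstrap support

Ward.D2 linkage on Euclidean distances between treatment columns: scipy's
`linkage(..., "ward")` on the condensed distance matrix implements the
Murtagh–Legendre recurrence (squared dissimilarities in the Lance–Williams
update, square-rooted heights); the tests verify its merge sequences and
heights against an independent greedy oracle that recomputes every merge
cost from raw coordinates. Tie-breaking follows scipy's deterministic
nearest-neighbour-chain order, so runs are bit-reproducible.

The resampling unit is the feature row (molecular features for omics
profiles, bit positions for fingerprints). At each scale
r ∈ {0.5, 0.6, …, 1.4}, `n_boot` replicates draw round(n·r) features with
replacement; scales where that is < 2 are skipped with a flag. A single
seed fans out to one substream per scale, so results do not depend on
evaluation order. For speed, per-feature squared-difference (Euclidean) or
discordance/union (binary) accumulators reduce each replicate's distance
matrix to one matrix product with the multinomial resampling weights.

Per observed cluster, the scale-wise recovery probabilities are fitted to
Φ⁻¹(1 − BP_r) = v√r + c/√r by weighted least squares with delta-method
binomial weights B·φ(z)²/(BP(1−BP)). Then

* AU = 1 − Φ(v − c) — approximately unbiased support,
* BP = 1 − Φ(v + c) — fitted plain bootstrap probability,
* SI = 1 − Φ(v − c)/Φ(−v − c), clipped to [0, 1] — the
  selective-inference variant, conditioning on the cluster having been
  selected by appearing in the observed tree (hence SI ≤ AU for supported
  clusters). The closed form follows the Terada–Shimodaira
  selective-inference extension and is validated in the tests by its
  internal relations (bounds, SI ≤ AU, AU = BP at c = 0, degenerate
  limits); the published reference implementation was not available in
  this environment for a numerical diff.

Numerical decisions: scale-wise BP values are clipped to
[1/(B+1), B/(B+1)] before the probit; scales where *every* or *no*
replicate recovered the cluster carry no probit information and are
excluded from the fit — fitting them as clipped constants fakes a
negative curvature and can report AU ≈ 0.6 for a cluster recovered in
99.9% of replicates. When fewer than two informative scales remain the
degenerate limit (AU = BP = SI = 1 or 0) is reported with a flag. The
root cluster is always recovered and reported with support 1 and a
`root` flag. An optional archive retains every replicate's cluster set
per scale, enabling frequency queries for arbitrary member sets (e.g.
"how often do the target's and one source's doses form an exclusive
cluster").

The weighted residual sum of squares of the probit fit is reported as a
fit diagnostic (`deviance`).

## Structural grouping

Fingerprints are fixed-length binary vectors (default 729 bits, the
chemotype-style encoding). Distance is |a XOR b| / |a OR b|
(= 1 − Tanimoto), which ignores jointly-absent bits — restricting a set
to its non-zero positions leaves all distances unchanged. The undefined
0/0 case (two all-zero fingerprints) returns 0 with a warning. Bootstrap
resampling covers all bit positions by default (the raw encoding), with a
restrict-to-non-zero switch. Clusters with SI ≥ 0.95 are flagged
strongly supported. Fragment mapping reports, per group of any partition,
the bits set in all members (*shared*) and the shared bits absent from
every non-member (*unique*); unique sets of disjoint groups are provably
disjoint. Fingerprint generation from chemical structures is out of the
package's core: fingerprints are consumed as CSV, and the proprietary
chemotype definition is not re-implemented.

## Xenobiotic scan

A transparent three-filter simplification of untargeted
internal-exposure confirmation: (1) ppm match of feature m/z against
parent and predicted biotransformation-product neutral masses plus adduct
offsets (positive-ion protonated molecule by default, table extensible;
|obs − theo|/theo·10⁶ ≤ 5 ppm default); (2) treated/control mean
fold-change ≥ 10 confirms, otherwise the annotation is kept as
*tentative*; a zero control mean confirms with an `infinite_fc` flag;
(3) Spearman correlation of replicate intensities with nominal dose
(controls as dose 0), flagged dose-responsive at ρ ≥ 0.8. All thresholds
are configuration, not claims about any particular instrument workflow;
raising the ppm tolerance never removes hits.

## Analogue selection and read-across

On the collapsed (substance, dose) dendrogram, candidate sources are
substances whose complete dose set co-clusters with the target's inside a
cluster with AU at or above the threshold (default 0.80); among
candidates the smallest join height wins, and ties are returned as a
list, not resolved. Absence of any supported companion is a result, not
an exception. Read-across copies the source's measured NOEC/LOEC to the
target bit-exactly and sets the worst-case flag only when the source's
equi-effective dose is at or below the target's; a prediction violating
worst-case is still emitted, with a warning. Benchmark-dose estimation is
out of scope — the equi-effective dose is an input.

## Synthetic-study generator

The generator produces the complete default study: seven substances in
three planted bioactivity groups {DY3, S1, SRG}, {DO25, DR1},
{DR13, DO61}; three doses and three times; two intensity layers
(log-normal noise, σ = 0.3 natural-log, 6 replicates; 245 and 183
features) and one count layer (gamma-Poisson with dispersion 0.05,
log-normal baselines around 200 counts, 4 replicates; 1889 features).

**Effect model.** Ten percent of each layer's features are "responsive".
Each planted group has a dense Gaussian loading (template) over that
subset; group templates and the analogue pair's extra component are
orthogonalised so distinct planted mechanisms share nothing by
construction. Member templates add individual jitter (weight 0.15) and
the designated source/target pair (S1, DY3) shares an extra component
(weight 1.2), making S1 the plantedly nearest analogue while SRG still
joins the same group. Treated means are baseline × exp(δ), with
δ = effect_z · (feature noise sd) · dose multiplier · time multiplier;
`effect_z` is therefore a standardised per-feature effect size (default
3, i.e. a three-standard-deviation log-scale shift at the highest
dose/time multiplier), and the count layer uses each gene's own
log-scale sd √(dispersion + 1/baseline) so the stated effect size holds
for every responsive gene. Dose multipliers (0.6, 0.8, 1.0) and time
multipliers (0.5, 0.8, 1.0) encode a steep dose–response over the
half-log ladder and a response growing with exposure time.

**Missing groups.** The historical missing-treatment-group pattern
(three acute losses, two QC removals; 63 → 58) ships as a preset
(`azo_study_config(missing_groups=True)`) rather than a default. Reason:
with unbalanced time availability the maximum-perturbation collapse
systematically shrinks the profile norms of substances with fewer time
points (the largest of two |t| draws is stochastically smaller than of
three), and at the benchmark effect size this norm artefact can rival
the planted between-group signal, drawing the two affected substances
together regardless of mechanism. The artefact is a genuine property of
the collapse under unbalanced designs — worth knowing when applying the
method to real data — but it would corrupt a recovery benchmark whose
purpose is to test group recovery. The pattern is still exercised by the
design-bookkeeping and pipeline tests.

**Extras.** One spiked parent-dye feature per substance is appended to
the apolar layer at m/z within 2 ppm of the protonated mass, with
intensity exactly proportional to nominal dose in that substance's
treated samples and zero elsewhere — the idealised internal-exposure
signal (endogenous feature m/z values are kept > 20 ppm away from all
targets). Fingerprints plant per-family shared bits (each also set in
one outsider, so shared ≠ unique), per-family unique bits (2/3/3), a
common scaffold (5 global bits) and sparse background (density 0.02);
any background bit covering a whole family is cleared in one member so
planted unique counts are exact.

**What passing tests show — and don't.** Planted effects are clean
multiplicative shifts with i.i.d. noise and exactly shared templates.
Real data carry batch drift, correlated features, QC structure,
heteroscedasticity beyond the mean–variance model, and annotation
uncertainty. Recovery of planted groups here validates the machinery
(profiles, collapse, normalisation, Ward.D2, bootstrap supports,
analogue logic), not the biological sensitivity of any particular real
study.

## Problem sizes used in checks

The test suite and acceptance script use the default study shapes
(245/183/1889 features) with 1,000–10,000 bootstrap replicates per scale,
a 200-replicate null calibration of the percent-significant summary
(expected ≈ 5% at α = 0.05), 50 random instances for the Ward
merge-order oracle at 4–6 leaves, and noiseless model-generated recovery
curves for the (v, c) probit fit (v = 1, c = 0.2 → AU = 1 − Φ(0.8)).

## Known limitations

* The selective-inference closed form is validated by internal relations
  and simulation behaviour, not by a numerical diff against the reference
  implementation.
* Support values are reported per node without adjustment across the
  many nodes of a tree.
* The maximum-perturbation collapse is biased under unbalanced time
  availability (see above); users with missing groups should interpret
  clusters joining the affected substances with care.
* The xenobiotic scan has no isotope-pattern or MS/MS scoring; it is an
  evidence filter, not an annotation engine.
* Analogue selection returns ties unresolved; downstream users must
  decide (e.g. by potency) when two sources join at the same height.
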