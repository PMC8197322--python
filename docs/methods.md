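# Methods

## Data model

A Ct matrix holds one cycle-threshold value per (assay, sample) well.
Failed amplification ("Undetermined") and physically missing wells are
recorded as distinct states, but both count as "not detected": the
detection rule requires a finite Ct ≤ 40 cycles (the PCR run length,
configurable) in *every* sample, because a panel-level comparison with
per-assay dropout would silently change the sample support of each
contrast. Matrices are fixed as assays-in-rows; a header that looks
like miRNA assay names is rejected as transposed input rather than
auto-corrected, since silent transposition is a classic qPCR pipeline
failure.

## Reference-assay selection

With no canonical housekeeping miRNA, references are selected from the
panel by four criteria applied in order.

1. **Expression**: detected everywhere, median Ct < 30 cycles
   (default `median_ct_max`). Low-expressed assays are too noisy near
   the detection limit to anchor normalization.
2. **Group stability**: two-sided Mann–Whitney U between the two
   contrast conditions, p strictly > 0.1 (default `stability_p_min`).
   The test is exact — full enumeration of all group assignments with
   midranks, ties handled by the permutation distribution — whenever
   n₁+n₂ ≤ 12, which covers the 3-vs-3 design; otherwise a
   tie-corrected normal approximation with continuity correction is
   used. At 3 vs 3 the attainable two-sided p-values are
   {0.1, 0.2, 0.4, 0.7, 1.0}, so the strict p > 0.1 rule excludes
   exactly the completely separated assays.
3. **Variability**: the coefficient of variation of the linear
   relative quantity 2^−Ct across samples must stay below
   mean(CV) + 2·SD(CV) computed over the criterion-(i) survivors, and
   no sample's linear level may fall outside a 5-fold window around the
   assay mean. A screen phrased directly as "CV < 2×SD" mixes units
   (CV is dimensionless, SD is not); the mean+k·SD reading is the
   standard way such screens are operationalized and the multiplier is
   configurable. CV and the fold window are evaluated on the linear
   scale because "levels" and "fold" are linear-scale notions. A
   numerically zero spread of candidate CVs (all candidates identical)
   would make the strict inequality reject everything, so the
   comparison carries a relative tolerance of 1e-9.
4. **Coherence**: Pearson r strictly > 0.7 (default `r_min`) between
   the assay's −Ct profile and the −(reference profile), where the
   reference profile is the per-sample arithmetic mean Ct of the
   current candidate set — identically the geometric mean of their
   linear quantities, an identity the tests assert. Negating both
   series leaves Pearson r unchanged, so it is computed on Ct directly.
   The criterion is iterated: assays failing it are dropped and the
   reference recomputed until a fixed point, which is guaranteed
   because the set shrinks monotonically. By default a candidate is
   correlated against a reference that includes itself (a running set
   of, typically, ~48 assays, where self-inclusion contributes ~2%);
   a leave-self-out mode is provided. Degenerate profiles are defined
   explicitly: a zero-variance candidate is maximally stable (r := 1),
   a varying candidate against a zero-variance reference scores r := 0.

The selection is invariant under assay and sample reordering and under
adding a constant to every Ct (all criteria depend on differences,
ranks, ratios of linear quantities, or correlations).

## Normalization and fold change

ΔCt = Ct − reference profile; relative quantity 2^−ΔCt. For a contrast
(reference condition, test condition), log2FC = mean ΔCt(reference) −
mean ΔCt(test): one cycle in favour of the test group doubles the
estimate, and FC > 1 always means higher in the test condition — the
orientation is part of the output schema. Swapping the contrast inverts
FC exactly.

In-silico pooling mixes equal cell numbers, so it averages *linear*
quantities: pooled Ct = −log2(mean 2^−Ct of the members), not a mean of
Ct values. Normalizing a pooled sample or pooling normalized quantities
agree within 0.05 cycles on reference-stable panels (tested); they are
not identical because the reference of the pooled sample is itself a
pooled quantity.

The precision summary expresses, per assay, the dispersion of replicate
linear levels (across cell lines or experiments) relative to the
pooled-group mean level: SD/pooled-mean × 100% by default, with a
mean-absolute-deviation variant exposed because the percent-dispersion
measure is not uniquely determined; the summary reports the median and
IQR over fully amplified assays.

## Moderated t and q-values

For each assay, the two-group effect on ΔCt (which *is* the log2 fold
change), pooled residual variance sg² with dg = n₁+n₂−2 degrees of
freedom. The empirical-Bayes prior (d₀, s₀²) is estimated by the method
of moments on log sg²: with
e = log sg² − ψ(dg/2) + log(dg/2), the excess variance of e over
ψ′(dg/2) identifies ψ′(d₀/2), solved by Newton iteration on the
trigamma inverse; the mean of e identifies log s₀². When the observed
variances carry no excess spread, d₀ = ∞ and every posterior variance
equals s₀². Posterior variance s̃g² = (d₀s₀² + dg sg²)/(d₀+dg);
t = effect/(s̃g·√(1/n₁+1/n₂)) is referred to a t distribution on d₀+dg
df (normal when d₀ = ∞). The limits behave as expected and are tested:
d₀ = 0 reproduces the ordinary pooled t exactly; d₀ = ∞ pins the
variance at the prior. The implementation is checked to 1e-6 against an
independent root-bracketing implementation of the same moment
equations, and to 1e-4 against Bioconductor limma's `eBayes`.

q-values use the fixed-λ point estimator with λ = 0.5 (configurable):
π₀ = #{pᵢ > λ}/(m(1−λ)) capped at 1, q₍ᵢ₎ = min_{j≥i} π₀·m·p₍ⱼ₎/j on
the sorted p-values, ties sharing a value. With π₀ = 1 this is exactly
Benjamini–Hochberg (asserted on random vectors). With m ≈ 80–110 the π₀
estimate is noisy; it is therefore reported alongside the q-values
rather than hidden. No smoothing over a λ grid is attempted — the
point estimator is the method actually being emulated, and with these
panel sizes a smoother would add variance of its own.

Significance: q ≤ 0.10 by default, partitioned into increased (FC > 1)
and decreased (FC < 1). The design matrix is a plain two-group
contrast; the moderated fit requires at least two samples per group, so
designs with single-sample arms are rejected rather than guessed at.

## Enrichment

Over-representation of a query gene set in each pathway uses the
upper-tail hypergeometric probability with the pathway database's own
universe (all genes known to the database, not the genome — using the
genome inflates significance for any curated database), corrected by
Benjamini–Hochberg (default) or Bonferroni, significant at corrected
p ≤ 0.05. This is a standard ORA reimplementation, not a replica of any
web service's statistic; absolute p-values from such services depend on
database versions and are not comparable. The bundled target and
pathway tables are deterministic synthetic fixtures whose set sizes are
realistic (e.g. 431 validated targets for hsa-miR-27a-3p, a 47-gene p53
pathway); gene symbols beyond a few marquee genes (TP53, SLC7A11,
ribosomal proteins, …) are placeholders.

## Assay mathematics

PE = colonies/plated × 100% (colonies > plated is an error, not a
warning); SF = PE_treated/PE_control × 100%. SF is computed per
replicate against the mean control PE and then averaged — matching
per-experiment means ± SD — with a pooled-counts mode exposed.

Apoptosis quadrants: viable % is normalized to the vehicle control
(ratio × 100); vehicle early/late apoptotic background is subtracted
from the treated values. Subtraction is clamped at zero — a negative
apoptotic excess is noise — and every clamp is flagged in the output so
the decision is auditable.

The 4PL curve y = bottom + (top−bottom)/(1+(x/IC50)^hill) is fitted by
least squares with the IC50 on the log scale, multi-start over three
dose quantiles × four Hill magnitudes × both orientations. Asymptotes
are constrained to the observed response range ± 25% of its span, the
IC50 to within one decade of the tested doses and |hill| ≤ 10
(removable via `bounded=False`): with six doses and realistic noise an
unconstrained 4PL will happily place an asymptote at −60% viability.
The reported IC50 is the curve midpoint (relative IC50, the inflection
of the parameterization); the absolute 50%-response crossing is
reported additionally when the fitted curve spans it. The convention
is hill > 0 for viability decreasing with dose. Fits are invariant to
dose-unit rescaling up to the matching IC50 rescaling (tested).
IC50 precision is noise-limited: with single wells per dose and
response noise of SD 3 units, even fixing one asymptote at truth leaves
a median relative IC50 error above 10%, so dose-response fitting always
consumes all replicate wells (triplicates in the default design).

Densitometry: loading factor = lane intensity / brightest lane;
band / factor. Invariant to global exposure scaling.

## Synthetic-data generators

All generators are pure functions of (truth, seed) using a counter-based
RNG; identical inputs give identical outputs byte-for-byte.

The default panel: 111 assays = 48 designed stable references
(baseline Ct 18–28) + 5 increased (FC 1.3) + 10 decreased (FC spaced
0.60–0.85) + 19 stable but low-expressed (Ct 31–36, designed to fail
the expression criterion) + 29 assays with designed detection dropout
in ≥ 1 sample, so the detection filter keeps exactly 82 of 111.
Designed fold changes enter the test-group Ct additively as −log2 FC,
making them exactly recoverable through the ΔCt/fold-change stack —
the core parameter-recovery contract. Dropout is deterministic (listed
wells plus any Ct above the 40-cycle ceiling), so the filter count is
designed exactly rather than approximately.

Noise has two components, chosen once for the designed-recovery regime:

- a per-batch loading/RT shift (SD 0.04 cycles) shared by all assays of
  a sample *and* by the condition-paired samples processed in the same
  batch (line k of each condition prepared in parallel, as paired
  designs are run). This shared variation is what the criterion-(iv)
  correlation feeds on, and ΔCt normalization removes it exactly;
  pairing it across conditions keeps a rank test at n = 3 vs 3 from
  being confounded by loading — with independent per-sample shifts,
  one seed in ten would separate the groups on loading alone and empty
  the reference screen.
- independent per-well technical noise (SD 0.005 cycles), the residual
  scatter after technical-replicate averaging on a preamplified panel.

This is deliberately a low-noise regime: the generator's job is to make
the designed structure unambiguous so that recovery failures indict the
algorithms, not the data. Real OpenArray data carry per-well SDs one to
two orders larger, stochastic dropout, and loading shifts that are not
perfectly batch-paired; passing the recovery tests therefore
demonstrates correctness of the computations, not expected performance
on real data. Features not emulated at all: amplification-efficiency
differences between assays (the 2-fold model is assumed throughout),
plate-position effects, and pre-amplification chemistry.

Clonogenic counts are Binomial(plated, true PE) per well, triplicate
wells per dose, with default efficiencies matching counted colonies of
~95/500 and ~53/750 (control) versus ~102/500 and ~88/750 (knockout) —
designed survival fractions of ~37% and ~58% at 2 Gy. Dose-response
quadrants are Multinomial(2000 events, [viable, early, late]) with the
viable probability on a designed 4PL (default midpoints 8, 19, 7.8 and
6.7 µM for the four drugs); an infinite event count returns the exact
expectation, used to test the noiseless limit.

## Problem sizes in the checks

The simulation-scale checks use 20 panels for reference recovery, 100
end-to-end runs for designed-truth recovery, 500 null panels for FDR
control, 200 replicates for IC50 recovery and 1000 for the binomial
survival-fraction recovery; together they run in well under a minute on
one CPU, and the acceptance script re-runs the same computations from a
single command-line seed.

## Known limitations

- Two-group contrasts only; no covariates, no multi-factor designs, no
  trend or robust variants of the variance prior.
- The moderated fit needs ≥ 2 samples per group; designs that pool an
  arm down to duplicates are the supported minimum, single-sample arms
  are rejected.
- π₀ from ~80 p-values is noisy; q-values inherit that noise.
- Reference selection at n = 3 vs 3 has limited power by construction:
  the exact Mann–Whitney floor means criterion (ii) can only exclude
  completely separated assays.
- Enrichment p-values are not comparable to any live database's output.
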