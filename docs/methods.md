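# Methods

## Quantification scales

**Relative expression (RQ).** For each expression assay the comparative-Ct
identity is used with a fixed amplification efficiency E:

    ΔΔCt = (Ct_target − Ct_ref)_tumor − (Ct_target − Ct_ref)_normal
    RQ    = E^(−ΔΔCt),   E = 2.0 by default

with GAPDH as the reference gene. RQ is a unitless fold change; RQ = 1 means
equal target abundance in tumor and paired normal tissue. The efficiency is
configurable per call but defaulted to 2.0, since no assay-specific
efficiencies are available; RQ is invariant to adding a common offset to the
target and reference Ct of the same tissue, which is what makes the fixed
anchors of the raw-Ct simulator legitimate.

**Methylation index (MI).** MI is defined as the methylated fraction of the
two allele-specific reactions,

    MI = 100 · Q_M / (Q_M + Q_U),   Q = E^(−Ct),

which maps exactly onto the 0–100% semantics: an undetermined reaction
contributes Q = 0, so MI is exactly 0 when only the unmethylated reaction
amplifies and exactly 100 when only the methylated one does. Alternative MI
definitions exist (e.g. absolute quantification against a fully methylated
control); the M/(M+U) fraction was chosen because it is self-normalizing and
reproduces the boundary semantics without external calibrators.

**Undetermined Ct.** A reaction that never crosses threshold is encoded as
the reserved token `Undetermined` in files and NaN in memory. It is never
coerced to a late cycle number (e.g. 40): for RQ any undetermined reaction
makes the value missing with a recorded reason; for MI it is the mechanism
that produces the boundaries.

**Bisulfite-conversion QC.** Completeness of conversion is checked per sample
with an ACTB reaction specific to the *unconverted* template. The sample
passes if that reaction shows no amplification or only amplifies at/above a
threshold (default 35 cycles — late enough to be background in a 40–45-cycle
run). A failing sample keeps its expression values (cDNA is unaffected by
conversion) but has all methylation values set missing, with the exclusion
logged.

## Marker screening

Group comparison uses the two-sided Mann–Whitney U test: exact enumeration
when both groups have ≤ 8 observations and the pooled sample is tie-free,
otherwise the normal approximation with tie correction and continuity
correction. If every pooled value is identical the test is vacuous and
reported as p = 1 with a warning.

Multiplicity is controlled with Benjamini–Hochberg step-up adjustment. The
default family structure is one family per modality (4 expression markers,
9 methylation markers), mirroring how the two marker groups were screened as
separate blocks; a global family is available as an option. Note that BH is
*not* idempotent — re-adjusting an adjusted vector rescales by m/i again —
so adjusted p-values are computed once from the raw ones.

Univariate logistic regression is fitted by Newton/IRLS
(`statsmodels.Logit`), with the Wald two-sided p-value reported. Expression
markers are log2-transformed before fitting (RQ spans orders of magnitude;
rank tests and ROC are transform-invariant but the logistic model is not),
methylation markers enter on the raw percent scale. Complete or
quasi-complete separation is detected (solver exception, non-convergence, or
|slope| > 50 on these scales) and flagged rather than reported as a tiny
p-value. Wald was chosen over likelihood-ratio/score tests as the most common
default in clinical statistics software.

Missing marker values are handled by pairwise deletion; markers missing in
more than half the samples are excluded from the screen with a warning.

## ROC analysis

Event directions are fixed a priori by modality — expression markers are
`low_positive` (risk call when value ≤ cutoff), methylation markers
`high_positive` (risk call when value > cutoff) — and are never auto-flipped
by the AUC, to avoid learning the direction from the same data twice.
The boundary convention (inclusive ≤ for expression, strict > for
methylation) follows the panel's event definitions.

The AUC is the pairwise concordance probability with ties counted 1/2,
computed via midranks (numerically identical to the trapezoidal area under
the empirical ROC). Its variance uses DeLong's structural components, giving
a normal 95% CI clipped to [0, 1] and a two-sided z-test of AUC = 0.5. A
degenerate AUC of 0 or 1 has zero DeLong variance; this is warned about and
the CI collapses rather than being invented.

The operating cutoff maximizes Youden's J = sensitivity + specificity − 1
over the observed marker values (cutoffs are always observed data values,
not midpoints); ties in J are broken toward the higher-specificity point, a
deliberate choice for a metastasis test where a false positive escalates
surgical staging.

## Count-rule panels

Markers are binarized into events at their cutoffs and a sample is called
high metastatic potential when at least k of the panel's m events fire. The
built-in rules are 3-of-4 (expression), 4-of-5 (methylation) and 6-of-9
(combined); k is treated as fixed, not optimized. Samples missing any panel
marker are excluded from that panel and counted.

Performance reporting: confusion counts; sensitivity, specificity, PPV and
NPV in percent with exact Clopper–Pearson 95% CIs (chosen over Wald/Wilson
because several cells are small at n = 80); and the AUC of the raw event
count used as an ordinal score (the concordance AUC, equal to the trapezoid
over the k-swept ROC). Raising k can only lower sensitivity and raise
specificity — a property the test suite checks exhaustively. The ordinal
count AUC does **not** in general dominate (sens+spec)/2 of every binary
k-rule, because the empirical ROC need not be concave; no such dominance is
claimed or relied on.

`reconstruct_confusion` inverts published sensitivity/specificity
percentages to integer counts (tp = round(sens·n₁/100) half-up, etc.) and
verifies that the counts round back to the stated percentages at two
decimals, raising an inconsistency error otherwise. This is what makes
published panel characteristics recomputable: with group sizes 31/49, the
three published panels reconstruct to unique integer confusion matrices
whose NPV/PPV the package recomputes exactly. All reported percentages are
rounded half-up (not banker's rounding) and only at the reporting boundary;
comparisons happen on unrounded values.

`CountRulePanelClassifier` packages the same rule in scikit-learn form:
parameters are the marker list, per-marker directions, cutoffs (`"auto"` →
Youden from the training data) and k (default: a majority, ⌊m/2⌋+1);
fitted attributes are `cutoffs_`, `directions_`, `k_`, `classes_`. Learning
cutoffs and evaluating on the same cohort is in-sample and optimistic —
cross-validate through sklearn when an honest estimate is needed.

## Synthetic cohorts

The generator emulates the study conditions: 31 metastatic / 49
non-metastatic samples and 13 markers with the published per-group medians.

* Expression values are log-normal, parameterized by the median (exp of the
  log-mean) and a common log-scale s.d. per marker — medians, not means, are
  the published quantities, and the log-normal matches RQ's positive,
  right-skewed, multiplicative nature.
* Methylation values are Beta distributions rescaled to [0, 100] with a
  common concentration (a+b) per marker; the first shape parameter is solved
  by bisection so the distribution median equals the target. The Beta keeps
  the support honest (no clipping artifacts at 0/100).

No dispersion information is published, so per-marker dispersions are
**calibrated**: the log-normal s.d. has the closed form
σ = |ln(m₁/m₀)|/(√2·Φ⁻¹(AUC)) and the Beta concentration is solved
numerically (Gauss–Legendre quadrature of the pair-concordance integral
inside a root bracket) so that each marker's *theoretical* two-group AUC
equals its published single-marker AUC. Markers without a published ROC row
(MIR107, MIR203A, MIR132) get a weak target AUC of 0.60, consistent with the
non-significant rank tests they showed at this sample size. This calibration
is a modelling choice, not ground truth: the real data's dispersions,
inter-marker correlations (the generator draws markers independently),
measurement error structure and any batch effects are unknown and not
emulated, so passing tests demonstrate the *machinery* and the qualitative
single-marker-to-panel gain, not clinical performance.

Determinism: one global seed; each marker draws from a substream keyed on
(seed, sha256(marker name)), so adding a marker never perturbs the others.

The generator can invert the measurement equations to raw Ct tables
(`emit_raw_ct`): reference and normal-tissue Ct are fixed at 20/24 cycles
and the stronger methylation reaction at 25 cycles (arbitrary anchors — only
Ct differences matter), the remaining Ct carries −log2(RQ) or
log2(MI/(100−MI)), a boundary MI is emitted as an undetermined reaction, and
the ACTB conversion control is emitted as "no amplification". Quantifying
these tables reproduces the simulated values to ≤1e−9, which the test suite
uses as a round-trip oracle.

## Problem sizes and numerical choices

The test suite exercises the statistical properties at sizes chosen to make
the checks sharp but quick: median-calibration at n = 5000/group, median
unbiasedness over 200 study-sized replicates (sign tests, both group sizes
odd so the sample median is exactly median-unbiased), type-I error over 500
null cohorts of n = 80, oracle equivalence (brute-force concordance,
exhaustive Youden sweeps, exact-vs-asymptotic U tests) over 100 random
instances each, and DeLong-vs-bootstrap variance agreement at 2000
resamples.

Degenerate inputs are handled explicitly rather than silently: empty groups
and one-class outcomes raise; all-tied samples give p = 1 with a warning;
perfect separation flags the logistic fit; degenerate AUCs warn; undefined
predictive values (empty denominator) are NaN, not 0 or 100.

## Known limitations

* Markers are simulated independently; real expression/methylation markers
  are correlated (shared HIF1 and PI3K/AKT biology), which typically makes a
  combined panel *less* informative than independence suggests. Synthetic
  panel performance is therefore an optimistic analogue.
* Published per-gene AUCs, cutoffs and medians cannot be reproduced exactly
  without the raw cohort; they serve as calibration references only. The
  recomputable anchors are the published panels' predictive values and the
  cohort demographics, which are pure arithmetic on printed numbers.
* The published panel CIs came from an unspecified calculator; this package
  reports Clopper–Pearson exact CIs, so CI bounds are not comparable
  figure-for-figure (point estimates are).
* Single-reference-gene normalization, PCR efficiency estimation and
  plate/batch effects are out of scope.
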