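# Methods

This package re-implements, as tested library code plus narrative analysis
scripts, the bespoke computational steps of a multi-omics characterisation of
anti-androgen-resistant prostate cancer cells: a cross-condition differential
proteomics signature, natural-abundance correction of ¹³C-glucose tracing
data, lipid saturation profiling, a hyperspectral Raman tissue-map QC and
band-ratio pipeline, and expression-based survival stratification.  Raw
mass-spectrometry and spectroscopy data are not redistributable at desk
scale, so a synthetic-data generator with planted ground truth stands in for
them; every downstream claim the test suite makes is scored against that
planted truth.

## Differential signature (`diffsig`)

Abundances are modelled on the log₂ scale.  For each resistant-line-vs-
parental comparison, within each culture format (2D monolayer, 3D organoid),
a two-sided Welch t-test is applied per feature to log₂ intensities;
log₂FC is the difference of group means.  Benjamini–Hochberg q-values are
computed across features within each comparison.  Features with fewer than
two finite (positive) values in either group of a comparison are dropped
from that comparison rather than imputed.

The consistency filter retains a feature iff |log₂FC| ≥ log₂(1.5) and
p < 0.05 in at least *k* of *n* comparisons with a single sign across the
qualifying comparisons; the signature panel is the intersection of the
per-format selections, ordered by mean |log₂FC|.  The default significance
column is the raw per-comparison p (the printed selection rule of the
source study); q-based filtering is available (`p_column="q"`), as is a
seeded label-permutation engine (≥ 250 shuffles) for users who prefer a
permutation null over the t distribution.  Note one subtlety: the
sign-consistency veto makes retention non-monotone in the thresholds
(tightening p can re-admit a feature by disqualifying a contrary-sign
comparison); monotonicity holds exactly with `require_sign=False`.

Under the synthetic operating point used throughout the tests (2 000
features, 5 % signature at |log₂FC| ∈ [1, 2], 4 replicates/group, residual
SD 0.3 log₂ units), the intersected panel achieves ≈ 0.98 mean sensitivity
at ≈ 0 observed FDR over 20 seeds.  Requiring BH q < 0.05 in all six
comparisons instead collapses sensitivity to ≈ 0.23 at these sample sizes —
the package therefore documents raw p as the default and leaves q-filtering
opt-in.

Many-to-one group comparisons (metabolite/lipid panels) use a Dunnett-style
test: variance pooled across all groups (ANOVA residual), per-group t
contrasts against the reference, and family-wise adjusted p-values from a
seeded Monte Carlo estimate (default 100 000 draws) of the null max-|t|
distribution for the observed replication layout.  Monte Carlo was chosen
over multivariate-t quadrature because it handles unequal group sizes
directly and is trivially testable; the null table is cached per layout, and
adjusted p-values are floored at the analytic unadjusted p so adjustment can
never appear anti-conservative due to MC noise.  Against SciPy's
quadrature-based implementation the MC p-values agree to < 0.01 absolute.

## Isotope tracing (`isotope`)

For a compound with C carbons the measured raw vector y (M+0 … M+C peak
areas) relates to the tracer MID x through a correction matrix M whose
column j is the mass-shift distribution of a molecule with j labelled
positions: the convolution of binomial(j, purity) (tracer impurity),
binomial(C−j, a₁₃C) (natural ¹³C on unlabelled carbons) and, in
`all-elements` mode, the +1/+2 natural shift distributions of H, N, O, S and
Si.  Columns are truncated at shift C (measured vectors stop at M+C) and
renormalised to sum 1.  Default abundances are the IUPAC values
(¹³C 0.0107, ²H 0.000115, ¹⁵N 0.00364, ¹⁷O 0.00038, ¹⁸O 0.00205, ³³S 0.0075,
³⁴S 0.0425, ²⁹Si 0.0468, ³⁰Si 0.0310), overridable via `AbundanceTable`;
tracer purity defaults to 1.0 (0.99 matches typical U-¹³C glucose lots).

Correction solves min‖Mx − y‖₂ subject to x ≥ 0 (non-negative least
squares) and renormalises; plain inversion can return negative isotopologues
on noisy data.  In carbon-only mode at full purity M is lower triangular and
NNLS agrees with back-substitution to ≤ 1e-9 whenever the unconstrained
solution is non-negative.  Labelling metrics: labelled fraction = 1 − x₀,
fractional enrichment = (Σ i·xᵢ)/C.  `normalize_abundance` divides
per-sample totals by an internal standard (e.g. the C17 fatty acid) and/or
protein content / cell number.

The choice of mode matters: `all-elements` suits nominal-mass GC-MS where
heavy H/O/Si isotopologues are isobaric with tracer shifts; `carbon-only`
suits high-resolution Orbitrap data where they are resolved.  Both are
exposed; the tracing forward generator uses the same operator, so
generator + correction is the identity to ≤ 1e-9 L1 at zero noise for every
formula up to C30 (property-tested).

## Lipidomics (`lipids`)

Lipid names follow the summed shorthand `"<CLASS> <carbons>:<double
bonds>"` or the chain form `"<CLASS> c1:d1/c2:d2"` (sphingoid `d`/`t`
prefixes tolerated; chains summed).  Supported classes: Cer, CL, DG, LysoPC,
PC, PE, PG, PI, PS, SM, TG, BMP.  Ether/oxidised notations (`O-`, `P-`) are
rejected with a clear error rather than mis-parsed.  The saturation level of
a species is its total double-bond count; > 2 counts as highly unsaturated,
≤ 2 (saturated, mono- or bi-unsaturated) as lowly unsaturated.  Fatty-acid
pools: SFA = 0, MUFA = 1, PUFA ≥ 2 double bonds per fatty acid.

`lipid_diff_matrix` reuses the consistency filter (default FC > 1.2,
p < 0.05 in ≥ 1 knockout comparison, sign not enforced since the planted
contrast is bidirectional) and emits either per-comparison log FC (natural
log by default, matching the source figures' `log(FC)` labelling; log₂ via
`log_base="2"`) or per-row z-scores, with class/saturation annotations
sorted by class then double bonds.  Clustering of heatmap rows is left to
the caller (linkage/distance conventions vary); the matrix and annotations
are the package's contract.

## Raman tissue maps (`raman`)

Pipeline order is fixed: despike → baseline → crop (2800–3020 cm⁻¹) →
tissue mask → intensity-floor QC → 1-SD spectral QC → min–max scaling →
anchor scaling (2933 cm⁻¹) → band ratios.

* **Despike.**  Single-channel cosmic spikes are replaced by the local
  median (window 5) when they exceed it by more than 5 local MADs plus 2 %
  of the spectrum's range.  The relative prominence floor prevents smooth
  band maxima — where the local MAD vanishes — from being clipped, and keeps
  the detector equivariant under positive affine rescaling.
* **Baseline.**  Iterative clipped polynomial least squares (order 11): fit,
  clip the working spectrum to the fit, refit to convergence.  A plain
  one-shot LS polynomial was measured to absorb roughly a third of the
  CH-stretch band intensity and to shrink a planted band-ratio group
  difference of 0.30 to ≈ 0.13; the clipped iteration rides under the peaks
  instead and transfers the planted difference within ≈ 5 %.  A Chebyshev
  basis keeps the fit conditioned, so an input that is exactly an order-11
  polynomial maps to zero at machine precision.
* **QC.**  Stage 1 drops pixels with total cropped intensity strictly below
  60 000 counts (a vendor-scale threshold; configurable in the units of the
  input, which is also why end-to-end affine invariance holds only when the
  floor is rescaled with the data).  Stage 2 computes the mean spectrum of
  the survivors and drops pixels whose Euclidean distance to it exceeds
  mean + 1 SD of the distances — the distance-to-mean reading of
  "one standard deviation of the mean"; the multiplier `sd_k` is a
  parameter.  The QC report satisfies retained + dropped₁ + dropped₂ =
  input pixels.
* **Ratios.**  Intensities are read at the axis point nearest each band
  (2845 lipid CH₂, 2880 cholesterol-associated, 2935 protein CH₃; anchor
  2933 with 2935 available by flag — the 1–2 cm⁻¹ discrepancy exists in the
  source conventions).  Group comparison is a two-sided Mann–Whitney U on
  per-map mean ratios: the map (one tissue section / animal) is the
  independent unit, not the pixel.

The synthetic maps place Gaussian bands (σ = 7 cm⁻¹) at the three band
positions on a smooth cubic baseline, with per-pixel amplitude jitter,
Gaussian noise, planted low-intensity background pixels (below the QC floor
by construction) and recorded single-channel spikes.  The lipid-band
amplitude is solved per pixel so the clean-spectrum 2845/2935 ratio equals
the condition target, making the planted group difference well defined.
σ = 7 keeps the three bands resolved — the pipeline reads peak heights at
fixed positions, which presumes resolved bands; broader, strongly
overlapping bands would re-introduce baseline-fit bias that the real
instrument's higher spectral detail does not show.  What the synthetic maps
do not emulate: fluorescence saturation, detector nonlinearity, spatially
correlated tissue texture, and real biological variation between animals —
passing tests demonstrate the pipeline's algebra and calibration, not
instrument realism.

## Survival stratification (`survival`)

Expression is mean-centred and clustered by 1-D k-means (k = 3, best of 10
seeded k-means++ restarts; clusters relabelled low/mid/high by centroid).
An exact O(kn²) dynamic-programming 1-D k-means is included and the
heuristic is tested to attain the DP optimum on cohorts up to n = 50.
Kaplan–Meier curves use the product-limit estimator with right censoring;
the k-sample logrank test uses pooled risk sets with hypergeometric
variance for ties (χ² with k−1 df).  Both are delegated to `lifelines` and
cross-checked in the tests against closed-form and hand-computed oracles.
The paired pre/post histoscore comparison uses a Wilcoxon matched-pair
signed-rank test written here: zero differences dropped, tie-averaged ranks,
exact two-sided p by convolution over sign assignments for n ≤ 25 (ranks
doubled to integers so tied half-ranks stay exact), normal approximation
with tie correction beyond.  SciPy's implementation switches to the normal
approximation in the presence of ties; the convolution keeps the exact
distribution, which is why the test is hand-written.

## Synthetic data (`synthetic`)

All generators are bit-reproducible under a fixed seed; the pipeline splits
one global seed into stable per-stage children (SHA-256 of the stage name
into a `SeedSequence` spawn key).  Defaults are the study conditions used
by the acceptance suite:

| generator | defaults | planted truth |
|---|---|---|
| proteome | 2 000 features, WT + 3 resistant lines × 2D/3D × 4 reps, log-normal (log₂ base N(23, 2)), 5 % signature, same-sign |log₂FC| ∈ [1, 2] in every comparison, replicate SD 0.3 | per-feature signature flag, sign, true log₂FC |
| tracing | forward operator = the correction matrix itself, multiplicative log-normal channel noise | the input MID |
| lipidome | 12 classes × 8 species, CTL/KO × 3 reps, SD 0.1; DB > 2 scaled ×ko_effect in KO, DB ≤ 2 scaled ×1/ko_effect | per-species double bonds, saturation class, true linear FC |
| Raman | 2500–3200 cm⁻¹ @1 cm⁻¹, σ = 7 bands, tissue scale 2×10⁴ counts, 1 % noise, ratio jitter 0.02, 20 % background, 3 spikes/map | per-pixel clean band ratio, background flags, spike positions |
| cohort | n = 300, three expression components at (−2, 0, 2) ± 0.5, exponential event times scaled by per-component hazard ratios, independent exponential censoring calibrated to the requested censoring fraction | latent component and hazard ratio per patient |

The log-normal abundance model with additive Gaussian log-scale noise is the
standard label-free quantification error model; effects are applied
identically in both formats because the published panel shows same-sign
effects in all six comparisons.  The baseline planted in Raman maps is a
low-order polynomial so the pipeline's polynomial detrend can in principle
remove it exactly.

## Numerical choices and degenerate inputs

* Welch t on identical zero-variance groups returns p = 1 (no evidence)
  rather than NaN; a zero-variance group with different means returns p = 0.
* NNLS ill-conditioning (cond > 1e8) triggers a warning with the bound.
* Min–max-degenerate (constant) spectra and zero anchor intensities are
  flagged per pixel and excluded, never silently propagated.
* Fully tied Mann–Whitney inputs return p = 1 (scipy's tie-corrected normal
  approximation is undefined there).
* k-means stratification sorts values before fitting so the result is
  invariant to patient order; fewer distinct values than clusters raises.
* The packaged fold-change fixture is SHA-256-checked at load.

## Problem sizes in the test suite

The default suite runs in ≈ 1–2 CPU minutes: 20 seeds × 2 000 features for
signature recovery, 2 000 null features for Dunnett calibration (one shared
100 000-draw null table), 2 000 logrank null simulations at n = 60, 100
seeded Raman studies of 12 six-by-six-pixel maps for the power check, and
exhaustive 2ⁿ enumeration up to n = 12 for the signed-rank oracle.  These
sizes were chosen to keep the full suite interactive while leaving the
Monte Carlo standard errors well inside the asserted bands.

## Known limitations

* The permutation significance engine uses per-feature permutation p-values;
  with 4v4 designs the p floor is ≈ 3/n_permutations because near-identity
  label splits recur.
* The Dunnett MC null assumes a balanced common variance model (the ANOVA
  pooled-variance assumption); strongly heteroscedastic groups are better
  served by the Welch path.
* `lipid_diff_matrix` annotates but does not cluster; no sn-position or
  ether lipid support.
* The Raman pipeline reads band heights at fixed positions (no local-maximum
  search) and models no fluorescence; the 60 000-count floor is meaningful
  only on vendor-scale counts.
* Survival tooling is outcome-agnostic (no Cox models, no covariates).
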