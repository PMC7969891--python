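# Methods

## Data and scales

The package's fixtures are the study's two printed summary tables. Exposure
effects are per SD of each iron biomarker (ferritin on the natural-log scale,
used as-is; no back-transformation) from the Genetics of Iron Status
consortium (N = 48,972). Outcome effects are log-odds of ALS from an
80,610-subject meta-analysis (20,806 cases). Positions are 1-based, build 37.
The exposure table lists only genome-wide-significant associations and prints
no p-values, so exposure records carry `pvalue=None`, which the significance
filter treats as passing p < 5×10⁻⁸; outcome records carry their printed p.
Both tables are stored as TSV exactly as printed (two-decimal betas) and are
guarded by frozen checksums.

## Instrument selection

Three criteria: genome-wide significance, pairwise linkage equilibrium
(r² ≤ 0.01; the LD matrix is an input, not computed here — the fixture SNPs
are already independent), and F > 10. The conservative rule keeps SNPs
significant for all four biomarkers with sign(iron) = sign(ferritin) =
sign(transferrin saturation) = −sign(transferrin); the test is symmetric
under a global sign flip, so it cannot depend on allele labelling. Nominal
(sub-genome-wide) concordance is deliberately not accepted. LD pruning, when
an LD matrix is supplied, is greedy by ascending p (missing p ranks most
significant; input order breaks ties) with a strict r² > threshold drop rule.

Per-SNP strength uses R² = 2β²(1−EAF)EAF — valid for a standardized
phenotype, no allele-count correction — and F with k = 1; a set-level F with
summed R² and k = |set| is also reported. Across the 25 significant
biomarker-SNP cells the per-SNP F spans ≈39 to ≈3,340.

## Harmonization

Exposure and outcome effects are aligned to a shared effect allele: identical
pairs kept, swapped pairs flipped (negate β_y, complement EAF), strand
complements resolved, and palindromic (A/T, C/G) SNPs resolved by EAF
concordance with an ambiguity window of ±0.08 around 0.5 (either EAF inside
the window drops the SNP). The window default follows common harmonization
practice; both fixture palindromes sit near EAF 0.85, so fixture results do
not depend on it. Indels and multi-allelic records are dropped, not guessed.
An aligned-EAF discrepancy above 0.2 warns without dropping (the two
consortia's frequencies differ by up to ~0.02, which must pass silently).

## Estimators

* **Wald ratio** β_y/β_x with first-order delta SE se_y/|β_x|. The exposure
  uncertainty is ignored, standard with strong instruments (all fixture
  F ≥ 39); a second-order SE is available behind a flag.
* **IVW**: weighted mean of Wald ratios, w_j = β_xj²/se_yj². Fixed-effect
  SE (Σw)^(−1/2); the default multiplicative random-effects variant scales it
  by max(1, √(Q/(J−1))) with Q Cochran's heterogeneity statistic. Point
  estimates are identical; one instrument reduces to the Wald ratio.
* **MR-Egger**: WLS of β_y on β_x with intercept after orienting every
  β_x ≥ 0 (making the fit invariant to allele coding). SEs are scaled by
  max(1, σ̂) with σ̂² the weighted residual mean square on J−2 df — never
  deflated below the fixed-effect SE. Slope and intercept p-values use the
  t distribution with J−2 df, the convention of the standard regression-based
  MR software; a normal reference is available via `pvalue_dist="normal"`.
  With the few instruments available here (J−2 as low as 3) the choice
  matters and t is the faithful one.
* **Weighted median**: order Wald ratios, normalized weights p_j = w_j/Σw,
  cumulative midpoints s_j = Σ_{i≤j}p_i − p_j/2, linear interpolation at 0.5.
  SE by parametric bootstrap (β_x*, β_y* drawn at the observed values with
  the observed SEs; default 1,000 draws, seed 0, both recorded).
* **Residual-sum outlier test** (PRESSO-style): leave-one-out IVW slopes give
  each SNP an expected outcome effect; the observed weighted residual sum of
  squares is compared against parametric simulations (default 5,000; +1
  Monte-Carlo correction, so p ≥ 1/(n_sim+1)). Per-SNP squared residuals give
  Bonferroni-adjusted outlier p-values; outliers are *flagged only when the
  global test is significant*, following the published construction, and the
  IVW estimate is refit without them. The distortion statistic is not
  computed by default.
* Results are reported as OR = exp(β) with 95% CI exp(β ± 1.96·se) and (except
  Egger) two-sided normal p-values.

Leave-one-out re-estimates the IVW result omitting each SNP in turn, with the
same effects model as the main run; single-SNP tables are the per-SNP Wald
results in forest-plot layout.

## Power

Normal-approximation power for a binary outcome:
power = Φ(|ln OR|·√(N·R²·φ(1−φ)) − z₁₋α/₂), inverted for the detectable OR at
a target power. With the conservative iron set (R² ≈ 0.039) and the outcome
study's dimensions, the detectable OR at 80% power is ≈1.12 per SD —
moderate effects below that would be missed, a real limitation of the null
result.

## Synthetic data and calibration

The generator draws true exposure effects γ_j ~ U(0.05, 0.35) (the magnitude
range of the fixture betas), observed β_xj ~ N(γ_j, 1/√N_exp), pleiotropy
α_j ~ N(μ_α, σ_α) — optionally correlated with γ_j through a Gaussian copula
to violate the InSIDE assumption — and β_yj ~ N(θγ_j + α_j, se_y) with
se_y = 1/√(N_out·φ(1−φ)), the standardized-genotype log-odds SE. Defaults
mirror the study's dimensions (N_exp = 48,972; N_out = 80,610; φ = 0.258;
J = 12). An optional outlier adds a shift in units of se_y to one SNP.

What it emulates: summary-level two-sample MR with independent instruments
and correctly specified SEs. What it does not: LD between instruments,
winner's-curse in instrument selection, sample overlap, allele-frequency-
dependent SE heterogeneity, and non-collapsibility of the odds ratio. Passing
calibration therefore validates the estimators' arithmetic and their sampling
behaviour under the assumed model, not robustness to those real-data features.

The calibration harness (500 replicates per configuration, J = 30) measures
empirical size at α = 0.05, bias and RMSE. Size cells use the fixed-effect
IVW, whose null is exactly nominal under the generator; the multiplicative
random-effects variant is conservative by construction (its SE is bounded
below by the fixed SE), and that conservatism — measured size ≈0.026 — is
expected behaviour, not an implementation defect. Observed: IVW size 0.036,
global outlier-test size 0.032, IVW mean 0.1000 at θ = 0.1, Egger intercept
mean 0.0198 at μ_α = 0.02 (replicate counts keep each Monte-Carlo SE below
0.01 / 0.0005 respectively).

## Numerical and design choices

* 95% CIs always use the 1.96 normal multiplier, matching the study's
  reporting style.
* The weighted-median interpolation extrapolates flatly outside [s_1, s_J]
  (numpy `interp` endpoint behaviour); with ≥3 instruments and positive
  weights 0.5 lies inside in all non-degenerate cases.
* Greedy LD pruning order (by significance) is stated explicitly because the
  original 12 SNPs were already independent and no order was published.
* Seeds: every stochastic routine (bootstrap, outlier simulation, generator)
  takes an explicit seed and records it in its result object.
* Biomarker orientation: estimates are per SD *increase of the biomarker*
  itself, including transferrin (which falls as iron status rises). The
  alternative — orienting transferrin to the iron-status direction — negates
  its log-OR; reports label the direction so the two conventions cannot be
  silently confused.

## Reproducibility limits of the printed inputs

The study computed from unrounded consortium data; the printed tables round
betas to two decimals. Consequences, all deliberate:

* Conservative IVW ORs recomputed from the fixtures land within 0.15 on the
  log scale of the printed 1.00 / 0.96 / 0.99 / 1.04 but do not equal them
  (printed iron inputs give OR ≈ 1.04, not 1.00); reproduction is asserted as
  CI-level and tolerance checks, not equality.
* For conservative transferrin the fixture log-OR (−0.039) is near the
  negative of the printed value (+0.039, OR 1.04), consistent with an
  orientation-convention difference for the inverse biomarker; see above.
* The liberal transferrin IVW and weighted-median CIs computed from rounded
  inputs are (0.909, 0.995) and (0.906, 0.997) — narrowly excluding 1.0,
  unlike the study's null conclusion from unrounded data. No defensible
  implementation choice moves them; the discrepancy is documented rather than
  patched, and the corresponding checks are expected to flag it.
* Simulation-based p-values (global outlier test) match the study
  qualitatively (all > 0.05, no outliers), not numerically.
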