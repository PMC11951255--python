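# Methods

## Model

Two-sample summary-data MR treats each harmonized variant j as an instrument
contributing an exposure association β_Xj (se_Xj) from one GWAS and an outcome
association β_Yj (se_Yj) from a non-overlapping GWAS. Under the instrumental
assumptions, β_Yj ≈ θ·β_Xj, and θ is estimated by weighted regression through
the origin. For a binary outcome the associations and θ are on the log-odds
scale.

The mediation model adds a mediator M on the causal path:

    protein X --α--> mediator M --γ--> outcome Y,  and X --δ--> Y directly,

so the total effect is θ_total = δ + αγ, the indirect (mediated) effect is
αγ, and the proportion mediated is αγ/(δ + αγ). Two-step cis-MR estimates α
from the cis instruments against the mediator GWAS, γ from genome-wide
mediator instruments against the outcome GWAS, and θ_total from the cis
instruments against the outcome GWAS. Two routes to the direct effect are
computed: the difference of coefficients (θ_total − θ_XM·θ_MY) and a
variant-level route that subtracts θ_MY·β_Mj from every variant's outcome
association (with se'ⱼ² = se_Yj² + β_Mj²·se(θ_MY)²) and re-runs IVW. The two
routes use slightly different weights and therefore differ at order se²;
they coincide as sampling error vanishes.

## Estimators and numerical conventions

- **IVW, multiplicative random effects.** θ̂ = Σwβ_Xβ_Y/Σwβ_X² with
  w = 1/se_Y². The fixed-effect SE (Σwβ_X²)^(−1/2) is multiplied by
  max(1, √(Q/(J−1))), where Q is the weighted residual sum of squares, so
  between-variant heterogeneity can widen but never narrow the interval.
  J = 1 reduces to the Wald ratio with scale 1.
- **LD-adjusted IVW.** GLS with Ω = diag(se_Y)·ρ·diag(se_Y) solved by
  Cholesky factorization; a non-invertible ρ (e.g. a duplicated variant at
  r = 1, smallest eigenvalue below 1e−10 of the largest) is a fatal
  `singular_ld` error rather than a silent pseudo-inverse.
- **Egger.** Variants are oriented to β_X ≥ 0 before the weighted fit with
  intercept; the overdispersion factor uses J − 2 degrees of freedom.
- **Weighted median.** Wald ratios sorted ascending with normalized weights
  w'ⱼ ∝ 1/se_ratio,j² (first-order ratio SE se_Yj/|β_Xj|); cumulative
  positions sⱼ = Σ_{k≤j} w'_k − w'ⱼ/2; the estimate interpolates linearly at
  s = 0.5. SE by seeded parametric bootstrap over both association sets
  (5000 draws by default).
- **Contamination mixture.** Each ratio is valid, N(θ, se²), or invalid,
  N(0, ψ² + se²), with ψ defaulting to 1.5× the SD of the ratios. The profile
  log-likelihood is maximized over a 1001-point grid spanning the ratio range
  ± 5 grid half-widths of the largest ratio SE; the 95% CI is the set of grid
  points within χ²₁(0.95)/2 = 1.920729 of the maximum. A non-contiguous set
  is flagged multimodal and its enclosing hull is reported. Ratios identical
  to float precision collapse to a zero-width CI at that point.
- **MR-PRESSO.** The observed residual sum of squares uses leave-one-out IVW
  predictions; its null distribution comes from 1000 parametric draws
  β*_Yj ~ N(θ̂₋ⱼβ_Xj, se_Yj²) with the leave-one-out fits recomputed per
  draw. Per-variant outlier p-values are Bonferroni-corrected by J and
  flagged at 0.05; the corrected estimate is IVW on the unflagged variants.
  The distortion test is out of scope.
- **Multivariable IVW.** WLS of β_Y on the J×k exposure matrix without
  intercept, overdispersion max(1, √(Q/(J−k))); a design condition number
  above 1e12 is fatal (`collinear_exposures`).
- **Conditional F.** Summary-data Sanderson–Windmeijer construction: the
  indexed exposure's associations are regressed on the other exposures' with
  residual-variance weights wⱼ = 1/(se_xj² + Σ_m δ_m² se_mj²) iterated to
  convergence; F = Σ wⱼ(xⱼ − Zⱼδ)²/(J − k + 1). With orthogonal strong
  instrument blocks this approaches the exposure's univariable mean F.
- 95% intervals use the fixed normal quantile 1.959964 and two-sided normal
  p-values throughout (summary-data MR convention; not t).
- All estimates can be reported per 1 SD *lower* exposure (a sign flip,
  default on in the pipeline) to mirror pharmacological inhibition.

## Harmonization and selection conventions

Positions are 1-based; the cis window is the closed interval
[start − flank, end + flank] with flank 100 kb by default. MAF and p filters
are strict inequalities (eaf = 0.01 or p = 5e−8 are excluded). Indels and
multi-allelic rows are rejected at read time. Clumping is greedy to the
smallest p with ties broken by larger |β/se| then lexicographic id, making
the kept set invariant to input row order. Palindromic variants are retained
only when min(eaf, 1−eaf) < 0.42 in both studies and the frequencies fall on
the same side of 0.5; the 0.42 limit is a common two-sample convention and is
configurable. A proxy variant (r² ≥ 0.8) inherits the missing instrument's
identity with its beta sign flipped when the LD correlation is negative.
Stored p-values win over recomputed ones; p is recomputed from z = β/se only
when absent.

## Trait-SD standardization

For a quantitative trait GWAS, se_j² ≈ var(Y)/(2·n·eaf_j(1−eaf_j)), so the
zero-intercept regression of 2·n·eaf(1−eaf) on 1/se² across variants has
slope var(Y). `estimate_trait_sd` returns its square root; `rescale_to_sd`
divides betas and SEs by it, leaving z-scores and p-values unchanged. The
estimator recovers the SD within 2% from 50 variants with 1% multiplicative
SE noise.

## Bootstrap for the mediation decomposition

The three component estimates (θ_total, θ_XM, θ_MY) are drawn independently
from normals centred at their point estimates with their standard errors —
the two-sample framing; possible sample overlap between mediator and outcome
GWAS is not modelled, but the generator has an `overlap_rho` knob for
sensitivity analysis. Indirect, direct and proportion are recomputed per
draw; CIs are percentile (2.5/97.5), robust to the ratio's skew, and SEs are
draw standard deviations. Draws with |θ*_total| below a guard (1e−6) are
rejected from the proportion; a rejection fraction above 1% raises an
`unstable_proportion_ci` warning. The default is 10⁶ draws; tests use 10⁴,
for which the quantile Monte-Carlo error is about 1% of a CI half-width
(it scales as 1/√n_boot).

## Synthetic-data generator

`SimulationConfig` defaults encode the study conditions the package is
validated under: 8 cis instruments in an AR(1) LD block (ρ = 0.3, so
adjacent pairs sit just below the r² < 0.1 clumping threshold) on a
protein GWAS of n = 35,365; 100 independent genome-wide mediator
instruments on a mediator GWAS of n = 114,999; a binary outcome GWAS of
n = 1,165,690 with case fraction 0.156, whose log-odds SEs use the
effective-sample-size form 1/√(2·maf(1−maf)·n·φ(1−φ)). Path coefficients
default to α = 0.46, γ = −0.30, δ = −0.062, giving θ_total = −0.2 and a true
proportion mediated of 0.69. Cis effect sizes are N(0.0765, 0.008), chosen so
the default panel explains ≈1.8% of protein variance with mean F ≈ 82. MAFs
are uniform on (0.1, 0.5); alleles are non-palindromic by construction;
p-values derive from z-scores. The binary outcome is simulated directly on
the log-odds summary-statistic scale (no individual-level logistic
sampling) — adequate for two-sample summary MR, and a documented
approximation. A `fasting_attenuated` helper halves α to emulate the weaker
protein–lipid coupling seen in non-fasted samples.

What the generator does **not** emulate: genome-wide realistic LD, allele
frequency differences between studies, population stratification, winner's
curse in instrument discovery, or participant overlap (beyond the
`overlap_rho` knob). Passing tests therefore demonstrate correctness of the
estimators and decomposition under the stated model, not robustness to those
real-data complications.

## Calibration-scenario design

Frequentist checks run under the conditions where their nominal levels are
defined: the IVW coverage scenario uses independent instruments (ld_rho = 0,
the post-clumping assumption plain IVW makes) and a pure direct effect of
−0.19; the Egger intercept type-I and MR-PRESSO global-null scenarios
additionally use a large exposure GWAS (n = 10⁷) and heterogeneous instrument
effects, i.e. the NOME condition those tests assume. Under the default
generator (residual cis LD), plain IVW intervals are anti-conservative, which
is why the mediation pipeline uses the LD-adjusted GLS IVW for all cis-based
estimates whenever an LD matrix is supplied. Robustness scenarios plant 30%
invalid instruments with directional pleiotropy N(0.02, 0.005) on the
variant–outcome path.

## Known limitations

- First-order ratio SEs for median/contamination-mixture weights;
  second-order terms omitted.
- The contamination-mixture CI is grid-limited (resolution = grid span /
  1000) and reports the hull when multimodal.
- Conditional F assumes zero cross-GWAS covariance between exposures
  (different cohorts).
- Proportion-mediated CIs can legitimately extend outside [0, 1]; opposite
  signs of indirect and total are flagged `inconsistent_mediation` rather
  than suppressed.
- R² (and hence Cragg–Donald F) assumes SD-standardized traits and
  post-clumping independence; residual LD below the clumping threshold
  slightly inflates it. Not corrected, by design.
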