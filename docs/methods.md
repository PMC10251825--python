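# Methods

This note records the statistical model the package implements, the
conventions and numerical choices behind each stage, what the synthetic
data generator does and does not emulate, and the design decisions taken
where the methodology left the choice open.

## Two-sample MR model

Exposure and outcome effects come from non-overlapping GWAS samples of the
same ancestry. For instrument $j$: $\hat\gamma_j \sim N(\gamma_j,
\sigma_{X_j}^2)$ on the exposure and $\hat\Gamma_j \sim N(\Gamma_j,
\sigma_{Y_j}^2)$ on the outcome, with $\Gamma_j = \beta\gamma_j +
\alpha_j$, where $\beta$ is the causal effect of interest and $\alpha_j$ a
(horizontal) pleiotropic effect, zero for valid instruments. All
estimators operate on this summary scale; $\beta$ is a log odds ratio when
the outcome is binary, and 95% CIs are formed as $\hat\beta \pm 1.96\,
\mathrm{SE}$ on the log-odds scale and exponentiated for OR presentation.

## Instrument selection

Variants associated with the exposure at p < 5e-8 (strict inequality) are
greedily clumped: the remaining variant with the smallest p-value becomes
an index, and every remaining same-chromosome variant within ±10,000 kb of
it with panel r² ≥ 0.01 is removed. p-value ties break by (chromosome,
position, id) ascending, making the output invariant to input order. The
window is anchored at the index variant's position; candidates not covered
by the LD panel are dropped with a logged reason.

Instruments absent from the outcome GWAS may be replaced by a proxy with
r² > 0.8 (strict); among qualifying proxies the highest r² wins, ties
broken by genomic distance then id. Proxy outcome statistics are mapped
onto the target's alleles by the sign of the dosage correlation; sparse r²
tables carry no sign, so table-based panels assume concordant dosage
coding (a documented limitation — supply a dosage-matrix panel if signed
alignment matters).

Strength accounting: per-variant explained variance is
$2\,\mathrm{eaf}(1-\mathrm{eaf})\beta^2$ (standardized trait,
Hardy–Weinberg); variants with missing eaf stay instruments but are logged
out of the R² sum. Since published "mean F" columns do not pin down the
aggregation, both the mean of per-SNP F values (k = 1) and the overall F
evaluated at the summed R² with k = set size are reported.

## Harmonization

Allele resolution order: exact match; swapped effect/other (outcome beta
negated, frequency mirrored); reverse-complement of either (strand flip);
palindromic A/T / C/G pairs, where strand is unresolvable from alleles —
orientation is inferred from allele-frequency concordance when both
minor-allele frequencies are below 0.3, else the variant is excluded as
ambiguous; anything else is excluded as allele-incompatible. The 0.3
bound is the conventional compromise between losing variants and risking
mis-orientation near eaf 0.5; `palindromic_maf_limit=0` always excludes
palindromic variants and `0.5` always infers. Indels and multi-allelic
records are excluded at ingest (alleles restricted to single bases).
Every input instrument is accounted for as either kept or excluded with a
reason; empty harmonized sets raise an explicit error rather than passing
silently downstream.

## Estimators and diagnostics

- **IVW** is the weighted zero-intercept regression with weights
  $\sigma_{Y_j}^{-2}$, algebraically identical to the inverse-variance
  meta-analysis of Wald ratios. Multiplicative random effects — the
  reported default — inflate the SE by $\max(1, \sqrt{Q/(J-1)})$ so
  heterogeneity widens but never tightens inference; fixed effects are
  available as an option. IVW and Wald p-values are normal.
- **MR-Egger** orients pairs so $\hat\gamma_j \ge 0$, fits WLS with an
  intercept, and floors the residual dispersion at 1 so an underdispersed
  fit cannot undercut fixed-effect uncertainty; slope and intercept
  p-values use the t distribution with J − 2 df. A constant regressor
  raises a collinearity error.
- **Weighted median** uses ratio weights $(\hat\gamma_j/\sigma_{Y_j})^2$
  (first-order inverse variances), linear interpolation of the weighted
  empirical CDF at 0.5, and a seeded parametric bootstrap for the SE: each
  ratio is redrawn around its estimate with its first-order SE
  $\sigma_{Y_j}/|\hat\gamma_j|$, weights held fixed, 1000 replicates by
  default. `n_boot=0` skips the bootstrap for point-estimate-only studies.
- **Weighted mode** maximises a Gaussian-kernel weighted density of the
  ratios on a 512-point grid spanning their range, with modified-Silverman
  bandwidth $0.9\,\min(\mathrm{sd}, 1.4826\,\mathrm{MAD})\,J^{-1/5}$
  scaled by a user `bandwidth_factor`; if one spread measure is zero the
  other is used, and if all ratios coincide the common ratio is returned
  directly. SEs use the same bootstrap.
- **Dispatch**: 1 instrument → Wald ratio only; 2 → IVW + Cochran's Q;
  ≥3 → IVW, Egger (with intercept test), weighted median, weighted mode.

Method availability thresholds (2 for IVW, 3 for Egger/median/mode) follow
the estimators' degrees-of-freedom requirements.

## Power and multiple testing

Binary-outcome power uses the noncentrality calculation of the standard
MR power calculator: $b = K(\mathrm{OR}/(1 + K(\mathrm{OR}-1)) - 1)$,
$v = (K(1-K) - b^2)/(N R^2_{xz})$, and power is the upper tail of a
noncentral $\chi^2_1(b^2/v)$ beyond the central critical value at
$1-\alpha$; it returns exactly $\alpha$ at OR = 1. It is implemented
locally so the pipeline has no web dependency. The screen reports power at
OR 0.9 and 1.1 per exposure, using the instruments' summed R² and the
outcome's size and case fraction.

Bonferroni correction uses m = the number of exposures actually estimated
(not attempted), within each user-assigned correction family; by default
all exposures form one family, mirroring screens that correct within a
trait family only.

## Synthetic data generator

The generator works directly on the standardized summary scale — no
individual-level genotypes. Per instrument: maf uniform on the configured
range; true effects $\gamma_j$ half-normal (the effect allele is reported
as the exposure-increasing allele, the orientation in which directional
pleiotropy is defined), rescaled so $\sum 2p(1-p)\gamma^2$ equals the
target R²; exposure SE $(2n_Xp(1-p))^{-1/2}$; outcome SE
$(2n_Yp(1-p)K(1-K))^{-1/2}$ for case fraction K; observed effects drawn
around the truth. Pleiotropy modes: none, balanced (zero-mean), directional
(nonzero mean), and InSIDE-violating (correlated with $\gamma$, ρ = 0.7),
applied to a configurable fraction of instruments. Realism features: LD
decoy variants with exact pairwise r² recorded in the panel (so clumping
is deterministic), a configurable palindromic-allele fraction,
between-sample allele-frequency jitter (±0.02), and random allele-frame
and strand flips in the outcome file so harmonization is genuinely
exercised.

Defaults are the package's reference study conditions, chosen once:
J = 100 instruments explaining R² = 0.05 of the exposure (mean
per-instrument F ≈ 25 at $n_X$ = 50,000, within the range published
instrument tables report), outcome GWAS of 100,000 with case fraction
0.00217 — the case fraction of a registry liver-cancer GWAS (518 cases in
239,196), whose large outcome-side SEs dominate weak-instrument
attenuation just as in real rare-outcome screens; causal effect zero by
default. The screen fixture mirrors a proteome-scale screen: exposure
GWAS of n = 35,559, shared rare outcome, instrument counts varying from
1 (exercising the Wald path, ~11% of exposures) to 8.

What the generator does **not** emulate: genome-wide variant counts and
realistic LD maps (decoys use a simple construction targeting a drawn r²),
assay measurement error, winner's-curse in instrument discovery,
population stratification, or sample overlap. Passing calibration tests
therefore demonstrates correctness of the estimators and pipeline under
the stated model, not robustness to these real-data complications.

## Reference simulation studies

The standing evaluation suite (`mrscreen.studies`, asserted by the test
suite and reported by `scripts/acceptance.py`) uses these scenario
definitions, fixed a priori:

- **Recovery**: defaults with β = 0.2, no pleiotropy; 200 replicates; IVW
  mean bias vs its Monte-Carlo SE and 95% CI coverage.
- **Type-I**: β = 0 with balanced pleiotropy on all instruments,
  pleiotropy SD 0.1 (comparable to the outcome-side SE, so heterogeneity
  is genuinely present); 500 replicates; rejection rates of the
  random-effects IVW test and the Egger intercept test at α = 0.05.
- **Robustness**: β = 0.2 with directional pleiotropy (mean 0.02) on 40%
  of instruments, balanced outcome (K = 0.5) and $n_X$ = 2,000,000 — the
  NOME regime in which exposure-side regression dilution (≈ β/F̄) is
  negligible, isolating the properties under test: weighted-median bias
  below fixed-effect IVW bias, Egger slope unbiased under InSIDE; 200
  replicates.
- **Heterogeneity**: defaults with β = 0.2, no pleiotropy; 500 replicates;
  mean Q/(J−1) and uniformity of Q p-values. (Exposure-side sampling error
  inflates Q/df by ~10⁻³ at these sizes, far inside Monte-Carlo error.)
- **Null screen**: 187 all-null exposures against one shared rare outcome;
  nominal p < 0.05 counts should be binomial and no exposure should
  survive α/m.

Calibration scenarios set the palindromic fraction to zero so each
replicate keeps exactly J instruments; the palindromic paths are covered
by their own fixtures. Replicate seeds are derived from a single study
seed via a seeded integer stream.

## Numerical choices and degenerate inputs

p-values recorded as 0 in input files are floored to the smallest positive
normal double (they only feed ranking and thresholding); p-values computed
internally are floored at the smallest subnormal. Zero-variance dosage
vectors make LD undefined (error); unknown panel ids raise lookup errors.
beta_x = 0 makes the Wald ratio and per-instrument ratios undefined
(error). The bootstrap RNG is an explicit seeded generator, so identical
configs and seeds give byte-identical outputs end to end, a property the
pipeline tests assert on the written files.

## Known limitations

No MR-PRESSO outlier removal, Steiger directionality filtering,
multivariable MR, or colocalization. Proxy alignment from r²-only tables
assumes positive dosage correlation (see above). The weighted-mode grid
spans the observed ratio range only, which is the relevant region for the
argmax but means densities are not evaluated beyond the extreme ratios.
Power is the binary-outcome calculation only; continuous-outcome power and
ascertainment corrections are out of scope.
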