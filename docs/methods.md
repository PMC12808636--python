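# Methods

This note documents the statistical model behind `pwmr`, the assumptions and
defaults of every stage, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Two-sample MR model

Let β_X ± se_X be a variant's effect on a standardized exposure (circulating
protein level, SD units per effect-allele copy) from one GWAS and β_Y ± se_Y
its effect on a standardized outcome (BMI) from a second, non-overlapping
GWAS. Under the instrumental-variable assumptions (relevance, independence,
exclusion restriction) the causal effect θ in SD-outcome per SD-exposure is
identified by the ratio β_Y/β_X.

**Wald ratio** (single instrument): θ̂ = β_Y/β_X with first-order
delta-method SE se_Y/|β_X| (default) or second-order
√(se_Y²/β_X² + β_Y²·se_X²/β_X⁴) (flag `se_order="second"`). The first-order
form is the conventional choice when the instrument is strong; at F ≈ 700
(the default study scale) the two differ by under 4%, which shows up as
slightly-below-nominal CI coverage (~0.93–0.94 measured) — within the
calibration band we target ([0.92, 0.97]).

**IVW**: weighted least squares of β_Y on β_X through the origin with
weights 1/se_Y². The fixed-effect SE is √(1/Σ wβ_X²); with ≥ 4 instruments
the default switches to multiplicative random effects, multiplying the SE by
√max(1, Q/(k−1)) where Q is Cochran's heterogeneity statistic. Dispersion
never deflates the SE. With one instrument IVW reduces bit-for-bit to the
first-order Wald ratio.

**MR-Egger**: the same regression with a free intercept after orienting all
pairs to β_X > 0 (a joint sign flip, under which every estimator here is
equivariant). The intercept estimates directional pleiotropy; both
coefficient SEs carry the √max(1, Q/(k−2)) inflation. Constraining the
intercept to zero recovers the IVW slope exactly (both go through one shared
weighted-LS routine).

**Weighted median / weighted mode**: consensus estimates over the per-SNP
ratios with inverse-variance weights on the first-order ratio SEs. The
median interpolates the weighted 50th percentile; the mode maximizes a
normal-kernel density with bandwidth `bandwidth_factor` × 0.9·min(weighted
SD, 1.4826·weighted MAD)·k^(−1/5). Standard errors come from a parametric
bootstrap that redraws (β_X, β_Y) from their sampling normals per SNP
(default 1,000 draws, seed 1234 — both mandatory, surfaced in the config).

All p-values are two-sided normal (never t): at GWAS sample sizes the
distinction is negligible, and fixing it makes runs exactly reproducible.
95% CIs are β ± 1.959964·se throughout. Multiple testing across the proteome
is controlled with Benjamini–Hochberg (statsmodels' step-up implementation);
significance is declared on adjusted p ≤ 0.05. The raw-p threshold this
corresponds to is dataset-dependent and is reported, not hard-coded.

## Instrument selection and harmonization

A cis-pQTL instrument satisfies: same chromosome as the gene, |pos − TSS| ≤
1 Mb, p ≤ 5×10⁻⁸, and single-SNP F = (β/se)² > 10 (strict inequality). When
an LD matrix is supplied, survivors are greedily clumped by ascending
p-value (ties broken by rsid, making selection order-invariant) at
r² ≤ 0.001 — a deliberately strict default, exposed in the config, since
sources rarely report their clumping parameters. The single-SNP F
approximation is used because per-study variance explained is not generally
available; it equals the squared Wald z of the exposure association. An
instrument missing from the outcome GWAS may be replaced by its best LD
proxy with r² ≥ 0.8; the proxy's own alleles and effects are used and
re-harmonized, never copied from the query. Proteins with no usable
instrument or proxy are reported "not testable" rather than failing the run.

Harmonization aligns the outcome to the exposure's effect allele:

- identical allele pairs pass through; swapped pairs (or, for
  non-palindromic SNPs, their strand complements) flip β_Y and replace
  eaf_Y by 1 − eaf_Y;
- palindromic SNPs are strand-ambiguous, so allele labels are ignored and
  orientation is inferred from frequency concordance: flip iff
  |eaf_X − eaf_Y| > |eaf_X − (1 − eaf_Y)|. Those with min(eaf, 1−eaf) > 0.42
  in either table (strict), or missing eaf, are excluded — near 0.5 the two
  strand readings are indistinguishable;
- anything irreconcilable is excluded with reason `allele_mismatch`; every
  exclusion lands in a per-run audit TSV.

Indels are harmonized by exact string match/swap and skipped by the
palindrome logic. Self-harmonization of a table is the identity (all pairs
`aligned`), and recoding the outcome onto the other allele before
harmonization leaves every (β_X, β_Y) pair unchanged — both are property
tests.

## Colocalization

Per SNP and trait, Wakefield's approximate Bayes factor with V = se²,
z = β/se and prior effect variance W = 0.15² (the quantitative-trait default
with unit-variance phenotypes):

log ABF = ½·log(V/(V+W)) + ½·z²·W/(V+W).

Under a single causal variant per trait, the un-normalized hypothesis
weights over a region of M SNPs are H0: 1, H1: p1·ΣABF₁, H2: p2·ΣABF₂,
H3: p1·p2·(ΣABF₁·ΣABF₂ − ΣABF₁ABF₂), H4: p12·ΣABF₁ABF₂, with priors
p1 = p2 = 10⁻⁴ and p12 = 10⁻⁵. Everything is accumulated in log space with
log-sum-exp (log-ABFs of several hundred are routine at these sample sizes);
the H3 term uses log1p of the ratio so that M = 1 gives PP.H3 = 0 exactly,
and p12 = 0 gives PP.H4 = 0 exactly. The implementation is tested to 1e-10
against a brute-force enumeration of all (M+1)² causal configurations.
Regions take the rsid intersection of the two tables, drop variants with
MAF < 0.01, and check allele-pair sanity (no sign alignment is needed — only
z² enters). PP.H4 > 0.75 is called `colocalized`, PP.H3 > 0.75 `distinct`,
anything else `underpowered`.

## Mediation, reverse MR, power

The two-step (network) MR indirect effect is a·b, the product of the
exposure→mediator and mediator→outcome MR estimates, with first-order Sobel
SE √(a²·se_b² + b²·se_a²) (the exact variant adds se_a²·se_b²; flag
`exact_se`). The proportion mediated is reported only when a total-effect
estimate is supplied and |total| exceeds its SE, to avoid unstable ratios.

Reverse MR instruments the outcome with its genome-wide-significant, clumped
SNPs and reports IVW plus Egger (with intercept test), weighted median and
weighted mode on the same harmonized set; below three instruments only IVW
is returned.

Power uses the normal approximation for a continuous outcome: the MR Wald z
is ≈ Normal(√NCP, 1) with NCP = n_outcome·R²·β², where R² is the variance in
the exposure explained by the instrument (computed as Σ 2·maf·(1−maf)·β_X²
over the clumped instruments). Two-sided power is
1 − Φ(z₁₋α/₂ − √NCP) + Φ(−z₁₋α/₂ − √NCP); at β = 0 this equals α exactly,
and it matches a Monte-Carlo simulation of the Wald z within 0.005 (tested).
The chi-square composition of the same test agrees to < 1e-4 at the NCPs
that matter here, so the choice between them is immaterial.

## Synthetic-data generator

Summary statistics are simulated directly on the z-score scale rather than
from individual-level genotypes. With standardized genotypes and traits, the
true marginal z-vector of a region is √n·R·b, where b holds the joint causal
effects (per SD of genotype) and R is the LD correlation matrix (AR(1),
r_ij = ρ^|i−j|, Cholesky factor in closed form); observed z-scores add one
multivariate-normal draw with covariance R per trait and region, so LD
structure appears in the noise exactly as in real regional statistics.
Per-allele scale follows from the per-SNP variance 2·maf·(1−maf):
se = 1/√(2·maf·(1−maf)·n), β = z·se. This is distributionally equivalent to
an individual-level simulation under the standard linear-model
approximation and orders of magnitude faster.

Scenario vocabulary mirrors the colocalization hypotheses (h0–h4) plus
`pleiotropy` (many instruments, optional constant direct outcome effect),
`mediation` (exposure → mediator → outcome chain, three tables) and
`reverse` (the protein keeps its own cis-pQTL but the outcome is causally
upstream through an independent block of instruments). Defaults emulate the
study setting the package targets: exposure GWAS n = 35,559, outcome GWAS
n = 39,620, mediator GWAS n = 155,961, one strong cis-pQTL per protein,
causal effects in the −0.07 to −0.33 SD/SD range, ~1 Mb cis regions of 200
SNPs at ρ = 0.9, MAF uniform on (0.05, 0.5). Named presets pin three
scales: `paper_scale_eng` (9% exposure variance explained, effect −0.07),
`paper_scale_fabp4` (0.36%, −0.33), `paper_scale_cadm1` (2%, −0.26, the
preset used for end-to-end validation) and `null_535` (no effects). A
fraction of outcome rows get their reported effect allele swapped, and an
optional fraction of SNPs is made palindromic, so harmonization is exercised
on every run; causal SNPs are always non-palindromic so the generative truth
survives harmonization.

What the generator does **not** emulate: realistic human LD maps and
allele-frequency spectra, binary traits, sample overlap between the two
GWAS, population stratification, winner's-curse selection of instruments in
the exposure GWAS, and assay-specific measurement error. Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery under the stated model, not robustness to those real-data
complications.

## Problem sizes and determinism

The validation suite uses sizes chosen to make the checks statistically
meaningful at desk scale: 5,000 replicates for type-I error (band
0.05 ± 0.01), 1,000 for CI coverage (band [0.92, 0.97]), 100 pipeline runs
for end-to-end h4 recovery (threshold 85%), 100 for the h3-preference rate,
200 for the robust-estimator breakdown simulations, and 10⁵ draws for the
Monte-Carlo oracles of the second-order Wald SE, Sobel SE and power. Every
stochastic component takes an explicit seed; pipeline reruns with identical
config and seeds are byte-identical (a test asserts this on the emitted
files).

## Known limitations

- Single-causal-variant colocalization only; no SuSiE-style multi-signal
  decomposition or conditional analysis.
- No MR-PRESSO, contamination mixture, multivariable MR or Steiger
  filtering.
- The F statistic uses the single-SNP (β/se)² approximation.
- Harmonization does not lift over genome builds or split multi-allelics.
- The confounder screen counts associations in a user-supplied local table;
  it does not query any external PheWAS service.
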