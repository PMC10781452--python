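# Methods

## The analysis model

`drugmr` performs two-sample drug-target Mendelian randomization. The
exposure is a circulating lipid trait (LDL cholesterol or triglycerides, in
SD units); instruments are restricted to variants in or near the gene
encoding a drug's protein target, so the estimated effect proxies
pharmacological modulation of that target rather than lipid levels in
general. The three instrumental-variable assumptions are: relevance (the
variant is robustly associated with the exposure), independence (no
association with confounders), and exclusion restriction (no effect on the
outcome except through the exposure). Exposure and outcome associations come
from separate cohorts, so their sampling errors are independent.

### Instrument selection

Candidates are SNPs on the gene's chromosome within
`[start − flank_bp, end + flank_bp]` (flank default 100 kb) with
`p ≤ 5 × 10⁻⁸`. Greedy p-ranked LD clumping then repeatedly keeps the most
significant remaining SNP and discards every remaining SNP with
r² ≥ `clump_r2` (default 0.3) to it within `clump_window_bp` (default
100 kb). Ties in p break deterministically by (position, variant id). The
clumping window and the gene flank are separate parameters that happen to
share a default. The LD matrix is an explicit input — no reference panel is
bundled — and a candidate pair missing from it is conservatively treated as
r² = 1 (discard; configurable to 0). Genes with fewer than `min_snps`
(default 3) survivors are skipped and reported, not errors: with a cis-only
search some targets genuinely lack enough independent instruments.

The r² < 0.3 threshold admits residual correlation between retained
instruments; the estimators nevertheless treat them as independent (the
standard first-order practice), which is a known limitation rather than a
modeling choice — a generalized (correlation-aware) IVW is out of scope.

### Harmonization

Outcome effects are aligned to the exposure's effect allele per SNP:
identical alleles copy, swapped alleles negate the outcome beta, alleles
matching only after base complement are treated as a strand flip, anything
else (e.g. A/G vs A/C) is excluded as allele-inconsistent. Palindromic
variants (A/T, G/C) are dropped by default because allele labels cannot
resolve the strand; an opt-in policy orients them by allele-frequency
agreement, excluding any SNP whose frequency on either side falls in
[0.42, 0.58], where orientation is not identifiable in practice.

### Steiger directionality filter

For each SNP the variance explained on each side is computed from the t
statistic, r² = t²/(t² + n − 2); a variant is "forward" only if
r²_exposure > r²_outcome strictly, so exact ties are removed. The default
mode removes every non-forward variant; a `significant` mode removes only
those whose Steiger z test (difference of Fisher-transformed correlations,
two-sided normal) rejects at `steiger_alpha`. The t-statistic form is the
default because effect-allele frequencies are missing from several common
source formats; the 2β²·eaf(1−eaf) form is available where eaf exists.

### Estimators

Definitions as in the README. Numerical choices worth recording:

- **IVW**: the `auto` effects model uses multiplicative random effects
  (SE × max(1, √(Q/(k−2)))) iff Cochran's Q has p < 0.05 and k ≥ 3,
  otherwise fixed. A single SNP degrades to the Wald ratio. Confidence
  intervals use z = Φ⁻¹(0.975); p-values are two-sided normal.
- **MR-Egger**: SNPs are oriented so b_X ≥ 0 before regression (the fit is
  then invariant to which allele a study chose to report). Slope and
  intercept SEs scale the weighted-regression covariance by
  max(1, √(RSS_w/(k−2))); p-values use t with k − 2 df. Zero variance in
  the oriented b_X is a collinearity error.
- **Weighted median/mode SEs** come from a parametric bootstrap,
  r_j* ~ N(r_j, s_j), with *antithetic* draws (each z paired with −z). The
  antithetic set is closed under negation, which makes the SE exactly
  invariant when all outcome effects change sign at the same seed, and
  slightly reduces bootstrap variance. Seeds are mandatory inputs surfaced
  in the output metadata. In the degenerate case where all bootstrap
  estimates coincide, the SE falls back to √(1/Σw).
- **Weighted mode** bandwidth: h = φ · 0.9 · min(sd, 1.4826·MAD) · k^(−1/5)
  (Silverman-type rule on a robust scale, φ tunable, default 1); if one of
  the two scale estimates is zero the other is used; if both are zero all
  ratios coincide and that value is returned. The KDE argmax is taken on a
  512-point grid spanning [min r − 3h, max r + 3h], ties broken toward the
  lowest grid index; the grid resolution bounds the estimator's precision.
- **Maximum likelihood** is fitted by exact block-coordinate updates (the
  negative log-likelihood is quadratic in γ for fixed β and vice versa, and
  the blocks are weakly coupled, so convergence is fast). The convergence
  criterion is the curvature-scaled gradient (per-coordinate Newton step)
  falling below `tol` (default 1e-8) — a raw gradient norm scales as 1/se²
  and would not mean the same thing across SE magnitudes. The SE comes from
  the observed information via Schur complement on the β block.

### Diagnostics, power, multiplicity

Cochran's Q is computed against the fixed-effect IVW estimate with a
χ²(k−1) reference. Leave-one-out refits IVW without each SNP and flags a
SNP as influential when its omission flips the estimate's sign or moves the
p-value across 0.05 (the criterion is a design choice; "influential" has no
canonical definition). Power uses the non-centrality normal approximation:
λ = |β|·√(N·R²) for continuous outcomes, λ = |β|·√(N·R²·K(1−K)) for binary
ones (log-odds β, case fraction K); the pipeline evaluates power at the
observed IVW estimate. Exact parity with any web calculator is not claimed.
Benjamini–Hochberg q-values are computed over the primary (IVW) p-values,
by default within outcome categories (longevity, cardiometabolic, cancer,
positive control) because that is how results grids are usually grouped and
read; a global scope is available. Meta-analytic pooling offers fixed
effects and DerSimonian–Laird random effects
(τ² = max(0, (Q − (m−1))/(Σw − Σw²/Σw))), with `auto` choosing random iff
the meta-Q has p < 0.05; pooling refuses to mix beta- and log-OR-scale
estimates.

### Reporting conventions

Estimates are reported per 1 unit *lower* exposure — the lipid-lowering
direction a drug produces — by negating the per-1-unit-increase regression
estimate; a per-trait `scale_factor` rescales first (e.g. SD → mmol/L).
Binary outcomes additionally report OR = exp(β) with its CI. Result tables
are TSV with a fixed column order and full-precision floats, so a
write/read round trip is lossless.

## The synthetic-data generator

The generator realises the two-sample MR data model directly at the
summary-statistic level (no individual-level genotypes):

- MAF ~ Uniform(0.05, 0.5); standard errors follow the standardized-trait
  approximation se = 1/√(2n·MAF(1−MAF)), divided by √(K(1−K)) for binary
  outcomes on the log-odds scale. Defaults n_exp = 170,000 and
  n_out = 300,000 match the scale of lipid-consortium exposure GWAS and
  large biobank outcome GWAS.
- True exposure effects γ_j ~ N(0, 0.02²) truncated at |γ| ≥ 0.005, then
  rescaled by one common factor so every SNP's expected exposure z
  statistic is ≥ 6 — instruments a cis-search at p ≤ 5 × 10⁻⁸ would
  actually find. A global rescale (rather than a per-SNP floor) preserves
  the shape of the effect-size distribution, whose spread is what
  identifies the Egger slope.
- Outcome effects: b_Y ~ N(β·γ + α, se_Y²) with true causal effect
  β = 0.1 per SD by default. Exposure and outcome noise are independent
  streams (two-sample design).
- Exclusion-restriction violations: a fraction `prop_invalid` (default 0.3
  when enabled, lowest-index SNPs) receives a direct outcome effect
  α ~ N(mean, 0.01²). *Balanced* pleiotropy uses mean 0. *Directional*
  pleiotropy uses mean 0.05 applied in the instrument's orientation
  (multiplied by sign(γ)) so every invalid SNP pushes the causal estimate
  the same way — with signed instruments a constant-mean α would otherwise
  self-cancel and not be directional in effect.
- Reverse causation: the last `n_reverse` SNPs have a large direct outcome
  effect δ (drawn like γ, floored at 6 outcome SEs) feeding back on the
  exposure with β_rev = 0.05 — the pattern Steiger filtering is built to
  remove.
- LD is AR(1) in position order, r²(i,j) = ρ^{2|i−j|}, positions 1 kb
  apart inside a synthetic LDL_C gene region; grid simulations derive
  per-cell seeds deterministically from the master seed and grid indices.

What the generator does *not* emulate: realistic human LD block structure,
allele-frequency-dependent effect sizes, winner's curse in the exposure
selection, sample overlap between cohorts, population stratification, and
LD-induced correlation between the effect estimates themselves (the AR(1)
matrix feeds the clumping stage only). Passing tests therefore demonstrate
the correctness and calibration of the statistical machinery under the
assumed model — not robustness to those real-data complications.

## Validation design and problem sizes

The test suite and `scripts/acceptance.py` validate against independent
oracles: closed-form weighted least squares for IVW, a brute-force clumping
reference, hand-computed Q/BH/DerSimonian–Laird values, a refined-grid mode
check, statsmodels' meta-analysis as a cross-check, and Monte-Carlo
recovery/calibration studies (500 replicates for bias, coverage and
robustness orderings, 1000 for type-I error, 200 replicates of a null
9 × 5 grid for FDR control). These sizes give Monte-Carlo standard errors
of about 1% on the rates being checked while keeping the full suite under
half a minute. Published drug-target estimates themselves are not
reproduced: they require multi-gigabyte consortium GWAS downloads and an
LD reference panel, which this package deliberately does not bundle.

## Known limitations

Correlated instruments are treated as independent below the clumping
threshold; second-order Wald-ratio SEs (using eaf/covariance terms) are not
implemented; no proxy-SNP lookup for variants missing from the outcome; no
multivariable MR, MR-PRESSO, contamination-mixture estimators, or
colocalization; no genome-build liftover (coordinates are GRCh37, 1-based
inclusive internally, BED converted at the boundary).
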