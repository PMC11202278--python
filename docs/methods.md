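# Methods

This note documents the statistical model, the defaults and the
numerical choices behind `ivmr`, and what the synthetic-data studies do
and do not demonstrate.

## Two-sample MR model and assumptions

For variant j, a GWAS of the exposure reports the per-allele effect
γⱼ with standard error σₓⱼ, and an independent GWAS of the outcome
reports Γⱼ with σ_yⱼ (log-odds for a binary outcome).  If variant j is a
valid instrument — associated with the exposure, independent of
confounders, and affecting the outcome only through the exposure — then
Γⱼ = β·γⱼ and the Wald ratio β̂ⱼ = Γⱼ/γⱼ estimates the causal effect β,
with first-order (delta) SE σ_yⱼ/|γⱼ|.  All estimators here condition on
the reported summary effects and treat them as normal; the exposure-side
error σₓⱼ is ignored in the weights (the usual NOME approximation),
which is accurate when instruments are strong (F ≫ 10).

Estimation is purely summary-level: the two GWAS are assumed to come
from non-overlapping samples of the same ancestry, and a binary outcome
is treated on the log-odds scale, so exp(β) is an odds ratio per SD of
exposure.

## Estimators

**IVW.**  β̂ = Σwⱼβ̂ⱼ/Σwⱼ with wⱼ = γⱼ²/σ_yⱼ² (equivalently, weighted
regression of Γ on γ through the origin).  The fixed-effect SE is
(Σwⱼ)^{-1/2}.  Random-effects inference (the default, and the primary
method) multiplies the SE by max(1, √(Q/(J−1))) — the multiplicative
over-dispersion model, which inflates uncertainty under heterogeneity
but never shrinks it below the fixed-effect value.  Additive
(DerSimonian–Laird) random effects are deliberately out of scope.
P-values use the standard normal.  A single instrument degrades to the
Wald ratio with a warning.

**MR-Egger.**  Pairs are oriented so γⱼ ≥ 0 (negating both members where
needed), then Γ is regressed on γ with an intercept by WLS with weights
1/σ_yⱼ² (delegated to `statsmodels`).  The intercept estimates the mean
directional pleiotropy; the slope is the pleiotropy-adjusted causal
effect under the InSIDE assumption (instrument strength independent of
direct effects).  SEs carry the multiplicative inflation
max(1, √(RSS_w/(J−2))) and p-values use t with J−2 df — the small-J
convention for intercept inference.  No SIMEX dilution correction is
applied.  Note that the γ ≥ 0 orientation is only meaningful when the
sign of each γⱼ is statistically determined; the pipeline's F ≥ 10
filter guarantees this, and the pleiotropy simulations below apply it
for exactly that reason.

**Weighted median.**  Ratio estimates are sorted; with normalized
weights wⱼ the cumulative midpoints pⱼ = Sⱼ − wⱼ/2 define a piecewise
linear quantile function, interpolated at 0.5.  With equal weights this
is the ordinary interpolated median.  Consistent when valid instruments
carry at least half the total weight.

**Mode estimators.**  The Wald ratios are smoothed with a normal kernel
of bandwidth h = φ·0.9·min(sd, 1.4826·mad)·J^{−1/5} (φ = 1 by default; if
the MAD degenerates to zero the SD is used, and identical ratios return
the common value directly).  The estimate is the density argmax over a
fixed 512-point grid spanning the ratios ± 3h — fixed so that a seeded
run is exactly reproducible.  The simple mode weights instruments
equally; the weighted mode uses the IVW weights.

**Bootstrap SEs.**  The weighted median and modes take their SEs from a
parametric bootstrap: γⱼ* ~ N(γⱼ, σₓⱼ), Γⱼ* ~ N(Γⱼ, σ_yⱼ), re-estimate,
take the SD over 1,000 draws (default; configurable, seeded).  Case
resampling is not used — with a few dozen instruments it is noticeably
less stable.  All methods report OR = exp(β) with
exp(β ∓ 1.96·se) as the 95% CI.

## Sensitivity battery

* **Cochran's Q** on the Wald ratios with IVW weights; chi-square with
  J−1 df under homogeneity.
* **Egger intercept test** as above; |intercept| significantly ≠ 0 at
  p < 0.05 flags directional pleiotropy.
* **MR-PRESSO-style procedure.**  The observed statistic is the weighted
  residual sum of squares about leave-one-out IVW slopes,
  RSS = Σⱼ (Γⱼ − γⱼ·β̂₍₋ⱼ₎)²/σ_yⱼ².  Its null distribution is simulated
  (default 1,000 draws, seeded) by redrawing both γⱼ* and Γⱼ* from their
  fitted normal models and recomputing RSS identically.  The global
  p-value uses the add-one correction, so it is never exactly zero.
  Per-variant statistics are compared with their own simulated
  distributions as plain empirical proportions (so a variant can reach
  p = 0, keeping Bonferroni flagging at α/J feasible for any J at 1,000
  simulations).  The distortion test reports the displacement of the IVW
  estimate after removing flagged outliers, compared two-sidedly against
  the displacement obtained by removing an equally sized random subset
  in each null simulation; when nothing is flagged it is reported as
  not applicable rather than 1.  If every variant is flagged the result
  says so explicitly instead of producing an empty estimate.
* **Leave-one-out** IVW for each excluded variant, and **funnel data**
  (β̂ⱼ against precision |γⱼ|/σ_yⱼ) with the IVW and Egger verticals;
  funnel symmetry is exported as data only — the assessment is visual,
  and no automated asymmetry statistic is computed.

## Instrument selection

Significance uses strict p < 5×10⁻⁸.  Clumping is greedy on ascending
p-value (ties broken by genomic position): each index variant removes
all others on the same chromosome within 10,000 kb having r² ≥ 0.001
with it.  LD is an explicit input — a TSV of pairwise r² — rather than a
reference-panel computation, which keeps the package download-free;
pairs absent from the table count as unlinked and are reported in a
single aggregated warning.  Instrument strength uses
R² = 2·EAF·(1−EAF)·β² and F = R²(n−2)/(1−R²); F ≥ 10 is retained (the
exclusion rule is strictly F < 10).

## Harmonization

Outcome records are aligned to the exposure's effect allele: swapped
alleles negate Γ and reflect EAF; non-palindromic variants matching only
after base complementation are strand-mapped first; irreconcilable
alleles are excluded as `allele-mismatch`.  Palindromic variants whose
outcome EAF lies inside the window (0.42, 0.58) are excluded as
`palindromic-intermediate-eaf`; the window makes the qualitative
"intermediate frequency" rule operational, is configurable
(`--palindrome-window`), and should be kept symmetric about 0.5 so the
result does not depend on which allele the outcome file reports.
Palindromes outside the window are retained and aligned by frequency
agreement (both EAFs on the same side of 0.5); a strict mode drops all
palindromes.  Indels and multi-allelic records are rejected at read
time.  Every shared rsid ends up either harmonized or excluded with a
reason — conservation that the tests fuzz.

## Synthetic-data generator

The generator emulates the shape of the motivating study directly at
the summary level: J = 100 variants (the real instrument sets held
83–103), exposure GWAS of n = 115,006, and a rare binary outcome
collapsed to its effective sample size 4/(1/1196 + 1/475049) ≈ 4,772,
with per-variant SEs from the standard GWAS approximation
se = (2·maf·(1−maf)·n)^{−1/2}.  True instrument effects are
N(0, 0.06) SD per allele — putting single-variant F-statistics in the
tens-to-hundreds, as in a metabolite GWAS — and the default causal
effect is −0.25 log-odds per SD (OR ≈ 0.78, the magnitude of the
protective effects the package was built to study).  Pleiotropy regimes:
`none`, `balanced` (zero-mean direct effects on an invalid fraction),
`directional` (nonzero-mean), `outliers` (a few variants at ±10σ_y).
`gamma_positive` draws effects half-normal, i.e. codes every effect
allele as exposure-increasing — required for planted directional
pleiotropy to survive Egger's orientation.  Allele-coding quirks are
applied after all effect randomness (so the truth record always stores
exposure-frame effects): a fraction of outcome records is emitted with
swapped alleles, and a fraction carries palindromic pairs.  LD is
generated as block-diagonal r² over consecutive variants.

What the generator does *not* emulate: genotype-level sampling,
realistic MAF spectra or LD decay, winner's curse from in-sample
instrument discovery, sample overlap between the two GWAS, and
case-control ascertainment beyond the effective-size approximation.
Passing simulations therefore validate the estimators and the pipeline
logic under the stated generative model, not robustness to those
real-data complications.

## Simulation studies and their sizes

The acceptance checks (mirrored in `scripts/acceptance.py`) use sizes
chosen to keep Monte-Carlo error well inside the tested bands while
running on a single CPU in well under a minute each: null calibration at
J = 50 with 1,000 replicates (type-I error band 0.035–0.065; mean Q
within 5% of 49); recovery at β = −0.25, J = 100, 500 replicates (mean
within 0.02, CI coverage 0.92–0.97); Egger-intercept recovery with 200
replicates of fully pleiotropic, F-filtered instruments; weighted-median
contamination with 300 replicates; MR-PRESSO detection/null behavior
with 200 replicates at 1,000 simulations each.  Per-replicate seeds are
spawned from one master seed via `numpy` `SeedSequence`, so every study
is exactly reproducible.  The weighted-median robustness study runs in a
deliberately strong-instrument, well-powered regime (γ spread 0.15,
continuous outcome of n = 115,006 — the reverse-direction setting):
the weighted median is consistent as per-ratio SEs shrink, and the study
targets that consistency property; at the rare-disease outcome's
effective sample size the per-ratio noise itself dominates any
contamination bias.

## Known limitations

* No Steiger directionality filtering, proxy-SNV lookup, multivariable
  MR, robust/penalized IVW, or radial diagnostics.
* Confounder-based instrument screening against external databases is
  out of scope; the pipeline instead accepts a user-supplied rsid
  exclusion list.
* The reverse direction of a rare-disease outcome typically yields no
  genome-wide-significant instruments; the pipeline reports this as an
  explicit "insufficient instruments" entry, and the reverse threshold
  is separately configurable for better-powered outcomes.
* Egger regression inherits its low power and InSIDE sensitivity; the
  mode estimators' bandwidth choice (φ) materially affects small-J
  results and is exposed as a parameter rather than tuned automatically.
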