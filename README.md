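# ivmr — bidirectional two-sample Mendelian randomization

`ivmr` estimates the causal effect of an exposure on an outcome from GWAS
summary statistics alone, using genetic variants as instrumental
variables.  It was built around a concrete epidemiological question — do
circulating polyunsaturated fatty acid (PUFA) levels, measured in a
115,006-sample biobank GWAS, causally modulate the risk of a rare cancer
(1,196 cases / 475,049 controls)? — but every component is generic
two-sample MR and works for any pair of summary-statistic files.

The package covers the full workflow:

* **Instrument selection** — genome-wide significance (p < 5×10⁻⁸), greedy
  LD clumping (r² < 0.001 within 10,000 kb) against an explicit pairwise
  LD table, and weak-instrument exclusion via the per-SNV statistics
  R² = 2·EAF·(1−EAF)·β² and F = R²(n−2)/(1−R²), dropping F < 10.
* **Harmonization** — aligning the outcome association to the exposure's
  effect allele, resolving strand flips through the base complement and
  excluding palindromic (A/T, C/G) variants with ambiguous intermediate
  allele frequency.
* **Five causal estimators** — for harmonized per-variant effects
  (γⱼ, σₓⱼ) on the exposure and (Γⱼ, σ_yⱼ) on the outcome: random-effects
  inverse-variance weighted (IVW) meta-analysis of the Wald ratios
  Γⱼ/γⱼ, MR-Egger regression (slope + pleiotropy intercept), the
  weighted median, and the simple and weighted mode, all reported as odds
  ratios with 95% CIs.
* **Sensitivity battery** — Cochran's Q heterogeneity test, the Egger
  intercept test, an MR-PRESSO-style global/outlier/distortion procedure,
  leave-one-out influence analysis, and funnel-plot data export.
* **Synthetic data** — a summary-level GWAS generator with known ground
  truth (causal effect, instrument strengths, pleiotropy regime, LD
  blocks, allele-coding quirks), so the whole pipeline is testable and
  benchmarkable without any data download.

## The model in brief

Each valid instrument j gives a Wald ratio β̂ⱼ = Γⱼ/γⱼ of the causal
effect.  IVW combines them with weights wⱼ = γⱼ²/σ_yⱼ²:

    β̂ = Σ wⱼ β̂ⱼ / Σ wⱼ ,   se²(β̂) = 1/Σ wⱼ ,

inflating the SE by max(1, √(Q/(J−1))) under the multiplicative
random-effects model, where Q = Σ wⱼ(β̂ⱼ − β̂)² is Cochran's statistic.
MR-Egger regresses Γⱼ on γⱼ with an intercept (weights 1/σ_yⱼ²) after
orienting γⱼ ≥ 0; a nonzero intercept estimates directional horizontal
pleiotropy.  The weighted median is consistent when valid instruments
carry ≥ 50% of the weight, and the mode estimators when the largest
homogeneous cluster of instruments is valid.  See `docs/methods.md` for
assumptions, defaults and numerical details.

## Worked example

Simulate a protective exposure (true causal effect −0.25 log-odds per SD,
OR ≈ 0.78) and run the full bidirectional analysis:

```bash
mr simulate --n-snps 80 --causal-beta -0.25 --seed 11 --out sim
mr run --exposure sim/exposure.tsv:omega3 \
       --outcome sim/outcome.tsv:pancreatic_cancer \
       --seed 11 --out run_out
```

which prints

```
wrote 10 file(s) to run_out
  forward omega3 -> pancreatic_cancer: IVW OR=0.771 [0.703, 0.845] p=3.13e-08 (nsnp=53)
  reverse pancreatic_cancer -> omega3: insufficient instruments (no instruments shared with the outcome)
```

Reading this: of the 80 simulated SNVs, 53 survive significance,
clumping, weak-instrument filtering and harmonization; the IVW odds
ratio 0.771 (95% CI 0.703–0.845) recovers the planted protective effect
(true OR = e⁻⁰·²⁵ ≈ 0.78), and the rare-disease outcome yields no
genome-wide-significant instruments of its own, so the reverse direction
is reported as insufficient rather than silently skipped.
`run_out/estimates.tsv` holds the same analysis for all five methods:

```
exposure	outcome	method	nsnp	pval	or	or_lci95	or_uci95
omega3	pancreatic_cancer	MR Egger	53	0.0272508	0.785555	0.637968	0.967283
omega3	pancreatic_cancer	Weighted median	53	0.000296707	0.77944	0.68102	0.892083
...
```

alongside the sensitivity report (`sensitivity_*.json`: Cochran's Q,
Egger intercept, MR-PRESSO, leave-one-out) and plot-ready scatter,
forest, funnel and leave-one-out tables.  The same analysis can be driven
from a flat YAML config (`mr run --config config.yaml`), and everything is
available as a library (`ivmr.run_bidirectional`, `ivmr.ivw`, ...).

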