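"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator works directly at the summary level (no individual-level
genotypes): for each SNV j it draws a minor-allele frequency, a true
instrument effect ``gamma_j ~ N(0, gamma_sd)``, and per-study standard
errors from the usual GWAS approximation

    se = (2 * maf * (1 - maf) * n) ** -0.5,

then observes noisy effects ``gamma_hat ~ N(gamma, se_x)`` and
``Gamma_hat ~ N(causal_beta * gamma + alpha, se_y)`` where ``alpha`` is the
horizontal-pleiotropy contribution of the chosen regime.  A binary outcome
GWAS is emulated through its effective sample size
``4 / (1/cases + 1/controls)``.

Allele-coding quirks of real summary files are reproduced on the outcome
side: a configurable fraction of SNVs is emitted with the opposite effect
allele (beta negated, EAF reflected), and a fraction carries palindromic
(A/T or C/G) allele pairs.  The truth record retains every latent value so
tests never need to re-derive them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError
from .instruments import LdInfo
from .summary import GwasDataset, SnpAssociation

#: exposure GWAS size of the fatty-acid panels used as the reference scale
DEFAULT_N_EXPOSURE = 115_006
#: pancreatic-cancer outcome GWAS: 1,196 cases / 475,049 controls
DEFAULT_CASES = 1_196
DEFAULT_CONTROLS = 475_049

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]

_POS_START = 1_000_000
_POS_STEP = 100_000


def effective_sample_size(cases: int, controls: int) -> float:
    """Effective size of a case-control GWAS: 4 / (1/cases + 1/controls)."""
    return 4.0 / (1.0 / cases + 1.0 / controls)


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth generative parameters for one exposure/outcome pair.

    Defaults mirror the study conditions this package targets: a
    continuous exposure GWAS of 115,006 samples, a rare binary outcome
    collapsed to its effective sample size (~4,772), instrument effects
    with spread 0.06 SD per allele (so single-SNV F-statistics land in the
    tens-to-hundreds range), and a protective causal effect of -0.25
    log-odds per SD of exposure (OR ~ 0.78).
    """

    n_snps: int = 100
    n_exposure: float = DEFAULT_N_EXPOSURE
    n_outcome: float = field(
        default_factory=lambda: effective_sample_size(DEFAULT_CASES, DEFAULT_CONTROLS)
    )
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.06
    #: draw instrument effects half-normal (all positive), i.e. code every
    #: effect allele as the exposure-increasing one; needed for planted
    #: directional pleiotropy to survive Egger's gamma >= 0 orientation
    gamma_positive: bool = False
    causal_beta: float = -0.25
    pleiotropy: str = "none"  # none | balanced | directional | outliers
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    invalid_fraction: float = 0.0
    outlier_scale: float = 10.0  # |alpha| in sigma_y units under "outliers"
    flip_fraction: float = 0.3
    palindromic_fraction: float = 0.1
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        for name in ("invalid_fraction", "flip_fraction", "palindromic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.pleiotropy not in ("none", "balanced", "directional", "outliers"):
            raise ConfigurationError(f"unknown pleiotropy regime {self.pleiotropy!r}")


@dataclass
class SimTruth:
    """Latent values behind one simulated pair of datasets."""

    causal_beta: float
    seed: int
    rsids: list[str]
    maf: np.ndarray
    gamma_true: np.ndarray
    gamma_hat: np.ndarray
    sigma_x: np.ndarray
    alpha: np.ndarray
    Gamma_true: np.ndarray
    Gamma_hat: np.ndarray
    sigma_y: np.ndarray
    invalid: np.ndarray  # boolean: received pleiotropy
    flipped_coding: np.ndarray  # boolean: outcome emitted on opposite allele
    palindromic: np.ndarray  # boolean: A/T or C/G allele pair

    def to_json(self, path: str | Path) -> None:
        payload = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(self).items()
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    # the container requires p in (0, 1]; clip astronomically small values
    return np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_pair(config: SimConfig) -> tuple[GwasDataset, GwasDataset, SimTruth]:
    """Draw one exposure/outcome dataset pair plus its ground truth.

    Deterministic given ``config.seed``: repeated calls return identical
    datasets.  All stochastic latent values are drawn before the
    allele-coding perturbations, so the truth record always stores the
    unperturbed (exposure-frame) effects.
    """
    rng = np.random.default_rng(config.seed)
    J = config.n_snps

    maf = rng.uniform(*config.maf_range, size=J)
    gamma_true = rng.normal(0.0, config.gamma_sd, size=J)
    if config.gamma_positive:
        gamma_true = np.abs(gamma_true)
    sigma_x = (2.0 * maf * (1.0 - maf) * config.n_exposure) ** -0.5
    gamma_hat = rng.normal(gamma_true, sigma_x)
    sigma_y = (2.0 * maf * (1.0 - maf) * config.n_outcome) ** -0.5

    n_invalid = int(round(config.invalid_fraction * J))
    if config.pleiotropy == "outliers":
        n_invalid = max(1, n_invalid)
    invalid = np.zeros(J, dtype=bool)
    if config.pleiotropy != "none" and n_invalid > 0:
        invalid[rng.choice(J, size=n_invalid, replace=False)] = True

    alpha = np.zeros(J)
    if config.pleiotropy == "balanced":
        alpha[invalid] = rng.normal(0.0, config.alpha_sd, size=n_invalid)
    elif config.pleiotropy == "directional":
        alpha[invalid] = rng.normal(config.alpha_mean, config.alpha_sd, size=n_invalid)
    elif config.pleiotropy == "outliers":
        signs = rng.choice([-1.0, 1.0], size=n_invalid)
        alpha[invalid] = signs * config.outlier_scale * sigma_y[invalid]

    Gamma_true = config.causal_beta * gamma_true + alpha
    Gamma_hat = rng.normal(Gamma_true, sigma_y)

    # allele coding, drawn after all effect-size randomness
    pal = rng.random(J) < config.palindromic_fraction
    pair_pick = rng.integers(0, 4, size=J)
    flip = rng.random(J) < config.flip_fraction

    rsids = [f"rs{j + 1:06d}" for j in range(J)]
    positions = [_POS_START + j * _POS_STEP for j in range(J)]

    exp_records, out_records = [], []
    for j in range(J):
        if pal[j]:
            ea, oa = _PALINDROMIC_PAIRS[pair_pick[j] % 2]
        else:
            ea, oa = _NONPALINDROMIC_PAIRS[pair_pick[j]]
        exp_records.append(
            SnpAssociation(
                rsid=rsids[j], chrom="1", pos=positions[j],
                effect_allele=ea, other_allele=oa,
                eaf=float(maf[j]), beta=float(gamma_hat[j]), se=float(sigma_x[j]),
                pval=float(_pvalues(gamma_hat[j : j + 1], sigma_x[j : j + 1])[0]),
                n=config.n_exposure,
            )
        )
        if flip[j]:
            o_ea, o_oa = oa, ea
            o_beta, o_eaf = -float(Gamma_hat[j]), 1.0 - float(maf[j])
        else:
            o_ea, o_oa = ea, oa
            o_beta, o_eaf = float(Gamma_hat[j]), float(maf[j])
        out_records.append(
            SnpAssociation(
                rsid=rsids[j], chrom="1", pos=positions[j],
                effect_allele=o_ea, other_allele=o_oa,
                eaf=o_eaf, beta=o_beta, se=float(sigma_y[j]),
                pval=float(_pvalues(Gamma_hat[j : j + 1], sigma_y[j : j + 1])[0]),
                n=config.n_outcome,
            )
        )

    exposure = GwasDataset(config.exposure_label, "exposure", exp_records)
    outcome = GwasDataset(config.outcome_label, "outcome", out_records)
    truth = SimTruth(
        causal_beta=config.causal_beta,
        seed=config.seed,
        rsids=rsids,
        maf=maf,
        gamma_true=gamma_true,
        gamma_hat=gamma_hat,
        sigma_x=sigma_x,
        alpha=alpha,
        Gamma_true=Gamma_true,
        Gamma_hat=Gamma_hat,
        sigma_y=sigma_y,
        invalid=invalid,
        flipped_coding=flip,
        palindromic=pal,
    )
    return exposure, outcome, truth


def simulate_ld(config: SimConfig, block_size: int, within_r2: float) -> LdInfo:
    """Block-diagonal LD: consecutive SNVs share ``within_r2``, blocks are free.

    SNV positions from :func:`simulate_pair` are spaced 100 kb apart, so a
    whole block of any reasonable size sits inside one 10,000 kb clump
    window; between-block r-squared is 0 (omitted from the table).
    """
    if block_size < 1:
        raise ConfigurationError("block_size must be >= 1")
    if not 0.0 <= within_r2 <= 1.0:
        raise ConfigurationError("within_r2 must be in [0, 1]")
    rsids = [f"rs{j + 1:06d}" for j in range(config.n_snps)]
    ld = LdInfo()
    for start in range(0, config.n_snps, block_size):
        block = rsids[start : start + block_size]
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                ld.add(block[i], block[j], within_r2)
    return ld


def harmonized_truth(config: SimConfig):
    """Convenience: simulate a pair and harmonize it (window defaults).

    Returns ``(harmonized_set, truth)``.  Intended for simulation studies
    that do not exercise instrument selection.
    """
    from .summary import harmonize

    exposure, outcome, truth = simulate_pair(config)
    return harmonize(exposure, outcome), truth
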