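"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume a :class:`~ivmr.summary.HarmonizedSet` holding, for
each instrument j, the SNV-exposure effect ``gamma_j`` (SE ``sigma_xj``)
and the SNV-outcome effect ``Gamma_j`` (SE ``sigma_yj``).  The per-variant
Wald ratio is ``beta_j = Gamma_j / gamma_j`` with first-order (delta) SE
``sigma_yj / |gamma_j|``.

Implemented methods
-------------------
* **IVW** — inverse-variance weighted meta-analysis of the Wald ratios,
  equivalently weighted regression of Gamma on gamma through the origin
  with weights ``1/sigma_y**2``.  Random-effects inference inflates the
  fixed-effect SE by ``max(1, sqrt(Q/(J-1)))`` (multiplicative model).
* **MR-Egger** — the same weighted regression with an intercept; a nonzero
  intercept indicates directional horizontal pleiotropy.  Inference uses
  the t distribution with J-2 degrees of freedom.
* **Weighted median** — the 50% point of the weight-ordered Wald ratios;
  consistent when instruments carrying at least half the weight are valid.
* **Simple / weighted mode** — the argmax of a kernel-smoothed density of
  the Wald ratios; consistent when the largest homogeneous cluster of
  instruments is valid.

Weighted-median and mode standard errors come from a parametric bootstrap
(normal resampling of the summary effects), seeded through
:class:`EstimatorConfig` for determinism.  Binary-outcome effects are
reported as odds ratios with normal-theory 95% confidence intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    ConfigurationError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .summary import HarmonizedPair, HarmonizedSet

logger = logging.getLogger(__name__)

_MODE_GRID_POINTS = 512


@dataclass(frozen=True)
class EstimatorConfig:
    """Settings shared by the estimators.

    ``bootstrap_reps`` controls the parametric bootstrap behind the
    weighted-median and mode SEs; ``mode_phi`` scales the mode bandwidth.
    """

    random_effects: bool = True
    bootstrap_reps: int = 1000
    mode_phi: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bootstrap_reps < 100:
            raise ConfigurationError("bootstrap_reps must be at least 100")
        if not self.mode_phi > 0:
            raise ConfigurationError("mode_phi must be positive")


@dataclass(frozen=True)
class MrEstimate:
    """One method's causal estimate on the log-odds scale, with OR and CI."""

    method: str
    n_snps: int
    beta: float
    se: float
    pval: float
    or_: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_beta_se(
        cls,
        method: str,
        n_snps: int,
        beta: float,
        se: float,
        *,
        df: int | None = None,
    ) -> "MrEstimate":
        """Build an estimate with normal (default) or t(df) two-sided p."""
        if se > 0:
            z = beta / se
            pval = 2.0 * (stats.t.sf(abs(z), df) if df else stats.norm.sf(abs(z)))
        else:
            pval = 0.0 if beta != 0 else 1.0
        return cls(
            method=method,
            n_snps=n_snps,
            beta=beta,
            se=se,
            pval=float(pval),
            or_=math.exp(beta),
            ci_low=math.exp(beta - 1.96 * se),
            ci_high=math.exp(beta + 1.96 * se),
        )


def wald_ratio(pair: "HarmonizedPair") -> MrEstimate:
    """Single-instrument causal estimate Gamma/gamma with delta-method SE."""
    if pair.gamma == 0:
        raise DegenerateInstrumentError(f"{pair.rsid}: zero exposure effect")
    beta = pair.Gamma / pair.gamma
    se = pair.sigma_y / abs(pair.gamma)
    return MrEstimate.from_beta_se("wald_ratio", 1, beta, se)


def _ratios_weights(hset: "HarmonizedSet") -> tuple[np.ndarray, np.ndarray]:
    """Wald ratios and IVW weights gamma^2 / sigma_y^2."""
    g, _, G, sy = hset.arrays()
    if np.any(g == 0):
        raise DegenerateInstrumentError("zero exposure effect among instruments")
    return G / g, g * g / (sy * sy)


def ivw(hset: "HarmonizedSet", config: EstimatorConfig | None = None) -> MrEstimate:
    """Inverse-variance weighted estimate (random-effects by default).

    beta = sum(gamma*Gamma/sigma_y^2) / sum(gamma^2/sigma_y^2); the
    fixed-effect SE is the inverse square root of the denominator, inflated
    by ``max(1, sqrt(Q/(J-1)))`` under the multiplicative random-effects
    model.  A single pair degrades to the Wald ratio with a warning.
    """
    config = config or EstimatorConfig()
    J = len(hset)
    if J == 0:
        raise InsufficientInstrumentsError("IVW requires at least one pair")
    if J == 1:
        logger.warning("IVW on a single instrument degrades to the Wald ratio")
        est = wald_ratio(hset.pairs[0])
        return MrEstimate.from_beta_se("ivw", 1, est.beta, est.se)
    b, w = _ratios_weights(hset)
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    if config.random_effects:
        q = float(np.sum(w * (b - beta) ** 2))
        se *= max(1.0, math.sqrt(q / (J - 1)))
    return MrEstimate.from_beta_se("ivw", J, beta, se)


def egger(
    hset: "HarmonizedSet", config: EstimatorConfig | None = None
) -> tuple[MrEstimate, MrEstimate]:
    """MR-Egger slope and intercept (directional-pleiotropy test).

    Each pair is oriented so that gamma >= 0, then Gamma is regressed on
    gamma with an intercept by weighted least squares (weights
    ``1/sigma_y^2``).  SEs carry a multiplicative inflation
    ``max(1, sqrt(RSS_w/(J-2)))`` and p-values use t(J-2).
    """
    del config  # inference settings are fixed by convention
    J = len(hset)
    if J < 3:
        raise InsufficientInstrumentsError(f"MR-Egger requires >= 3 pairs, got {J}")
    g, _, G, sy = hset.arrays()
    sign = np.where(g < 0, -1.0, 1.0)
    x, y = g * sign, G * sign
    fit = sm.WLS(y, sm.add_constant(x), weights=1.0 / sy**2).fit()
    scale = float(fit.scale)  # RSS_w / (J - 2)
    infl = 1.0 if scale >= 1.0 else 1.0 / math.sqrt(scale)
    se = fit.bse * infl  # bse already includes sqrt(scale)
    intercept = MrEstimate.from_beta_se(
        "egger_intercept", J, float(fit.params[0]), float(se[0]), df=J - 2
    )
    slope = MrEstimate.from_beta_se(
        "egger_slope", J, float(fit.params[1]), float(se[1]), df=J - 2
    )
    return slope, intercept


def _weighted_median(b: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median of ratios ``b`` with weights ``w``."""
    order = np.argsort(b, kind="stable")
    bs, ws = b[order], w[order] / np.sum(w)
    p = np.cumsum(ws) - ws / 2.0
    if 0.5 <= p[0]:
        return float(bs[0])
    if 0.5 >= p[-1]:
        return float(bs[-1])
    return float(np.interp(0.5, p, bs))


def _bootstrap_samples(
    hset: "HarmonizedSet", config: EstimatorConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parametric bootstrap draws (B, J) of gamma* and Gamma*, plus sigma_y."""
    g, sx, G, sy = hset.arrays()
    rng = np.random.default_rng(config.seed)
    B = config.bootstrap_reps
    g_star = rng.normal(g, sx, size=(B, g.size))
    G_star = rng.normal(G, sy, size=(B, g.size))
    return g_star, G_star, sy


def weighted_median(hset: "HarmonizedSet", config: EstimatorConfig | None = None) -> MrEstimate:
    """Weighted-median estimate with parametric-bootstrap SE."""
    config = config or EstimatorConfig()
    J = len(hset)
    if J < 3:
        raise InsufficientInstrumentsError(f"weighted median requires >= 3 pairs, got {J}")
    b, w = _ratios_weights(hset)
    beta = _weighted_median(b, w)
    g_star, G_star, sy = _bootstrap_samples(hset, config)
    boots = np.empty(config.bootstrap_reps)
    for i in range(config.bootstrap_reps):
        gs = g_star[i]
        gs = np.where(gs == 0, np.finfo(float).tiny, gs)
        boots[i] = _weighted_median(G_star[i] / gs, gs * gs / (sy * sy))
    se = float(np.std(boots, ddof=1))
    return MrEstimate.from_beta_se("weighted_median", J, beta, se)


def _mode_bandwidth(b: np.ndarray, phi: float) -> float:
    """Modified Silverman bandwidth: phi * 0.9 * min(sd, 1.4826*mad) * J^(-1/5)."""
    sd = float(np.std(b, ddof=1)) if b.size > 1 else 0.0
    mad = 1.4826 * float(np.median(np.abs(b - np.median(b))))
    candidates = [s for s in (sd, mad) if s > 0]
    if not candidates:
        return 0.0
    return phi * 0.9 * min(candidates) * b.size ** (-1.0 / 5.0)


def _mode_point(b: np.ndarray, w: np.ndarray, phi: float) -> float:
    """Argmax of the normal-kernel smoothed weighted density of the ratios."""
    h = _mode_bandwidth(b, phi)
    if h == 0.0:
        return float(b[0])
    grid = np.linspace(b.min() - 3 * h, b.max() + 3 * h, _MODE_GRID_POINTS)
    wn = w / np.sum(w)
    dens = np.exp(-0.5 * ((grid[:, None] - b[None, :]) / h) ** 2) @ wn
    return float(grid[np.argmax(dens)])


def mode_estimate(
    hset: "HarmonizedSet",
    config: EstimatorConfig | None = None,
    *,
    weighted: bool = False,
) -> MrEstimate:
    """Mode-based estimate: simple (uniform weights) or weighted.

    The estimate is the argmax over a fixed 512-point grid of the
    kernel-smoothed Wald-ratio density; the SE comes from the same
    parametric bootstrap as the weighted median.
    """
    config = config or EstimatorConfig()
    J = len(hset)
    if J < 3:
        raise InsufficientInstrumentsError(f"mode estimators require >= 3 pairs, got {J}")
    b, w_ivw = _ratios_weights(hset)
    w = w_ivw if weighted else np.ones(J)
    beta = _mode_point(b, w, config.mode_phi)
    g_star, G_star, sy = _bootstrap_samples(hset, config)
    boots = np.empty(config.bootstrap_reps)
    for i in range(config.bootstrap_reps):
        gs = g_star[i]
        gs = np.where(gs == 0, np.finfo(float).tiny, gs)
        bs = G_star[i] / gs
        ws = gs * gs / (sy * sy) if weighted else w
        boots[i] = _mode_point(bs, ws, config.mode_phi)
    se = float(np.std(boots, ddof=1))
    method = "weighted_mode" if weighted else "simple_mode"
    return MrEstimate.from_beta_se(method, J, beta, se)


def all_estimates(
    hset: "HarmonizedSet", config: EstimatorConfig | None = None
) -> dict[str, MrEstimate]:
    """The five causal estimators plus the Egger intercept, keyed by method."""
    config = config or EstimatorConfig()
    slope, intercept = egger(hset, config)
    return {
        "ivw": ivw(hset, config),
        "egger_slope": slope,
        "egger_intercept": intercept,
        "weighted_median": weighted_median(hset, config),
        "simple_mode": mode_estimate(hset, config, weighted=False),
        "weighted_mode": mode_estimate(hset, config, weighted=True),
    }
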