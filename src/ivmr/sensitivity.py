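"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

Covers Cochran's Q heterogeneity test, the MR-Egger intercept test (via
:func:`ivmr.estimators.egger`), an MR-PRESSO-style residual outlier
procedure (global, outlier and distortion tests), leave-one-out influence
analysis, and funnel-plot data export.

MR-PRESSO notes
---------------
The observed statistic is the weighted residual sum of squares about the
leave-one-out IVW slope: for each instrument j the slope is re-estimated
without j, the residual is ``r_j = Gamma_j - gamma_j * beta_{-j}``, and

    RSS_obs = sum_j r_j^2 / sigma_yj^2.

The null distribution is simulated by drawing ``Gamma_j* ~ N(gamma_j *
beta_{-j}, sigma_yj)`` and ``gamma_j* ~ N(gamma_j, sigma_xj)`` and
recomputing RSS identically.  The global p-value uses the add-one
empirical correction (so it can never be exactly 0); per-SNV outlier
p-values are plain empirical proportions tested against a Bonferroni
threshold ``alpha / J``.  The distortion test compares the observed
displacement of the IVW estimate after outlier removal with the
displacement produced by removing an equally sized random subset in each
null simulation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import EstimatorConfig, MrEstimate, _ratios_weights, egger, ivw
from .exceptions import ConfigurationError, InsufficientInstrumentsError

if TYPE_CHECKING:  # pragma: no cover
    from .summary import HarmonizedSet

logger = logging.getLogger(__name__)


def cochran_q(hset: "HarmonizedSet") -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic across the Wald ratios.

    Q = sum_j w_j (beta_j - beta_IVW)^2 with w_j = gamma_j^2 / sigma_yj^2;
    under instrument homogeneity Q ~ chi-square with J-1 df.
    """
    J = len(hset)
    if J < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires >= 2 pairs")
    b, w = _ratios_weights(hset)
    beta = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - beta) ** 2))
    df = J - 1
    return q, df, float(stats.chi2.sf(q, df))


def leave_one_out(
    hset: "HarmonizedSet", config: EstimatorConfig | None = None
) -> list[tuple[str, MrEstimate]]:
    """IVW estimate with each instrument excluded in turn."""
    if len(hset) < 3:
        raise InsufficientInstrumentsError("leave-one-out requires >= 3 pairs")
    config = config or EstimatorConfig()
    return [(rsid, ivw(hset.drop(rsid), config)) for rsid in hset.rsids]


@dataclass
class PressoResult:
    """Outcome of the MR-PRESSO-style global/outlier/distortion procedure."""

    rss_obs: float
    global_pval: float
    outliers: list[str]
    distortion_pval: float | None
    corrected_estimate: MrEstimate | None
    n_sim: int
    seed: int
    all_outliers: bool = False
    outlier_pvals: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rss_obs": self.rss_obs,
            "global_pval": self.global_pval,
            "outliers": list(self.outliers),
            "distortion_pval": self.distortion_pval,
            "corrected_estimate": (
                None if self.corrected_estimate is None else vars(self.corrected_estimate)
            ),
            "n_sim": self.n_sim,
            "seed": self.seed,
            "all_outliers": self.all_outliers,
            "outlier_pvals": dict(self.outlier_pvals),
        }


def _loo_slopes(g: np.ndarray, G: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorized over the left-out index."""
    wy = 1.0 / (sy * sy)
    num = np.sum(g * G * wy) - g * G * wy
    den = np.sum(g * g * wy) - g * g * wy
    return num / den


def _rss_terms(g: np.ndarray, G: np.ndarray, sy: np.ndarray) -> np.ndarray:
    r = G - g * _loo_slopes(g, G, sy)
    return r * r / (sy * sy)


def mr_presso(
    hset: "HarmonizedSet",
    config: EstimatorConfig | None = None,
    *,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Residual-based pleiotropy test with outlier removal.

    Returns the observed weighted RSS, its empirical global p-value, the
    Bonferroni-flagged outlier rsids, the distortion p-value for the
    estimate shift after outlier removal (None when nothing is flagged),
    and the IVW estimate on the outlier-free set.
    """
    config = config or EstimatorConfig()
    J = len(hset)
    if J < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO requires >= 4 pairs, got {J}")
    if n_sim < 1000:
        raise ConfigurationError("n_sim must be at least 1000")

    g, sx, G, sy = hset.arrays()
    slopes = _loo_slopes(g, G, sy)
    t_obs = _rss_terms(g, G, sy)
    rss_obs = float(np.sum(t_obs))

    rng = np.random.default_rng(config.seed)
    g_star = rng.normal(g, sx, size=(n_sim, J))
    G_star = rng.normal(g * slopes, sy, size=(n_sim, J))

    wy = 1.0 / (sy * sy)
    num = np.sum(g_star * G_star * wy, axis=1, keepdims=True) - g_star * G_star * wy
    den = np.sum(g_star * g_star * wy, axis=1, keepdims=True) - g_star * g_star * wy
    r_star = G_star - g_star * (num / den)
    t_star = r_star * r_star * wy  # (n_sim, J) per-SNV statistics
    rss_star = t_star.sum(axis=1)

    global_pval = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    outlier_p = np.mean(t_star >= t_obs[None, :], axis=0)
    flagged = outlier_p < outlier_alpha / J
    rsids = hset.rsids
    outliers = [rsids[j] for j in np.flatnonzero(flagged)]
    outlier_pvals = {rsids[j]: float(outlier_p[j]) for j in range(J)}

    if len(outliers) == J:
        logger.warning("MR-PRESSO flagged every instrument as an outlier")
        return PressoResult(
            rss_obs, global_pval, outliers, None, None, n_sim, config.seed,
            all_outliers=True, outlier_pvals=outlier_pvals,
        )
    if not outliers:
        return PressoResult(
            rss_obs, global_pval, [], None, None, n_sim, config.seed,
            outlier_pvals=outlier_pvals,
        )

    keep_idx = [j for j in range(J) if rsids[j] not in outliers]
    full = ivw(hset, config)
    corrected = ivw(hset.take(keep_idx), config)
    d_obs = corrected.beta - full.beta

    # null displacement: drop an equally sized random subset in each simulation
    k = len(outliers)
    drop_order = np.argsort(rng.random(size=(n_sim, J)), axis=1)
    keep_mask = np.ones((n_sim, J), dtype=bool)
    np.put_along_axis(keep_mask, drop_order[:, :k], False, axis=1)
    slope_full = np.sum(g_star * G_star * wy, axis=1) / np.sum(g_star * g_star * wy, axis=1)
    slope_sub = (
        np.sum(g_star * G_star * wy * keep_mask, axis=1)
        / np.sum(g_star * g_star * wy * keep_mask, axis=1)
    )
    d_star = slope_sub - slope_full
    distortion_pval = float((1 + np.sum(np.abs(d_star) >= abs(d_obs))) / (n_sim + 1))

    return PressoResult(
        rss_obs, global_pval, outliers, distortion_pval, corrected, n_sim,
        config.seed, outlier_pvals=outlier_pvals,
    )


@dataclass
class FunnelData:
    """Per-SNV Wald estimates and precisions, with overall verticals."""

    table: pd.DataFrame  # columns: rsid, beta, precision
    ivw_beta: float
    egger_beta: float

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def funnel_data(hset: "HarmonizedSet", config: EstimatorConfig | None = None) -> FunnelData:
    """Funnel-plot data: Wald ratio vs precision |gamma|/sigma_y per SNV.

    Visual symmetry of the funnel about the overall estimate indicates the
    absence of directional pleiotropy.
    """
    if len(hset) == 0:
        raise InsufficientInstrumentsError("funnel data requires a non-empty set")
    config = config or EstimatorConfig()
    g, _, G, sy = hset.arrays()
    table = pd.DataFrame(
        {"rsid": hset.rsids, "beta": G / g, "precision": np.abs(g) / sy}
    )
    ivw_beta = ivw(hset, config).beta if len(hset) >= 1 else float("nan")
    egger_beta = egger(hset, config)[0].beta if len(hset) >= 3 else float("nan")
    return FunnelData(table, ivw_beta, egger_beta)


@dataclass
class SensitivityReport:
    """The full diagnostic battery for one harmonized set."""

    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: MrEstimate
    presso: PressoResult | None
    loo: list[tuple[str, MrEstimate]]

    def to_dict(self) -> dict:
        return {
            "cochran_q": {"q": self.q_stat, "df": self.q_df, "pval": self.q_pval},
            "egger_intercept": vars(self.egger_intercept),
            "presso": None if self.presso is None else self.presso.to_dict(),
            "leave_one_out": [
                {"excluded_rsid": rsid, **vars(est)} for rsid, est in self.loo
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def loo_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"excluded_rsid": rsid, **vars(est)} for rsid, est in self.loo]
        )


def sensitivity_report(
    hset: "HarmonizedSet",
    config: EstimatorConfig | None = None,
    *,
    presso_nsim: int = 1000,
    outlier_alpha: float = 0.05,
) -> SensitivityReport:
    """Run the whole diagnostic battery on one harmonized set."""
    config = config or EstimatorConfig()
    q, df, q_pval = cochran_q(hset)
    _, intercept = egger(hset, config)
    presso = (
        mr_presso(hset, config, n_sim=presso_nsim, outlier_alpha=outlier_alpha)
        if len(hset) >= 4
        else None
    )
    loo = leave_one_out(hset, config)
    return SensitivityReport(q, df, q_pval, intercept, presso, loo)
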