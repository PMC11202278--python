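"""Bidirectional analysis orchestration and report writing.

``run_direction`` executes the canonical stage order for one
exposure→outcome direction:

    significance filter → LD clumping → weak-instrument filter →
    harmonization → {IVW, MR-Egger, weighted median, simple mode,
    weighted mode} → {Cochran's Q, Egger intercept, MR-PRESSO,
    leave-one-out, funnel data}

``run_bidirectional`` repeats it forward for every exposure and in reverse
(instrumenting the outcome, possibly at a laxer significance threshold,
since disease GWAS rarely yield many genome-wide-significant variants).
``write_report`` emits a publication-style estimates TSV (one row per
method and direction: nsnp, p, OR, 95% CI) plus sensitivity JSON,
per-stage logs and plot-ready data tables.  Everything is
deterministic given the configured seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .estimators import EstimatorConfig, MrEstimate, all_estimates
from .exceptions import ConfigurationError
from .instruments import (
    InstrumentReport,
    LdInfo,
    SelectionConfig,
    clump,
    filter_weak,
    select_significant,
)
from .sensitivity import SensitivityReport, funnel_data, sensitivity_report
from .summary import GwasDataset, HarmonizedSet, harmonize, read_gwas_table

logger = logging.getLogger(__name__)

#: presentation labels for the estimates table, in output order
METHOD_LABELS = {
    "egger_slope": "MR Egger",
    "weighted_median": "Weighted median",
    "ivw": "IVW",
    "simple_mode": "Simple mode",
    "weighted_mode": "Weighted mode",
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything needed to reproduce one bidirectional analysis."""

    exposure_files: tuple[str, ...]
    exposure_labels: tuple[str, ...]
    outcome_file: str
    outcome_label: str
    ld_file: str | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    eaf_window: tuple[float, float] = (0.42, 0.58)
    strict_palindromes: bool = False
    presso_nsim: int = 1000
    outlier_alpha: float = 0.05
    reverse: bool = True
    reverse_p_threshold: float = 5e-8
    exclude_rsids: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.exposure_files:
            raise ConfigurationError("at least one exposure file is required")
        if len(self.exposure_files) != len(self.exposure_labels):
            raise ConfigurationError("exposure_files and exposure_labels differ in length")
        if not self.reverse_p_threshold > 0:
            raise ConfigurationError("reverse_p_threshold must be positive")


@dataclass
class DirectionResult:
    """Everything computed for one exposure→outcome direction."""

    exposure: str
    outcome: str
    direction: str  # "forward" | "reverse"
    stage_counts: dict[str, int]
    instrument_report: InstrumentReport
    harmonized: HarmonizedSet | None
    estimates: dict[str, MrEstimate] | None
    sensitivity: SensitivityReport | None
    funnel: object | None
    insufficient: bool = False
    reason: str = ""

    def estimates_frame(self) -> pd.DataFrame:
        rows = []
        if self.estimates is not None:
            for key, label in METHOD_LABELS.items():
                est = self.estimates[key]
                rows.append(
                    {
                        "exposure": self.exposure,
                        "outcome": self.outcome,
                        "method": label,
                        "nsnp": est.n_snps,
                        "pval": est.pval,
                        "or": est.or_,
                        "or_lci95": est.ci_low,
                        "or_uci95": est.ci_high,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["exposure", "outcome", "method", "nsnp", "pval", "or", "or_lci95", "or_uci95"],
        )


@dataclass
class AnalysisReport:
    """Combined forward and reverse results plus run metadata."""

    entries: list[DirectionResult]
    config: AnalysisConfig

    def estimates_frame(self) -> pd.DataFrame:
        frames = [f for e in self.entries if len(f := e.estimates_frame())]
        if not frames:
            return self.entries[0].estimates_frame() if self.entries else pd.DataFrame()
        return pd.concat(frames, ignore_index=True)


def run_direction(
    exposure: GwasDataset,
    outcome: GwasDataset,
    config: AnalysisConfig,
    *,
    direction: str = "forward",
    p_threshold: float | None = None,
    ld: LdInfo | None = None,
) -> DirectionResult:
    """Run the full stage sequence for one direction."""
    sel = config.selection
    p_thr = sel.p_threshold if p_threshold is None else p_threshold
    ld = ld if ld is not None else LdInfo()

    counts = {"input": len(exposure)}
    if config.exclude_rsids:
        exposure = exposure.subset(
            [r for r in exposure.rsids if r not in set(config.exclude_rsids)]
        )
        counts["after_exclusion_list"] = len(exposure)
    significant = select_significant(exposure, p_thr)
    counts["significant"] = len(significant)
    clumped = clump(significant, ld, sel)
    counts["clumped"] = len(clumped)
    strong, inst_report = filter_weak(clumped, sel)
    counts["strong"] = len(strong)
    logger.info(
        "%s %s->%s: input=%d significant=%d clumped=%d strong=%d",
        direction, exposure.trait, outcome.trait,
        counts["input"], counts["significant"], counts["clumped"], counts["strong"],
    )

    base = dict(
        exposure=exposure.trait,
        outcome=outcome.trait,
        direction=direction,
        stage_counts=counts,
        instrument_report=inst_report,
    )
    if len(strong) == 0 or not any(r.rsid in outcome for r in strong):
        return DirectionResult(
            **base, harmonized=None, estimates=None, sensitivity=None, funnel=None,
            insufficient=True, reason="no instruments shared with the outcome",
        )

    hset = harmonize(
        strong, outcome, config.eaf_window, strict_palindromes=config.strict_palindromes
    )
    counts["harmonized"] = len(hset)
    if len(hset) < 3:
        return DirectionResult(
            **base, harmonized=hset, estimates=None, sensitivity=None, funnel=None,
            insufficient=True,
            reason=f"only {len(hset)} harmonized instrument(s); >= 3 required",
        )

    estimates = all_estimates(hset, config.estimator)
    sens = sensitivity_report(
        hset, config.estimator,
        presso_nsim=config.presso_nsim, outlier_alpha=config.outlier_alpha,
    )
    funnel = funnel_data(hset, config.estimator)
    return DirectionResult(
        **base, harmonized=hset, estimates=estimates, sensitivity=sens, funnel=funnel
    )


def run_bidirectional(config: AnalysisConfig) -> AnalysisReport:
    """Forward runs for every exposure, then reverse runs instrumenting the outcome."""
    exposures = [
        read_gwas_table(path, trait=label, role="exposure")
        for path, label in zip(config.exposure_files, config.exposure_labels)
    ]
    outcome = read_gwas_table(config.outcome_file, trait=config.outcome_label, role="outcome")
    ld = LdInfo.from_tsv(config.ld_file) if config.ld_file else LdInfo()

    entries: list[DirectionResult] = []
    for exp in exposures:
        entries.append(run_direction(exp, outcome, config, direction="forward", ld=ld))
    if config.reverse:
        outcome_as_exposure = GwasDataset(outcome.trait, "exposure", outcome.records)
        for exp in exposures:
            exp_as_outcome = GwasDataset(exp.trait, "outcome", exp.records)
            entries.append(
                run_direction(
                    outcome_as_exposure, exp_as_outcome, config,
                    direction="reverse", p_threshold=config.reverse_p_threshold, ld=ld,
                )
            )
    return AnalysisReport(entries, config)


def _slug(entry: DirectionResult) -> str:
    clean = lambda s: "".join(c if c.isalnum() else "_" for c in s)
    return f"{entry.direction}__{clean(entry.exposure)}__{clean(entry.outcome)}"


def write_report(report: AnalysisReport, outdir: str | Path) -> list[Path]:
    """Serialize a report: estimates TSV, sensitivity JSON, plot-data TSVs.

    Output is byte-reproducible for a fixed config and seed (no timestamps;
    fixed float formatting).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit_frame(frame: pd.DataFrame, name: str) -> None:
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)

    emit_frame(report.estimates_frame(), "estimates.tsv")

    for entry in report.entries:
        slug = _slug(entry)
        entry.instrument_report.to_tsv(outdir / f"instruments_{slug}.tsv")
        written.append(outdir / f"instruments_{slug}.tsv")
        if entry.harmonized is not None:
            emit_frame(entry.harmonized.to_frame(), f"scatter_{slug}.tsv")
            pd.DataFrame(
                entry.harmonized.exclusions, columns=["rsid", "reason"]
            ).to_csv(outdir / f"exclusions_{slug}.tsv", sep="\t", index=False)
            written.append(outdir / f"exclusions_{slug}.tsv")
        if entry.sensitivity is not None:
            path = outdir / f"sensitivity_{slug}.json"
            entry.sensitivity.to_json(path)
            written.append(path)
            emit_frame(entry.sensitivity.loo_frame(), f"leaveoneout_{slug}.tsv")
        if entry.funnel is not None:
            emit_frame(entry.funnel.table, f"funnel_{slug}.tsv")
        if entry.estimates is not None:
            forest = pd.DataFrame(
                [
                    {"label": METHOD_LABELS[k], "beta": e.beta, "se": e.se,
                     "or": e.or_, "or_lci95": e.ci_low, "or_uci95": e.ci_high}
                    for k, e in entry.estimates.items()
                    if k in METHOD_LABELS
                ]
            )
            emit_frame(forest, f"forest_{slug}.tsv")

    metadata = {
        "package_version": __version__,
        "seed": report.config.seed,
        "estimator_seed": report.config.estimator.seed,
        "p_threshold": report.config.selection.p_threshold,
        "reverse_p_threshold": report.config.reverse_p_threshold,
        "clump_r2": report.config.selection.clump_r2,
        "clump_window_kb": report.config.selection.clump_window_kb,
        "f_min": report.config.selection.f_min,
        "eaf_window": list(report.config.eaf_window),
        "strict_palindromes": report.config.strict_palindromes,
        "presso_nsim": report.config.presso_nsim,
        "outlier_alpha": report.config.outlier_alpha,
        "bootstrap_reps": report.config.estimator.bootstrap_reps,
        "mode_phi": report.config.estimator.mode_phi,
        "random_effects": report.config.estimator.random_effects,
        "reverse": report.config.reverse,
        "exposures": list(report.config.exposure_labels),
        "outcome": report.config.outcome_label,
        "directions": [
            {
                "direction": e.direction,
                "exposure": e.exposure,
                "outcome": e.outcome,
                "stage_counts": e.stage_counts,
                "insufficient": e.insufficient,
                "reason": e.reason,
            }
            for e in report.entries
        ],
    }
    meta_path = outdir / "run_metadata.json"
    meta_path.write_text(json.dumps(metadata, indent=2, sort_keys=True))
    written.append(meta_path)
    return written
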