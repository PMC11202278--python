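"""Instrument selection: significance filtering, LD clumping, strength metrics.

A valid instrumental variable must be robustly associated with the exposure
(genome-wide significance, p < 5e-8 by convention), independent of the
other instruments (LD clumping at r-squared < 0.001 within a 10,000 kb
window), and strong enough to avoid weak-instrument bias (F >= 10).

The proportion of exposure variance explained by one SNV is

    R2 = 2 * EAF * (1 - EAF) * beta**2

and the corresponding single-instrument F-statistic is

    F = R2 * (n - 2) / (1 - R2).

LD is supplied explicitly (a pairwise r-squared table) rather than computed
from a genotype reference panel; pairs absent from the table are treated as
unlinked, with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .summary import GwasDataset, SnpAssociation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds governing instrument selection."""

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0

    def __post_init__(self) -> None:
        if not self.p_threshold > 0:
            raise ConfigurationError("p_threshold must be positive")
        if not 0 < self.clump_r2 <= 1:
            raise ConfigurationError("clump_r2 must be in (0, 1]")
        if not self.clump_window_kb > 0:
            raise ConfigurationError("clump_window_kb must be positive")
        if not self.f_min > 0:
            raise ConfigurationError("f_min must be positive")


class LdInfo:
    """Symmetric pairwise r-squared lookup over rsids.

    Self r-squared is 1; pairs not present are reported as 0 (unlinked).
    """

    def __init__(self, pairs: Iterable[tuple[str, str, float]] = ()) -> None:
        self._r2: dict[tuple[str, str], float] = {}
        for a, b, r2 in pairs:
            self.add(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValidationError(f"r2({a},{b})={r2} outside [0, 1]")
        if a == b:
            return
        self._r2[self._key(a, b)] = float(r2)

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(self._key(a, b), 0.0)

    def knows(self, a: str, b: str) -> bool:
        return a == b or self._key(a, b) in self._r2

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LdInfo":
        frame = pd.read_csv(path, sep="\t", dtype={"rsid_a": str, "rsid_b": str})
        for col in ("rsid_a", "rsid_b", "r2"):
            if col not in frame.columns:
                raise ConfigurationError(f"{path}: LD table missing column {col!r}")
        return cls(zip(frame["rsid_a"], frame["rsid_b"], frame["r2"].astype(float)))

    def to_tsv(self, path: str | Path) -> None:
        rows = sorted((a, b, r2) for (a, b), r2 in self._r2.items())
        pd.DataFrame(rows, columns=["rsid_a", "rsid_b", "r2"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class InstrumentRecord:
    rsid: str
    r2_explained: float
    f_stat: float
    kept: bool
    reason: str = ""

    def __post_init__(self) -> None:
        if self.kept and self.reason:
            raise ValidationError(f"{self.rsid}: kept instruments carry no removal reason")


@dataclass
class InstrumentReport:
    """Per-SNV instrument-strength bookkeeping for one selection run."""

    rows: list[InstrumentRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": [r.rsid for r in self.rows],
                "r2_explained": [r.r2_explained for r in self.rows],
                "f_stat": [r.f_stat for r in self.rows],
                "kept": [r.kept for r in self.rows],
                "reason": [r.reason for r in self.rows],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def variance_explained(beta: float, eaf: float) -> float:
    """Exposure variance explained by one SNV: 2 * EAF * (1 - EAF) * beta**2."""
    if not 0.0 <= eaf <= 1.0:
        raise ValidationError(f"eaf {eaf} outside [0, 1]")
    return 2.0 * eaf * (1.0 - eaf) * beta * beta


def f_statistic(r2: float, n: float) -> float:
    """Single-instrument F-statistic: R2 * (n - 2) / (1 - R2)."""
    if not 0.0 <= r2 < 1.0:
        raise ValidationError(f"r2 {r2} outside [0, 1)")
    if not n > 2:
        raise ValidationError(f"sample size {n} must exceed 2")
    return r2 * (n - 2.0) / (1.0 - r2)


def select_significant(dataset: GwasDataset, p_threshold: float = 5e-8) -> GwasDataset:
    """Retain records with p strictly below the genome-wide threshold."""
    kept = [r for r in dataset.records if r.pval < p_threshold]
    logger.info(
        "significance filter p<%g on %s: %d/%d kept",
        p_threshold, dataset.trait, len(kept), len(dataset),
    )
    if not kept:
        logger.warning("no records reach p<%g in %s", p_threshold, dataset.trait)
    return GwasDataset(dataset.trait, dataset.role, kept)


def clump(dataset: GwasDataset, ld: LdInfo, config: SelectionConfig | None = None) -> GwasDataset:
    """Greedy LD clumping: keep index SNVs in ascending p order.

    Repeatedly take the remaining record with the smallest p-value (ties
    broken by genomic order), then discard every remaining record on the
    same chromosome within ``clump_window_kb`` of it whose r-squared with it
    is at least ``clump_r2``.
    """
    config = config or SelectionConfig()
    window_bp = config.clump_window_kb * 1000.0
    order = sorted(dataset.records, key=lambda r: (r.pval, r.chrom, r.pos))
    removed: set[str] = set()
    kept: set[str] = set()
    unknown_pairs = 0
    for idx in order:
        if idx.rsid in removed:
            continue
        kept.add(idx.rsid)
        for other in order:
            if other.rsid in removed or other.rsid in kept:
                continue
            if other.chrom != idx.chrom or abs(other.pos - idx.pos) > window_bp:
                continue
            if not ld.knows(idx.rsid, other.rsid):
                unknown_pairs += 1
            if ld.get(idx.rsid, other.rsid) >= config.clump_r2:
                removed.add(other.rsid)
    if unknown_pairs:
        logger.warning(
            "clump: %d same-window pair(s) absent from LD table, treated as unlinked",
            unknown_pairs,
        )
    result = dataset.subset(kept)
    logger.info("clumping on %s: %d/%d kept", dataset.trait, len(result), len(dataset))
    return result


def filter_weak(
    dataset: GwasDataset, config: SelectionConfig | None = None
) -> tuple[GwasDataset, InstrumentReport]:
    """Drop weak instruments (F below ``f_min``); report both statistics for all."""
    config = config or SelectionConfig()
    rows: list[InstrumentRecord] = []
    kept: list[SnpAssociation] = []
    for r in dataset.records:
        r2 = variance_explained(r.beta, r.eaf)
        f = f_statistic(min(r2, np.nextafter(1.0, 0.0)), r.n)
        if f >= config.f_min:
            kept.append(r)
            rows.append(InstrumentRecord(r.rsid, r2, f, True))
        else:
            rows.append(InstrumentRecord(r.rsid, r2, f, False, f"F<{config.f_min:g}"))
    logger.info(
        "weak-instrument filter F>=%g on %s: %d/%d kept",
        config.f_min, dataset.trait, len(kept), len(dataset),
    )
    if not kept:
        logger.warning("no instruments with F >= %g in %s", config.f_min, dataset.trait)
    return GwasDataset(dataset.trait, dataset.role, kept), InstrumentReport(rows)
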