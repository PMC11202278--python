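"""GWAS summary-statistic containers, tabular I/O, and allele harmonization.

Two-sample Mendelian randomization consumes per-variant summary
associations only: for each single-nucleotide variant (SNV) a GWAS reports
the effect allele, the other allele, the effect-allele frequency (EAF), the
per-allele effect size with its standard error, a p-value and the sample
size.  This module provides validated containers for such records, a
tab-delimited reader/writer with configurable column names, and the
harmonization step that puts the outcome association on the exposure's
effect-allele frame before any causal estimation.

Harmonization conventions
-------------------------
* If the outcome reports the same allele pair with the effect allele
  swapped, the outcome beta is negated and its EAF reflected (``1 - eaf``).
* Non-palindromic variants reported on the opposite strand are mapped
  through the base complement (A<->T, C<->G) and then aligned as above.
* Palindromic variants (allele pair A/T or C/G) cannot be strand-resolved
  from alleles alone.  Those whose outcome EAF falls inside a configurable
  window around 0.5 are dropped as ambiguous; the rest are aligned by
  frequency agreement (exposure and aligned outcome EAF on the same side
  of 0.5).  A strict mode drops every palindromic variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, HarmonizationError, ValidationError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default header names of the ten required columns in a summary table
DEFAULT_COLUMNS: dict[str, str] = {
    "rsid": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}


def is_palindromic(allele_a: str, allele_b: str) -> bool:
    """True when the allele pair is its own strand complement (A/T or C/G)."""
    return COMPLEMENT.get(allele_a) == allele_b


@dataclass(frozen=True)
class SnpAssociation:
    """One SNV's summary association with one trait.

    ``beta`` is the per-effect-allele effect: standard-deviation units for a
    continuous trait, log-odds for a binary one.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_BASES:
            raise ValidationError(
                f"{self.rsid}: effect allele {self.effect_allele!r} is not a single base"
            )
        if self.other_allele not in VALID_BASES:
            raise ValidationError(
                f"{self.rsid}: other allele {self.other_allele!r} is not a single base"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: alleles must differ")
        if not 0.0 <= self.eaf <= 1.0:
            raise ValidationError(f"{self.rsid}: eaf {self.eaf} outside [0, 1]")
        if not self.se > 0:
            raise ValidationError(f"{self.rsid}: se must be > 0, got {self.se}")
        if not 0.0 < self.pval <= 1.0:
            raise ValidationError(f"{self.rsid}: pval {self.pval} outside (0, 1]")
        if not self.n > 2:
            raise ValidationError(f"{self.rsid}: sample size must exceed 2, got {self.n}")
        if self.pos < 1:
            raise ValidationError(f"{self.rsid}: position must be >= 1, got {self.pos}")

    @property
    def palindromic(self) -> bool:
        return is_palindromic(self.effect_allele, self.other_allele)


@dataclass
class GwasDataset:
    """A named collection of :class:`SnpAssociation` with unique rsids."""

    trait: str
    role: str  # "exposure" or "outcome"
    records: list[SnpAssociation]
    _index: dict[str, SnpAssociation] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.role not in ("exposure", "outcome"):
            raise ValidationError(f"role must be 'exposure' or 'outcome', got {self.role!r}")
        # empty datasets are legal intermediates (a filter may remove everything);
        # the reader refuses empty files
        self._index = {r.rsid: r for r in self.records}
        if len(self._index) != len(self.records):
            seen: set[str] = set()
            dups = sorted({r.rsid for r in self.records if r.rsid in seen or seen.add(r.rsid)})
            raise ValidationError(f"duplicate rsids in {self.trait!r}: {', '.join(dups)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SnpAssociation]:
        return iter(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def get(self, rsid: str) -> SnpAssociation:
        return self._index[rsid]

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    def subset(self, rsids: Iterable[str]) -> "GwasDataset":
        """New dataset restricted to ``rsids``, preserving record order."""
        wanted = set(rsids)
        kept = [r for r in self.records if r.rsid in wanted]
        return GwasDataset(trait=self.trait, role=self.role, records=kept)

    def to_frame(self, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
        cols = dict(DEFAULT_COLUMNS if column_map is None else column_map)
        data = {
            cols[name]: [getattr(r, name) for r in self.records]
            for name in DEFAULT_COLUMNS
        }
        return pd.DataFrame(data)


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure/outcome effects for one SNV on a common effect-allele frame.

    ``gamma``/``sigma_x`` are the SNV-exposure effect and SE, ``Gamma`` /
    ``sigma_y`` the SNV-outcome effect and SE — the standard two-sample MR
    quantities.  ``eaf`` is the outcome EAF expressed for the exposure's
    effect allele.
    """

    rsid: str
    gamma: float
    sigma_x: float
    Gamma: float
    sigma_y: float
    eaf: float
    flipped: bool
    palindromic: bool

    def __post_init__(self) -> None:
        if not self.sigma_x > 0:
            raise ValidationError(f"{self.rsid}: sigma_x must be > 0")
        if not self.sigma_y > 0:
            raise ValidationError(f"{self.rsid}: sigma_y must be > 0")


@dataclass
class HarmonizedSet:
    """Harmonized exposure/outcome effect pairs — the unit of all estimation."""

    exposure: str
    outcome: str
    pairs: list[HarmonizedPair]
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        rsids = [p.rsid for p in self.pairs]
        if len(set(rsids)) != len(rsids):
            raise ValidationError("harmonized pairs contain duplicate rsids")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def rsids(self) -> list[str]:
        return [p.rsid for p in self.pairs]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(gamma, sigma_x, Gamma, sigma_y) as float arrays."""
        g = np.array([p.gamma for p in self.pairs], dtype=float)
        sx = np.array([p.sigma_x for p in self.pairs], dtype=float)
        G = np.array([p.Gamma for p in self.pairs], dtype=float)
        sy = np.array([p.sigma_y for p in self.pairs], dtype=float)
        return g, sx, G, sy

    def drop(self, rsid: str) -> "HarmonizedSet":
        """New set without the named pair (exclusion log not carried over)."""
        kept = [p for p in self.pairs if p.rsid != rsid]
        return HarmonizedSet(self.exposure, self.outcome, kept, [])

    def take(self, indices: Sequence[int]) -> "HarmonizedSet":
        kept = [self.pairs[i] for i in indices]
        return HarmonizedSet(self.exposure, self.outcome, kept, [])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": self.rsids,
                "gamma": [p.gamma for p in self.pairs],
                "sigma_x": [p.sigma_x for p in self.pairs],
                "Gamma": [p.Gamma for p in self.pairs],
                "sigma_y": [p.sigma_y for p in self.pairs],
                "eaf": [p.eaf for p in self.pairs],
                "flipped": [p.flipped for p in self.pairs],
                "palindromic": [p.palindromic for p in self.pairs],
            }
        )


def read_gwas_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    trait: str | None = None,
    role: str = "exposure",
) -> GwasDataset:
    """Read a tab-delimited GWAS summary table into a :class:`GwasDataset`.

    ``column_map`` maps the ten canonical field names (keys of
    :data:`DEFAULT_COLUMNS`) to the header names used in the file.  Rows
    that fail type or invariant checks (indels, se <= 0, eaf outside
    [0, 1]...) are rejected with their 1-based data-row numbers reported.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map is not None:
        cols.update(column_map)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [v for v in cols.values() if v not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {', '.join(missing)}; "
            f"present: {', '.join(frame.columns)}"
        )

    records: list[SnpAssociation] = []
    bad: list[str] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        values = dict(zip(frame.columns, row))
        try:
            records.append(
                SnpAssociation(
                    rsid=str(values[cols["rsid"]]),
                    chrom=str(values[cols["chrom"]]),
                    pos=int(values[cols["pos"]]),
                    effect_allele=str(values[cols["effect_allele"]]).upper(),
                    other_allele=str(values[cols["other_allele"]]).upper(),
                    eaf=float(values[cols["eaf"]]),
                    beta=float(values[cols["beta"]]),
                    se=float(values[cols["se"]]),
                    pval=float(values[cols["pval"]]),
                    n=float(values[cols["n"]]),
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            bad.append(f"row {i}: {exc}")
    if bad:
        raise ValidationError(f"{path}: {len(bad)} invalid row(s):\n" + "\n".join(bad))
    if not records:
        raise ValidationError(f"{path}: no data rows")

    dataset = GwasDataset(trait=trait or path.stem, role=role, records=records)
    logger.info("read %d records from %s (%s)", len(dataset), path, dataset.trait)
    return dataset


def write_gwas_table(
    dataset: GwasDataset,
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write ``dataset`` in the same tab-delimited dialect the reader accepts."""
    frame = dataset.to_frame(column_map)
    frame.to_csv(path, sep="\t", index=False)


def write_exclusion_log(exclusions: Sequence[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(exclusions, columns=["rsid", "reason"]).to_csv(path, sep="\t", index=False)


def _align_to(ex: SnpAssociation, out: SnpAssociation) -> tuple[float, float, bool] | None:
    """Align a non-palindromic outcome record to the exposure allele frame.

    Returns (Gamma, eaf, flipped) or None when the alleles are irreconcilable.
    """
    ex_pair = {ex.effect_allele, ex.other_allele}
    ea, oa = out.effect_allele, out.other_allele
    if {ea, oa} != ex_pair:
        ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
        if {ea, oa} != ex_pair:
            return None
    if ea == ex.effect_allele:
        return out.beta, out.eaf, False
    return -out.beta, 1.0 - out.eaf, True


def harmonize(
    exposure: GwasDataset,
    outcome: GwasDataset,
    eaf_window: tuple[float, float] = (0.42, 0.58),
    *,
    strict_palindromes: bool = False,
) -> HarmonizedSet:
    """Put outcome effects on the exposure's effect-allele frame.

    Operates on the rsid intersection, in exposure record order.  Every
    shared rsid ends up either in ``pairs`` or in ``exclusions`` (with
    reason ``"palindromic-intermediate-eaf"``, ``"palindromic-strict"`` or
    ``"allele-mismatch"``).

    ``eaf_window`` is the open interval of outcome EAFs within which a
    palindromic variant is considered strand-ambiguous and dropped.  The
    window should be symmetric about 0.5 for the result to be independent
    of which allele the outcome file happens to report as the effect one.
    """
    lo, hi = eaf_window
    if not (0.0 <= lo < hi <= 1.0):
        raise ConfigurationError(f"invalid eaf window ({lo}, {hi})")

    shared = [r for r in exposure.records if r.rsid in outcome]
    if not shared:
        raise HarmonizationError(
            f"no shared rsids between {exposure.trait!r} and {outcome.trait!r}"
        )

    pairs: list[HarmonizedPair] = []
    exclusions: list[tuple[str, str]] = []
    for ex in shared:
        out = outcome.get(ex.rsid)
        if ex.palindromic:
            if {out.effect_allele, out.other_allele} != {ex.effect_allele, ex.other_allele}:
                exclusions.append((ex.rsid, "allele-mismatch"))
                continue
            if strict_palindromes:
                exclusions.append((ex.rsid, "palindromic-strict"))
                continue
            if lo < out.eaf < hi:
                exclusions.append((ex.rsid, "palindromic-intermediate-eaf"))
                continue
            flipped = out.effect_allele != ex.effect_allele
            Gamma = -out.beta if flipped else out.beta
            eaf = 1.0 - out.eaf if flipped else out.eaf
            # strand cannot be read off the alleles; require frequency agreement
            if (ex.eaf - 0.5) * (eaf - 0.5) < 0:
                Gamma, eaf, flipped = -Gamma, 1.0 - eaf, not flipped
        else:
            aligned = _align_to(ex, out)
            if aligned is None:
                exclusions.append((ex.rsid, "allele-mismatch"))
                continue
            Gamma, eaf, flipped = aligned
        pairs.append(
            HarmonizedPair(
                rsid=ex.rsid,
                gamma=ex.beta,
                sigma_x=ex.se,
                Gamma=Gamma,
                sigma_y=out.se,
                eaf=eaf,
                flipped=flipped,
                palindromic=ex.palindromic,
            )
        )

    logger.info(
        "harmonized %s vs %s: %d pairs, %d excluded",
        exposure.trait, outcome.trait, len(pairs), len(exclusions),
    )
    return HarmonizedSet(exposure.trait, outcome.trait, pairs, exclusions)


def recode_opposite(record: SnpAssociation) -> SnpAssociation:
    """Re-express a record for the opposite effect allele (equivalent coding)."""
    return replace(
        record,
        effect_allele=record.other_allele,
        other_allele=record.effect_allele,
        eaf=1.0 - record.eaf,
        beta=-record.beta,
    )
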