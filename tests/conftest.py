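"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ivmr.summary import GwasDataset, HarmonizedPair, HarmonizedSet, SnpAssociation


def make_snp(
    rsid: str = "rs1",
    chrom: str = "1",
    pos: int = 1_000_000,
    effect_allele: str = "A",
    other_allele: str = "G",
    eaf: float = 0.3,
    beta: float = 0.1,
    se: float = 0.01,
    pval: float = 1e-10,
    n: float = 100_000,
) -> SnpAssociation:
    return SnpAssociation(
        rsid=rsid, chrom=chrom, pos=pos, effect_allele=effect_allele,
        other_allele=other_allele, eaf=eaf, beta=beta, se=se, pval=pval, n=n,
    )


def make_dataset(records, trait="trait", role="exposure") -> GwasDataset:
    return GwasDataset(trait=trait, role=role, records=list(records))


def make_hset(gamma, sigma_x, Gamma, sigma_y, exposure="X", outcome="Y") -> HarmonizedSet:
    pairs = [
        HarmonizedPair(
            rsid=f"rs{j + 1}", gamma=float(g), sigma_x=float(sx),
            Gamma=float(G), sigma_y=float(sy), eaf=0.3, flipped=False, palindromic=False,
        )
        for j, (g, sx, G, sy) in enumerate(zip(gamma, sigma_x, Gamma, sigma_y))
    ]
    return HarmonizedSet(exposure, outcome, pairs, [])


def random_hset(rng: np.random.Generator, J: int = 6) -> HarmonizedSet:
    """A generic random harmonized set for oracle comparisons."""
    gamma = rng.uniform(0.02, 0.2, J) * rng.choice([-1, 1], J)
    sigma_x = rng.uniform(0.002, 0.01, J)
    Gamma = rng.normal(0.0, 0.1, J)
    sigma_y = rng.uniform(0.01, 0.08, J)
    return make_hset(gamma, sigma_x, Gamma, sigma_y)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240614)
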