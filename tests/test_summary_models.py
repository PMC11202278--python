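"""Summary-statistic containers, tabular I/O, and harmonization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivmr.exceptions import ConfigurationError, HarmonizationError, ValidationError
from ivmr.summary import (
    GwasDataset,
    SnpAssociation,
    harmonize,
    read_gwas_table,
    recode_opposite,
    write_gwas_table,
)

from conftest import make_dataset, make_snp

ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("A", "T"), ("C", "G")]


class TestSnpAssociation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"se": 0.0},
            {"se": -1.0},
            {"eaf": 1.2},
            {"effect_allele": "G", "other_allele": "G"},
            {"effect_allele": "AT"},
            {"other_allele": "-"},
            {"pval": 0.0},
            {"pos": 0},
            {"n": 2},
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            make_snp(**kwargs)

    def test_palindromic_detection(self):
        assert make_snp(effect_allele="A", other_allele="T").palindromic
        assert make_snp(effect_allele="C", other_allele="G").palindromic
        assert not make_snp(effect_allele="A", other_allele="G").palindromic


class TestTableIO:
    def test_three_row_round_trip(self, tmp_path):
        ds = make_dataset([make_snp(rsid=f"rs{i}", pos=1000 + i) for i in range(3)])
        path = tmp_path / "t.tsv"
        write_gwas_table(ds, path)
        back = read_gwas_table(path, trait="trait", role="exposure")
        assert back.records == ds.records

    def test_missing_column_is_configuration_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("SNP\tCHR\n" "rs1\t1\n")
        with pytest.raises(ConfigurationError, match="POS"):
            read_gwas_table(path)

    def test_bad_row_reported_with_row_number(self, tmp_path):
        ds = make_dataset([make_snp(rsid="rs1"), make_snp(rsid="rs2")])
        path = tmp_path / "t.tsv"
        write_gwas_table(ds, path)
        text = path.read_text().splitlines()
        text[2] = text[2].replace("\t0.01\t", "\t0\t")  # zero the SE of data row 2
        path.write_text("\n".join(text) + "\n")
        with pytest.raises(ValidationError, match="row 2"):
            read_gwas_table(path)

    def test_duplicate_rsids_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_gwas_table(make_dataset([make_snp(rsid="rs1")]), path)
        row = path.read_text().splitlines()[1]
        path.write_text(path.read_text() + row + "\n")
        with pytest.raises(ValidationError, match="rs1"):
            read_gwas_table(path)

    def test_custom_column_map(self, tmp_path):
        ds = make_dataset([make_snp()])
        cols = {
            "rsid": "variant_id", "chrom": "chromosome", "pos": "base_pair",
            "effect_allele": "a1", "other_allele": "a2", "eaf": "freq",
            "beta": "effect", "se": "stderr", "pval": "p_value", "n": "samples",
        }
        path = tmp_path / "t.tsv"
        write_gwas_table(ds, path, cols)
        back = read_gwas_table(path, cols)
        assert back.records == ds.records


@st.composite
def snp_records(draw, rsid: str):
    ea, oa = draw(st.sampled_from(ALLELE_PAIRS))
    return SnpAssociation(
        rsid=rsid,
        chrom=draw(st.sampled_from(["1", "2", "X"])),
        pos=draw(st.integers(min_value=1, max_value=10**8)),
        effect_allele=ea,
        other_allele=oa,
        eaf=draw(st.floats(0.01, 0.99)),
        beta=draw(st.floats(-1.0, 1.0)),
        se=draw(st.floats(1e-4, 1.0)),
        pval=draw(st.floats(1e-30, 1.0, exclude_min=False)),
        n=draw(st.integers(10, 10**6)),
    )


@st.composite
def gwas_datasets(draw, min_size=1, max_size=8):
    k = draw(st.integers(min_size, max_size))
    records = [draw(snp_records(f"rs{i}")) for i in range(k)]
    return GwasDataset("fuzz", "exposure", records)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(gwas_datasets())
def test_write_read_round_trip_property(tmp_path_factory, ds):
    """Writing then reading any valid dataset reproduces it."""
    path = tmp_path_factory.mktemp("io") / "ds.tsv"
    write_gwas_table(ds, path)
    back = read_gwas_table(path, trait="fuzz", role="exposure")
    for a, b in zip(back.records, ds.records):
        assert a.rsid == b.rsid and a.effect_allele == b.effect_allele
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.eaf == pytest.approx(b.eaf, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)


class TestHarmonize:
    def test_identity_coding_unchanged(self):
        exp = make_dataset([make_snp(beta=0.10)], role="exposure")
        out = make_dataset([make_snp(beta=0.05, se=0.02)], trait="Y", role="outcome")
        h = harmonize(exp, out)
        (pair,) = h.pairs
        assert not pair.flipped
        assert pair.Gamma == 0.05
        assert pair.eaf == 0.3

    def test_allele_swap_negates_outcome(self):
        exp = make_dataset([make_snp(effect_allele="A", other_allele="G", beta=0.10)])
        out = make_dataset(
            [make_snp(effect_allele="G", other_allele="A", beta=0.05, eaf=0.30, se=0.02)],
            trait="Y", role="outcome",
        )
        h = harmonize(exp, out)
        (pair,) = h.pairs
        assert pair.flipped
        assert pair.Gamma == pytest.approx(-0.05)
        assert pair.eaf == pytest.approx(0.70)

    def test_strand_complement_resolved(self):
        # outcome reports T/C on the other strand for an exposure A/G variant
        exp = make_dataset([make_snp(effect_allele="A", other_allele="G", beta=0.10)])
        out = make_dataset(
            [make_snp(effect_allele="T", other_allele="C", beta=0.05, eaf=0.30, se=0.02)],
            trait="Y", role="outcome",
        )
        h = harmonize(exp, out)
        (pair,) = h.pairs
        assert not pair.flipped
        assert pair.Gamma == pytest.approx(0.05)

    def test_palindromic_mid_eaf_excluded(self):
        exp = make_dataset([make_snp(effect_allele="A", other_allele="T", eaf=0.5)])
        out = make_dataset(
            [make_snp(effect_allele="A", other_allele="T", eaf=0.50, se=0.02)],
            trait="Y", role="outcome",
        )
        h = harmonize(exp, out, eaf_window=(0.42, 0.58))
        assert h.pairs == []
        assert h.exclusions == [("rs1", "palindromic-intermediate-eaf")]

    def test_palindromic_outside_window_aligned_by_frequency(self):
        exp = make_dataset([make_snp(effect_allele="A", other_allele="T", eaf=0.2, beta=0.1)])
        # outcome coded for the high-frequency allele: frequency disagreement
        out = make_dataset(
            [make_snp(effect_allele="A", other_allele="T", eaf=0.8, beta=0.05, se=0.02)],
            trait="Y", role="outcome",
        )
        h = harmonize(exp, out)
        (pair,) = h.pairs
        assert pair.flipped
        assert pair.Gamma == pytest.approx(-0.05)
        assert pair.eaf == pytest.approx(0.2)

    def test_strict_mode_drops_all_palindromes(self):
        exp = make_dataset([make_snp(effect_allele="C", other_allele="G", eaf=0.2)])
        out = make_dataset(
            [make_snp(effect_allele="C", other_allele="G", eaf=0.2, se=0.02)],
            trait="Y", role="outcome",
        )
        h = harmonize(exp, out, strict_palindromes=True)
        assert h.exclusions == [("rs1", "palindromic-strict")]

    def test_allele_mismatch_excluded(self):
        exp = make_dataset([make_snp(effect_allele="A", other_allele="G")])
        out = make_dataset(
            [make_snp(effect_allele="A", other_allele="C", se=0.02)],
            trait="Y", role="outcome",
        )
        h = harmonize(exp, out)
        assert h.exclusions == [("rs1", "allele-mismatch")]

    def test_empty_intersection_errors(self):
        exp = make_dataset([make_snp(rsid="rs1")])
        out = make_dataset([make_snp(rsid="rs2", se=0.02)], trait="Y", role="outcome")
        with pytest.raises(HarmonizationError):
            harmonize(exp, out)


class TestHarmonizeInvariants:
    def _random_pair(self, rng, n=12):
        """Exposure plus an outcome with randomly perturbed allele coding."""
        from ivmr.summary import COMPLEMENT

        exp_records, out_records = [], []
        for i in range(n):
            ea, oa = ALLELE_PAIRS[rng.integers(0, len(ALLELE_PAIRS))]
            eaf = float(rng.uniform(0.05, 0.95))
            exp_records.append(
                make_snp(rsid=f"rs{i}", effect_allele=ea, other_allele=oa,
                         eaf=eaf, beta=float(rng.normal(0, 0.1)))
            )
            o_ea, o_oa, o_beta, o_eaf = ea, oa, float(rng.normal(0, 0.05)), eaf
            if rng.random() < 0.5:  # swap alleles
                o_ea, o_oa, o_beta, o_eaf = o_oa, o_ea, -o_beta, 1 - o_eaf
            if rng.random() < 0.5 and ea not in (COMPLEMENT[oa],):  # strand flip
                o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
            out_records.append(
                make_snp(rsid=f"rs{i}", effect_allele=o_ea, other_allele=o_oa,
                         eaf=o_eaf, beta=o_beta, se=0.02)
            )
        return (
            make_dataset(exp_records, trait="X"),
            make_dataset(out_records, trait="Y", role="outcome"),
        )

    def test_conservation(self, rng):
        for _ in range(20):
            exp, out = self._random_pair(rng)
            h = harmonize(exp, out)
            assert len(h.pairs) + len(h.exclusions) == len(exp)

    def test_idempotence(self, rng):
        """Harmonizing the already-aligned outcome changes nothing."""
        for _ in range(10):
            exp, out = self._random_pair(rng)
            h1 = harmonize(exp, out)
            aligned_records = []
            for p in h1.pairs:
                ex = exp.get(p.rsid)
                aligned_records.append(
                    make_snp(rsid=p.rsid, effect_allele=ex.effect_allele,
                             other_allele=ex.other_allele, eaf=p.eaf,
                             beta=p.Gamma, se=p.sigma_y)
                )
            if not aligned_records:
                continue
            h2 = harmonize(exp.subset([r.rsid for r in aligned_records]),
                           make_dataset(aligned_records, trait="Y", role="outcome"))
            for a, b in zip(h1.pairs, h2.pairs):
                assert a.rsid == b.rsid
                assert not b.flipped
                assert b.Gamma == pytest.approx(a.Gamma, abs=1e-15)
                assert b.eaf == pytest.approx(a.eaf, abs=1e-15)

    def test_sign_equivariance_under_outcome_recoding(self, rng):
        """Recoding any outcome record to its opposite allele is a no-op."""
        for _ in range(20):
            exp, out = self._random_pair(rng)
            recoded = make_dataset(
                [recode_opposite(r) if rng.random() < 0.5 else r for r in out.records],
                trait="Y", role="outcome",
            )
            h1, h2 = harmonize(exp, out), harmonize(exp, recoded)
            assert [e for e in h1.exclusions] == [e for e in h2.exclusions]
            for a, b in zip(h1.pairs, h2.pairs):
                assert a.rsid == b.rsid
                assert b.Gamma == pytest.approx(a.Gamma, abs=1e-15)
                assert b.eaf == pytest.approx(a.eaf, abs=1e-15)
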