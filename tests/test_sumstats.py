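"""Record validation, TSV round-trips and effect-allele alignment."""

import math
import sys

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sarcopred import (
    AssociationRecord,
    TraitSpec,
    VariantKey,
    align_to_allele,
    load_trait_specs,
    read_sumstats,
    write_sumstats,
)
from sarcopred.sumstats import AlignmentError, parse_p


def _record(beta=0.1, ea="A", p=0.01, rsid="rs1", alleles=("A", "G")):
    v = VariantKey(rsid, *alleles)
    return AssociationRecord(v, "trait", ea, beta, 0.02, p, n=1000)


class TestVariantKey:
    def test_identity_is_rsid_plus_unordered_alleles(self):
        assert VariantKey("rs1", "A", "G") == VariantKey("rs1", "G", "A")
        assert hash(VariantKey("rs1", "A", "G")) == hash(VariantKey("rs1", "G", "A"))
        assert VariantKey("rs1", "A", "G") != VariantKey("rs2", "A", "G")

    def test_indel_style_alleles_allowed(self):
        v = VariantKey("rs10686842", "TAAA", "T")
        assert v.other_allele("T") == "TAAA"

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(rsid="", allele_a="A", allele_b="G"),
            dict(rsid="rs1", allele_a="A", allele_b="A"),
            dict(rsid="rs1", allele_a="N", allele_b="G"),
            dict(rsid="rs1", allele_a="", allele_b="G"),
        ],
    )
    def test_invalid_keys_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VariantKey(**kwargs)

    def test_palindromic_detection(self):
        assert VariantKey("rs1", "A", "T").is_palindromic()
        assert VariantKey("rs1", "C", "G").is_palindromic()
        assert not VariantKey("rs1", "A", "G").is_palindromic()


class TestTraitSpec:
    def test_adiposity_requires_risk_direction(self):
        with pytest.raises(ValueError):
            TraitSpec("fat", "adiposity", +1)

    def test_replication_cannot_be_tighter_than_discovery(self):
        with pytest.raises(ValueError):
            TraitSpec("t", "strength", +1, discovery_threshold=0.005,
                      replication_threshold=5e-8)

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "traits.yaml"
        path.write_text(
            "- {name: grip, category: strength, benefit_direction: 1,\n"
            "   discovery_threshold: 5.0e-8, replication_threshold: 0.005, n: 195180}\n"
            "- {name: fat, category: adiposity, benefit_direction: -1,\n"
            "   replication_threshold: 0.005, n: 354628}\n"
        )
        specs = load_trait_specs(path)
        assert [s.name for s in specs] == ["grip", "fat"]
        assert specs[0].discovery_threshold == 5e-8


class TestAlignment:
    def test_identity_when_already_aligned(self):
        r = _record(beta=0.1, ea="G", alleles=("A", "G"))
        assert align_to_allele(r, "G") is r

    def test_sign_flips_when_switching_allele(self):
        r = _record(beta=0.1, ea="A", alleles=("A", "G"))
        flipped = align_to_allele(r, "G")
        assert flipped.effect_allele == "G"
        assert flipped.beta == -0.1
        assert (flipped.p, flipped.se, flipped.n) == (r.p, r.se, r.n)

    def test_unknown_allele_names_variant(self):
        with pytest.raises(AlignmentError, match="rs1"):
            align_to_allele(_record(), "T")

    @settings(max_examples=100, derandomize=True)
    @given(
        beta=st.floats(-10, 10, allow_nan=False),
        start_on_a=st.booleans(),
    )
    def test_involution_and_single_positive_alignment(self, beta, start_on_a):
        ea = "A" if start_on_a else "G"
        r = _record(beta=beta, ea=ea)
        other = r.variant.other_allele(ea)
        back = align_to_allele(align_to_allele(r, other), ea)
        assert back == r
        if beta != 0:
            signs = {align_to_allele(r, a).beta > 0 for a in ("A", "G")}
            assert signs == {True, False}


class TestParseP:
    def test_subnormal_values_kept_as_parsed(self):
        p = parse_p("7.0e-319")
        assert 0.0 < p < sys.float_info.min
        assert p == float("7.0e-319")

    def test_underflow_clamped_to_smallest_normal(self):
        assert parse_p("1e-400") == sys.float_info.min

    def test_literal_zero_not_clamped(self):
        assert parse_p("0") == 0.0


class TestReadWrite:
    def test_well_formed_rows_all_read(self, tmp_path):
        path = tmp_path / "ss.tsv"
        path.write_text(
            "rsid\tchrom\tpos\teffect_allele\tother_allele\tbeta\tse\tp\tn\n"
            "rs1\t1\t100\tA\tG\t0.1\t0.02\t0.001\t1000\n"
            "rs2\t1\t200\tC\tT\t-0.2\t0.05\t0.5\t1000\n"
            "rs3\t2\t300\tG\tA\t0.0\t0.01\t1.0\t1000\n"
        )
        result = read_sumstats(path, trait="grip")
        assert len(result.records) == 3 and result.n_rejected == 0

    @pytest.mark.parametrize(
        "row",
        [
            "rs1\t1\t100\tA\tG\t0.1\t0.02\t0\t1000",      # p = 0
            "rs1\t1\t100\tA\tG\t0.1\t0.02\t1.5\t1000",     # p > 1
            "rs1\t1\t100\tA\tG\t0.1\t-0.02\t0.1\t1000",    # se <= 0
            "rs1\t1\t100\tA\tA\t0.1\t0.02\t0.1\t1000",     # equal alleles
            "rs1\t1\t100\tA\tG\tnot_a_number\t0.02\t0.1\t1000",
        ],
    )
    def test_bad_rows_rejected_not_fatal(self, tmp_path, row):
        path = tmp_path / "ss.tsv"
        path.write_text(
            "rsid\tchrom\tpos\teffect_allele\tother_allele\tbeta\tse\tp\tn\n"
            + row + "\n"
            + "rs9\t1\t900\tC\tT\t0.3\t0.04\t0.02\t500\n"
        )
        result = read_sumstats(path, trait="grip")
        assert result.n_rejected == 1
        assert [r.variant.rsid for r in result.records] == ["rs9"]

    def test_missing_mapped_column_raises(self, tmp_path):
        path = tmp_path / "ss.tsv"
        path.write_text("rsid\teffect_allele\n")
        with pytest.raises(KeyError):
            read_sumstats(path, trait="grip")

    def test_column_map_for_foreign_dialect(self, tmp_path):
        path = tmp_path / "ss.tsv"
        path.write_text(
            "SNP\tA1\tA2\tBETA\tSE\tP\n" "rs1\tA\tG\t0.1\t0.02\t0.001\n"
        )
        result = read_sumstats(
            path,
            trait="grip",
            column_map={"rsid": "SNP", "effect_allele": "A1",
                        "other_allele": "A2", "beta": "BETA", "se": "SE", "p": "P"},
        )
        assert len(result.records) == 1
        assert result.records[0].variant.rsid == "rs1"

    def test_empty_collection_gives_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_sumstats([], path)
        assert path.read_text().count("\n") == 1

    def test_round_trip_is_lossless(self, tmp_path):
        rng = np.random.default_rng(7)
        records = []
        for i in range(500):
            alleles = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
            v = VariantKey(f"rs{i}", alleles[0], alleles[1],
                           chrom=str(rng.integers(1, 23)), pos=int(rng.integers(1, 10**8)))
            records.append(
                AssociationRecord(
                    v, "grip", alleles[rng.integers(0, 2)],
                    beta=float(rng.normal()),
                    se=float(rng.uniform(1e-6, 2.0)),
                    p=float(rng.uniform(1e-300, 1.0)),
                    n=int(rng.integers(100, 10**6)),
                )
            )
        path = tmp_path / "rt.tsv"
        write_sumstats(records, path)
        reread = read_sumstats(path, trait="grip").records
        assert len(reread) == 500
        for orig, new in zip(records, reread):
            assert new.variant == orig.variant
            assert new.variant.chrom == orig.variant.chrom
            assert new.variant.pos == orig.variant.pos
            assert new.effect_allele == orig.effect_allele
            assert new.beta == orig.beta
            assert new.se == orig.se
            assert new.p == orig.p
            assert new.n == orig.n
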