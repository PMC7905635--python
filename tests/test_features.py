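from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import random_dna
from oracles import (
    c_weight_oracle,
    gc_oracle,
    gc_pos_oracle,
    kmer_freq_oracle,
    kmer_variance_oracle,
)
from orfrf.errors import FeatureDomainError
from orfrf.features import (
    FEATURE_NAMES,
    GENETIC_CODE,
    GeneticCode,
    c_weight,
    feature_correlation,
    feature_vector,
    featurize,
    gc_by_position,
    gc_content,
    kmer_frequency_vector,
    kmer_variance,
)
from orfrf.orfs import Orf


def random_orf_seq(rng, n_codons: int) -> str:
    """ORF-shaped sequence: ATG + random stop-free codons + stop."""
    sense = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    body = "".join(
        sense[i] for i in rng.integers(0, len(sense), size=n_codons - 2)
    )
    return "ATG" + body + ["TAA", "TAG", "TGA"][rng.integers(3)]


class TestGeneticCode:
    def test_table11_structure(self):
        code = GeneticCode(11)
        assert code.stop_codons == ("TAA", "TAG", "TGA")
        assert len(code.sense_codons) == 61
        sizes = sorted(len(f) for f in code.families.values())
        assert sum(sizes) == 61 and len(sizes) == 20
        assert code.families["M"] == ("ATG",)
        assert code.families["W"] == ("TGG",)


class TestGcFeatures:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGC", 0.5), ("GGCC", 1.0), ("ATGCCGTAA", 4 / 9)],
    )
    def test_gc_content_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATGCCGTAA", (1 / 3, 1 / 3, 2 / 3)),
            ("GGGGGG", (1.0, 1.0, 1.0)),
            ("ATATAT", (0.0, 0.0, 0.0)),
        ],
    )
    def test_gc_by_position_examples(self, seq, expected):
        assert gc_by_position(seq) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(FeatureDomainError):
            gc_content("")
        with pytest.raises(FeatureDomainError):
            gc_by_position("ACGT")
        with pytest.raises(FeatureDomainError):
            gc_content("ACGN")

    def test_gc_is_mean_of_positional_gc(self, rng):
        """Exact identity for triplet-length sequences."""
        for _ in range(100):
            seq = random_dna(rng, 3 * int(rng.integers(1, 80)))
            g1, g2, g3 = gc_by_position(seq)
            assert gc_content(seq) == pytest.approx((g1 + g2 + g3) / 3, abs=1e-12)


class TestKmerFeatures:
    def test_homopolymer_vector(self):
        v = kmer_frequency_vector("AAAA", 2)
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_acgt_dimers(self):
        v = kmer_frequency_vector("ACGT", 2)
        # AC=1, CG=6, GT=11 in lexicographic order
        assert v[[1, 6, 11]] == pytest.approx([1 / 3] * 3)
        assert v.sum() == pytest.approx(1.0)

    def test_components_sum_to_one(self, rng):
        for k in range(2, 7):
            seq = random_dna(rng, 200)
            assert kmer_frequency_vector(seq, k).sum() == pytest.approx(1.0)

    def test_homopolymer_variance_fixture(self):
        assert kmer_variance("AAAAA", 2) == pytest.approx(1 / 16)

    def test_de_bruijn_coverage_gives_zero_variance(self):
        # length-17 cyclic walk covering all 16 dimers exactly once
        seq = "AACAGATCCGCTGGTTA"
        assert kmer_variance(seq, 2) == pytest.approx(0.0, abs=1e-18)

    def test_variance_invariant_under_nucleotide_relabeling(self, rng):
        perm = dict(zip("ACGT", "TGCA"))
        for _ in range(20):
            seq = random_dna(rng, 120)
            relabeled = "".join(perm[b] for b in seq)
            for k in (2, 3, 4):
                assert kmer_variance(seq, k) == pytest.approx(
                    kmer_variance(relabeled, k), rel=1e-12
                )

    def test_short_sequence_rejected(self):
        with pytest.raises(FeatureDomainError):
            kmer_frequency_vector("ACG", 4)


class TestCWeight:
    def test_single_codon_per_family_is_one(self):
        # one codon per observed family: every codon is its family maximum
        assert c_weight("ATGGCTAAATAA") == 1.0

    def test_mixed_family_fixture(self):
        assert c_weight("ATGGCTGCTGCTGCATAA") == pytest.approx(2 / 3)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(50):
            seq = random_orf_seq(rng, int(rng.integers(10, 100)))
            assert 0.0 < c_weight(seq) <= 1.0

    def test_non_triplet_rejected(self):
        with pytest.raises(FeatureDomainError):
            c_weight("ACGTA")


class TestFeaturize:
    def test_component_agreement_with_standalone_operations(self, rng):
        """Assembled vector equals each standalone feature, canonical order."""
        for _ in range(100):
            seq = random_orf_seq(rng, int(rng.integers(10, 120)))
            fv = feature_vector(seq)
            assert fv.length_nt == len(seq)
            assert fv.gc == pytest.approx(gc_content(seq))
            assert (fv.gc1, fv.gc2, fv.gc3) == pytest.approx(gc_by_position(seq))
            for k in range(2, 7):
                assert getattr(fv, f"var{k}") == pytest.approx(kmer_variance(seq, k))
            assert fv.c_weight == pytest.approx(c_weight(seq))

    def test_oracle_agreement_dictionary_counting(self, rng):
        """All 11 features match naive dictionary-counting implementations."""
        for _ in range(100):
            seq = random_orf_seq(rng, int(rng.integers(10, 80)))
            fv = feature_vector(seq)
            assert fv.gc == pytest.approx(gc_oracle(seq))
            assert (fv.gc1, fv.gc2, fv.gc3) == pytest.approx(gc_pos_oracle(seq))
            for k in range(2, 7):
                assert getattr(fv, f"var{k}") == pytest.approx(
                    kmer_variance_oracle(seq, k), rel=1e-9
                )
            assert fv.c_weight == pytest.approx(c_weight_oracle(seq))

    def test_featurize_orf_is_deterministic(self):
        orf = Orf("s", 1, 9, "+", 1, "ATGAAATAG")
        assert featurize(orf) == featurize(orf)
        assert featurize(orf).length_nt == 9

    def test_canonical_order(self):
        fv = feature_vector("ATGAAATAGGCC")
        arr = fv.as_array()
        assert len(arr) == len(FEATURE_NAMES) == 11
        assert arr[0] == fv.length_nt and arr[-1] == fv.c_weight


class TestFeatureCorrelation:
    def test_self_and_duplicate_columns(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({n: rng.normal(size=50) for n in FEATURE_NAMES})
        df["gc"] = x
        df["gc3"] = x  # duplicated column pair
        corr = feature_correlation(df)
        assert np.allclose(np.diag(corr), 1.0)
        assert corr.loc["gc", "gc3"] == pytest.approx(1.0)
        assert np.allclose(corr.values, corr.values.T)

    def test_constant_column_zeroed_with_warning(self, rng):
        df = pd.DataFrame({n: rng.normal(size=30) for n in FEATURE_NAMES})
        df["var6"] = 1.0
        with pytest.warns(UserWarning, match="var6"):
            corr = feature_correlation(df)
        off = corr.loc["var6"].drop("var6")
        assert (off == 0).all()

    def test_too_few_rows_rejected(self):
        with pytest.raises(FeatureDomainError):
            feature_correlation(pd.DataFrame(np.ones((2, 11)), columns=FEATURE_NAMES))

    def test_coupled_gc_features_correlate_on_synthetic_data(self):
        """GC couples to GC3 more than to var6 on generated genomes."""
        from orfrf import synthetic
        from orfrf.features import feature_frame

        usage = synthetic.sample_codon_usage(GENETIC_CODE, 0.7, 5, gc3_preference=0.9)
        rng = np.random.default_rng(5)
        seqs = [
            synthetic.generate_cds(int(rng.integers(40, 300)), usage, rng)
            for _ in range(150)
        ]
        # mix in unbiased ORFs so GC varies across rows
        usage0 = synthetic.sample_codon_usage(GENETIC_CODE, 0.0, 6)
        seqs += [
            synthetic.generate_cds(int(rng.integers(40, 300)), usage0, rng)
            for _ in range(150)
        ]
        corr = feature_correlation(feature_frame(seqs))
        assert abs(corr.loc["gc", "gc3"]) > abs(corr.loc["gc", "var6"])
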