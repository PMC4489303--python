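"""Parallel/series correlation profiles and the pseudo-composition vector."""

from dataclasses import replace

import numpy as np
import pytest

from pseqfeat import (
    Alphabet,
    ParameterSet,
    Sequence,
    kmer_vector,
    load_builtin,
    normalize_index,
    parallel_theta,
    pseudo_composition,
    series_tau,
    validate_alphabet,
)
from pseqfeat.testkit import oracle_suite, random_sequences


def _dna(r):
    return validate_alphabet(Sequence("t", r), Alphabet.DNA)


@pytest.fixture(scope="module")
def di1():
    return load_builtin(Alphabet.DNA, 2)[:1]


class TestParallelTheta:
    def test_homopolymer_all_zero(self, structural6):
        prof = parallel_theta(_dna("A" * 12), structural6, lam=4, g=2)
        assert np.array_equal(prof.values, np.zeros(4))

    def test_hand_summed_squared_differences(self, di1):
        # single property on ACGT: track AC, CG, GT; theta_1 averages the
        # two adjacent squared differences
        seq = _dna("ACGT")
        z = normalize_index(di1[0]).values
        track = [z["AC"], z["CG"], z["GT"]]
        expected = ((track[0] - track[1]) ** 2 + (track[1] - track[2]) ** 2) / 2
        prof = parallel_theta(seq, di1, lam=1, g=2)
        assert prof.values[0] == pytest.approx(expected, abs=1e-12)

    def test_duplicating_a_property_changes_nothing(self, di1):
        seq = _dna("ACGTTGCAACGT")
        doubled = [di1[0], replace(di1[0], name="again")]
        a = parallel_theta(seq, di1, lam=3, g=2)
        b = parallel_theta(seq, doubled, lam=3, g=2)
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_thetas_nonnegative(self, structural6):
        for seq in random_sequences(Alphabet.DNA, 20, (10, 80), 33):
            prof = parallel_theta(seq, structural6, lam=3, g=2)
            assert np.all(prof.values >= 0)

    def test_lambda_exceeding_track_is_error(self, di1):
        with pytest.raises(ValueError, match="maximum legal value 2"):
            parallel_theta(_dna("ACGT"), di1, lam=3, g=2)  # T=3 -> max lam 2


class TestSeriesTau:
    def test_single_property_count_is_lambda(self, di1):
        prof = series_tau(_dna("ACGTACGTAC"), di1, lam=4, g=2)
        assert len(prof.values) == 4

    def test_homopolymer_constant_track_squares(self, di1):
        seq = _dna("A" * 10)
        c = normalize_index(di1[0]).values["AA"]
        prof = series_tau(seq, di1, lam=3, g=2)
        assert np.allclose(prof.values, c**2, atol=1e-12)

    def test_lag_major_property_minor_order(self, structural6):
        prof = series_tau(_dna("ACGTACGTACGT"), structural6[:2], lam=2, g=2)
        assert [l.split(":")[1] for l in prof.labels] == ["lag1", "lag1", "lag2", "lag2"]

    def test_matches_naive_oracle(self, structural6):
        props = structural6[:2]
        for seq in random_sequences(Alphabet.DNA, 20, (10, 90), 37):
            prof = series_tau(seq, props, lam=3, g=2)
            from pseqfeat.testkit import _naive_tau

            assert np.allclose(prof.values, _naive_tau(seq, props, 3, 2), atol=1e-12)


class TestPseudoComposition:
    def test_zero_weight_reduces_to_composition(self, structural6):
        seq = _dna("ACGTTGCAGCTA")
        v = pseudo_composition(seq, structural6, k=2, lam=4, w=0.0, kind="parallel", corr_g=2)
        comp = kmer_vector(seq, 2)
        assert np.allclose(v.values[:16], comp.values, atol=0)
        assert np.array_equal(v.values[16:], np.zeros(4))

    @pytest.mark.parametrize("lam,dim", [(10, 26), (3, 19)])
    def test_psednc_dimensions(self, structural6, lam, dim):
        seq = _dna("ACGTACGTACGTACGTACGTACGT")
        v = pseudo_composition(seq, structural6, k=2, lam=lam, w=0.05,
                               kind="parallel", corr_g=2)
        assert len(v) == dim
        assert v.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_lambda_zero_gives_bare_composition(self, structural6):
        seq = _dna("ACGTACGT")
        v = pseudo_composition(seq, structural6, k=2, lam=0, w=0.05,
                               kind="parallel", corr_g=2)
        assert np.allclose(v.values, kmer_vector(seq, 2).values, atol=0)

    @pytest.mark.parametrize("kind", ["parallel", "series"])
    def test_end_to_end_vs_naive_oracle(self, structural6, kind):
        props = structural6[:2]
        mode = "PC-PseDNC-General" if kind == "parallel" else "SC-PseDNC-General"
        for seq in random_sequences(Alphabet.DNA, 25, (12, 100), 41):
            engine = pseudo_composition(seq, props, k=2, lam=3, w=0.05,
                                        kind=kind, corr_g=2)
            oracle = oracle_suite(mode, seq, ParameterSet(lamada=3, weight=0.05), props)
            assert np.allclose(engine.values, oracle.values, atol=1e-12)
            assert engine.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_weight_monotonicity_of_pseudo_mass(self, structural6):
        seq = random_sequences(Alphabet.DNA, 1, (60, 60), 43)[0]
        masses = []
        for w in (0.01, 0.05, 0.2, 1.0, 5.0):
            v = pseudo_composition(seq, structural6, k=2, lam=5, w=w,
                                   kind="parallel", corr_g=2)
            masses.append(v.values[16:].sum())
        assert all(a < b for a, b in zip(masses, masses[1:]))
        # closed form: pseudo mass = w*phi / (1 + w*phi)
        from pseqfeat import parallel_theta as pt

        phi = pt(seq, structural6, 5, 2).values.sum()
        assert masses[1] == pytest.approx(0.05 * phi / (1 + 0.05 * phi), abs=1e-12)

    def test_pseknc_correlates_on_dinucleotides(self, structural6):
        # composition over 3-mers (64 features) + lambda dinucleotide tiers
        seq = _dna("ACGTACGTACGTACGT")
        v = pseudo_composition(seq, structural6, k=3, lam=2, w=0.05,
                               kind="parallel", corr_g=2)
        assert len(v) == 64 + 2
        theta = parallel_theta(seq, structural6, 2, 2)
        phi = theta.values.sum()
        assert np.allclose(v.values[64:], 0.05 * theta.values / (1 + 0.05 * phi), atol=1e-12)

    def test_negative_weight_rejected(self, structural6):
        with pytest.raises(ValueError, match=">= 0"):
            pseudo_composition(_dna("ACGTACGT"), structural6, k=2, lam=2, w=-0.1)

    def test_protein_series_dimension_20_plus_2lam(self):
        props = load_builtin(Alphabet.PROTEIN, 1)[:2]
        seq = random_sequences(Alphabet.PROTEIN, 1, (40, 40), 47)[0]
        v = pseudo_composition(seq, props, k=1, lam=6, w=0.05, kind="series", corr_g=1)
        assert len(v) == 20 + 2 * 6
        assert v.values.sum() == pytest.approx(1.0, abs=1e-12)
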