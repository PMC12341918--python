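"""Polyploid relationship structures against enumeration/closed-form oracles."""

import itertools

import numpy as np
import pytest

from triploidcross.genotypes import ParentGenotypes
from triploidcross.kinship import (additive_grm, build_kinship_set,
                                   dominance_regressor, epistasis_grm,
                                   expected_dominance_grm,
                                   expected_hybrid_regressor,
                                   expected_inbreeding, regressor_constants)
from triploidcross.simulate import simulate_cross_progeny


def gamete_moments(x2: int, x4: int):
    """Exact hybrid-dosage moments by enumerating both gamete distributions.

    The diploid gamete is Bernoulli(x2/2); the tetraploid gamete draws two
    of the four chromosome copies without replacement (hypergeometric).
    """
    from math import comb

    p2 = {0: 1 - x2 / 2, 1: x2 / 2}
    p4 = {k: comb(x4, k) * comb(4 - x4, 2 - k) / comb(4, 2)
          for k in range(3)}
    ex = ex2 = 0.0
    dist = {}
    for a, pa in p2.items():
        for b, pb in p4.items():
            x = a + b
            dist[x] = dist.get(x, 0.0) + pa * pb
    for x, p in dist.items():
        ex += p * x
        ex2 += p * x * x
    return ex, ex2, dist


class TestAdditiveGrm:
    def test_single_marker_hand_values(self):
        A = additive_grm(np.array([[0.0], [2.0]]), 2, np.array([0.5]))
        np.testing.assert_allclose(A, [[2.0, -2.0], [-2.0, 2.0]])

    def test_doubled_diploids_double_the_matrix(self, rng):
        dos = rng.integers(0, 3, size=(6, 120))
        # keep only polymorphic markers
        keep = (dos.sum(0) > 0) & (dos.sum(0) < 12)
        dos = dos[:, keep]
        f = dos.sum(0) / 12.0
        A2 = additive_grm(dos, 2, f)
        A4 = additive_grm(2 * dos, 4, f)
        np.testing.assert_allclose(A4, 2.0 * A2, rtol=1e-12)

    def test_centered_dosages_give_zero_matrix(self):
        f = np.array([0.25, 0.5])
        dos = np.tile(2 * f, (3, 1))
        A = additive_grm(dos, 2, f)
        np.testing.assert_allclose(A, 0.0, atol=1e-12)

    def test_fixed_marker_frequency_rejected(self):
        with pytest.raises(ValueError, match="strictly"):
            additive_grm(np.array([[0.0], [2.0]]), 2, np.array([1.0]))

    def test_grm_is_psd(self, rng):
        dos = rng.binomial(2, 0.4, size=(8, 200))
        f = dos.mean(0) / 2
        ok = (f > 0) & (f < 1)
        A = additive_grm(dos[:, ok], 2, f[ok])
        assert np.linalg.eigvalsh(A).min() > -1e-8


class TestDominanceRegressor:
    @pytest.mark.parametrize("ploidy,freq,dosage,expected", [
        (2, 0.5, 1, 0.5),
        (3, 0.5, 0, -1.5),
        (3, 0.5, 3, 0.75 - 2.25),
    ])
    def test_hand_values(self, ploidy, freq, dosage, expected):
        assert dominance_regressor(dosage, ploidy, freq) == pytest.approx(
            expected)

    @pytest.mark.parametrize("freq", [0.1, 0.25, 0.5, 0.8])
    def test_zero_expectation_under_hardy_weinberg(self, freq):
        probs = [(1 - freq) ** 2, 2 * freq * (1 - freq), freq**2]
        q = [dominance_regressor(x, 2, freq) for x in (0, 1, 2)]
        assert sum(p * v for p, v in zip(probs, q)) == pytest.approx(0.0,
                                                                     abs=1e-12)

    def test_out_of_range_dosage_rejected(self):
        with pytest.raises(ValueError):
            dominance_regressor(4, 3, 0.5)


class TestExpectedHybridRegressor:
    def test_reference_case(self):
        q, ex, ex2 = expected_hybrid_regressor(1, 2, 0.5)
        assert ex == pytest.approx(1.5)
        assert ex2 == pytest.approx(17.0 / 6.0)
        assert q == pytest.approx(1.0 / 6.0)

    def test_fixed_cross_equals_pointwise_regressor(self):
        q, _, _ = expected_hybrid_regressor(2, 4, 0.5)
        assert q == pytest.approx(dominance_regressor(3, 3, 0.5))

    def test_matches_exhaustive_gamete_enumeration(self):
        tau3 = lambda f: 2 * f * (1 - f) + 0.25
        xi3 = lambda f: 2 * f + 0.5
        for x2, x4, f in itertools.product(
                range(3), range(5), (0.05, 0.2, 0.5, 0.8)):
            ex_o, ex2_o, dist = gamete_moments(x2, x4)
            q_o = sum(p * (tau3(f) - (x - xi3(f)) ** 2)
                      for x, p in dist.items())
            q, ex, ex2 = expected_hybrid_regressor(x2, x4, f)
            assert ex == pytest.approx(ex_o, abs=1e-12), (x2, x4)
            assert ex2 == pytest.approx(ex2_o, abs=1e-12), (x2, x4)
            assert q == pytest.approx(q_o, abs=1e-12), (x2, x4, f)

    def test_matches_monte_carlo_progeny(self):
        rng = np.random.default_rng(7)
        n = 100_000
        x = simulate_cross_progeny(np.array([1]), np.array([1]), n, rng)
        q = dominance_regressor(x[:, 0].astype(float), 3, 0.3)
        expected, _, _ = expected_hybrid_regressor(1, 2, 0.3)
        se = q.std(ddof=1) / np.sqrt(n)
        assert abs(q.mean() - expected) < 3 * se

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expected_hybrid_regressor(3, 0, 0.5)
        with pytest.raises(ValueError):
            expected_hybrid_regressor(0, 5, 0.5)


def _single_marker_panel(dosages):
    return ParentGenotypes(
        parent_ids=[f"P{i}" for i in range(len(dosages))],
        marker_ids=["chr1:1"], chrom=np.array(["chr1"]), pos=np.array([1]),
        dosages=np.array(dosages, dtype=np.int8)[:, None],
    )


class TestExpectedInbreeding:
    def test_fully_autozygous_cross(self):
        # 2x parent homozygous alt, 4x parent doubled homozygous alt
        geno = _single_marker_panel([2, 2, 0])
        F = expected_inbreeding([("P0", "P1")], geno, np.array([0.5]))
        assert F[0] == pytest.approx(1.0)

    def test_heterozygous_by_duplex_cross(self):
        geno = _single_marker_panel([1, 1, 0])
        F = expected_inbreeding([("P0", "P1")], geno, np.array([0.5]))
        assert F[0] == pytest.approx(-1.0 / 9.0)

    def test_zero_regressor_gives_zero_inbreeding(self):
        # at f = 1/3 the (het x duplex) expected regressor vanishes exactly
        geno = _single_marker_panel([1, 1, 0])
        F = expected_inbreeding([("P0", "P1")], geno, np.array([1.0 / 3.0]))
        assert F[0] == pytest.approx(0.0, abs=1e-12)


class TestExpectedDominanceGrm:
    def test_single_marker_entry(self):
        geno = _single_marker_panel([2, 2, 0, 0])
        D = expected_dominance_grm([("P0", "P1"), ("P2", "P3")], geno,
                                   np.array([0.5]))
        np.testing.assert_allclose(D, 1.0)

    def test_symmetry_and_zero_rows(self, rng):
        dos = rng.binomial(2, 0.4, size=(6, 50))
        f = dos.mean(0) / 2
        ok = (f > 0) & (f < 1)
        geno = ParentGenotypes(
            parent_ids=[f"P{i}" for i in range(6)],
            marker_ids=[f"chr1:{j}" for j in range(ok.sum())],
            chrom=np.array(["chr1"] * ok.sum()),
            pos=np.arange(ok.sum()) + 1, dosages=dos[:, ok])
        crosses = [("P0", "P1"), ("P2", "P3"), ("P4", "P5")]
        D = expected_dominance_grm(crosses, geno)
        np.testing.assert_allclose(D, D.T)


class TestEpistasisGrm:
    def test_entry_is_product_of_parental_relationships(self):
        AD = np.array([[1.0, 0.5], [0.5, 1.0]])
        AT = np.array([[2.0, 1.2], [1.2, 2.0]])
        K = epistasis_grm(AD, AT, [(0, 0), (1, 1)])
        assert K[0, 1] == pytest.approx(0.5 * 1.2)
        assert K[0, 0] == pytest.approx(AD[0, 0] * AT[0, 0])

    def test_principal_submatrix_of_kronecker_is_psd(self, rng):
        dos = rng.binomial(2, 0.5, size=(5, 80))
        f = dos.mean(0) / 2
        ok = (f > 0) & (f < 1)
        AD = additive_grm(dos[:, ok], 2, f[ok])
        AT = additive_grm(2 * dos[:, ok], 4, f[ok])
        crosses = [(i, j) for i in range(5) for j in range(5) if i != j][:12]
        K = epistasis_grm(AD, AT, crosses)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_unindexed_parent_rejected(self):
        with pytest.raises(IndexError):
            epistasis_grm(np.eye(2), np.eye(2), [(0, 5)])


class TestKinshipSet:
    def test_build_is_consistent(self, small_dataset, small_kinships):
        kin = small_kinships
        assert kin.AD.shape == (len(kin.parents2x),) * 2
        assert kin.AT.shape == (len(kin.parents4x),) * 2
        assert len(kin.F) == len(kin.crosses) == kin.Kepi.shape[0]
        np.testing.assert_allclose(kin.Dmat, kin.Dmat.T)

    def test_doubled_diploid_crosses_show_bivalent_autozygosity(self, rng):
        # the two chromosomes of a 4x gamete are IBD copies with probability
        # 1/3 under random bivalent pairing of a doubled diploid, so crosses
        # between unrelated parents have expected inbreeding near
        # (1/3 pair share) x (1/3 IBD) = 1/9, not zero
        n, m = 30, 2000
        f = rng.uniform(0.2, 0.8, size=m)
        dos = rng.binomial(2, f, size=(n, m))
        ok = (dos.sum(0) > 0) & (dos.sum(0) < 2 * n)
        geno = ParentGenotypes(
            parent_ids=[f"P{i}" for i in range(n)],
            marker_ids=[f"chr1:{j + 1}" for j in range(ok.sum())],
            chrom=np.array(["chr1"] * ok.sum()), pos=np.arange(ok.sum()) + 1,
            dosages=dos[:, ok])
        crosses = [(f"P{2 * i}", f"P{2 * i + 1}") for i in range(10)]
        F = expected_inbreeding(crosses, geno)
        assert np.all(F > 0)
        assert 0.05 < F.mean() < 0.15
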