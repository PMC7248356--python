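"""Tests for the four-variable information-decomposition machinery.

Analytic distributions (independent, copies, XOR, binary symmetric
channels) give exact expected values; brute-force summation over small
tables serves as the independent oracle for the derived quantities.
"""

import numpy as np
import pytest

import cannet as cn
from cannet.infodecomp import AXES


def pmf_from_function(fn, p_flip=0.0, rng=None):
    """4-way pmf over binary (X, Z, U, Y) with X, Z, U uniform independent
    and Y = fn(x, z, u), optionally flipped with probability p_flip."""
    table = np.zeros((2, 2, 2, 2))
    for x in (0, 1):
        for z in (0, 1):
            for u in (0, 1):
                y = fn(x, z, u)
                table[x, z, u, y] += 0.125 * (1 - p_flip)
                table[x, z, u, 1 - y] += 0.125 * p_flip
    return cn.JointPMF(table=table)


def random_pmf(seed, shape=(2, 2, 2, 2)):
    rng = np.random.default_rng(seed)
    t = rng.uniform(0.05, 1.0, shape)
    return cn.JointPMF(table=t / t.sum())


def brute_force_entropy(pmf, axes):
    p = pmf.marginal(axes).ravel()
    return float(-sum(pi * np.log2(pi) for pi in p if pi > 0))


def h2(p):
    return -p * np.log2(p) - (1 - p) * np.log2(1 - p)


class TestEntropy:
    def test_uniform_binary_is_one_bit(self):
        pmf = pmf_from_function(lambda x, z, u: x)
        assert cn.entropy(pmf, ["Y"]) == pytest.approx(1.0, abs=1e-12)

    def test_point_mass_is_zero_bits(self):
        t = np.zeros((2, 2, 2, 2)); t[0, 0, 0, 0] = 1.0
        pmf = cn.JointPMF(table=t)
        assert cn.entropy(pmf, ["Y"]) == pytest.approx(0.0, abs=1e-12)

    def test_skewed_marginal(self):
        t = np.zeros((1, 1, 1, 2)); t[0, 0, 0] = [0.25, 0.75]
        pmf = cn.JointPMF(table=t)
        assert cn.entropy(pmf, ["Y"]) == pytest.approx(0.811278, abs=1e-6)

    def test_empty_axis_set_rejected(self):
        with pytest.raises(cn.InfoError):
            cn.entropy(random_pmf(0), [])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_tables(self, seed):
        pmf = random_pmf(seed)
        for axes in (["Y"], ["X", "Y"], ["X", "Z", "U"]):
            assert cn.entropy(pmf, axes) == pytest.approx(
                brute_force_entropy(pmf, axes), abs=1e-12)


class TestConditionalEntropy:
    def test_deterministic_relation_has_no_residual_entropy(self):
        pmf = pmf_from_function(lambda x, z, u: x)
        assert cn.conditional_entropy(pmf, ["Y"], ["X"]) == pytest.approx(0.0, abs=1e-12)

    def test_independence_preserves_entropy(self):
        pmf = pmf_from_function(lambda x, z, u: z)
        assert cn.conditional_entropy(pmf, ["Y"], ["X"]) == pytest.approx(
            cn.entropy(pmf, ["Y"]), abs=1e-12)

    def test_binary_symmetric_channel(self):
        pmf = pmf_from_function(lambda x, z, u: x, p_flip=0.1)
        assert cn.conditional_entropy(pmf, ["Y"], ["X"]) == pytest.approx(
            h2(0.1), abs=1e-6)
        assert cn.conditional_entropy(pmf, ["Y"], ["X"]) == pytest.approx(
            0.468996, abs=1e-6)

    def test_overlapping_axes_rejected(self):
        with pytest.raises(cn.InfoError):
            cn.conditional_entropy(random_pmf(0), ["Y"], ["Y", "X"])


class TestMutualInformation:
    def test_independent_variables_share_nothing(self):
        pmf = pmf_from_function(lambda x, z, u: z)
        assert cn.mutual_information(pmf, ["X"], ["Y"]) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_copy_shares_one_bit(self):
        pmf = pmf_from_function(lambda x, z, u: x)
        assert cn.mutual_information(pmf, ["X"], ["Y"]) == pytest.approx(1.0, abs=1e-12)

    def test_binary_symmetric_channel_capacity(self):
        pmf = pmf_from_function(lambda x, z, u: x, p_flip=0.1)
        assert cn.mutual_information(pmf, ["X"], ["Y"]) == pytest.approx(
            1.0 - h2(0.1), abs=1e-6)
        assert cn.mutual_information(pmf, ["X"], ["Y"]) == pytest.approx(
            0.531004, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry(self, seed):
        pmf = random_pmf(seed)
        assert cn.mutual_information(pmf, ["X"], ["Y"]) == pytest.approx(
            cn.mutual_information(pmf, ["Y"], ["X"]), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_chain_rule(self, seed):
        pmf = random_pmf(seed)
        lhs = (cn.mutual_information(pmf, ["Y"], ["X"])
               + cn.conditional_mutual_information(pmf, ["Z"], ["Y"], ["X"])
               + cn.conditional_mutual_information(pmf, ["U"], ["Y"], ["X", "Z"]))
        rhs = cn.mutual_information(pmf, ["Y"], ["X", "Z", "U"])
        assert lhs == pytest.approx(rhs, abs=1e-12)


class TestConditionalMutualInformation:
    def test_independent_variables(self):
        pmf = random_pmf(3)
        # product distribution: build an actually independent table
        t = np.ones((2, 2, 2, 2)) / 16.0
        pmf = cn.JointPMF(table=t)
        assert cn.conditional_mutual_information(pmf, ["X"], ["Y"], ["Z", "U"]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_xor_revealed_by_conditioning(self):
        pmf = pmf_from_function(lambda x, z, u: x ^ z)
        assert cn.mutual_information(pmf, ["X"], ["Y"]) == pytest.approx(0.0, abs=1e-12)
        assert cn.conditional_mutual_information(pmf, ["X"], ["Y"], ["Z"]) == \
            pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_triple_sum(self, seed):
        pmf = random_pmf(seed, shape=(2, 2, 1, 2))
        # oracle: I(X;Y|Z) = sum p(x,y,z) log [p(z) p(x,y,z) / (p(x,z) p(y,z))]
        p = pmf.table.sum(axis=2)  # collapse unit U axis -> (X, Z, Y)
        total = 0.0
        for x in range(2):
            for z in range(2):
                for y in range(2):
                    pxzy = p[x, z, y]
                    pz = p[:, z, :].sum()
                    pxz = p[x, z, :].sum()
                    pzy = p[:, z, y].sum()
                    total += pxzy * np.log2(pz * pxzy / (pxz * pzy))
        assert cn.conditional_mutual_information(pmf, ["X"], ["Y"], ["Z"]) == \
            pytest.approx(total, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_non_negative_on_exact_pmfs(self, seed):
        pmf = random_pmf(seed, shape=(3, 3, 2, 3))
        for a, b, g in (("X", "Y", ["Z", "U"]), ("Z", "Y", ["X", "U"]),
                        ("U", "Y", ["X", "Z"])):
            assert cn.conditional_mutual_information(pmf, [a], [b], g) >= -1e-12


class TestFourWayInteraction:
    def test_fully_independent_vanishes_and_expressions_agree(self):
        pmf = cn.JointPMF(table=np.ones((2, 2, 2, 2)) / 16.0)
        info = cn.four_way_interaction(pmf)
        assert info.value == pytest.approx(0.0, abs=1e-12)
        assert info.max_discrepancy == pytest.approx(0.0, abs=1e-12)

    def test_redundant_copies_give_plus_one_bit(self):
        # Y = X = Z uniform binary, U independent
        pmf = pmf_from_function(lambda x, z, u: x)
        t = pmf.table.copy()
        # force Z = X
        t2 = np.zeros_like(t)
        for x in (0, 1):
            for u in (0, 1):
                t2[x, x, u, x] = 0.25
        info = cn.four_way_interaction(cn.JointPMF(table=t2))
        assert info.value == pytest.approx(1.0, abs=1e-12)

    def test_xor_synergy_gives_minus_one_bit(self):
        pmf = pmf_from_function(lambda x, z, u: x ^ z)
        info = cn.four_way_interaction(pmf)
        assert info.value == pytest.approx(-1.0, abs=1e-12)

    def test_expressions_differ_in_general(self):
        # for XOR the X-anchored and Z-anchored forms agree but the
        # U-anchored one does not: the diagnostic must expose the spread
        pmf = pmf_from_function(lambda x, z, u: x ^ z)
        info = cn.four_way_interaction(pmf)
        assert info.max_discrepancy == pytest.approx(1.0, abs=1e-12)


class TestDecomposition:
    def test_independent_output(self):
        rng = np.random.default_rng(0)
        py = np.array([0.3, 0.7])
        pxzu = rng.uniform(0.1, 1.0, (2, 2, 2))
        pxzu /= pxzu.sum()
        table = pxzu[..., None] * py[None, None, None, :]
        rep = cn.decompose_output_entropy(cn.JointPMF(table=table))
        assert rep.interaction == pytest.approx(0.0, abs=1e-12)
        assert rep.i_yx_given_zu == pytest.approx(0.0, abs=1e-12)
        assert rep.h_y_given_xzu == pytest.approx(rep.h_y, abs=1e-12)
        assert rep.residual == pytest.approx(0.0, abs=1e-12)

    def test_xor_of_contexts_has_minus_one_bit_residual(self):
        # Y = Z xor U with X independent: the five terms overshoot H(Y)
        pmf = pmf_from_function(lambda x, z, u: z ^ u)
        rep = cn.decompose_output_entropy(pmf)
        assert rep.interaction == pytest.approx(0.0, abs=1e-12)
        assert rep.i_yx_given_zu == pytest.approx(0.0, abs=1e-12)
        assert rep.i_yz_given_xu == pytest.approx(1.0, abs=1e-12)
        assert rep.i_yu_given_xz == pytest.approx(1.0, abs=1e-12)
        assert rep.h_y_given_xzu == pytest.approx(0.0, abs=1e-12)
        assert rep.h_y == pytest.approx(1.0, abs=1e-12)
        assert rep.residual == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_residual_identity(self, seed):
        # residual = I(Y;Z|X) - I(Y;Z|X,U) analytically
        pmf = random_pmf(seed)
        rep = cn.decompose_output_entropy(pmf)
        expected = (cn.conditional_mutual_information(pmf, ["Z"], ["Y"], ["X"])
                    - cn.conditional_mutual_information(pmf, ["Z"], ["Y"], ["X", "U"]))
        assert rep.residual == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_phi_selection_recovers_pairwise_information(self, seed):
        pmf = random_pmf(seed)
        phis = cn.ObjectiveWeights(phi0=1, phi1=1, phi2=0, phi3=0, phi4=0)
        rep = cn.decompose_output_entropy(pmf, phis)
        assert rep.objective == pytest.approx(
            cn.mutual_information(pmf, ["Y"], ["X"]), abs=1e-12)

    def test_invalid_phi_rejected(self):
        with pytest.raises(cn.InfoError):
            cn.ObjectiveWeights(phi0=1.5)

    def test_report_round_trip(self, tmp_path):
        rep = cn.decompose_output_entropy(random_pmf(1))
        df = rep.to_frame()
        assert set(df["quantity"]) >= {"H(Y)", "residual", "F"}
        assert "I(Y;X;Z;U)" in rep.to_json()


class TestEstimator:
    def test_constant_samples_give_point_mass(self):
        c = np.ones(50)
        pmf = cn.estimate_pmf(c, c, c, c)
        assert pmf.table.sum() == pytest.approx(1.0, abs=1e-12)
        assert cn.entropy(pmf, ["Y"]) == pytest.approx(0.0, abs=1e-12)

    def test_normalization_for_any_input(self):
        rng = np.random.default_rng(0)
        pmf = cn.estimate_pmf(*(rng.standard_normal(500) for _ in range(4)))
        assert pmf.table.sum() == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_mutual_information(self):
        # corr(X, Y) = 0.9 -> I = -0.5 log2(1 - rho^2) = 1.1979 bits;
        # 32 equal-width bins keep the discretization loss inside the
        # 0.1-bit budget at this sample size
        rng = np.random.default_rng(42)
        n, rho = 100_000, 0.9
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
        z = rng.standard_normal(n)
        u = rng.standard_normal(n)
        pmf = cn.estimate_pmf(x, z, u, y, n_bins=32)
        est = cn.mutual_information(pmf, ["X"], ["Y"])
        assert est == pytest.approx(-0.5 * np.log2(1 - rho ** 2), abs=0.1)

    def test_coarser_binning_does_not_inflate_information(self):
        rng = np.random.default_rng(7)
        n = 20_000
        x = rng.standard_normal(n)
        y = 0.8 * x + 0.6 * rng.standard_normal(n)
        z = rng.standard_normal(n)
        u = rng.standard_normal(n)
        fine = cn.mutual_information(cn.estimate_pmf(x, z, u, y, n_bins=16), ["X"], ["Y"])
        coarse = cn.mutual_information(cn.estimate_pmf(x, z, u, y, n_bins=4), ["X"], ["Y"])
        assert coarse <= fine + 0.02

    def test_zero_samples_rejected(self):
        with pytest.raises(cn.InfoError):
            cn.estimate_pmf(np.array([]), np.array([]), np.array([]), np.array([]))

    def test_pmf_csv_round_trip(self, tmp_path):
        pmf = random_pmf(5)
        path = tmp_path / "pmf.csv"
        pmf.to_csv(path)
        back = cn.JointPMF.from_csv(path)
        assert np.allclose(back.table, pmf.table, atol=1e-15)
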