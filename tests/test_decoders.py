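"""Hard, naive and generalized Bradley-Terry decoding."""

import numpy as np
import pytest

from mcrum import (
    CodingMatrix,
    GBTProblem,
    ap_matrix,
    code_distance,
    consistent_gbt_observations,
    decode_gbt,
    decode_hard,
    decode_naive,
    decode_naive_counted,
    gbt_objective,
    ovr_matrix,
)

from conftest import random_valid_code


def naive_product_oracle(code, g):
    """Direct product-then-normalize implementation (no logarithms)."""
    g = np.clip(np.asarray(g, dtype=float), 1e-12, 1 - 1e-12)
    mass = np.ones(code.K)
    for k in range(code.K):
        for i in range(code.L):
            m = int(code.entries[k, i])
            if m == 1:
                mass[k] *= g[i]
            elif m == 0:
                mass[k] *= 1.0 - g[i]
    return mass / mass.sum()


def nearest_codeword_oracle(code, g, cutoff=0.5):
    """Exhaustive nearest-codeword search, written independently."""
    word = [1 if v >= cutoff else 0 for v in g]
    best_k, best_d = 0, float("inf")
    for k in range(code.K):
        d = sum(
            0.5 if (a == -1 or b == -1) else (0.0 if a == b else 1.0)
            for a, b in zip(code.entries[k], word)
        )
        if d < best_d:
            best_k, best_d = k, d
    return best_k


class TestHardDecoding:
    def test_exact_codeword_recovers_class(self):
        code = ovr_matrix(4)
        for k in range(4):
            g = (code.entries[k] == 1).astype(float)
            assert decode_hard(code, g) == k

    def test_ap3_worked_distances(self):
        # binarized (1,1,0) vs rows of the 3-class all-pairs code:
        # distances 0.5, 2.5, 1.5 -> class index 0
        code = ap_matrix(3)
        g = [1.0, 1.0, 0.0]
        dists = [code_distance(code.row(k), [1, 1, 0]) for k in range(3)]
        assert dists == [0.5, 2.5, 1.5]
        assert decode_hard(code, g) == 0

    def test_tie_breaks_to_smallest_index(self):
        # OVR K=2, binarized (1,1): both rows at distance 1
        assert decode_hard(ovr_matrix(2), [1.0, 1.0]) == 0

    def test_cutoff_validation(self):
        with pytest.raises(ValueError):
            decode_hard(ovr_matrix(3), [0.1, 0.2, 0.3], cutoff=1.5)


class TestNaiveDecoding:
    def test_ap3_worked_posterior(self):
        # unnormalized masses 0.2*0.5, 0.8*0.9, 0.5*0.1 -> /0.87
        p = decode_naive(ap_matrix(3), [0.2, 0.5, 0.9])
        np.testing.assert_allclose(p, [0.10 / 0.87, 0.72 / 0.87, 0.05 / 0.87],
                                   atol=1e-12)
        # class-2 mass is (1 - g1) * g3 under this decomposition
        assert p[1] == pytest.approx(0.8 * 0.9 / 0.87)

    def test_uninformative_outputs_give_uniform(self):
        for K in (2, 3, 5):
            p = decode_naive(ovr_matrix(K), np.full(K, 0.5))
            np.testing.assert_allclose(p, np.full(K, 1.0 / K), atol=1e-12)

    def test_single_column_reduces_to_binary(self):
        code = CodingMatrix([[1], [0]])
        for g1 in (0.1, 0.5, 0.93):
            np.testing.assert_allclose(
                decode_naive(code, [g1]), [g1, 1 - g1], atol=1e-12
            )

    def test_matches_product_oracle_on_random_instances(self):
        rng = np.random.default_rng(202)
        for _ in range(300):
            K = int(rng.integers(2, 7))
            L = int(rng.integers(K, 16))  # enough columns for K distinct rows
            sparse = bool(rng.integers(0, 2))
            if K == 2:
                L = 2  # only two distinct mixed columns exist
            elif sparse:
                L = min(L, 3**K - 2 ** (K + 1) + 1)  # distinct mixed sparse columns
            else:
                L = min(L, 2**K - 2)  # distinct mixed dense columns
            code = random_valid_code(rng, K, L, sparse=sparse)
            g = rng.uniform(0, 1, size=L)
            np.testing.assert_allclose(
                decode_naive(code, g), naive_product_oracle(code, g), atol=1e-12
            )

    def test_monotone_in_positive_outputs(self):
        code = ap_matrix(3)
        g = np.array([0.4, 0.6, 0.3])
        base = decode_naive(code, g)
        g2 = g.copy()
        g2[0] += 0.2  # column 0 has class 0 positive
        assert decode_naive(code, g2)[0] > base[0]

    def test_extreme_outputs_stay_finite(self):
        p = decode_naive(ovr_matrix(3), [1.0, 0.0, 0.0])
        assert np.all(np.isfinite(p)) and p.sum() == pytest.approx(1.0)

    def test_counted_variant_matches_and_counts_non_delta(self):
        code = ap_matrix(4)
        g = np.linspace(0.1, 0.9, code.L)
        p_fast = decode_naive(code, g)
        p_slow, ops = decode_naive_counted(code, g)
        np.testing.assert_allclose(p_fast, p_slow, atol=1e-12)
        assert ops == int(np.sum(code.entries != -1))


class TestClassPermutationEquivariance:
    def test_soft_decoders_commute_with_class_relabeling(self):
        rng = np.random.default_rng(7)
        code = ap_matrix(4)
        g = rng.uniform(0.05, 0.95, size=code.L)
        perm = np.array([2, 0, 3, 1])
        permuted = CodingMatrix(code.entries[perm])
        p = decode_naive(code, g)
        q = decode_naive(permuted, g)
        np.testing.assert_allclose(q, p[perm], atol=1e-12)
        r = decode_gbt(consistent_gbt_observations([0.4, 0.3, 0.2, 0.1], code))
        r_perm = decode_gbt(
            consistent_gbt_observations(np.array([0.4, 0.3, 0.2, 0.1])[perm], permuted)
        )
        np.testing.assert_allclose(r_perm.posterior, r.posterior[perm], atol=1e-6)


class TestGBTDecoding:
    def test_single_pair_solved_exactly(self):
        prob = GBTProblem([[0]], [[1]], [1.0], [0.7])
        res = decode_gbt(prob)
        np.testing.assert_allclose(res.posterior, [0.7, 0.3], atol=1e-7)
        assert res.converged

    def test_uniform_fixed_point(self):
        prob = GBTProblem.from_code(ap_matrix(3), [0.5, 0.5, 0.5])
        np.testing.assert_allclose(decode_gbt(prob).posterior, np.full(3, 1 / 3),
                                   atol=1e-9)

    def test_consistent_ap_observations_recover_truth(self):
        p_true = np.array([0.5, 0.3, 0.2])
        prob = consistent_gbt_observations(p_true, ap_matrix(3))
        np.testing.assert_allclose(prob.observations, [0.625, 0.714286, 0.6],
                                   atol=1e-6)
        res = decode_gbt(prob)
        assert res.converged and res.n_iter <= 1000
        np.testing.assert_allclose(res.posterior, p_true, atol=1e-4)

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(5)
        for code in (ap_matrix(4), ovr_matrix(4)):
            prob = GBTProblem.from_code(code, rng.uniform(0.05, 0.95, size=code.L),
                                        weights=rng.integers(10, 100, size=code.L))
            res = decode_gbt(prob)
            diffs = np.diff(res.objective)
            assert np.all(diffs <= 1e-9)

    def test_objective_matches_definition_at_truth(self):
        # at a consistency-constructed solution the KL-style objective equals
        # the entropy term: -sum_i N_i * H(r_i) is its minimum value
        p_true = np.array([0.4, 0.35, 0.25])
        prob = consistent_gbt_observations(p_true, ap_matrix(3))
        r = prob.observations
        expected = -np.sum(r * np.log(r) + (1 - r) * np.log(1 - r))
        assert gbt_objective(prob, p_true) == pytest.approx(expected, rel=1e-12)

    def test_weights_matter(self):
        # conflicting observations: the heavier classifier dominates
        code = ovr_matrix(2)
        heavy_first = GBTProblem.from_code(code, [0.9, 0.9], weights=[100, 1])
        p = decode_gbt(heavy_first).posterior
        assert p[0] > 0.5

    def test_invalid_problem_rejected(self):
        with pytest.raises(ValueError):
            GBTProblem([[0]], [[0]], [1.0], [0.5])  # overlapping sets
        with pytest.raises(ValueError):
            GBTProblem([[0]], [[]], [1.0], [0.5])  # empty negative set


class TestBinaryDegeneracy:
    def test_all_decoders_agree_on_single_column_code(self):
        code = CodingMatrix([[1], [0]])
        for g1 in (0.12, 0.49, 0.51, 0.97):
            naive = decode_naive(code, [g1])
            gbt = decode_gbt(GBTProblem.from_code(code, [g1])).posterior
            hard = decode_hard(code, [g1])
            np.testing.assert_allclose(naive, [g1, 1 - g1], atol=1e-12)
            np.testing.assert_allclose(gbt, [g1, 1 - g1], atol=1e-6)
            assert hard == int(np.argmax(naive)) == int(np.argmax(gbt))
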