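from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import linalg

from ahp_needs.judgments import JudgmentMatrix
from ahp_needs.prioritize import (
    UnsupportedOrderError,
    consistency_ratio,
    derive_priorities,
    suggest_revision,
)
from ahp_needs.scale import SAATY_FRACTIONS


def _matrix(entries, n, node="m"):
    return JudgmentMatrix(node, [f"i{k}" for k in range(n)], entries)


def _random_saaty(rng, n, node="m"):
    entries = {
        (i, j): SAATY_FRACTIONS[int(rng.integers(0, len(SAATY_FRACTIONS)))]
        for i in range(n)
        for j in range(i + 1, n)
    }
    return _matrix(entries, n, node)


def _consistent_from(w):
    n = len(w)
    entries = {(i, j): Fraction(w[i], w[j]) for i in range(n) for j in range(i + 1, n)}
    return _matrix(entries, n)


class TestDerivation:
    @pytest.mark.parametrize("method", ["eigenvector", "geometric_mean"])
    def test_unit_matrix_gives_uniform_weights(self, method):
        m = _matrix({(0, 1): 1, (0, 2): 1, (1, 2): 1}, 3)
        res = derive_priorities(m, method)
        assert np.allclose(res.weights, 1 / 3)
        assert res.lambda_max == pytest.approx(3, abs=1e-12)
        assert res.cr == pytest.approx(0, abs=1e-12)

    @pytest.mark.parametrize("method", ["eigenvector", "geometric_mean"])
    def test_consistent_matrix_recovers_generating_weights(self, method):
        m = _consistent_from([6, 3, 1])  # w = (0.6, 0.3, 0.1)
        res = derive_priorities(m, method)
        assert np.allclose(res.weights, [0.6, 0.3, 0.1], atol=1e-12)
        assert res.cr == pytest.approx(0, abs=1e-12)

    def test_powers_of_two_matrix(self):
        # [[1,2,4],[1/2,1,2],[1/4,1/2,1]] is consistent: w = (4/7, 2/7, 1/7)
        m = _matrix({(0, 1): 2, (0, 2): 4, (1, 2): 2}, 3)
        for method in ("eigenvector", "geometric_mean"):
            res = derive_priorities(m, method)
            assert np.allclose(res.weights, [4 / 7, 2 / 7, 1 / 7], atol=1e-12)
            assert res.cr == pytest.approx(0, abs=1e-12)

    def test_eigenvector_matches_dense_eigensolver(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            m = _random_saaty(rng, 4)
            res = derive_priorities(m)
            vals, vecs = linalg.eig(m.array())
            k = np.argmax(vals.real)
            v = np.abs(vecs[:, k].real)
            v /= v.sum()
            assert np.max(np.abs(res.weights - v)) < 1e-8
            assert res.lambda_max == pytest.approx(float(vals.real[k]), abs=1e-8)

    def test_methods_agree_in_rank_on_near_consistent(self):
        # pooled over 200 seeded noisy matrices the two derivations give
        # essentially identical weight orderings
        from scipy import stats

        rng = np.random.default_rng(3)
        all_e, all_g = [], []
        for _ in range(200):
            n = int(rng.integers(3, 8))
            w = rng.dirichlet(np.ones(n))
            entries = {
                (i, j): Fraction(
                    float(w[i] / w[j] * np.exp(rng.normal(0, 0.1)))
                )
                for i in range(n)
                for j in range(i + 1, n)
            }
            m = _matrix(entries, n)
            all_e.extend(derive_priorities(m, "eigenvector").weights)
            all_g.extend(derive_priorities(m, "geometric_mean").weights)
        assert stats.spearmanr(all_e, all_g)[0] > 0.99

    def test_non_reciprocal_rejected(self):
        A = np.array([[1.0, 2.0], [0.4, 1.0]])
        with pytest.raises(ValueError, match="reciprocal"):
            derive_priorities(A)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 7))
    def test_lambda_max_at_least_n_and_weights_normalized(self, seed, n):
        rng = np.random.default_rng(seed)
        res = derive_priorities(_random_saaty(rng, n))
        assert res.lambda_max >= n - 1e-9
        assert res.weights.sum() == pytest.approx(1, abs=1e-9)
        assert (res.weights > 0).all()

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.permutations([0, 1, 2, 3]))
    def test_permutation_equivariance(self, seed, perm):
        rng = np.random.default_rng(seed)
        m = _random_saaty(rng, 4)
        perm = list(perm)
        entries = {}
        for i in range(4):
            for j in range(i + 1, 4):
                pi, pj = perm[i], perm[j]
                v = m.entry(pi, pj)
                entries[(i, j)] = v
        permuted = _matrix(entries, 4)
        w, wp = derive_priorities(m).weights, derive_priorities(permuted).weights
        assert np.allclose(wp, w[perm], atol=1e-9)


class TestConsistencyRatio:
    def test_any_2x2_is_consistent(self):
        m = _matrix({(0, 1): 9}, 2)
        res = derive_priorities(m)
        assert res.cr == 0 and res.acceptable

    def test_consistent_4x4_zero_ci(self):
        m = _consistent_from([8, 4, 2, 1])
        res = derive_priorities(m)
        assert res.ci == pytest.approx(0, abs=1e-12)
        assert res.cr == pytest.approx(0, abs=1e-12)

    def test_maximally_cyclic_3x3_rejected(self):
        # a beats b 9:1, b beats c 9:1, c beats a 9:1
        m = _matrix({(0, 1): 9, (0, 2): Fraction(1, 9), (1, 2): 9}, 3)
        res = derive_priorities(m)
        assert res.cr > 0.10 and not res.acceptable
        # against a dense-solver oracle
        lam = float(np.max(linalg.eigvals(m.array()).real))
        assert res.lambda_max == pytest.approx(lam, abs=1e-8)

    def test_order_above_table_rejected(self):
        with pytest.raises(UnsupportedOrderError):
            consistency_ratio(11, 12.0)

    def test_cr_zero_iff_consistent(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            w = rng.integers(1, 10, size=4)
            res = derive_priorities(_consistent_from(list(w)))
            assert res.cr < 1e-9
        inconsistent = _matrix({(0, 1): 3, (0, 2): Fraction(1, 3), (1, 2): 3}, 3)
        assert derive_priorities(inconsistent).cr > 1e-6


class TestSuggestRevision:
    def test_acceptable_matrix_is_noop(self):
        assert suggest_revision(_consistent_from([6, 3, 1])) is None

    def test_single_perturbed_entry_is_found(self):
        # consistent base w = (8,4,2,1)/15, corrupt exactly one entry
        base = {(i, j): Fraction(2) ** (j - i) for i in range(4) for j in range(i + 1, 4)}
        corrupted = dict(base)
        corrupted[(0, 3)] = Fraction(1, 9)  # truth is 8
        m = _matrix(corrupted, 4)
        res = derive_priorities(m)
        assert not res.acceptable
        suggestion = suggest_revision(m)
        assert suggestion.pair == ("i0", "i3")
        assert suggestion.suggested in SAATY_FRACTIONS
        # brute force: no other single pair deviates more under w
        A, w = m.array(), res.weights
        devs = {
            (i, j): abs(np.log(A[i, j] * w[j] / w[i]))
            for i in range(4)
            for j in range(i + 1, 4)
        }
        assert max(devs, key=devs.get) == (0, 3)

    def test_applying_suggestion_reduces_cr(self):
        rng = np.random.default_rng(21)
        tested = 0
        while tested < 10:
            m = _random_saaty(rng, 5)
            before = derive_priorities(m)
            if before.acceptable:
                continue
            tested += 1
            s = suggest_revision(m)
            i, j = m.items.index(s.pair[0]), m.items.index(s.pair[1])
            entries = {
                (a, b): m.entry(a, b) for a in range(5) for b in range(a + 1, 5)
            }
            entries[(i, j)] = s.suggested
            after = derive_priorities(_matrix(entries, 5))
            assert after.cr <= before.cr + 1e-12
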