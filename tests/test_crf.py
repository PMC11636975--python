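"""Linear-chain CRF: scores, exact partition, Viterbi, gradients.

The independent oracle is exhaustive enumeration of all K^L paths.
"""

import itertools

import numpy as np
import pytest

import dualner as d
from dualner.crf import CrfParams, bio_constraint_mask, bio_start_mask, nll_gradients


def random_instance(seed, K=None, L=None, h=3):
    rng = np.random.default_rng(seed)
    K = K or int(rng.integers(2, 6))
    L = L or int(rng.integers(1, 8))
    params = CrfParams(
        proj=rng.normal(size=(h, K)),
        proj_bias=rng.normal(size=K),
        transitions=rng.normal(size=(K, K)),
        start=rng.normal(size=K),
        stop=rng.normal(size=K),
    )
    e = rng.normal(size=(L, K))
    return params, e, K, L


def enumerate_scores(params, e):
    L, K = e.shape
    return {
        y: d.path_score(params, e, np.array(y))
        for y in itertools.product(range(K), repeat=L)
    }


def zero_params(K, h=2):
    return CrfParams(
        np.zeros((h, K)), np.zeros(K), np.zeros((K, K)), np.zeros(K), np.zeros(K)
    )


class TestEmissions:
    def test_zero_projection_gives_bias_rows(self, rng):
        p = zero_params(4, h=3)
        p.proj_bias[:] = [1.0, -2.0, 0.5, 3.0]
        e = d.emissions(p, rng.normal(size=(5, 3)))
        assert np.allclose(e, np.tile(p.proj_bias, (5, 1)))

    def test_identity_projection(self, rng):
        p = zero_params(3, h=3)
        p.proj[:] = np.eye(3)
        p.proj_bias[:] = [0.1, 0.2, 0.3]
        v = rng.normal(size=(4, 3))
        assert np.allclose(d.emissions(p, v), v + p.proj_bias)

    def test_matches_row_by_row_scalar_oracle(self, rng):
        p = CrfParams(
            rng.normal(size=(4, 3)),
            rng.normal(size=3),
            np.zeros((3, 3)),
            np.zeros(3),
            np.zeros(3),
        )
        v = rng.normal(size=(5, 4))
        e = d.emissions(p, v)
        for i in range(5):
            for k in range(3):
                expect = sum(v[i, a] * p.proj[a, k] for a in range(4)) + p.proj_bias[k]
                assert abs(e[i, k] - expect) < 1e-9

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            d.emissions(zero_params(3, h=4), rng.normal(size=(5, 7)))


class TestPathScore:
    def test_length_one(self, rng):
        p, e, K, _ = random_instance(0, L=1)
        for y in range(K):
            expect = p.start[y] + e[0, y] + p.stop[y]
            assert abs(d.path_score(p, e, np.array([y])) - expect) < 1e-12

    def test_all_zero_params_score_zero(self):
        p = zero_params(3)
        e = np.zeros((4, 3))
        for y in itertools.product(range(3), repeat=2):
            assert d.path_score(p, e[:2], np.array(y)) == 0.0

    def test_term_by_term_hand_sum(self):
        rng = np.random.default_rng(7)
        p, e, K, L = random_instance(7, K=3, L=4)
        y = rng.integers(0, K, size=L)
        expect = p.start[y[0]] + p.stop[y[-1]]
        for i in range(L):
            expect += e[i, y[i]]
        for i in range(1, L):
            expect += p.transitions[y[i - 1], y[i]]
        assert abs(d.path_score(p, e, y) - expect) < 1e-12

    def test_out_of_range_tag(self):
        p, e, K, L = random_instance(1)
        with pytest.raises(IndexError):
            d.path_score(p, e, np.full(L, K))


class TestLogPartition:
    def test_length_one_is_logsumexp(self):
        p, e, K, _ = random_instance(2, L=1)
        scores = p.start + e[0] + p.stop
        expect = np.log(np.exp(scores - scores.max()).sum()) + scores.max()
        assert abs(d.log_partition(p, e[:1]) - expect) < 1e-10

    def test_uniform_paths_k2_l3(self):
        assert abs(d.log_partition(zero_params(2), np.zeros((3, 2))) - 3 * np.log(2)) < 1e-12

    def test_brute_force_k4_l5(self):
        p, e, _, _ = random_instance(3, K=4, L=5)
        scores = np.array(list(enumerate_scores(p, e).values()))
        m = scores.max()
        expect = m + np.log(np.exp(scores - m).sum())
        assert abs(d.log_partition(p, e) - expect) < 1e-6


class TestNll:
    def test_single_tag_universe_nll_zero(self):
        p, e, _, L = random_instance(4, K=1, L=4)
        assert abs(d.nll(p, e, np.zeros(L, dtype=int))) < 1e-10

    def test_path_probabilities_sum_to_one(self):
        p, e, _, _ = random_instance(5, K=3, L=3)
        lz = d.log_partition(p, e)
        total = sum(np.exp(s - lz) for s in enumerate_scores(p, e).values())
        assert abs(total - 1.0) < 1e-9

    def test_viterbi_path_has_minimal_nll(self):
        p, e, K, L = random_instance(6, K=3, L=4)
        best, _ = d.viterbi_decode(p, e)
        best_nll = d.nll(p, e, best)
        rng = np.random.default_rng(0)
        for _ in range(20):
            other = rng.integers(0, K, size=L)
            assert best_nll <= d.nll(p, e, other) + 1e-10

    def test_nll_non_negative(self):
        for seed in range(10):
            p, e, K, L = random_instance(100 + seed)
            y = np.random.default_rng(seed).integers(0, K, size=L)
            assert d.nll(p, e, y) >= -1e-10


class TestViterbi:
    def test_length_one_argmax(self):
        p, e, _, _ = random_instance(8, L=1)
        path, score = d.viterbi_decode(p, e[:1])
        expect = int(np.argmax(p.start + e[0] + p.stop))
        assert path[0] == expect

    def test_brute_force_k4_l6(self):
        p, e, _, _ = random_instance(9, K=4, L=6)
        scores = enumerate_scores(p, e)
        best_path = max(scores, key=scores.get)
        path, score = d.viterbi_decode(p, e)
        assert tuple(path) == best_path
        assert abs(score - scores[best_path]) < 1e-9

    def test_tie_break_prefers_lowest_index(self):
        # all-zero parameters: every path ties at 0; the deterministic rule
        # returns the lexicographically smallest index sequence
        path, score = d.viterbi_decode(zero_params(3), np.zeros((4, 3)))
        assert np.array_equal(path, np.zeros(4, dtype=int))
        assert score == 0.0

    def test_score_equals_path_score_of_returned_path(self):
        for seed in range(5):
            p, e, _, _ = random_instance(200 + seed)
            path, score = d.viterbi_decode(p, e)
            assert abs(score - d.path_score(p, e, path)) < 1e-9

    def test_constrained_decode_respects_bio(self):
        ts = d.TagSet(("X", "Y"))
        rng = np.random.default_rng(3)
        p = CrfParams(
            rng.normal(size=(2, 5)),
            rng.normal(size=5),
            rng.normal(size=(5, 5)) * 3,
            rng.normal(size=5),
            rng.normal(size=5),
        )
        mask = bio_constraint_mask(ts)
        start = bio_start_mask(ts)
        for trial in range(10):
            e = np.random.default_rng(trial).normal(scale=4, size=(6, 5))
            path, _ = d.viterbi_decode(p, e, mask, start)
            tags = [ts.tag_of(int(i)) for i in path]
            seq = d.LabeledSequence(["x"] * 6, tags)
            assert d.validate_bio(seq) == []


def test_oracle_equivalence_many_random_instances():
    """Viterbi and log-partition match exhaustive enumeration, K<=5, L<=7."""
    for seed in range(30):
        p, e, K, L = random_instance(seed)
        scores = enumerate_scores(p, e)
        arr = np.array(list(scores.values()))
        m = arr.max()
        lz = m + np.log(np.exp(arr - m).sum())
        assert abs(d.log_partition(p, e) - lz) < 1e-6
        path, score = d.viterbi_decode(p, e)
        assert abs(score - arr.max()) < 1e-6


def test_nll_gradient_matches_finite_differences(rng):
    p, e, K, L = random_instance(42, K=4, L=5)
    y = rng.integers(0, K, size=L)
    g = nll_gradients(p, e, y)
    assert abs(g.value - d.nll(p, e, y)) < 1e-10
    eps = 1e-6
    for idx in [(0, 1), (2, 3), (4, 0)]:
        e2, e3 = e.copy(), e.copy()
        e2[idx] += eps
        e3[idx] -= eps
        fd = (d.nll(p, e2, y) - d.nll(p, e3, y)) / (2 * eps)
        assert abs(fd - g.d_emissions[idx]) < 1e-4
    for idx in [(0, 0), (1, 3), (3, 2)]:
        hi = CrfParams(p.proj, p.proj_bias, p.transitions.copy(), p.start, p.stop)
        lo = CrfParams(p.proj, p.proj_bias, p.transitions.copy(), p.start, p.stop)
        hi.transitions[idx] += eps
        lo.transitions[idx] -= eps
        fd = (d.nll(hi, e, y) - d.nll(lo, e, y)) / (2 * eps)
        assert abs(fd - g.d_transitions[idx]) < 1e-4
    for vec, gv in [(p.start, g.d_start), (p.stop, g.d_stop)]:
        orig = vec[1]
        vec[1] = orig + eps
        hi = d.nll(p, e, y)
        vec[1] = orig - eps
        lo = d.nll(p, e, y)
        vec[1] = orig
        assert abs((hi - lo) / (2 * eps) - gv[1]) < 1e-4
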