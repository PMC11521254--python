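import numpy as np
import pytest

from cgflow.containers import ExpressionMatrix
from cgflow.realspace import (
    coarse_grain_step,
    correlation_matrix,
    greedy_pair,
    initial_state,
    realspace_flow,
)


def brute_force_greedy(corr, mode="signed"):
    """Independent oracle: repeated argmax with lexicographic tie-break."""
    c = np.abs(corr) if mode == "absolute" else corr.copy()
    n = c.shape[0]
    remaining = set(range(n))
    pairs = []
    while len(remaining) >= 2:
        best = None
        for i in sorted(remaining):
            for j in sorted(remaining):
                if j <= i:
                    continue
                if best is None or c[i, j] > best[0]:
                    best = (c[i, j], i, j)
        _, i, j = best
        pairs.append((i, j))
        remaining -= {i, j}
    leftover = remaining.pop() if remaining else None
    return pairs, leftover


def std_expr(x):
    x = np.asarray(x, dtype=float)
    x = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
    return ExpressionMatrix(
        x, [f"g{i}" for i in range(x.shape[0])], [f"c{i}" for i in range(x.shape[1])],
        standardized=True,
    )


class TestCorrelationMatrix:
    def test_identical_and_negated_rows(self, rng):
        u = rng.standard_normal(20)
        c = correlation_matrix(np.vstack([u, u, -u]))
        assert c.values[0, 1] == pytest.approx(1.0)
        assert c.values[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(c.values), 1.0)

    def test_matches_direct_pearson_formula(self):
        x = np.array(
            [
                [1.0, 3.0, 2.0, 5.0, 4.0],
                [2.0, 1.0, 4.0, 3.0, 5.0],
                [5.0, 4.0, 1.0, 2.0, 2.0],
            ]
        )
        c = correlation_matrix(x).values
        for i in range(3):
            for j in range(3):
                xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert c[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_variable_named(self):
        x = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="v0"):
            correlation_matrix(x)


class TestGreedyPair:
    def test_clear_two_pair_structure(self):
        c = np.full((4, 4), 0.1)
        np.fill_diagonal(c, 1.0)
        c[0, 1] = c[1, 0] = 0.9
        c[2, 3] = c[3, 2] = 0.8
        pairs, leftover = greedy_pair(c)
        assert pairs == [(0, 1), (2, 3)] and leftover is None

    def test_two_variables_forced(self):
        pairs, leftover = greedy_pair(np.array([[1.0, -0.4], [-0.4, 1.0]]))
        assert pairs == [(0, 1)] and leftover is None

    def test_lexicographic_tie_break_with_leftover(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.5
        c[0, 2] = c[2, 0] = 0.5
        c[1, 2] = c[2, 1] = 0.4
        pairs, leftover = greedy_pair(c)
        assert pairs == [(0, 1)] and leftover == 2

    def test_absolute_mode_prefers_strong_anticorrelation(self):
        c = np.eye(2 + 2)
        c[0, 1] = c[1, 0] = -0.95
        c[2, 3] = c[3, 2] = 0.5
        signed, _ = greedy_pair(c, "signed")
        absolute, _ = greedy_pair(c, "absolute")
        assert signed[0] == (2, 3)
        assert absolute[0] == (0, 1)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        a = rng.standard_normal((n, n))
        c = np.corrcoef(a)
        # every other seed: quantize to force ties
        if seed % 2:
            c = np.round(c, 1)
            c = (c + c.T) / 2
            np.fill_diagonal(c, 1.0)
        for mode in ("signed", "absolute"):
            assert greedy_pair(c, mode) == brute_force_greedy(c, mode)


class TestCoarseGrainStep:
    def test_identical_rows_metagene_reproduces_parent(self, rng):
        u = rng.standard_normal(40)
        u = (u - u.mean()) / u.std(ddof=1)
        s = initial_state(std_expr(np.vstack([u, u])))
        out = coarse_grain_step(s)
        np.testing.assert_allclose(out.expression[0], u, atol=1e-10)
        assert out.membership[0] == frozenset({0, 1})
        assert out.depth == 1

    def test_floor_schedule_including_odd_drop(self, rng):
        for n, expect in [(6, 3), (5, 2)]:
            s = initial_state(std_expr(rng.standard_normal((n, 30))))
            out = coarse_grain_step(s)
            assert out.n_variables == expect == n // 2

    def test_keep_leftover_carries_odd_variable(self, rng):
        s = initial_state(std_expr(rng.standard_normal((5, 30))))
        out = coarse_grain_step(s, keep_leftover=True)
        assert out.n_variables == 3
        singles = [m for m in out.membership.values() if len(m) == 1]
        assert len(singles) == 1

    def test_metagene_equals_direct_normalized_sum(self, rng):
        u, v = rng.standard_normal((2, 10))
        e = std_expr(np.vstack([u, v]))
        out = coarse_grain_step(initial_state(e))
        summed = e.values[0] + e.values[1]
        summed = summed - summed.mean()
        np.testing.assert_allclose(
            out.expression[0], summed / summed.std(ddof=1), atol=1e-12
        )

    def test_anticorrelated_pair_is_error_in_absolute_mode(self):
        u = np.array([1.0, -1.0, 2.0, -2.0, 0.0])
        u = (u - u.mean()) / u.std(ddof=1)
        s = initial_state(std_expr(np.vstack([u, -u])))
        with pytest.raises(ValueError, match="zero-variance"):
            coarse_grain_step(s, "absolute")


class TestFlow:
    def test_halving_schedule_to_single_variable(self, rng):
        states = realspace_flow(std_expr(rng.standard_normal((8, 25))))
        assert [s.n_variables for s in states] == [8, 4, 2, 1]
        assert [s.depth for s in states] == [0, 1, 2, 3]

    def test_max_depth_truncation(self, rng):
        states = realspace_flow(std_expr(rng.standard_normal((8, 25))), max_depth=1)
        assert len(states) == 2

    def test_requires_standardized_input(self, rng):
        e = ExpressionMatrix(rng.standard_normal((4, 10)), list("abcd"),
                             [f"c{i}" for i in range(10)], standardized=False)
        with pytest.raises(ValueError, match="standardized"):
            realspace_flow(e)

    def test_variance_conservation_all_depths(self, rng):
        states = realspace_flow(std_expr(rng.standard_normal((16, 60))))
        for s in states:
            np.testing.assert_allclose(s.expression.var(axis=1, ddof=1), 1.0, atol=1e-8)
            np.testing.assert_allclose(s.expression.mean(axis=1), 0.0, atol=1e-10)

    def test_membership_partition_schedule(self, rng):
        states = realspace_flow(std_expr(rng.standard_normal((12, 40))))
        for s in states:
            assert s.n_variables == 12 // 2**s.depth
            sizes = {len(m) for m in s.membership.values()}
            assert sizes == {2**s.depth}

    def test_permutation_equivariance_of_metagene_set(self, rng):
        x = rng.standard_normal((8, 50))
        e = std_expr(x)
        perm = rng.permutation(8)
        ep = std_expr(x[perm])
        a = realspace_flow(e, max_depth=2)[-1]
        b = realspace_flow(ep, max_depth=2)[-1]
        # same multiset of metagene vectors, memberships mapped through perm
        sa = sorted(map(tuple, np.round(a.expression, 10)))
        sb = sorted(map(tuple, np.round(b.expression, 10)))
        np.testing.assert_allclose(sa, sb, atol=1e-9)
        mapped = {frozenset(int(perm[i]) for i in m) for m in b.membership.values()}
        assert mapped == set(a.membership.values())

    def test_block_structure_recovered_in_memberships(self, block_expression):
        expr, labels = block_expression
        labels = np.asarray(labels)
        states = realspace_flow(expr, max_depth=3)
        purities = []
        for members in states[-1].membership.values():
            lab = labels[list(members)]
            _, counts = np.unique(lab, return_counts=True)
            purities.append(counts.max() / lab.size)
        assert np.mean(purities) >= 0.95
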