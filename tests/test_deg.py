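"""Integrative differential-expression statistics against independent oracles."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cholnet import (
    CholnetError, ExpressionMatrix, RunConfig,
    permutation_pvalues, run_integrative_test, select_degs,
    stat_m, stat_t, storey_qvalues, stouffer_combine,
)
from conftest import random_matrix

floats = st.floats(min_value=-50, max_value=50, allow_nan=False)
groups2 = st.lists(floats, min_size=2, max_size=5)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_pooled_t(a, b):
    """Textbook pooled-variance two-sample t, plain Python."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    se = sp * math.sqrt(1 / na + 1 / nb)
    diff = ma - mb
    if se == 0.0:
        return 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    return diff / se


def oracle_median_diff(a, b):
    import statistics
    return statistics.median(a) - statistics.median(b)


def oracle_permutation_pvalues(x, n_a, stat, null_mode):
    """Brute-force enumeration of every distinct group relabeling."""
    n = x.shape[1]
    labelings = list(combinations(range(n), n_a))
    stat_of = {
        lab: [stat([x[g, j] for j in lab],
                   [x[g, j] for j in range(n) if j not in lab])
              for g in range(x.shape[0])]
        for lab in labelings
    }
    identity = tuple(range(n_a))
    obs = stat_of[identity]
    if null_mode == "per_gene":
        return [
            sum(abs(stat_of[lab][g]) >= abs(obs[g]) for lab in labelings)
            / len(labelings)
            for g in range(x.shape[0])
        ]
    mirror = tuple(range(n_a, n)) if n == 2 * n_a else None
    null_labs = [l for l in labelings if l not in (identity, mirror)]
    pool = [abs(stat_of[l][g]) for l in null_labs for g in range(x.shape[0])]
    return [
        (sum(v >= abs(obs[g]) for v in pool) + 1) / (len(pool) + 1)
        for g in range(x.shape[0])
    ]


def oracle_storey(ps, grid):
    """Step-by-step q-value recomputation with explicit loops."""
    n = len(ps)
    ests = sorted(sum(1 for p in ps if p > lam) / ((1 - lam) * n) for lam in grid)
    mid = len(ests) // 2
    pi0 = ests[mid] if len(ests) % 2 else (ests[mid - 1] + ests[mid]) / 2
    pi0 = max(min(pi0, 1.0), 1.0 / n)
    order = sorted(range(n), key=lambda i: ps[i])
    q = [0.0] * n
    running = math.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pi0 * n * ps[i] / rank, 1.0)
        q[i] = running
    return pi0, q


# ---------------------------------------------------------------------------
# Per-gene statistics
# ---------------------------------------------------------------------------

class TestStatistics:
    def test_identical_groups_give_zero_t(self):
        assert stat_t([1, 1], [1, 1]) == 0.0

    def test_pooled_t_matches_hand_computation(self):
        # mean diff 1, pooled sd sqrt(2), t = 1 / (sqrt(2) * 1) = 0.7071...
        assert stat_t([2, 4], [1, 3]) == pytest.approx(1 / math.sqrt(2), abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(groups2, groups2)
    def test_t_antisymmetric_and_matches_oracle(self, a, b):
        t = stat_t(a, b)
        assert stat_t(b, a) == pytest.approx(-t, abs=1e-9) or (
            math.isinf(t) and stat_t(b, a) == -t)
        o = oracle_pooled_t(a, b)
        if math.isinf(o):
            assert t == o
        else:
            assert t == pytest.approx(o, abs=1e-9)

    def test_group_too_small_errors(self):
        with pytest.raises(CholnetError):
            stat_t([1], [2, 3])

    def test_median_ratio_examples(self):
        assert stat_m([5, 6, 7], [5, 6, 7]) == 0.0
        assert stat_m([5, 6, 7], [3, 4, 5]) == 2.0
        with pytest.raises(CholnetError):
            stat_m([], [1])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(floats, min_size=1, max_size=7),
           st.lists(floats, min_size=1, max_size=7),
           st.floats(min_value=-10, max_value=10, allow_nan=False))
    def test_median_ratio_shift_invariant(self, a, b, c):
        base = stat_m(a, b)
        shifted = stat_m([x + c for x in a], [x + c for x in b])
        assert shifted == pytest.approx(base, abs=1e-9)


# ---------------------------------------------------------------------------
# Permutation p-values
# ---------------------------------------------------------------------------

class TestPermutationPvalues:
    @pytest.mark.parametrize("null_mode", ["per_gene", "pooled"])
    @pytest.mark.parametrize("n_per_group", [2, 3])
    @pytest.mark.parametrize("statistic", ["t", "m"])
    def test_exhaustive_matches_brute_force(self, rng, null_mode, n_per_group, statistic):
        m = random_matrix(rng, 20, n_per_group)
        cfg = RunConfig(null_mode=null_mode)
        stat = oracle_pooled_t if statistic == "t" else oracle_median_diff
        null, p = permutation_pvalues(m, statistic, cfg)
        assert null.exhaustive
        expected = oracle_permutation_pvalues(
            m.values.to_numpy(), n_per_group, stat, null_mode)
        np.testing.assert_array_equal(p, expected)

    def test_2v2_separated_gene_per_gene_p_is_two_sixths(self):
        values = pd.DataFrame([[0.0, 0.0, 1.0, 1.0]], index=["g"],
                              columns=["a1", "a2", "b1", "b2"])
        m = ExpressionMatrix(values=values,
                             design={"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        null, p = permutation_pvalues(m, "t", RunConfig(null_mode="per_gene"))
        assert null.n_perm == 6 and null.exhaustive
        assert p[0] == pytest.approx(2 / 6)

    def test_constant_gene_p_is_one(self):
        values = pd.DataFrame([[3.0, 3.0, 3.0, 3.0]], index=["g"],
                              columns=["a1", "a2", "b1", "b2"])
        m = ExpressionMatrix(values=values,
                             design={"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        for mode in ("per_gene", "pooled"):
            _, p = permutation_pvalues(m, "t", RunConfig(null_mode=mode))
            assert p[0] == 1.0

    def test_sampled_mode_is_deterministic(self, rng):
        m = random_matrix(rng, 10, 5)  # C(10,5) = 252 relabelings
        cfg = RunConfig(permutation_cap=100, rng_seed=42)
        null1, p1 = permutation_pvalues(m, "t", cfg)
        null2, p2 = permutation_pvalues(m, "t", cfg)
        assert not null1.exhaustive and null1.n_perm <= 100
        np.testing.assert_array_equal(p1, p2)

    def test_three_groups_rejected(self, rng):
        m = random_matrix(rng, 5, 2)
        m.design["B1"] = "C"
        with pytest.raises(CholnetError, match="two-group"):
            permutation_pvalues(m, "t", RunConfig())


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

class TestStorey:
    def test_all_ones(self):
        est = storey_qvalues([1.0] * 20)
        assert est.pi0 == 1.0
        assert np.all(est.qvalues == 1.0)

    def test_spike_plus_uniform_matches_step_by_step_recomputation(self, rng):
        ps = np.concatenate([np.full(50, 0.001), rng.uniform(0, 1, 950)])
        grid = RunConfig().storey_lambda
        est = storey_qvalues(ps, grid)
        pi0_o, q_o = oracle_storey(list(ps), grid)
        assert est.pi0 == pytest.approx(pi0_o, rel=1e-12)
        np.testing.assert_allclose(est.qvalues, q_o, rtol=1e-12)
        assert np.all(est.qvalues[:50] < 0.05)

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=2, max_size=100))
    def test_qvalues_monotone_in_p_rank(self, ps):
        est = storey_qvalues(ps)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(est.qvalues[order]) >= -1e-15)

    def test_empty_input_errors(self):
        with pytest.raises(CholnetError):
            storey_qvalues([])


# ---------------------------------------------------------------------------
# Stouffer combination
# ---------------------------------------------------------------------------

class TestStouffer:
    def test_single_test_identity(self):
        assert stouffer_combine([0.2]) == pytest.approx(0.2, abs=1e-12)

    def test_half_half_is_half(self):
        assert stouffer_combine([0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_two_nominal_fdrs_combine_to_one_percent(self):
        # z = Phi^-1(0.95) = 1.6449 each; combined 2.3262; tail 0.0100
        assert stouffer_combine([0.05, 0.05]) == pytest.approx(0.0100, abs=1e-4)

    def test_monotone_in_each_input(self, rng):
        base = rng.uniform(0, 1, size=(2, 1000))
        lowered = base.copy()
        lowered[0] *= rng.uniform(0, 1, 1000)
        assert np.all(stouffer_combine(lowered) <= stouffer_combine(base) + 1e-12)

    @pytest.mark.parametrize("f", [0.01, 0.1, 0.3, 0.49])
    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_identical_small_fdrs_accumulate_evidence(self, f, k):
        assert stouffer_combine([f] * k) <= f

    def test_empty_errors(self):
        with pytest.raises(CholnetError):
            stouffer_combine(np.empty((0, 5)))


# ---------------------------------------------------------------------------
# DEG selection
# ---------------------------------------------------------------------------

class TestSelectDegs:
    @pytest.mark.parametrize("fdr,fc,expect_deg,expect_dir", [
        (0.03, 0.70, True, "up"),     # passes both gates
        (0.03, 0.585, False, "none"),  # fold-change boundary is strict
        (0.05, 2.00, False, "none"),   # FDR boundary is strict
        (0.03, -0.70, True, "down"),
    ])
    def test_joint_rule_boundaries(self, fdr, fc, expect_deg, expect_dir):
        table = pd.DataFrame({"log2fc": [fc], "fdr_overall": [fdr]},
                             index=pd.Index(["g"], name="gene"))
        out = select_degs(table, RunConfig())
        assert bool(out["is_deg"].iloc[0]) is expect_deg
        assert out["direction"].iloc[0] == expect_dir

    def test_full_table_has_consistent_directions(self, rng):
        m = random_matrix(rng, 100, 2)
        out = run_integrative_test(m)
        called = out[out["is_deg"]]
        assert ((called["log2fc"] > 0) == (called["direction"] == "up")).all()
        assert set(out.loc[~out["is_deg"], "direction"]) <= {"none"}
        # invariant: is_deg implies both strict gates
        assert (called["fdr_overall"] < 0.05).all()
        assert (called["log2fc"].abs() > 0.585).all()
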