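"""Integrative permutation-based differential expression for two-group designs.

The method behind this module targets replicated two-group comparisons with
very small replicate counts (the motivating study used n = 2 per diet group):

1. two per-gene statistics — a pooled-variance two-sample t statistic and a
   log2-median-ratio (difference of group medians on the log2 scale);
2. permutation null distributions from all distinct group relabelings
   (exhaustive below ``permutation_cap``, seeded sampling above it);
3. Storey q-values per statistic (the per-test FDRs);
4. Stouffer combination of the per-test FDRs into one overall FDR;
5. joint selection: overall FDR < alpha AND |log2 fold change| > threshold.

With two samples per group a gene's own relabeling set has only six
elements, so a per-gene permutation p-value cannot fall below 1/3.  The
default null therefore pools permuted statistics across genes
(``null_mode="pooled"``): every relabeling other than the observed grouping
contributes its statistics for all genes to one empirical null ensemble,
and each gene's two-sided p-value is the add-one-corrected fraction of that
ensemble at least as extreme as its observed statistic.  The classical
per-gene formula remains available as ``null_mode="per_gene"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CholnetError, ExpressionMatrix, RunConfig

__all__ = [
    "stat_t", "stat_m", "PermutationNull", "permutation_pvalues",
    "StoreyEstimate", "storey_qvalues", "stouffer_combine",
    "run_integrative_test", "select_degs",
]

_EPS = 1e-15


# ---------------------------------------------------------------------------
# Per-gene statistics
# ---------------------------------------------------------------------------

def _pooled_t_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t for each row; sign = mean(a) - mean(b).

    Zero pooled variance yields a signed infinity sentinel (0 when the mean
    difference is also 0); rank-based p computation handles the sentinel.
    """
    na, nb = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    sp2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        t = np.where(se == 0.0, np.sign(diff) * np.inf, t)
    return np.where(np.isnan(t), 0.0, t)  # 0/0: identical constant groups


def stat_t(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Pooled-variance two-sample t statistic, sign = mean(A) - mean(B)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise CholnetError("stat_t requires at least 2 values per group")
    return float(_pooled_t_matrix(a[None, :], b[None, :])[0])


def stat_m(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Log2-median-ratio: difference of group medians on the log2 scale."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise CholnetError("stat_m requires non-empty groups")
    return float(np.median(a) - np.median(b))


def _median_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.median(a, axis=1) - np.median(b, axis=1)


_STAT_FUNCS = {"t": _pooled_t_matrix, "m": _median_matrix}


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

@dataclass
class PermutationNull:
    """Observed statistics plus the permutation ensemble that nulls them."""

    observed: np.ndarray          # per gene
    permuted: np.ndarray          # genes x n_perm
    n_perm: int
    exhaustive: bool
    null_mode: str

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise CholnetError("permutation null needs n_perm >= 1")


def _two_group_indices(matrix: ExpressionMatrix) -> tuple[str, str, np.ndarray, np.ndarray]:
    groups = matrix.groups()
    if len(groups) != 2:
        raise CholnetError(f"two-group design required, found groups {sorted(groups)}")
    (la, sa), (lb, sb) = groups.items()
    cols = {s: i for i, s in enumerate(matrix.sample_ids)}
    ia = np.array([cols[s] for s in sa])
    ib = np.array([cols[s] for s in sb])
    if ia.size < 2 or ib.size < 2:
        raise CholnetError("each group needs >= 2 samples; "
                           "use the time-course caller for unreplicated designs")
    return la, lb, ia, ib


def _relabelings(n_a: int, n_total: int, cap: int, seed: int) -> tuple[list[tuple[int, ...]], bool]:
    """Distinct assignments of ``n_a`` of ``n_total`` samples to group A.

    Enumerates all C(n_total, n_a) assignments when that count is within
    ``cap``; otherwise draws ``cap`` distinct assignments with the seeded
    generator (always including the identity assignment first).
    """
    from math import comb
    total = comb(n_total, n_a)
    identity = tuple(range(n_a))
    if total <= cap:
        return list(combinations(range(n_total), n_a)), True
    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, ...]] = {identity}
    while len(chosen) < cap:
        draw = tuple(sorted(rng.choice(n_total, size=n_a, replace=False).tolist()))
        chosen.add(draw)
    out = [identity] + sorted(chosen - {identity})
    return out, False


def permutation_pvalues(
    matrix: ExpressionMatrix,
    statistic: str,
    config: RunConfig | None = None,
) -> tuple[PermutationNull, np.ndarray]:
    """Two-sided permutation p-values for ``statistic`` ("t" or "m").

    In ``per_gene`` mode the p-value of a gene is the fraction of its own
    relabelings (identity included) whose |statistic| reaches the observed
    one.  In the default ``pooled`` mode the null ensemble is every
    relabeling that changes the group composition (the observed assignment
    and its mirror are excluded), pooled across all genes, and
    p = (count >= observed + 1) / (ensemble size + 1).
    """
    config = config or RunConfig()
    if statistic not in _STAT_FUNCS:
        raise CholnetError(f"unknown statistic {statistic!r}; use 't' or 'm'")
    func = _STAT_FUNCS[statistic]
    _, _, ia, ib = _two_group_indices(matrix)
    x = matrix.values.to_numpy(dtype=float)
    order = np.concatenate([ia, ib])   # samples reordered as [A | B]
    x = x[:, order]
    n_a, n = ia.size, order.size

    labelings, exhaustive = _relabelings(n_a, n, config.permutation_cap, config.rng_seed)
    all_idx = frozenset(range(n))
    perm = np.empty((x.shape[0], len(labelings)))
    for j, asel in enumerate(labelings):
        bsel = sorted(all_idx - set(asel))
        perm[:, j] = func(x[:, list(asel)], x[:, bsel])

    identity = tuple(range(n_a))
    obs = perm[:, labelings.index(identity)]

    if config.null_mode == "per_gene":
        abs_perm = np.abs(perm)
        p = (abs_perm >= np.abs(obs)[:, None]).sum(axis=1) / perm.shape[1]
        null = PermutationNull(obs, perm, perm.shape[1], exhaustive, "per_gene")
        return null, p

    mirror = tuple(range(n_a, n)) if n - n_a == n_a else None
    keep = [j for j, lab in enumerate(labelings) if lab != identity and lab != mirror]
    if not keep:
        raise CholnetError("pooled null needs at least one non-identity relabeling")
    null_stats = perm[:, keep]
    pool = np.sort(np.abs(null_stats), axis=None)
    n_pool = pool.size
    # count of pooled null values >= |obs| via right-open searchsorted
    ge = n_pool - np.searchsorted(pool, np.abs(obs), side="left")
    p = (ge + 1.0) / (n_pool + 1.0)
    null = PermutationNull(obs, null_stats, null_stats.shape[1], exhaustive, "pooled")
    return null, p


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

@dataclass
class StoreyEstimate:
    pvalues: np.ndarray
    pi0: float
    qvalues: np.ndarray
    lambda_grid: tuple[float, ...]


def storey_qvalues(
    pvalues: Sequence[float],
    lambda_grid: Sequence[float] | None = None,
) -> StoreyEstimate:
    """Storey q-values with the null proportion estimated over a lambda grid.

    pi0 is the median over the grid of #{p > lambda} / ((1 - lambda) * n),
    clamped into (0, 1] (lower clamp 1/n); q-values are the usual
    step-up-monotone pi0 * n * p / rank, cumulative-minimized from the
    largest p down.  The median aggregation replaces Storey's spline
    smoother, which is unstable at small gene counts.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise CholnetError("storey_qvalues needs at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise CholnetError("p-values must lie in [0, 1]")
    grid = tuple(lambda_grid) if lambda_grid is not None else RunConfig().storey_lambda
    n = p.size
    estimates = [(p > lam).sum() / ((1.0 - lam) * n) for lam in grid]
    pi0 = float(np.median(estimates))
    pi0 = min(pi0, 1.0)
    pi0 = max(pi0, 1.0 / n)

    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw = pi0 * n * ranked / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return StoreyEstimate(pvalues=p, pi0=pi0, qvalues=q, lambda_grid=grid)


# ---------------------------------------------------------------------------
# Stouffer combination
# ---------------------------------------------------------------------------

def stouffer_combine(fdrs: Sequence[Sequence[float]] | np.ndarray) -> np.ndarray:
    """Combine per-test FDRs into overall FDRs by Stouffer's method.

    ``fdrs`` is (k tests) x (n genes) or a flat length-k vector for a single
    gene.  Each value is clamped to [1e-15, 1 - 1e-15], probit-transformed
    (z_i = Phi^-1(1 - f_i)), summed and rescaled by sqrt(k); the overall
    FDR is 1 - Phi(z).  With k = 1 this is the identity.
    """
    arr = np.asarray(fdrs, dtype=float)
    single = arr.ndim == 1
    if single:
        arr = arr[:, None]
    if arr.shape[0] == 0:
        raise CholnetError("stouffer_combine needs at least one test")
    if np.any((arr < 0) | (arr > 1)):
        raise CholnetError("FDRs must lie in [0, 1]")
    clamped = np.clip(arr, _EPS, 1.0 - _EPS)
    z = stats.norm.isf(clamped)          # Phi^-1(1 - f)
    combined = z.sum(axis=0) / np.sqrt(arr.shape[0])
    overall = stats.norm.sf(combined)    # 1 - Phi(z)
    return float(overall[0]) if single else overall


# ---------------------------------------------------------------------------
# End-to-end two-group test and DEG selection
# ---------------------------------------------------------------------------

def run_integrative_test(
    matrix: ExpressionMatrix,
    config: RunConfig | None = None,
    group_a: str | None = None,
    group_b: str | None = None,
) -> pd.DataFrame:
    """Full integrative test on a replicated two-group matrix.

    Returns the per-gene table with columns log2fc, stat_t, stat_m, p_t,
    p_m, fdr_t, fdr_m, fdr_overall, direction, is_deg, indexed by gene.
    Group A defaults to the design label that appears first; log2fc =
    mean(A) - mean(B) on the log2 scale.
    """
    config = config or RunConfig()
    la, lb, ia, ib = _two_group_indices(matrix)
    flip = False
    if group_a is not None:
        if {group_a, group_b or lb} != {la, lb}:
            raise CholnetError(f"groups {group_a!r}/{group_b!r} not in design ({la!r}, {lb!r})")
        flip = group_a != la
        if flip:
            ia, ib = ib, ia
    x = matrix.values.to_numpy(dtype=float)
    log2fc = x[:, ia].mean(axis=1) - x[:, ib].mean(axis=1)

    # both statistics are antisymmetric under a group swap; p-values are not
    null_t, p_t = permutation_pvalues(matrix, "t", config)
    null_m, p_m = permutation_pvalues(matrix, "m", config)
    sign = -1.0 if flip else 1.0
    est_t = storey_qvalues(p_t, config.storey_lambda)
    est_m = storey_qvalues(p_m, config.storey_lambda)
    overall = stouffer_combine(np.vstack([est_t.qvalues, est_m.qvalues]))

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "stat_t": sign * null_t.observed,
            "stat_m": sign * null_m.observed,
            "p_t": p_t,
            "p_m": p_m,
            "fdr_t": est_t.qvalues,
            "fdr_m": est_m.qvalues,
            "fdr_overall": overall,
        },
        index=pd.Index(matrix.gene_ids, name="gene"),
    )
    return select_degs(table, config)


def select_degs(table: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Apply the joint DEG rule: fdr_overall < alpha AND |log2fc| > threshold.

    Both comparisons are strict; direction is the fold-change sign for
    called genes and "none" otherwise.
    """
    config = config or RunConfig()
    out = table.copy()
    called = (out["fdr_overall"] < config.alpha) & (out["log2fc"].abs() > config.fc_threshold)
    out["is_deg"] = called
    out["direction"] = np.where(~called, "none", np.where(out["log2fc"] > 0, "up", "down"))
    return out
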