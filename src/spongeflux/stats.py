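"""Permutational statistics for small crossed feeding-experiment designs.

The comparisons of interest (species × food source effects on processing
rates, efficiencies and PLFA class totals) involve 1–4 individuals per cell,
so classical ANOVA assumptions cannot be checked.  PERMANOVA computes the
same sum-of-squares partitioning but tests the pseudo-F statistic by
unrestricted permutation of the raw observations.  For Euclidean distance on
a univariate response the pseudo-F is identical to the classical ANOVA F,
which provides the parametric "Monte Carlo" p-value (p_MC) used when the
number of distinct permutations is too small for a fine-grained permutation
p — the standard remedy for tiny designs.

Two equivalent computational routes are implemented: directly on the raw
response matrix (sums of squares from least-squares projections, summed over
response columns) and on the Gower-centred distance matrix
G = −½·(I−11ᵀ/n)·D²·(I−11ᵀ/n) via tr(H·G).  For Euclidean distances the two
agree to machine precision; the pair doubles as an internal consistency
check.

Term sums of squares are partial (type III): each term's SS is the drop in
explained SS when its effect-coded columns are removed from the full model,
so results do not depend on term order in unbalanced designs.  When the
number of distinct group relabelings is below the requested permutation
count, the permutation distribution is enumerated exactly and the count of
distinct relabelings is reported (e.g. 10 for two groups of three).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DesignTable",
    "PermanovaResult",
    "OneLevelFactorError",
    "permanova",
    "permanova_table",
    "pairwise",
    "welch_t",
    "distinct_relabelings",
]


class OneLevelFactorError(ValueError):
    """A factor used in the design has fewer than two levels."""


@dataclass
class DesignTable:
    """Observations with one or two crossed factors and a numeric response.

    ``response`` is (n,) or (n, p); Euclidean distance on it defines the
    multivariate geometry.
    """

    response: np.ndarray
    factor_a: np.ndarray
    factor_b: np.ndarray | None = None
    observation_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.response = np.atleast_2d(np.asarray(self.response, dtype=float))
        if self.response.shape[0] == 1 and len(np.asarray(self.factor_a)) > 1:
            self.response = self.response.T
        self.factor_a = np.asarray(self.factor_a)
        if self.factor_b is not None:
            self.factor_b = np.asarray(self.factor_b)
        n = self.response.shape[0]
        if len(self.factor_a) != n:
            raise ValueError("factor_a length does not match response")
        if self.factor_b is not None and len(self.factor_b) != n:
            raise ValueError("factor_b length does not match response")
        if np.any(~np.isfinite(self.response)):
            raise ValueError("response contains missing or non-finite values")
        for name, fac in (("factor_a", self.factor_a), ("factor_b", self.factor_b)):
            if fac is not None and len(np.unique(fac)) < 2:
                raise OneLevelFactorError(f"{name} has fewer than two levels")


@dataclass
class PermanovaResult:
    term: str
    df: int
    df_residual: int
    ss: float
    pseudo_f: float
    p_perm: float
    p_mc: float
    unique_permutations: int


def _effect_codes(fac: np.ndarray) -> np.ndarray:
    """Sum-to-zero (deviation) coding: k levels → k−1 columns."""
    levels = np.unique(fac)
    k = len(levels)
    out = np.zeros((len(fac), k - 1))
    for j, lev in enumerate(levels[:-1]):
        out[fac == lev, j] = 1.0
    out[fac == levels[-1], :] = -1.0
    return out


def _interaction_codes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    cols = [
        (a[:, i] * b[:, j]) for i in range(a.shape[1]) for j in range(b.shape[1])
    ]
    return np.column_stack(cols) if cols else np.zeros((a.shape[0], 0))


def _orthonormal_basis(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of x (rank-revealing)."""
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def distinct_relabelings(group_sizes: list[int]) -> int:
    """Number of distinct assignments of observations to groups of the given
    sizes, counting unordered partitions for groups of equal size (the
    'Unique Permutations' of permutation-ANOVA software)."""
    n = sum(group_sizes)
    count = math.factorial(n)
    for s in group_sizes:
        count //= math.factorial(s)
    sizes, reps = np.unique(group_sizes, return_counts=True)
    for r in reps:
        count //= math.factorial(int(r))
    return count


def _distinct_partitions(n: int, sizes: list[int]):
    """All distinct unordered-where-equal partitions of range(n) into groups
    of the given sizes.  Groups of equal size are deduplicated by requiring
    the minimum element to increase along each run of equal sizes (sizes must
    be pre-sorted for full dedup; callers sort)."""

    def rec(avail: tuple[int, ...], k: int):
        if k == len(sizes):
            yield ()
            return
        for comb in combinations(avail, sizes[k]):
            rest = tuple(i for i in avail if i not in comb)
            for tail in rec(rest, k + 1):
                yield (comb,) + tail

    for parts in rec(tuple(range(n)), 0):
        ok = True
        for i in range(1, len(sizes)):
            if sizes[i] == sizes[i - 1] and parts[i][0] < parts[i - 1][0]:
                ok = False
                break
        if ok:
            yield parts


def _one_factor_enumeration_perms(fac: np.ndarray) -> np.ndarray:
    """Row-permutation index matrix covering every distinct relabeling of a
    one-factor design."""
    levels, inverse = np.unique(fac, return_inverse=True)
    slots = [np.flatnonzero(inverse == j) for j in range(len(levels))]
    order = sorted(range(len(levels)), key=lambda j: len(slots[j]))
    sizes = [len(slots[j]) for j in order]
    perms = []
    for parts in _distinct_partitions(len(fac), sizes):
        perm = np.empty(len(fac), dtype=int)
        for pos, j in enumerate(order):
            perm[slots[j]] = parts[pos]
        perms.append(perm)
    return np.array(perms)


def _term_matrices(design: DesignTable):
    """Full-model basis and, per term, the reduced-model basis without it."""
    n = design.response.shape[0]
    intercept = np.ones((n, 1))
    a = _effect_codes(design.factor_a)
    blocks: dict[str, np.ndarray] = {"factor_a": a}
    if design.factor_b is not None:
        b = _effect_codes(design.factor_b)
        blocks["factor_b"] = b
        blocks["interaction"] = _interaction_codes(a, b)
    full = _orthonormal_basis(np.column_stack([intercept, *blocks.values()]))
    reduced = {}
    for term in blocks:
        others = [v for k, v in blocks.items() if k != term]
        reduced[term] = _orthonormal_basis(np.column_stack([intercept, *others]))
    return full, reduced, blocks


def _projection_ss(q: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum((q.T @ y) ** 2))


def permanova(
    design: DesignTable,
    permutations: int = 9999,
    seed: int | np.random.Generator | None = None,
    method: str = "raw",
) -> list[PermanovaResult]:
    """PERMANOVA on Euclidean distances with type III (partial) SS.

    p_perm comes from unrestricted permutation of the raw observations using
    the (b+1)/(m+1) estimator (ties count as ≥ observed); for one-factor
    designs whose distinct relabelings number fewer than ``permutations`` the
    null distribution is enumerated exactly.  p_MC is the parametric tail
    probability of F(df_term, df_residual), exact for the univariate Gaussian
    Euclidean case.

    ``method="gower"`` runs the identical partition on the Gower-centred
    squared-distance matrix (tr(H·G) route) as an internal cross-check.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = design.response
    n = y.shape[0]
    full, reduced, blocks = _term_matrices(design)
    df_res = n - full.shape[1]
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom (design saturated)")

    if method == "raw":

        def term_stats(yp: np.ndarray):
            ss_full = _projection_ss(full, yp)
            ss_res = float(np.sum(yp**2)) - ss_full
            return (
                {t: ss_full - _projection_ss(reduced[t], yp) for t in blocks},
                ss_res,
            )

        permute = lambda perm: y[perm]
    elif method == "gower":
        from scipy.spatial import distance_matrix as _dm

        d2 = _dm(y, y) ** 2
        j = np.eye(n) - np.ones((n, n)) / n
        g = -0.5 * j @ d2 @ j
        h_full = full @ full.T
        h_red = {t: reduced[t] @ reduced[t].T for t in blocks}

        def term_stats(gp: np.ndarray):
            ss_full = float(np.trace(h_full @ gp))
            ss_res = float(np.trace(gp)) - ss_full
            return (
                {t: ss_full - float(np.trace(h_red[t] @ gp)) for t in blocks},
                ss_res,
            )

        y = g
        permute = lambda perm: g[np.ix_(perm, perm)]
    else:
        raise ValueError(f"method must be 'raw' or 'gower', got {method!r}")

    ss_terms, ss_res = term_stats(y)
    df_terms = {t: blocks[t].shape[1] for t in blocks}

    degenerate = (ss_res <= 1e-12) and all(v <= 1e-12 for v in ss_terms.values())

    def f_stat(ss_t, df_t, ss_r):
        if ss_r <= 1e-12 * max(1.0, ss_t):
            return float("nan")
        return (ss_t / df_t) / (ss_r / df_res)

    f_obs = {t: f_stat(ss_terms[t], df_terms[t], ss_res) for t in blocks}

    # permutation scheme
    exact_perms = None
    if design.factor_b is None:
        n_distinct = distinct_relabelings(
            list(np.unique(design.factor_a, return_counts=True)[1])
        )
        if n_distinct <= permutations:
            exact_perms = _one_factor_enumeration_perms(design.factor_a)

    if degenerate:
        return [
            PermanovaResult(t, df_terms[t], df_res, 0.0, float("nan"), 1.0, 1.0, 1)
            for t in blocks
        ]

    counts = {t: 0 for t in blocks}
    if exact_perms is not None:
        perm_iter = exact_perms
    else:
        perm_iter = (rng.permutation(n) for _ in range(permutations))
    n_evaluated = 0
    for perm in perm_iter:
        st, sr = term_stats(permute(perm))
        n_evaluated += 1
        for t in blocks:
            fp = f_stat(st[t], df_terms[t], sr)
            if np.isnan(fp) or fp >= f_obs[t] - 1e-12:
                counts[t] += 1

    results = []
    for term in blocks:
        if exact_perms is not None:
            p_perm = counts[term] / n_evaluated
            uniq = n_evaluated
        else:
            p_perm = (counts[term] + 1) / (n_evaluated + 1)
            uniq = n_evaluated
        p_mc = float(sps.f.sf(f_obs[term], df_terms[term], df_res))
        results.append(
            PermanovaResult(
                term, df_terms[term], df_res, ss_terms[term], f_obs[term],
                p_perm, p_mc, uniq,
            )
        )
    return results


def permanova_table(results: list[PermanovaResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def pairwise(
    design: DesignTable,
    factor: str = "factor_a",
    seed: int | None = None,
    permutations: int = 9999,
) -> pd.DataFrame:
    """Pairwise comparisons between the levels of a factor.

    Each pair is analysed as a two-level one-factor sub-design; the statistic
    is t = √(pseudo-F), with p_MC from the t distribution on the residual df
    (n1 + n2 − 2) and p_perm from the (enumerated where possible)
    permutation distribution.  Pairs with fewer than two observations per
    level are skipped with a warning row.
    """
    fac = design.factor_a if factor == "factor_a" else design.factor_b
    if fac is None:
        raise ValueError(f"design has no {factor}")
    levels = np.unique(fac)
    rows = []
    for la, lb in combinations(levels, 2):
        mask = (fac == la) | (fac == lb)
        n1, n2 = int(np.sum(fac == la)), int(np.sum(fac == lb))
        if min(n1, n2) < 2:
            rows.append(
                dict(pair=f"{la} * {lb}", df=n1 + n2 - 2, t=float("nan"),
                     p_mc=float("nan"), p_perm=float("nan"),
                     unique_permutations=0, note="skipped: <2 obs per level")
            )
            continue
        sub = DesignTable(design.response[mask], fac[mask])
        res = permanova(sub, permutations=permutations, seed=seed)[0]
        f = res.pseudo_f
        t = float(np.sqrt(f)) if np.isfinite(f) and f > 0 else 0.0
        p_mc = float(2.0 * sps.t.sf(t, res.df_residual)) if t > 0 else 1.0
        rows.append(
            dict(pair=f"{la} * {lb}", df=res.df_residual, t=t, p_mc=p_mc,
                 p_perm=res.p_perm, unique_permutations=res.unique_permutations,
                 note="")
        )
    return pd.DataFrame(rows)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: returns (t, Satterthwaite df, two-sided p).

    Degenerate case (zero variance in both samples, equal means) returns
    (0, n1+n2−2, 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return float("inf"), float(len(x) + len(y) - 2), 0.0
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
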