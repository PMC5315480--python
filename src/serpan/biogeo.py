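"""Distance-based variance partitioning by soil type and reserve.

Core-genome divergence (proportion of differing SNP sites) and accessory
gene-content divergence (Jaccard distance on gene sets) are partitioned
among categorical factors with an adonis-style PERMANOVA: Gower-centered
inner-product matrix, sequential (Type-I) sums of squares via projection
hat matrices, pseudo-F statistics, and p-values by free permutation of
strain labels (exact enumeration when feasible). Bootstrap confidence
intervals resample strains with replacement.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "snp_distance",
    "gene_content_distance",
    "permanova",
    "bootstrap_r2_ci",
]


def snp_distance(snp_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise proportion of differing sites over sites called in both."""
    vals = snp_matrix.to_numpy(dtype=float)
    n = vals.shape[0]
    called = ~np.isnan(vals)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = called[i] & called[j]
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise ValueError(
                    f"no shared called sites between strains "
                    f"{snp_matrix.index[i]} and {snp_matrix.index[j]}"
                )
            d[i, j] = d[j, i] = float(
                np.mean(vals[i, shared] != vals[j, shared])
            )
    return pd.DataFrame(d, index=snp_matrix.index, columns=snp_matrix.index)


def gene_content_distance(matrix: pd.DataFrame, metric: str = "jaccard") -> pd.DataFrame:
    """Jaccard (default) or simple-mismatch distance on gene sets.

    Two strains with empty gene sets get distance 0 by convention.
    """
    vals = matrix.to_numpy(dtype=bool)
    n = vals.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "jaccard":
                union = np.count_nonzero(vals[i] | vals[j])
                inter = np.count_nonzero(vals[i] & vals[j])
                d[i, j] = d[j, i] = 0.0 if union == 0 else 1.0 - inter / union
            elif metric == "mismatch":
                d[i, j] = d[j, i] = float(np.mean(vals[i] != vals[j]))
            else:
                raise ValueError(f"unknown metric: {metric}")
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def _partition(
    g: np.ndarray, dummies: Sequence[np.ndarray], n: int
) -> tuple[np.ndarray, float]:
    """Sequential SS per factor given Gower matrix and per-factor dummies."""
    ss = []
    x = np.ones((n, 1))
    prev = 0.0  # tr(H0 G) = 0 for centered G, but compute for safety
    prev = float(np.sum(_hat(x) * g))
    for dm in dummies:
        x = np.column_stack([x, dm])
        cur = float(np.sum(_hat(x) * g))
        ss.append(cur - prev)
        prev = cur
    ss_total = float(np.trace(g))
    return np.array(ss), ss_total


def permanova(
    distance: pd.DataFrame,
    factors: pd.DataFrame,
    n_perm: int = 9999,
    seed: int | None = None,
    order: Sequence[str] | None = None,
    exact_max_perms: int = 10_000,
) -> pd.DataFrame:
    """Adonis-style PERMANOVA with sequential sums of squares.

    Factors enter in ``order`` (default: column order of ``factors``). The
    p-value for each factor is the fraction of label permutations whose
    pseudo-F meets or exceeds the observed one; all n! permutations are
    enumerated when n! <= exact_max_perms, otherwise ``n_perm`` random
    permutations are drawn (observed permutation included in the numerator
    and denominator).
    """
    strains = list(distance.index)
    n = len(strains)
    if not distance.columns.equals(distance.index):
        raise ValueError("distance matrix must have matching row/column labels")
    d = distance.to_numpy(dtype=float)
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
        raise ValueError("invalid distance matrix")
    factors = factors.loc[strains]
    order = list(order) if order is not None else list(factors.columns)
    dummies, dfs = [], []
    for name in order:
        levels = pd.Categorical(factors[name])
        if len(levels.categories) < 2:
            raise ValueError(f"factor {name!r} has a single level")
        dm = pd.get_dummies(levels, drop_first=True).to_numpy(dtype=float)
        dummies.append(dm)
        dfs.append(dm.shape[1])
    g = _gower_center(d)
    ss, ss_total = _partition(g, dummies, n)
    ss_resid = ss_total - ss.sum()
    df_resid = n - 1 - sum(dfs)
    f_obs = (ss / np.array(dfs)) / (ss_resid / df_resid)

    def perm_f(perm: np.ndarray) -> np.ndarray:
        gp = g[np.ix_(perm, perm)]
        ss_p, _ = _partition(gp, dummies, n)
        resid_p = ss_total - ss_p.sum()
        return (ss_p / np.array(dfs)) / (resid_p / df_resid)

    if math.factorial(n) <= exact_max_perms:
        count = np.zeros(len(order))
        total = 0
        for perm in itertools.permutations(range(n)):
            fp = perm_f(np.array(perm))
            count += fp >= f_obs - 1e-12
            total += 1
        pvals = count / total
    else:
        rng = np.random.default_rng(seed)
        count = np.ones(len(order))  # observed ordering counts
        for _ in range(n_perm):
            fp = perm_f(rng.permutation(n))
            count += fp >= f_obs - 1e-12
        pvals = count / (n_perm + 1)

    rows = []
    for i, name in enumerate(order):
        rows.append((name, dfs[i], ss[i], ss[i] / ss_total, f_obs[i], pvals[i]))
    rows.append(("residual", df_resid, ss_resid, ss_resid / ss_total, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["factor", "df", "SS", "R2", "pseudo_F", "p"]
    ).set_index("factor")


def bootstrap_r2_ci(
    distance: pd.DataFrame,
    factors: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
    order: Sequence[str] | None = None,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Percentile bootstrap CIs for per-factor R² (strain-level resampling).

    Replicates in which any factor collapses to a single level are discarded
    and counted. Resampled duplicate strains have zero mutual distance by
    construction (the diagonal is zero).
    """
    strains = list(distance.index)
    n = len(strains)
    order = list(order) if order is not None else list(factors.columns)
    d = distance.to_numpy(dtype=float)
    fac = factors.loc[strains]
    rng = np.random.default_rng(seed)
    samples: list[np.ndarray] = []
    discarded = 0
    while len(samples) < n_boot:
        idx = rng.integers(0, n, size=n)
        fb = fac.iloc[idx]
        if any(fb[name].nunique() < 2 for name in order):
            discarded += 1
            if discarded > 100 * n_boot:
                raise RuntimeError("bootstrap cannot find non-degenerate replicates")
            continue
        db = d[np.ix_(idx, idx)]
        dummies = [
            pd.get_dummies(pd.Categorical(fb[name]), drop_first=True).to_numpy(float)
            for name in order
        ]
        g = _gower_center(db)
        ss, ss_total = _partition(g, dummies, n)
        samples.append(ss / ss_total if ss_total > 0 else np.zeros(len(order)))
    arr = np.array(samples)
    lo, hi = (1 - ci) / 2 * 100, (1 + ci) / 2 * 100
    point = permanova(distance, factors, n_perm=0, seed=seed, order=order)
    rows = []
    for i, name in enumerate(order):
        rows.append(
            (
                name,
                float(point.loc[name, "R2"]),
                float(np.percentile(arr[:, i], lo)),
                float(np.percentile(arr[:, i], hi)),
                discarded,
            )
        )
    return pd.DataFrame(
        rows, columns=["factor", "R2", "ci_low", "ci_high", "n_discarded"]
    ).set_index("factor")
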