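"""Horizontal-transfer signal: do candidate genes come from distant donors?

For each accessory gene the input table records the 16S divergence between
the focal clade and the lineage carrying the gene's closest homolog. If
candidate (nickel-associated) genes were acquired horizontally from outside
the clade's usual gene pool, their donor distances should be shifted upward
relative to non-candidate accessory genes. Both a two-sample
Kolmogorov-Smirnov test and a Wilcoxon rank-sum test are reported, per
candidate FDR tier.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import wilcoxon_rank_sum

__all__ = ["ks_two_sample", "distance_shift_test"]


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample KS statistic D = sup |ECDF_x - ECDF_y| and its p-value.

    The exact small-sample null distribution is used when n*m <= 10,000,
    otherwise the asymptotic Kolmogorov distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    method = "exact" if x.size * y.size <= 10_000 else "asymp"
    res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


REQUIRED_COLUMNS = ["group_id", "distance_16S", "candidate_flag"]


def distance_shift_test(
    records: pd.DataFrame, tiers: Sequence[int] = (1, 5, 10)
) -> pd.DataFrame:
    """Compare donor 16S distances of candidate vs non-candidate genes.

    The reference class is always the non-candidate accessory genes
    (candidate_flag False). One row is emitted for the overall candidate set
    and, when an ``fdr_tier`` column is present, one per nested tier
    (candidates at FDR <= tier%). Reports KS D and p, Wilcoxon rank-sum p,
    and the candidate-minus-reference mean distance difference.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records lack columns: {missing}")
    noncand = records.loc[~records["candidate_flag"].astype(bool), "distance_16S"]
    if len(noncand) < 2:
        raise ValueError("need >= 2 non-candidate records as reference")

    def one_row(label: str, cand: pd.Series) -> dict:
        if len(cand) < 2:
            raise ValueError(f"candidate class '{label}' has < 2 records")
        d, p_ks = ks_two_sample(cand.to_numpy(), noncand.to_numpy())
        _, p_w = wilcoxon_rank_sum(cand.to_numpy(), noncand.to_numpy())
        return {
            "tier": label,
            "n_candidates": len(cand),
            "n_reference": len(noncand),
            "ks_D": d,
            "ks_p": p_ks,
            "wilcoxon_p": p_w,
            "mean_shift": float(cand.mean() - noncand.mean()),
        }

    rows = [one_row("all", records.loc[records["candidate_flag"].astype(bool), "distance_16S"])]
    if "fdr_tier" in records.columns:
        tier_vals = records["fdr_tier"].to_numpy()
        for t in tiers:
            mask = (tier_vals >= 0) & (tier_vals <= t) & records["candidate_flag"].astype(bool)
            if mask.sum() >= 2:
                rows.append(one_row(f"fdr{t}", records.loc[mask, "distance_16S"]))
    return pd.DataFrame(rows)
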