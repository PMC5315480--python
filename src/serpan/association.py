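"""Structure-corrected association mapping of gene content and SNPs.

Growth phenotypes are first residualized against admixture proportions
(ordinary least squares on the Q-matrix, last column dropped for
identifiability), then each accessory gene (carrier vs non-carrier) and each
biallelic core SNP (allele classes) is tested with a two-sided Wilcoxon
rank-sum test on the residuals, excluding fixed variants and singletons.
Multiple testing is handled with Bonferroni and FDR (Benjamini-Hochberg by
default, Storey q-values optionally). Effect sizes are reported on the raw
(non-residualized) phenotype: mean OD600 of carriers minus non-carriers,
together with carrier frequencies in serpentine and non-serpentine strains.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "regress_out_structure",
    "wilcoxon_rank_sum",
    "gene_content_association",
    "snp_association",
    "adjust_pvalues",
    "effect_and_frequencies",
    "annotate_significance",
    "significant_set",
]

RESULT_COLUMNS = [
    "variant_id",
    "variant_kind",
    "W",
    "p",
    "effect",
    "freq_S",
    "freq_N",
    "n_with",
    "n_without",
]


def regress_out_structure(phenotype: pd.Series, q_matrix: pd.DataFrame) -> pd.Series:
    """Residuals of an OLS fit of phenotype on intercept + Q loadings.

    The last loading column is dropped (rows sum to one, so the full Q is
    collinear with the intercept). Any residual rank deficiency is absorbed
    by a minimum-norm least-squares fit, with a warning. Residuals sum to 0.
    """
    if not phenotype.index.equals(q_matrix.index):
        q_matrix = q_matrix.loc[phenotype.index]
    if phenotype.isna().any() or q_matrix.isna().any().any():
        raise ValueError("missing values in phenotype or Q-matrix")
    n, k = q_matrix.shape
    design = np.column_stack([np.ones(n), q_matrix.to_numpy()[:, : max(k - 1, 0)]])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            f"structure design rank-deficient ({rank} < {design.shape[1]}); "
            "collinear columns absorbed by least-squares",
            stacklevel=2,
        )
    y = phenotype.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    residuals = y - design @ beta
    return pd.Series(residuals, index=phenotype.index, name="residual")


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 25
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (W, p).

    W is the rank sum of the first sample (midranks for ties). The p-value
    is exact (full null distribution) when the smaller group has at most
    ``exact_max_n`` observations and there are no ties; otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    n1 = x.size
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    ranks = stats.rankdata(combined)
    w = float(ranks[:n1].sum())
    if np.ptp(combined) == 0:
        return w, 1.0  # complete ties: no evidence either way
    method = "exact" if (min(n1, y.size) <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return w, float(res.pvalue)


def adjust_pvalues(p: Sequence[float], method: str = "bh") -> np.ndarray:
    """Bonferroni, Benjamini-Hochberg, or Storey q-value adjustment.

    Output order matches input. Storey's q-values multiply the BH step-up
    values by an estimate of the null proportion pi0 = min(1,
    mean(p > 0.5) / 0.5).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "qvalue":
        lam = 0.5
        pi0 = min(1.0, float(np.mean(p > lam)) / (1.0 - lam)) if p.size else 1.0
        pi0 = max(pi0, 1.0 / p.size)  # guard against pi0 = 0 degeneracies
        return np.minimum(pi0 * multipletests(p, method="fdr_bh")[1], 1.0)
    raise ValueError(f"unknown adjustment method: {method}")


def effect_and_frequencies(
    carrier_mask: pd.Series,
    raw_phenotype: pd.Series,
    soil_labels: pd.Series,
) -> tuple[float, float, float]:
    """Table-1-style effect and per-soil carrier frequencies.

    Effect = mean raw high-Ni OD600 of strains with the variant minus that of
    strains lacking it (raw, not residualized). freq_S / freq_N are carrier
    fractions among serpentine / non-serpentine strains.
    """
    carrier_mask = carrier_mask.astype(bool)
    n_with = int(carrier_mask.sum())
    n_without = int((~carrier_mask).sum())
    if n_with == 0 or n_without == 0:
        raise ValueError("variant fixed or absent: effect undefined")
    effect = float(
        raw_phenotype[carrier_mask].mean() - raw_phenotype[~carrier_mask].mean()
    )
    serp = soil_labels == "serpentine"
    freq_s = float(carrier_mask[serp].mean()) if serp.any() else float("nan")
    freq_n = float(carrier_mask[~serp].mean()) if (~serp).any() else float("nan")
    return effect, freq_s, freq_n


def _association_scan(
    matrix: pd.DataFrame,
    residuals: pd.Series,
    raw_phenotype: pd.Series | None,
    soil_labels: pd.Series | None,
    variant_kind: str,
    min_minor: int,
    exact_max_n: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows, skipped = [], []
    res = residuals.loc[matrix.index].to_numpy()
    for variant in matrix.columns:
        col = matrix[variant]
        if col.isna().any():
            skipped.append((variant, "not biallelic"))
            continue
        mask = col.to_numpy().astype(bool)
        n_with = int(mask.sum())
        n_without = mask.size - n_with
        if n_with == 0 or n_without == 0:
            skipped.append((variant, "fixed"))
            continue
        if min(n_with, n_without) < min_minor:
            skipped.append((variant, "singleton"))
            continue
        w, p = wilcoxon_rank_sum(res[mask], res[~mask], exact_max_n=exact_max_n)
        if raw_phenotype is not None and soil_labels is not None:
            effect, freq_s, freq_n = effect_and_frequencies(
                col.astype(bool), raw_phenotype.loc[matrix.index], soil_labels.loc[matrix.index]
            )
        else:
            effect = freq_s = freq_n = float("nan")
        rows.append((variant, variant_kind, w, p, effect, freq_s, freq_n, n_with, n_without))
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    skipped_df = pd.DataFrame(skipped, columns=["variant_id", "reason"])
    return results, skipped_df


def gene_content_association(
    matrix: pd.DataFrame,
    residuals: pd.Series,
    soil_labels: pd.Series | None = None,
    raw_phenotype: pd.Series | None = None,
    min_minor: int = 2,
    exact_max_n: int = 25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wilcoxon association of accessory gene presence with residual growth.

    Fixed genes carry no contrast and singletons (minor class, carrier or
    non-carrier, smaller than ``min_minor``) are excluded; both appear in the
    skipped table with a reason code. Returns (results, skipped).
    """
    return _association_scan(
        matrix, residuals, raw_phenotype, soil_labels, "gene", min_minor, exact_max_n
    )


def snp_association(
    snp_matrix: pd.DataFrame,
    residuals: pd.Series,
    soil_labels: pd.Series | None = None,
    raw_phenotype: pd.Series | None = None,
    min_minor: int = 2,
    exact_max_n: int = 25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Identical scan over biallelic core-genome SNPs (allele classes).

    Multi-allelic sites must be coded NaN columns (see
    pangenome.snp_matrix_from_sites); they are skipped with reason
    "not biallelic".
    """
    return _association_scan(
        snp_matrix, residuals, raw_phenotype, soil_labels, "snp", min_minor, exact_max_n
    )


def annotate_significance(
    results: pd.DataFrame,
    fdr_method: str = "bh",
    bonferroni_alpha: float = 0.05,
) -> pd.DataFrame:
    """Add q-values and a Bonferroni flag to a raw association scan."""
    out = results.copy()
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        out["bonferroni_sig"] = pd.Series(dtype=bool)
        return out
    out["q"] = adjust_pvalues(out["p"].to_numpy(), method=fdr_method)
    out["bonferroni_sig"] = (
        adjust_pvalues(out["p"].to_numpy(), method="bonferroni") < bonferroni_alpha
    )
    return out


def significant_set(results: pd.DataFrame, fdr_level: float = 0.10) -> pd.DataFrame:
    """Variants with q < fdr_level, Bonferroni subset flagged.

    Expects the output of annotate_significance. Rows are ordered by q then
    p; the same frame with no rows is the documented "no hits" outcome used
    for the low-nickel no-association contract.
    """
    if "q" not in results.columns:
        raise ValueError("results lack q-values; run annotate_significance first")
    hits = results[results["q"] < fdr_level]
    return hits.sort_values(["q", "p", "variant_id"], kind="stable").reset_index(drop=True)
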