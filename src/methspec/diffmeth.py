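"""Differential methylation: per-cancer tumor-vs-normal testing, probe-to-
gene aggregation, and a generic hypergeometric gene-set enrichment test.

Significance for a site means p < 0.05 AND Benjamini-Hochberg FDR < 0.05
within its cancer; the FDR condition dominates, but the conjunction is kept
as the screening rule.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_P = 0.05
DEFAULT_FDR = 0.05


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t-test with Satterthwaite degrees of freedom.

    Degenerate inputs follow a fixed convention: both groups constant with
    equal means gives (t=0, p=1); both constant with unequal means gives
    (t=+-inf, p=0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return (np.inf if x.mean() > y.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dm_sites(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    annotation: pd.DataFrame,
    cancer: str,
    p_threshold: float = DEFAULT_P,
    fdr_threshold: float = DEFAULT_FDR,
    split: str = "train",
) -> pd.DataFrame:
    """Per-probe Welch test, tumor vs normal, within one cancer's split.

    Returns a DataFrame (cancer_type, probe_id, gene, t_stat, p_value,
    fdr, direction, significant) with BH adjustment across this cancer's
    probes; direction is hyper when tumor mean exceeds normal mean.
    """
    sub = sheet[(sheet["cancer_type"] == cancer) & (sheet["split"] == split)]
    tumor = sub.index[sub["tissue"] == "tumor"].intersection(beta.columns)
    normal = sub.index[sub["tissue"] == "normal"].intersection(beta.columns)
    if len(normal) < 2 or len(tumor) < 2:
        raise ValueError(
            f"cancer {cancer} lacks tumor or normal {split} samples and is "
            "excluded from differential analysis"
        )
    xt = beta[tumor].to_numpy(dtype=float)
    xn = beta[normal].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(xt, xn, axis=1, equal_var=False, nan_policy="omit")
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # degenerate zero-variance probes: NaN from scipy -> fixed convention
    mean_diff = np.nanmean(xt, axis=1) - np.nanmean(xn, axis=1)
    degenerate = np.isnan(p)
    with np.errstate(invalid="ignore"):
        t[degenerate] = np.where(
            mean_diff[degenerate] == 0,
            0.0,
            np.sign(mean_diff[degenerate]) * np.inf,
        )
    p[degenerate] = np.where(mean_diff[degenerate] == 0, 1.0, 0.0)
    fdr = bh_fdr(p)
    return pd.DataFrame(
        {
            "cancer_type": cancer,
            "probe_id": beta.index,
            "gene": annotation["gene"].reindex(beta.index).to_numpy(),
            "t_stat": t,
            "p_value": p,
            "fdr": fdr,
            "direction": np.where(mean_diff >= 0, "hyper", "hypo"),
            "significant": (p < p_threshold) & (fdr < fdr_threshold),
        }
    )


def aggregate_to_genes(beta: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe betas to gene betas by unweighted promoter-probe mean.

    Missing-aware: a gene's value for a sample averages that sample's
    observed probes. Genes with no retained probes are dropped (callers
    filtering on a probe set should expect this).
    """
    genes = annotation["gene"].reindex(beta.index)
    if genes.isna().any():
        raise ValueError("every retained probe must carry a gene annotation")
    gene_beta = beta.groupby(genes.to_numpy()).mean()
    gene_beta.index.name = "gene"
    all_missing = gene_beta.isna().all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} genes with no observed values"
        )
        gene_beta = gene_beta.loc[~all_missing]
    return gene_beta


def hypergeom_enrichment(
    query_genes: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    For each named set, p = P(X >= overlap) drawing |query| genes from the
    universe; BH adjustment runs across sets. Returns a DataFrame indexed
    by set name with columns overlap, set_size, p_value, fdr, significant.
    """
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes) & set(universe)
    if query != set(query_genes):
        raise ValueError("query genes must be a subset of the universe")
    rows = []
    for name, genes in gene_sets.items():
        genes = set(genes) & set(universe)
        overlap = len(query & genes)
        # P(X >= overlap), X ~ Hypergeom(|U|, |set|, |query|)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(genes), len(query)))
        rows.append((name, overlap, len(genes), min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["set_name", "overlap", "set_size", "p_value"]
    ).set_index("set_name")
    out["fdr"] = bh_fdr(out["p_value"].to_numpy()) if len(out) else []
    out["significant"] = out["fdr"] < fdr_threshold
    return out
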