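"""Cancer-specificity scoring of gene methylation profiles.

For gene i and cancer N, with gene-level beta values aggregated over
promoter probes and m_iN the mean beta over cancer N's tumor samples:

    p_iN  = m_iN / sum_N m_iN                  (relative methylation prob.)
    H_i   = -sum_N p_iN log2 p_iN              (Shannon entropy, bits)
    mbar_N = mean_i m_iN                        (gene-average beta in N)
    C_iN  = SD_iN / mbar_N * 100                (coefficient of variation %)
    T_iN  = (H_i * m_iN) / (C_iN * mbar_N)      (specificity value)
    Xbar_i = mean_N T_iN
    M_iN  = (T_iN - Xbar_i) / (max_N T_iN - min_N T_iN)   (dissociation)

SD_iN is the sample standard deviation (n-1 denominator) of gene i's beta
across cancer N's tumor samples; the product C_iN * mbar_N penalizes
within-cancer heterogeneity. Each gene is assigned to the cancer maximizing
M_iN (equivalently T_iN), giving a one-gene-one-cancer specific biomarker
map. Per gene, M sums to zero and lies in [-1, 1].

Note the scoring direction: multiplying by H_i rewards genes whose
methylation mass is spread across cancers with a numerator boost, while the
m_iN factor and the heterogeneity denominator drive the cancer-wise
contrast. The formula is applied exactly as stated above; its recovery of
planted cancer-specific genes is established empirically in the test suite
rather than argued from the entropy term alone.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

DEFAULT_EPSILON = 1e-6

_COLUMNS = ["gene", "cancer_type", "m", "p", "H", "SD", "C", "T", "Xbar", "M", "assigned"]


def _tumor_groups(gene_beta: pd.DataFrame, sheet: pd.DataFrame) -> dict[str, pd.Index]:
    """Columns of gene_beta per cancer type, tumor samples only."""
    tumor = sheet[sheet["tissue"] == "tumor"]
    groups: dict[str, pd.Index] = {}
    for cancer in sorted(tumor["cancer_type"].unique()):
        cols = tumor.index[tumor["cancer_type"] == cancer].intersection(
            gene_beta.columns
        )
        if len(cols):
            groups[cancer] = cols
    if not groups:
        raise ValueError("no tumor samples found for any cancer")
    return groups


def gene_cancer_means(gene_beta: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """m_iN: genes x cancers mean beta over each cancer's tumor samples."""
    groups = _tumor_groups(gene_beta, sheet)
    m = pd.DataFrame(
        {cancer: gene_beta[cols].mean(axis=1) for cancer, cols in groups.items()}
    )
    m.columns.name = "cancer_type"
    return m


def relative_probabilities(m: pd.DataFrame) -> pd.DataFrame:
    """p_iN: rows of m normalized to sum to one.

    All-zero rows are degenerate (no methylation anywhere) and raise;
    callers exclude such genes beforehand.
    """
    totals = m.sum(axis=1)
    if (totals <= 0).any():
        bad = m.index[totals <= 0][:5].tolist()
        raise ValueError(f"genes with zero total methylation: {bad}")
    return m.div(totals, axis=0)


def shannon_entropy(p: pd.DataFrame | np.ndarray) -> pd.Series | float:
    """H_i in bits with the 0*log2(0) := 0 convention.

    Accepts a probability vector (returns a float) or a row-stochastic
    genes x cancers frame (returns a per-gene Series).
    """
    arr = np.asarray(p, dtype=float)
    if (arr < 0).any():
        raise ValueError("probabilities must be non-negative")
    logs = np.zeros_like(arr, dtype=float)
    np.log2(arr, where=arr > 0, out=logs)
    terms = arr * logs
    if arr.ndim == 1:
        return float(-terms.sum())
    H = -terms.sum(axis=1)
    if isinstance(p, pd.DataFrame):
        return pd.Series(H, index=p.index, name="H")
    return pd.Series(H)


def heterogeneity_terms(
    gene_beta: pd.DataFrame, sheet: pd.DataFrame, m: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """mbar_N, SD_iN and C_iN = SD/mbar*100 on tumor samples.

    mbar_N averages m over the genes present in ``m`` (the analysis set);
    SD uses the n-1 denominator and requires >= 2 tumor samples per cancer.
    """
    groups = _tumor_groups(gene_beta, sheet)
    small = [c for c, cols in groups.items() if len(cols) < 2]
    if small:
        raise ValueError(
            f"cancers with a single tumor sample, SD undefined: {small}"
        )
    mbar = m.mean(axis=0)
    mbar.name = "mbar"
    sd = pd.DataFrame(
        {
            cancer: gene_beta.loc[m.index, cols].std(axis=1, ddof=1)
            for cancer, cols in groups.items()
            if cancer in m.columns
        }
    )
    C = sd.div(mbar, axis=1) * 100.0
    return mbar, sd, C


def specificity_score(
    H: pd.Series,
    m: pd.DataFrame,
    C: pd.DataFrame,
    mbar: pd.Series,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """T_iN = (H_i * m_iN) / (C_iN * mbar_N), with C floored at epsilon.

    A zero coefficient of variation (a gene constant within a cancer)
    would blow the ratio up; flooring C at a small epsilon caps T instead
    of discarding the gene, and is warned about.
    """
    if (mbar <= 0).any():
        raise ValueError("mbar must be positive for every cancer")
    C_safe = C.copy()
    floored = C_safe < epsilon
    if floored.to_numpy().any():
        warnings.warn(
            f"{int(floored.to_numpy().sum())} coefficient-of-variation cells "
            f"floored at epsilon={epsilon}"
        )
        C_safe = C_safe.clip(lower=epsilon)
    T = m.mul(H, axis=0) / C_safe.mul(mbar, axis=1)
    return T


def dissociation_score(
    T: pd.DataFrame,
) -> tuple[pd.Series, pd.DataFrame, pd.Series]:
    """Xbar_i, M_iN = (T - Xbar)/(T_max - T_min), and the argmax assignment.

    Genes with a constant T profile (max == min) have no preferred cancer;
    they are excluded with a warning and absent from all three outputs.
    Per gene, M sums to 0, |M| <= 1, and argmax M coincides with argmax T.
    """
    if T.shape[1] < 2:
        raise ValueError("specificity requires at least 2 cancers")
    t_range = T.max(axis=1) - T.min(axis=1)
    degenerate = t_range <= 0
    if degenerate.any():
        warnings.warn(
            f"excluding {int(degenerate.sum())} genes with constant "
            "specificity profile (non-specific)"
        )
        T = T.loc[~degenerate]
        t_range = t_range.loc[~degenerate]
    if T.empty:
        raise ValueError("no genes with a non-constant specificity profile")
    Xbar = T.mean(axis=1)
    Xbar.name = "Xbar"
    M = T.sub(Xbar, axis=0).div(t_range, axis=0)
    assignment = M.idxmax(axis=1)
    assignment.name = "assigned_cancer"
    return Xbar, M, assignment


def compute_specificity_table(
    gene_beta: pd.DataFrame,
    sheet: pd.DataFrame,
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[pd.DataFrame, pd.Series]:
    """Full scoring chain on tumor samples: returns (long table, assignment).

    The table has one row per retained gene x cancer with every
    intermediate quantity (m, p, H, SD, C, T, Xbar, M) and an ``assigned``
    flag marking each gene's single maximizing cancer. Genes with zero
    total methylation or a constant T profile are excluded with warnings.
    """
    m = gene_cancer_means(gene_beta, sheet)
    if m.shape[1] < 2:
        raise ValueError("specificity requires at least 2 cancers")
    totals = m.sum(axis=1)
    if (totals <= 0).any():
        warnings.warn(
            f"excluding {int((totals <= 0).sum())} genes with zero total "
            "methylation"
        )
        m = m.loc[totals > 0]
    if m.empty:
        raise ValueError("no scorable genes")
    p = relative_probabilities(m)
    H = shannon_entropy(p)
    mbar, sd, C = heterogeneity_terms(gene_beta, sheet, m)
    T = specificity_score(H, m, C, mbar, epsilon=epsilon)
    Xbar, M, assignment = dissociation_score(T)
    genes = M.index
    long = (
        pd.concat(
            {
                "m": m.loc[genes],
                "p": p.loc[genes],
                "SD": sd.loc[genes],
                "C": C.loc[genes],
                "T": T.loc[genes],
                "M": M,
            },
            axis=1,
        )
        .stack(future_stack=True)
        .reset_index()
    )
    long.columns = ["gene", "cancer_type"] + ["m", "p", "SD", "C", "T", "M"]
    long["H"] = H.reindex(long["gene"]).to_numpy()
    long["Xbar"] = Xbar.reindex(long["gene"]).to_numpy()
    long["assigned"] = (
        assignment.reindex(long["gene"]).to_numpy() == long["cancer_type"]
    )
    return long[_COLUMNS], assignment


def identify_grsdm(
    gene_beta: pd.DataFrame,
    sheet: pd.DataFrame,
    gpcr_genes: set[str],
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[pd.DataFrame, pd.Series, dict[str, list[str]]]:
    """Score the GPCR-related characteristic genes and assign each to one
    cancer.

    Restricts ``gene_beta`` to the supplied gene set (typically the union
    of per-cancer characteristic genes intersected with the GPCR list),
    runs the scoring chain, and emits per-cancer specific-gene lists sorted
    by descending dissociation score M.
    """
    genes = gene_beta.index.intersection(sorted(gpcr_genes))
    if genes.empty:
        raise ValueError("none of the requested genes are in the beta matrix")
    table, assignment = compute_specificity_table(
        gene_beta.loc[genes], sheet, epsilon=epsilon
    )
    assigned_rows = table[table["assigned"]]
    per_cancer: dict[str, list[str]] = {}
    for cancer, sub in assigned_rows.groupby("cancer_type"):
        ranked = sub.sort_values("M", ascending=False)
        per_cancer[str(cancer)] = ranked["gene"].tolist()
    return table, assignment, per_cancer
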