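"""Downstream evaluation of the specific-gene panel: pan-cancer overview
test, multi-class classification, survival screening, cross-cohort
validation, and ridge-based drug-sensitivity correlation.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from lifelines.statistics import logrank_test

from methspec.synthetic import DrugPanel

DEFAULT_RHO_THRESHOLD = -0.4
DEFAULT_P_THRESHOLD = 0.05
DEFAULT_RIDGE_LAMBDA = 1.0
VALIDATION_P = 1e-4


def kruskal_wallis_overview(
    gene_beta: pd.DataFrame, sheet: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene Kruskal-Wallis test of beta across cancers (tumor samples).

    Tie-corrected rank statistic with a chi-squared reference on N-1
    degrees of freedom. A gene whose values are all tied yields p = 1 with
    a warning.
    """
    tumor = sheet[sheet["tissue"] == "tumor"]
    cancers = sorted(tumor["cancer_type"].unique())
    if len(cancers) < 2:
        raise ValueError("need at least 2 cancers")
    groups_cols = []
    for cancer in cancers:
        cols = tumor.index[tumor["cancer_type"] == cancer].intersection(
            gene_beta.columns
        )
        if len(cols) < 2:
            raise ValueError(f"cancer {cancer} has fewer than 2 tumor samples")
        groups_cols.append(cols)
    rows = []
    n_tied = 0
    for gene, values in gene_beta.iterrows():
        samples = [values[cols].dropna().to_numpy() for cols in groups_cols]
        try:
            with np.errstate(invalid="ignore"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    h, p = stats.kruskal(*samples)
        except ValueError:
            h, p = np.nan, np.nan
        if np.isnan(p):  # every value tied: no rank information
            h, p = 0.0, 1.0
            n_tied += 1
        rows.append((gene, float(h), float(p)))
    if n_tied:
        warnings.warn(f"{n_tied} genes with all-tied values: p set to 1")
    return pd.DataFrame(rows, columns=["gene", "H_stat", "p_value"]).set_index(
        "gene"
    )


def rf_multiclass_auc(
    gene_beta: pd.DataFrame,
    sheet: pd.DataFrame,
    seed: int = 0,
    n_trees: int = 500,
    train_split: str = "train",
    test_split: str = "test",
) -> tuple[dict[str, float], float]:
    """Random-forest cancer-type diagnosis with one-vs-rest AUCs.

    Trains on tumor samples in ``train_split``, evaluates per-class
    one-vs-rest AUC from predicted probabilities on ``test_split``, and
    returns (per-class AUCs, unweighted macro average). Classes missing
    from the test split are skipped with a warning.
    """
    tumor = sheet[sheet["tissue"] == "tumor"]
    train_ids = tumor.index[tumor["split"] == train_split].intersection(
        gene_beta.columns
    )
    test_ids = tumor.index[tumor["split"] == test_split].intersection(
        gene_beta.columns
    )
    y_train = tumor.loc[train_ids, "cancer_type"].to_numpy()
    y_test = tumor.loc[test_ids, "cancer_type"].to_numpy()
    if len(np.unique(y_train)) < 2:
        raise ValueError("need at least 2 cancer types in training data")
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(gene_beta[train_ids].to_numpy(dtype=float).T, y_train)
    proba = forest.predict_proba(gene_beta[test_ids].to_numpy(dtype=float).T)
    aucs: dict[str, float] = {}
    for k, cls in enumerate(forest.classes_):
        positives = y_test == cls
        if positives.all() or not positives.any():
            warnings.warn(f"class {cls} absent from one side of the test split")
            continue
        aucs[str(cls)] = float(roc_auc_score(positives, proba[:, k]))
    if not aucs:
        raise ValueError("no evaluable classes in the test split")
    macro = float(np.mean(list(aucs.values())))
    return aucs, macro


def km_logrank_screen(
    gene_beta: pd.DataFrame,
    survival: pd.DataFrame,
    gene: str,
    cancer: str,
    sheet: pd.DataFrame | None = None,
    threshold_split: str = "train",
) -> tuple[float, pd.Series]:
    """Mean-beta split plus two-group log-rank test for one gene/cancer.

    The threshold is the gene's mean beta over the cancer's tumor samples
    (training split when a sheet with splits is supplied, all otherwise);
    samples at or below the mean form the low group. Returns (p, group
    labels); p is NaN with a warning when a side of the split is empty.
    A gene is called prognostic at p < 0.05.
    """
    surv = survival[survival["cancer_type"] == cancer]
    ids = surv.index.intersection(gene_beta.columns)
    if len(ids) < 4:
        raise ValueError(f"too few survival samples for {cancer}")
    betas = gene_beta.loc[gene, ids].astype(float)
    if sheet is not None and "split" in sheet.columns:
        thr_ids = sheet.index[
            (sheet["cancer_type"] == cancer)
            & (sheet["tissue"] == "tumor")
            & (sheet["split"] == threshold_split)
        ].intersection(gene_beta.columns)
        if len(thr_ids) == 0:
            thr_ids = ids
    else:
        thr_ids = ids
    threshold = float(gene_beta.loc[gene, thr_ids].astype(float).mean())
    groups = pd.Series(
        np.where(betas > threshold, "high", "low"), index=ids, name="group"
    )
    high = groups == "high"
    if high.all() or not high.any():
        warnings.warn(
            f"mean-beta threshold non-informative for {gene} in {cancer}"
        )
        return float("nan"), groups
    res = logrank_test(
        surv.loc[ids[high], "time"],
        surv.loc[ids[~high], "time"],
        event_observed_A=surv.loc[ids[high], "event"],
        event_observed_B=surv.loc[ids[~high], "event"],
    )
    return float(res.p_value), groups


def validate_grsdm(
    gene: str,
    assigned_cancer: str,
    val_gene_beta: pd.DataFrame,
    val_sheet: pd.DataFrame,
    p_threshold: float = VALIDATION_P,
) -> tuple[str, float]:
    """Cross-cohort consistency check for one assigned gene.

    Verdict 'consistent' requires the gene's mean beta among the
    validation cohort's tumor samples to peak in its assigned cancer AND a
    one-vs-rest Wilcoxon rank-sum test (assigned cancer vs all others
    pooled) with p below ``p_threshold``. Returns (verdict, p) where the
    verdict is 'consistent', 'inconsistent' or 'untestable' (gene or
    cancer absent).
    """
    if gene not in val_gene_beta.index:
        return "untestable", float("nan")
    tumor = val_sheet[val_sheet["tissue"] == "tumor"]
    cancers = sorted(tumor["cancer_type"].unique())
    if assigned_cancer not in cancers or len(cancers) < 2:
        return "untestable", float("nan")
    values = val_gene_beta.loc[gene]
    in_ids = tumor.index[tumor["cancer_type"] == assigned_cancer].intersection(
        values.index
    )
    out_ids = tumor.index[tumor["cancer_type"] != assigned_cancer].intersection(
        values.index
    )
    if len(in_ids) < 2 or len(out_ids) < 2:
        return "untestable", float("nan")
    means = {
        c: values[
            tumor.index[tumor["cancer_type"] == c].intersection(values.index)
        ].mean()
        for c in cancers
    }
    is_max = max(means, key=means.get) == assigned_cancer
    stat = stats.mannwhitneyu(
        values[in_ids].dropna(), values[out_ids].dropna(), alternative="two-sided"
    )
    p = float(stat.pvalue)
    return ("consistent" if is_max and p < p_threshold else "inconsistent"), p


def ridge_ic50_predict(
    panel: DrugPanel, ridge_lambda: float = DEFAULT_RIDGE_LAMBDA
) -> pd.DataFrame:
    """Predict per-sample IC50s from expression via ridge regression.

    Per drug, ridge regresses cell-line IC50 on gene-wise standardized
    cell-line expression (intercept unpenalized); the coefficients are
    applied to the sample expression standardized with the *cell-line*
    means and SDs, which is what makes coefficients transferable across
    the two matrices. Genes constant across cell lines carry no
    information and are zeroed after standardization.
    """
    if ridge_lambda < 0:
        raise ValueError("ridge penalty must be >= 0")
    if panel.cellline_expression.shape[1] < 2:
        raise ValueError("need at least 2 cell lines")
    X = panel.cellline_expression.to_numpy(dtype=float)  # genes x lines
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    safe_sd = np.where(sd > 0, sd, 1.0)
    Xz = ((X - mean) / safe_sd).T  # lines x genes
    Xz[:, (sd == 0).ravel()] = 0.0
    Sz = ((panel.sample_expression.to_numpy(dtype=float) - mean) / safe_sd).T
    Sz[:, (sd == 0).ravel()] = 0.0
    Y = panel.ic50.to_numpy(dtype=float)  # lines x drugs
    y_mean = Y.mean(axis=0, keepdims=True)
    # closed-form ridge with unpenalized intercept: center X and Y, solve
    # (X'X + lambda I) B = X'Y, then add back the intercept
    Xc = Xz - Xz.mean(axis=0, keepdims=True)
    Yc = Y - y_mean
    n_genes = Xc.shape[1]
    B = np.linalg.solve(Xc.T @ Xc + ridge_lambda * np.eye(n_genes), Xc.T @ Yc)
    pred = (Sz - Xz.mean(axis=0, keepdims=True)) @ B + y_mean
    return pd.DataFrame(
        pred, index=panel.sample_expression.columns, columns=panel.ic50.columns
    )


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Exact two-sided permutation p-value for Spearman rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    permuted = ry[perms]  # n! x n
    rx_c = rx - rx.mean()
    denom = np.sqrt((rx_c**2).sum() * ((permuted - permuted.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))
    num = permuted @ rx_c
    rhos = np.divide(num, denom, out=np.zeros_like(num, dtype=float), where=denom > 0)
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman correlation with a two-sided p-value.

    Tie-aware ranks; t-approximation for n >= 10 and an exact permutation
    p-value below that, where the approximation is unreliable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need >= 5 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if len(x) < 10:
        p = _spearman_exact_p(x, y, rho)
    return rho, float(p)


def drug_correlation(
    grsdm_beta: pd.DataFrame,
    predicted_ic50: pd.DataFrame,
    rho_threshold: float = DEFAULT_RHO_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Spearman screen of gene methylation against predicted drug IC50.

    For each (gene, drug) pair — all combinations unless ``pairs`` is
    given — computes Spearman rho over the shared samples. A pair is a hit
    iff rho < rho_threshold AND p < p_threshold, both strict, so a
    negative methylation/IC50 association marks the drug as a candidate
    sensitizer for tumors hypermethylated at that gene. Constant vectors
    are skipped with a warning.
    """
    samples = grsdm_beta.columns.intersection(predicted_ic50.index)
    if len(samples) < 5:
        raise ValueError("need >= 5 shared samples")
    if pairs is None:
        pairs = [
            (g, d) for g in grsdm_beta.index for d in predicted_ic50.columns
        ]
    rows = []
    n_skipped = 0
    for gene, drug in pairs:
        x = grsdm_beta.loc[gene, samples].to_numpy(dtype=float)
        y = predicted_ic50.loc[samples, drug].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 5:
            n_skipped += 1
            continue
        try:
            rho, p = spearman_test(x[ok], y[ok])
        except ValueError:
            n_skipped += 1
            continue
        rows.append(
            (gene, drug, rho, p, bool(rho < rho_threshold and p < p_threshold))
        )
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} degenerate (gene, drug) pairs")
    return pd.DataFrame(
        rows, columns=["gene", "drug", "spearman_rho", "p_value", "passes"]
    )
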