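"""Preprocessing: promoter mapping, missingness filter, KNN imputation,
batch harmonization and stratified sample splitting.

Conventions: coordinates are 0-based; the promoter window is the
strand-aware half-open interval [TSS-upstream, TSS+downstream); "missingness
exceeding" a threshold means strictly greater than; KNN imputation runs over
probes (rows), matching the classical array-imputation convention.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

DEFAULT_UPSTREAM = 2000
DEFAULT_DOWNSTREAM = 500


def _check_beta(beta: pd.DataFrame) -> None:
    if beta.index.has_duplicates:
        raise ValueError("duplicate probe ids in beta matrix")
    if beta.columns.has_duplicates:
        raise ValueError("duplicate sample ids in beta matrix")
    values = beta.to_numpy(dtype=float)
    observed = values[~np.isnan(values)]
    if observed.size and (observed.min() < 0.0 or observed.max() > 1.0):
        raise ValueError("observed beta values must lie in [0, 1]")


def promoter_filter(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> pd.DataFrame:
    """Retain probes inside the promoter window of their annotated gene.

    A probe on the + strand is kept iff
    ``tss - upstream <= pos < tss + downstream``; on the - strand the
    window is mirrored (transcription-direction offset ``tss - pos`` must
    lie in ``[-upstream, downstream)``). Probe order is preserved.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    ann = annotation.reindex(beta.index)
    if ann["gene"].isna().any():
        missing = beta.index[ann["gene"].isna()][:5].tolist()
        raise ValueError(f"probes missing annotation, e.g. {missing}")
    strand = ann["strand"]
    bad = ~strand.isin(["+", "-"])
    if bad.any():
        raise ValueError(
            f"unknown strand for probes {beta.index[bad][:5].tolist()}"
        )
    offset = np.where(
        strand == "+", ann["pos"] - ann["tss"], ann["tss"] - ann["pos"]
    )
    keep = (offset >= -upstream) & (offset < downstream)
    return beta.loc[keep]


def filter_missing(beta: pd.DataFrame, max_missing_frac: float = 0.7) -> pd.DataFrame:
    """Drop probes whose missing count strictly exceeds the allowed fraction.

    A probe is retained iff ``n_missing <= max_missing_frac * n_samples``
    (boundary kept): with 10 samples and threshold 0.7, a probe with 7
    missing values survives and one with 8 does not.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must lie in [0, 1]")
    _check_beta(beta)
    n_missing = beta.isna().sum(axis=1)
    keep = n_missing <= max_missing_frac * beta.shape[1]
    out = beta.loc[keep]
    if out.empty and not beta.empty:
        raise ValueError("no probes survive the missingness filter")
    return out


def knn_impute(beta: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing betas from the k nearest probes.

    Distance between two probes is the Euclidean distance over the samples
    where both are observed (infinite when they share none). Each missing
    entry is replaced by the unweighted mean of the k nearest probes'
    values at that sample, considering only probes observed there; distance
    ties break by probe order. Observed entries are returned untouched.

    The distance convention (plain Euclidean over the jointly observed
    columns, no missingness rescaling) is pinned so results are exactly
    reproducible; it is implemented directly rather than through a generic
    imputer whose distance differs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    _check_beta(beta)
    values = beta.to_numpy(dtype=float)
    mask = np.isnan(values)
    if not mask.any():
        return beta.copy()
    fully_missing = mask.all(axis=1)
    if fully_missing.any():
        raise ValueError(
            "probes with zero observed values cannot be imputed: "
            f"{beta.index[fully_missing][:5].tolist()}"
        )
    filled = np.where(mask, 0.0, values)
    obs = (~mask).astype(float)
    # squared partial Euclidean distances via masked inner products:
    # d2(a,b) = sum_{j observed in both} (a_j - b_j)^2
    sq = filled**2
    out = values.copy()
    for i in np.flatnonzero(mask.any(axis=1)):
        d2 = (
            (sq[i] * obs[i]) @ obs.T
            + obs[i] @ (sq * obs).T
            - 2.0 * (filled[i] * obs[i]) @ (filled * obs).T
        )
        shared = obs[i] @ obs.T
        d2[shared == 0] = np.inf
        d2[i] = np.inf  # never its own neighbor
        d = np.sqrt(np.maximum(d2, 0.0))
        order = np.argsort(d, kind="stable")
        for j in np.flatnonzero(mask[i]):
            donors = order[(~mask[order, j]) & np.isfinite(d[order])][:k]
            if donors.size == 0:
                raise ValueError(
                    f"no donor probes for entry ({beta.index[i]}, "
                    f"{beta.columns[j]})"
                )
            out[i, j] = values[donors, j].mean()
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


def batch_adjust(beta: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-probe location-scale batch harmonization.

    Each batch's values for a probe are standardized with the batch mean
    and SD, then rescaled to the probe's pooled mean and SD, and clipped to
    [0, 1]. This removes additive and multiplicative batch offsets probe by
    probe; it is a deliberate light-weight alternative to empirical-Bayes
    batch correction and shares its intent (bridge cohorts) without the
    hierarchical prior. Within-batch rank order per probe is preserved.
    """
    batches = sheet.loc[beta.columns, "batch"]
    levels = batches.unique()
    if len(levels) < 2:
        warnings.warn("single batch: returning input unchanged")
        return beta.copy()
    counts = batches.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"batches with fewer than 2 samples: {small.index.tolist()}")
    values = beta.to_numpy(dtype=float)
    pooled_mean = np.nanmean(values, axis=1, keepdims=True)
    pooled_sd = np.nanstd(values, axis=1, ddof=1, keepdims=True)
    out = values.copy()
    for level in levels:
        cols = np.flatnonzero((batches == level).to_numpy())
        block = values[:, cols]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            mean = np.nanmean(block, axis=1, keepdims=True)
            sd = np.nanstd(block, axis=1, ddof=1, keepdims=True)
        # betas live in [0, 1]; SDs below 1e-12 are numerically constant
        # and must not become explosive scale factors
        informative = (sd > 1e-12) & (pooled_sd > 1e-12)
        scale = np.divide(pooled_sd, sd, out=np.ones_like(sd), where=informative)
        scale[~informative] = 1.0
        out[:, cols] = (block - mean) * scale + pooled_mean
    out = np.clip(out, 0.0, 1.0)
    out[np.isnan(values)] = np.nan
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


def split_samples(
    sheet: pd.DataFrame, train_frac: float = 0.7, seed: int = 0
) -> pd.DataFrame:
    """Assign train/test splits stratified within cancer x tissue.

    Each stratum contributes ``round(train_frac * n)`` training samples
    (half-up rounding); strata of size 1 go wholly to train with a
    warning. Deterministic for a given seed. Samples already marked
    ``validation`` are left untouched.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    out = sheet.copy()
    assignable = out.index[out["split"] != "validation"]
    strata = out.loc[assignable].groupby(["cancer_type", "tissue"], sort=True)
    for (cancer, tissue), sub in strata:
        ids = sub.index.to_numpy()
        n = len(ids)
        if n == 1:
            warnings.warn(
                f"stratum {cancer}/{tissue} has a single sample; assigned to train"
            )
            out.loc[ids, "split"] = "train"
            continue
        n_train = int(np.floor(train_frac * n + 0.5))
        n_train = min(max(n_train, 0), n)
        perm = rng.permutation(n)
        out.loc[ids[perm[:n_train]], "split"] = "train"
        out.loc[ids[perm[n_train:]], "split"] = "test"
    return out
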