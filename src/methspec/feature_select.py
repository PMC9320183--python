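"""All-relevant feature selection (Boruta) and tumor/normal classification.

Boruta is implemented natively because its verdict procedure is part of the
tested pipeline: each iteration appends independently permuted "shadow"
copies of the surviving features, fits a random forest, and scores a hit
for every real feature whose mean-decrease-in-impurity importance exceeds
the best shadow importance. Hits accumulate into two-sided binomial tests
(Bonferroni-corrected across features still in play) that confirm or reject
features; features still tentative at the iteration cap are resolved by
comparing their median importance history against the median best-shadow
importance (the classical "rough fix").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier


@dataclass(frozen=True)
class BorutaConfig:
    n_iterations: int = 100
    alpha: float = 0.05
    forest_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 10:
            raise ValueError("n_iterations must be >= 10")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.forest_size < 1:
            raise ValueError("forest_size must be >= 1")


def boruta_select(
    X: pd.DataFrame, y: np.ndarray, cfg: BorutaConfig | None = None
) -> pd.DataFrame:
    """Run the Boruta loop on a features x samples matrix.

    Returns a DataFrame indexed by feature_id with columns status
    ('confirmed' / 'rejected'), hit_count, n_iterations_seen and
    importance_history (list of per-iteration importances; NaN once a
    feature leaves the forest). Deterministic under cfg.seed.
    """
    cfg = cfg or BorutaConfig()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are constant: nothing to select against")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    if X.shape[0] < 1:
        raise ValueError("at least one feature required")
    features = list(X.index)
    data = X.to_numpy(dtype=float).T  # samples x features
    n_feat = len(features)
    rng = np.random.default_rng(cfg.seed)

    status = np.array(["tentative"] * n_feat, dtype=object)
    hits = np.zeros(n_feat, dtype=int)
    seen = np.zeros(n_feat, dtype=int)
    history = [[] for _ in range(n_feat)]
    shadow_max_history: list[float] = []
    active = np.arange(n_feat)  # confirmed + tentative stay in the forest

    for it in range(1, cfg.n_iterations + 1):
        real = data[:, active]
        shadow = real.copy()
        for col in range(shadow.shape[1]):
            rng.shuffle(shadow[:, col])
        design = np.hstack([real, shadow])
        # max_features=1 (fully random split-candidate choice) spreads
        # impurity importance across redundant informative features; with
        # the usual sqrt(p) sampling, mutually redundant relevant features
        # dilute each other below the shadow threshold and an all-relevant
        # selector starts dropping true positives
        forest = RandomForestClassifier(
            n_estimators=cfg.forest_size,
            max_features=1,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        forest.fit(design, y)
        imp = forest.feature_importances_
        imp_real = imp[: len(active)]
        shadow_max = float(imp[len(active) :].max())
        shadow_max_history.append(shadow_max)
        tentative_mask = status[active] == "tentative"
        hits[active[tentative_mask]] += (imp_real > shadow_max)[tentative_mask]
        seen[active[tentative_mask]] += 1
        for pos, fi in enumerate(active):
            history[fi].append(float(imp_real[pos]))

        undecided = np.flatnonzero(status == "tentative")
        if undecided.size:
            m = undecided.size  # Bonferroni across features still in play
            p_hi = stats.binom.sf(hits[undecided] - 1, seen[undecided], 0.5)
            p_lo = stats.binom.cdf(hits[undecided], seen[undecided], 0.5)
            status[undecided[p_hi * m < cfg.alpha / 2]] = "confirmed"
            status[undecided[p_lo * m < cfg.alpha / 2]] = "rejected"
            active = np.flatnonzero(status != "rejected")
        if not (status == "tentative").any():
            break

    # rough fix for leftovers: median importance vs median best-shadow
    leftovers = np.flatnonzero(status == "tentative")
    if leftovers.size:
        shadow_median = float(np.median(shadow_max_history))
        for fi in leftovers:
            med = float(np.median(history[fi])) if history[fi] else 0.0
            status[fi] = "confirmed" if med > shadow_median else "rejected"

    return pd.DataFrame(
        {
            "status": status,
            "hit_count": hits,
            "n_iterations_seen": seen,
            "importance_history": [list(h) for h in history],
        },
        index=pd.Index(features, name="feature_id"),
    )


def decision_tree_auc(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    seed: int = 0,
) -> float:
    """CART decision tree AUC for a binary tumor/normal problem.

    Matrices are features x samples; probabilities for the positive class
    come from the leaf class fractions. Gini criterion, unlimited depth.
    """
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    if len(np.unique(y_test)) < 2:
        raise ValueError("test labels contain a single class: AUC undefined")
    tree = DecisionTreeClassifier(criterion="gini", random_state=seed)
    tree.fit(X_train.to_numpy(dtype=float).T, y_train)
    proba = tree.predict_proba(X_test.to_numpy(dtype=float).T)[:, 1]
    return float(roc_auc_score(y_test, proba))


def characteristic_gene_union(
    per_cancer_verdicts: dict[str, pd.DataFrame],
    probe_to_gene: pd.Series,
    gpcr_genes: set[str],
) -> set[str]:
    """Union of confirmed features' genes across cancers, intersected with
    the GPCR-related gene list.

    Verdicts index probes; ``probe_to_gene`` maps probe ids to gene ids.
    An empty intersection is legal (warned, not fatal).
    """
    union: set[str] = set()
    for cancer, verdict in per_cancer_verdicts.items():
        confirmed = verdict.index[verdict["status"] == "confirmed"]
        genes = probe_to_gene.reindex(confirmed)
        if genes.isna().any():
            raise ValueError(
                f"confirmed probes without gene mapping in {cancer}"
            )
        union |= set(genes)
    out = union & set(gpcr_genes)
    if not out:
        warnings.warn("no characteristic genes intersect the GPCR list")
    return out
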