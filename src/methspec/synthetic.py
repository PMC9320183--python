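"""Synthetic pan-cancer methylation study generator with planted truth.

Every downstream stage of the pipeline is exercised against cohorts built
here, where the answer is known by construction: which probes are
differentially methylated tumor-vs-normal, which genes are specifically
hypermethylated in exactly one cancer type, which genes drive survival, and
which (gene, drug) pairs carry a real methylation/IC50 anti-correlation.

Noise is added on the beta scale and clipped to [0, 1]; the clipping bias is
negligible for the default baselines (0.15-0.45) and noise SD (0.05), but
grows if effects push means near the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from methspec.config import CohortConfig

# child-stream indices off the base seed, so each artifact draws from an
# independent, reproducible stream
_STREAM_ANNOTATION = 0
_STREAM_COHORT = 1
_STREAM_VALIDATION = 2
_STREAM_SURVIVAL = 3
_STREAM_DRUGS = 4

PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 500


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config_seed).spawn(5)[stream])


@dataclass
class PlantedTruth:
    """Ground truth planted into a synthetic cohort.

    specific_gene_map maps each planted cancer-specific gene to the single
    cancer in which its tumor samples are hypermethylated. dm_sites holds,
    per cancer, every probe whose tumor samples are shifted relative to
    normals (extra differential probes plus the specific genes' probes).
    """

    specific_gene_map: dict[str, str]
    dm_sites: dict[str, list[str]]
    survival_risk_genes: list[str]
    drug_coefficients: dict[str, dict[str, float]] = field(default_factory=dict)
    drug_sensitive_pairs: list[tuple[str, str]] = field(default_factory=list)
    gpcr_genes: list[str] = field(default_factory=list)
    probe_baseline: pd.Series | None = None

    def __post_init__(self) -> None:
        genes = list(self.specific_gene_map)
        if len(genes) != len(set(genes)):
            raise ValueError("a specific gene may be planted in only one cancer")

    def extra_dm_sites(self, cancer: str, annotation: pd.DataFrame) -> list[str]:
        """Planted differential probes of `cancer` outside specific genes."""
        specific = {
            g for g, c in self.specific_gene_map.items() if c == cancer
        }
        gene_of = annotation["gene"]
        return [p for p in self.dm_sites[cancer] if gene_of.loc[p] not in specific]


def _gene_ids(config: CohortConfig) -> list[str]:
    width = max(4, len(str(config.n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]


def _cancer_ids(config: CohortConfig) -> list[str]:
    return [f"C{i:02d}" for i in range(1, config.n_cancers + 1)]


def generate_annotation(config: CohortConfig) -> pd.DataFrame:
    """Build a probe annotation table (probe_id-indexed DataFrame).

    Each gene receives a TSS, a strand, and ``sites_per_gene`` probes;
    ``promoter_fraction`` of the probes land inside the strand-aware
    promoter window [TSS-2000, TSS+500) and the rest land outside it, so
    the promoter filter is genuinely exercised. Coordinates are 0-based.
    """
    rng = _rng(config.seed, _STREAM_ANNOTATION)
    genes = _gene_ids(config)
    rows = []
    n_inside = int(round(config.promoter_fraction * config.sites_per_gene))
    for gi, gene in enumerate(genes):
        chrom = f"chr{gi % 22 + 1}"
        tss = 100_000 + 50_000 * gi
        strand = "+" if rng.random() < 0.5 else "-"
        # signed offsets relative to transcription direction: negative =
        # upstream, positive = downstream
        inside = rng.integers(-PROMOTER_UPSTREAM, PROMOTER_DOWNSTREAM, size=n_inside)
        outside = rng.integers(
            PROMOTER_DOWNSTREAM, 5_000, size=config.sites_per_gene - n_inside
        )
        for si, offset in enumerate(np.concatenate([inside, outside])):
            pos = tss + int(offset) if strand == "+" else tss - int(offset)
            rows.append(
                {
                    "probe_id": f"cg_{gene}_{si + 1}",
                    "chrom": chrom,
                    "pos": max(pos, 0),
                    "strand": strand,
                    "gene": gene,
                    "tss": tss,
                }
            )
    ann = pd.DataFrame(rows).set_index("probe_id")
    return ann


def _sample_sheet(
    config: CohortConfig, cohort: str, n_tumor: int, n_normal: int
) -> pd.DataFrame:
    rows = []
    tag = "" if cohort == "discovery" else "V"
    for cancer in _cancer_ids(config):
        for i in range(n_tumor):
            rows.append((f"{cancer}{tag}_T{i + 1:03d}", cancer, "tumor"))
        for i in range(n_normal):
            rows.append((f"{cancer}{tag}_N{i + 1:03d}", cancer, "normal"))
    sheet = pd.DataFrame(rows, columns=["sample_id", "cancer_type", "tissue"])
    sheet["batch"] = cohort
    sheet["split"] = "train" if cohort == "discovery" else "validation"
    return sheet.set_index("sample_id")


def _signal_matrix(
    config: CohortConfig,
    annotation: pd.DataFrame,
    sheet: pd.DataFrame,
    truth: PlantedTruth,
    baseline: pd.Series,
) -> pd.DataFrame:
    """Noise-free expected beta for every (probe, sample)."""
    signal = pd.DataFrame(
        np.tile(baseline.to_numpy()[:, None], (1, len(sheet))),
        index=annotation.index,
        columns=sheet.index,
    )
    gene_probes = annotation.groupby("gene").groups
    for cancer in _cancer_ids(config):
        tumor = sheet.index[
            (sheet["cancer_type"] == cancer) & (sheet["tissue"] == "tumor")
        ]
        extra = truth.extra_dm_sites(cancer, annotation)
        if extra:
            signal.loc[extra, tumor] += config.dm_effect
        for gene, assigned in truth.specific_gene_map.items():
            if assigned == cancer:
                signal.loc[gene_probes[gene], tumor] += config.specific_effect
    return signal


def _finish_matrix(
    signal: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    values = signal.to_numpy(dtype=float)
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, 1.0)
    n_missing = int(round(config.missing_rate * values.size))
    if n_missing:
        flat = rng.choice(values.size, size=n_missing, replace=False)
        values.flat[flat] = np.nan
    return pd.DataFrame(values, index=signal.index, columns=signal.columns)


def generate_cohort(
    config: CohortConfig, annotation: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Generate the discovery cohort: (beta, sample sheet, planted truth).

    Tumor and normal samples are drawn for each cancer type. Planted
    specific genes (all inside the GPCR panel) have every promoter probe
    elevated by ``specific_effect`` in their assigned cancer's tumor
    samples only; per-cancer extra differential probes are shifted by
    ``dm_effect`` tumor-vs-normal; Gaussian noise is added and values
    clipped to [0, 1]; missing entries are inserted uniformly at random.
    """
    if annotation is None:
        annotation = generate_annotation(config)
    rng = _rng(config.seed, _STREAM_COHORT)
    genes = _gene_ids(config)
    cancers = _cancer_ids(config)

    gpcr = sorted(rng.choice(genes, size=config.n_gpcr_genes, replace=False))
    n_specific = config.n_specific_genes_per_cancer * config.n_cancers
    specific = list(rng.choice(gpcr, size=n_specific, replace=False))
    specific_map = {
        gene: cancers[i // config.n_specific_genes_per_cancer]
        for i, gene in enumerate(specific)
    }

    # extra DM probes come from genes carrying no specificity signal and
    # outside the GPCR panel, so planted sets stay disjoint from noise sets
    non_panel_probes = annotation.index[
        ~annotation["gene"].isin(gpcr)
    ].to_numpy()
    dm_sites: dict[str, list[str]] = {}
    pool = rng.permutation(non_panel_probes)
    gene_probes = annotation.groupby("gene").groups
    cursor = 0
    for cancer in cancers:
        take = min(config.n_dm_sites_per_cancer, len(pool) - cursor)
        extra = list(pool[cursor : cursor + take])
        cursor += take
        own_specific_probes = [
            p
            for gene, assigned in specific_map.items()
            if assigned == cancer
            for p in gene_probes[gene]
        ]
        dm_sites[cancer] = sorted(extra + own_specific_probes)

    baseline = pd.Series(
        rng.uniform(config.baseline_low, config.baseline_high, size=len(genes)),
        index=genes,
    ).reindex(annotation["gene"]).set_axis(annotation.index)

    risk = [
        gene
        for i, gene in enumerate(specific)
        if i % config.n_specific_genes_per_cancer == 0
    ]
    truth = PlantedTruth(
        specific_gene_map=specific_map,
        dm_sites=dm_sites,
        survival_risk_genes=risk,
        gpcr_genes=list(gpcr),
        probe_baseline=baseline,
    )

    sheet = _sample_sheet(
        config,
        "discovery",
        config.samples_per_cancer_tumor,
        config.samples_per_cancer_normal,
    )
    signal = _signal_matrix(config, annotation, sheet, truth, baseline)
    beta = _finish_matrix(signal, config, rng)
    return beta, sheet, truth


def generate_validation_cohort(
    config: CohortConfig,
    truth: PlantedTruth,
    annotation: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an independent cohort with the same planted structure.

    New samples and a fresh noise draw, plus a global additive
    ``batch_shift`` that emulates a cross-platform/cohort offset. The shift
    is rank-preserving, so each planted specific gene still attains its
    maximum mean beta in its assigned cancer.
    """
    if truth.probe_baseline is None:
        raise ValueError("truth must carry probe baselines from generate_cohort")
    if annotation is None:
        annotation = generate_annotation(config)
    rng = _rng(config.seed, _STREAM_VALIDATION)
    sheet = _sample_sheet(
        config,
        "validation",
        config.samples_per_cancer_tumor,
        config.samples_per_cancer_normal,
    )
    signal = _signal_matrix(config, annotation, sheet, truth, truth.probe_baseline)
    signal = signal + config.batch_shift
    beta = _finish_matrix(signal, config, rng)
    return beta, sheet


def generate_survival(
    sheet: pd.DataFrame,
    gene_beta: pd.DataFrame,
    truth: PlantedTruth | None = None,
    *,
    risk_genes: list[str] | None = None,
    gamma: float = 2.0,
    baseline_hazard: float = 0.05,
    censor_hazard: float = 0.02,
    seed: int | None = None,
) -> pd.DataFrame:
    """Exponential proportional-hazards survival times for tumor samples.

    Hazard for sample s is ``baseline_hazard * exp(gamma * r_s)`` where
    r_s is the mean centered beta of the risk genes; censoring times are
    independent exponentials. gamma=0 yields survival independent of
    methylation (null calibration); gamma around 2 yields clearly
    separated risk groups at default cohort sizes.

    Returns a DataFrame with columns sample_id, time, event, cancer_type.
    """
    if risk_genes is None:
        if truth is None:
            raise ValueError("pass either truth or risk_genes")
        risk_genes = truth.survival_risk_genes
    missing = [g for g in risk_genes if g not in gene_beta.index]
    if missing:
        raise ValueError(f"risk genes absent from beta matrix: {missing}")
    rng = np.random.default_rng(
        seed if seed is not None else np.random.SeedSequence().entropy % (2**31)
    )
    tumor = sheet.index[sheet["tissue"] == "tumor"]
    tumor = tumor.intersection(gene_beta.columns)
    betas = gene_beta.loc[risk_genes, tumor]
    centered = betas.sub(betas.mean(axis=1), axis=0)
    score = centered.mean(axis=0).to_numpy() if len(risk_genes) else np.zeros(len(tumor))
    hazard = baseline_hazard * np.exp(gamma * score)
    event_time = rng.exponential(1.0 / hazard)
    if censor_hazard > 0:
        censor_time = rng.exponential(1.0 / censor_hazard, size=len(tumor))
    else:
        censor_time = np.full(len(tumor), np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    # strictly positive times: exponential draws of 0.0 are measure-zero but
    # guard against float underflow anyway
    time = np.maximum(time, np.finfo(float).tiny)
    return pd.DataFrame(
        {
            "sample_id": tumor,
            "time": time,
            "event": event,
            "cancer_type": sheet.loc[tumor, "cancer_type"].to_numpy(),
        }
    ).set_index("sample_id")


@dataclass
class DrugPanel:
    """Cell-line training data plus sample expression for IC50 prediction.

    ``cellline_expression``: genes x lines; ``ic50``: lines x drugs (log
    scale); ``sample_expression``: genes x samples, gene ids matching the
    cell-line matrix. ``true_sample_ic50`` holds the noise-free linear
    response for the cohort samples (simulation truth, not an input to the
    predictor).
    """

    cellline_expression: pd.DataFrame
    ic50: pd.DataFrame
    sample_expression: pd.DataFrame
    true_sample_ic50: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.cellline_expression.index.equals(self.sample_expression.index):
            raise ValueError("gene identifiers differ between expression matrices")
        if not self.cellline_expression.columns.equals(self.ic50.index):
            raise ValueError("cell-line identifiers differ between expression and IC50")
        if self.ic50.isna().any().any():
            raise ValueError("missing IC50 for a trained drug")


def generate_drug_panel(
    config: CohortConfig,
    truth: PlantedTruth,
    gene_beta: pd.DataFrame,
    sheet: pd.DataFrame,
    *,
    n_cell_lines: int = 60,
    n_drugs: int = 6,
    genes_per_drug: int = 3,
    ic50_noise_sd: float = 0.1,
    coupling: float = 1.5,
) -> DrugPanel:
    """Simulate a GDSC-style drug panel tied to the cohort's methylation.

    IC50 of each drug across cell lines is a sparse linear combination of
    expression plus Gaussian noise. For each drug, one designated specific
    gene's methylation drives (negatively) the expression of one of the
    drug's effector genes in the cohort samples, so Spearman(beta, IC50)
    is negative by construction for the designated (gene, drug) pairs and
    null for all others. Pairs are recorded in ``truth.drug_sensitive_pairs``
    and effector weights in ``truth.drug_coefficients``.
    """
    rng = _rng(config.seed, _STREAM_DRUGS)
    panel_genes = list(truth.gpcr_genes)
    lines = [f"CL{i:03d}" for i in range(1, n_cell_lines + 1)]
    drugs = [f"drug{j:02d}" for j in range(1, n_drugs + 1)]
    tumor = sheet.index[sheet["tissue"] == "tumor"].intersection(gene_beta.columns)

    expr_lines = pd.DataFrame(
        rng.normal(size=(len(panel_genes), n_cell_lines)),
        index=panel_genes,
        columns=lines,
    )
    specific = list(truth.specific_gene_map)
    coeffs: dict[str, dict[str, float]] = {}
    pairs: list[tuple[str, str]] = []
    W = pd.DataFrame(0.0, index=panel_genes, columns=drugs)
    for j, drug in enumerate(drugs):
        effectors = rng.choice(panel_genes, size=genes_per_drug, replace=False)
        weights = rng.uniform(0.5, 1.5, size=genes_per_drug)
        coeffs[drug] = dict(zip(effectors, weights.tolist()))
        W.loc[effectors, drug] = weights
        pairs.append((specific[j % len(specific)], drug))

    ic50 = expr_lines.T @ W
    if ic50_noise_sd > 0:
        ic50 = ic50 + rng.normal(0.0, ic50_noise_sd, size=ic50.shape)

    expr_samples = pd.DataFrame(
        rng.normal(size=(len(panel_genes), len(tumor))),
        index=panel_genes,
        columns=tumor,
    )
    for meth_gene, drug in pairs:
        effector = max(coeffs[drug], key=coeffs[drug].get)
        b = gene_beta.loc[meth_gene, tumor].astype(float)
        sd = b.std(ddof=1)
        z = (b - b.mean()) / (sd if sd > 0 else 1.0)
        expr_samples.loc[effector] = -coupling * z.to_numpy() + rng.normal(
            0.0, 0.2, size=len(tumor)
        )

    true_ic50 = expr_samples.T @ W
    truth.drug_coefficients = coeffs
    truth.drug_sensitive_pairs = pairs
    return DrugPanel(
        cellline_expression=expr_lines,
        ic50=ic50,
        sample_expression=expr_samples,
        true_sample_ic50=true_ic50,
    )
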