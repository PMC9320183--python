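"""Plain-text readers and writers for the pipeline's tabular artifacts.

All matrices travel as TSV with an index column; missing betas are written
as ``NA``. The planted-truth record round-trips through JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from methspec.synthetic import PlantedTruth


def write_beta(beta: pd.DataFrame, path: str | Path) -> None:
    beta.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


def read_beta(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def write_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index_label="sample_id")


def read_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    bad = set(sheet["tissue"].unique()) - {"tumor", "normal"}
    if bad:
        raise ValueError(f"unknown tissue labels: {sorted(bad)}")
    return sheet


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index_label="probe_id")


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0)
    if (ann["pos"] < 0).any():
        raise ValueError("positions must be >= 0 (0-based coordinates)")
    return ann


def write_gene_list(genes: list[str] | set[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]


def write_survival(survival: pd.DataFrame, path: str | Path) -> None:
    survival.to_csv(path, sep="\t", index_label="sample_id")


def read_survival(path: str | Path) -> pd.DataFrame:
    surv = pd.read_csv(path, sep="\t", index_col=0)
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not set(surv["event"].unique()) <= {0, 1}:
        raise ValueError("event indicators must be 0/1")
    return surv


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    payload = {
        "specific_gene_map": truth.specific_gene_map,
        "dm_sites": truth.dm_sites,
        "survival_risk_genes": truth.survival_risk_genes,
        "drug_coefficients": truth.drug_coefficients,
        "drug_sensitive_pairs": [list(p) for p in truth.drug_sensitive_pairs],
        "gpcr_genes": truth.gpcr_genes,
        "probe_baseline": (
            truth.probe_baseline.to_dict()
            if truth.probe_baseline is not None
            else None
        ),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> PlantedTruth:
    payload = json.loads(Path(path).read_text())
    baseline = payload.get("probe_baseline")
    return PlantedTruth(
        specific_gene_map=payload["specific_gene_map"],
        dm_sites=payload["dm_sites"],
        survival_risk_genes=payload["survival_risk_genes"],
        drug_coefficients=payload.get("drug_coefficients", {}),
        drug_sensitive_pairs=[
            tuple(p) for p in payload.get("drug_sensitive_pairs", [])
        ],
        gpcr_genes=payload.get("gpcr_genes", []),
        probe_baseline=pd.Series(baseline) if baseline else None,
    )
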