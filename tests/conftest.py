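import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from methspec.config import CohortConfig
from methspec import synthetic, diffmeth

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig(seed=11)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    """Default-scale discovery cohort shared across tests (read-only)."""
    ann = synthetic.generate_annotation(default_config)
    beta, sheet, truth = synthetic.generate_cohort(default_config, ann)
    return ann, beta, sheet, truth


@pytest.fixture(scope="session")
def default_gene_beta(default_cohort):
    ann, beta, _, _ = default_cohort
    return diffmeth.aggregate_to_genes(beta, ann)


@pytest.fixture()
def toy_annotation():
    """Three genes x 2 probes, all probes at TSS-100 (inside promoter)."""
    rows = []
    for gi, gene in enumerate(["gA", "gB", "gC"]):
        tss = 10_000 * (gi + 1)
        for si in range(2):
            rows.append(
                {
                    "probe_id": f"cg_{gene}_{si}",
                    "chrom": "chr1",
                    "pos": tss - 100,
                    "strand": "+",
                    "gene": gene,
                    "tss": tss,
                }
            )
    return pd.DataFrame(rows).set_index("probe_id")


def make_sheet(cancers, n_tumor, n_normal=0, batch="discovery", split="train"):
    rows = []
    for cancer in cancers:
        for i in range(n_tumor):
            rows.append((f"{cancer}_T{i}", cancer, "tumor"))
        for i in range(n_normal):
            rows.append((f"{cancer}_N{i}", cancer, "normal"))
    sheet = pd.DataFrame(rows, columns=["sample_id", "cancer_type", "tissue"])
    sheet["batch"] = batch
    sheet["split"] = split
    return sheet.set_index("sample_id")
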