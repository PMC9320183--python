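"""Configuration for the synthetic cohort generator.

The defaults define a desk-scale study: 8 cancer types with 30 tumor and 15
normal samples each, 500 genes with 4 promoter-region CpG probes apiece, a
40-gene GPCR-related panel, and 3 planted cancer-specific genes per cancer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the simulated pan-cancer methylation study.

    Parameters
    ----------
    n_cancers
        Number of cancer types, each with tumor and matched normal samples.
    samples_per_cancer_tumor, samples_per_cancer_normal
        Cohort sizes per cancer type.
    n_genes, sites_per_gene
        Genes on the array and CpG probes per gene.
    promoter_fraction
        Fraction of each gene's probes placed inside the promoter window
        [TSS-2000, TSS+500); the remainder fall outside so the promoter
        filter has work to do.
    n_gpcr_genes
        Size of the GPCR-related gene panel (a subset of all genes).
    n_specific_genes_per_cancer
        Cancer-specific genes planted per cancer; all are drawn from the
        GPCR panel and are hypermethylated in exactly one cancer's tumors.
    n_dm_sites_per_cancer
        Additional per-cancer tumor-vs-normal differential probes, planted
        in genes that carry no specificity signal.
    specific_effect
        Beta-value shift of a planted specific gene in its assigned
        cancer's tumor samples.
    dm_effect
        Tumor-vs-normal beta shift at planted differential probes.
    baseline_low, baseline_high
        Range of the per-gene baseline beta, drawn uniformly; a degenerate
        range (low == high) pins every baseline for exactness tests.
    noise_sd
        Within-group Gaussian noise SD on the beta scale (clipped to
        [0, 1]).
    missing_rate
        Fraction of entries masked as missing, uniformly at random.
    batch_shift
        Additive beta offset applied to the validation cohort.
    seed
        Base seed; the same seed yields byte-identical outputs.
    """

    n_cancers: int = 8
    samples_per_cancer_tumor: int = 30
    samples_per_cancer_normal: int = 15
    n_genes: int = 500
    sites_per_gene: int = 4
    promoter_fraction: float = 0.9
    n_gpcr_genes: int = 40
    n_specific_genes_per_cancer: int = 3
    n_dm_sites_per_cancer: int = 20
    specific_effect: float = 0.4
    dm_effect: float = 0.3
    baseline_low: float = 0.15
    baseline_high: float = 0.45
    noise_sd: float = 0.05
    missing_rate: float = 0.02
    batch_shift: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_cancers": self.n_cancers,
            "samples_per_cancer_tumor": self.samples_per_cancer_tumor,
            "samples_per_cancer_normal": self.samples_per_cancer_normal,
            "n_genes": self.n_genes,
            "sites_per_gene": self.sites_per_gene,
            "n_gpcr_genes": self.n_gpcr_genes,
            "n_specific_genes_per_cancer": self.n_specific_genes_per_cancer,
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.n_specific_genes_per_cancer * self.n_cancers > self.n_genes:
            raise ValueError(
                "n_specific_genes_per_cancer * n_cancers exceeds n_genes"
            )
        if self.n_specific_genes_per_cancer * self.n_cancers > self.n_gpcr_genes:
            raise ValueError(
                "planted specific genes must fit inside the GPCR panel"
            )
        if self.n_gpcr_genes > self.n_genes:
            raise ValueError("n_gpcr_genes exceeds n_genes")
        if not 0.0 < self.specific_effect <= 1.0:
            raise ValueError("specific_effect must lie in (0, 1]")
        if not 0.0 <= self.baseline_low <= self.baseline_high <= 1.0:
            raise ValueError("baseline range must satisfy 0 <= low <= high <= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.promoter_fraction <= 1.0:
            raise ValueError("promoter_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.missing_rate > 0.7:
            raise ValueError(
                "missing_rate > 0.7 would strip every probe at the default "
                "missingness filter (degenerate design)"
            )

    def replace(self, **changes) -> "CohortConfig":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
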