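"""Coding analysis: recurrent non-silent mutation enrichment in genes.

Per gene, ``n`` is the number of samples with at least one non-silent somatic
mutation and ``k`` the total non-silent mutation count; silent and other
annotated classes contribute only to the background (configurable via
``bg_count_class``). Input is a cohort of annotated, tabix-indexed VCFs plus a
GTF, or a cohort MAF table.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hotspots import Hotspot
from .io import VcfCohort, load_cohort, load_gene_models, load_maf
from .pipeline import FeatureResult, RunConfig, analyze_features, finalize

__all__ = ["CodingConfig", "run_coding", "run_parallel"]


@dataclass
class CodingConfig(RunConfig):
    vcf_list: str | None = None
    maf: str | None = None
    gtf: str = ""
    anno_field: str | None = None
    biotype_filter: str = "all"

    def validate(self) -> None:
        super().validate()
        if not self.gtf:
            raise ValueError("a GTF file of gene models is required")
        if (self.vcf_list is None) == (self.maf is None):
            raise ValueError("provide exactly one of vcf_list or maf")
        if self.vcf_list is not None and not self.anno_field:
            raise ValueError(
                "anno_field (the INFO key holding coding impact annotations) "
                "is required for VCF input"
            )


def run_coding(config: CodingConfig) -> tuple[list[FeatureResult], list[Hotspot]]:
    """Run the coding pipeline; returns (feature results, hotspots)."""
    config.validate()
    features = load_gene_models(config.gtf, biotype_filter=config.biotype_filter)
    if config.maf is not None:
        _, source = load_maf(config.maf)
    else:
        manifest = load_cohort(config.vcf_list)
        source = VcfCohort(manifest, anno_field=config.anno_field)
    results, hotspots = analyze_features(
        features, source, config, foreground_class="nonsilent", run_wap=False
    )
    return finalize(
        results,
        hotspots,
        config,
        {"pipeline": "coding", "n_features": len(features), "cohort_size": len(source.sample_ids)},
    )


def run_parallel(
    config: CodingConfig, n_workers: int
) -> tuple[list[FeatureResult], list[Hotspot]]:
    """run_coding partitioned over worker processes; output is worker-count invariant."""
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    config.processors = n_workers
    return run_coding(config)
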