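"""Noncoding analysis: somatic enrichment in user-defined genomic regions.

Per region (promoter, enhancer, ...), ``n`` counts samples with *any* somatic
mutation and ``k`` all mutations -- no impact annotations are needed. On top
of burden and hotspot testing, regions with at least two mutations get the
WAP positional-clustering permutation test; by default WAP is reported
alongside rather than entering the Fisher combination (``combine_wap``
switches that).
"""

from __future__ import annotations

from dataclasses import dataclass

from .hotspots import Hotspot
from .io import VcfCohort, load_cohort, load_regions
from .pipeline import FeatureResult, RunConfig, analyze_features, finalize

__all__ = ["NoncodingConfig", "run_noncoding", "run_parallel"]


@dataclass
class NoncodingConfig(RunConfig):
    vcf_list: str = ""
    bed: str = ""

    def validate(self) -> None:
        super().validate()
        if not self.vcf_list:
            raise ValueError("a cohort VCF list file is required")
        if not self.bed:
            raise ValueError("a BED file of regions is required")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


def run_noncoding(config: NoncodingConfig) -> tuple[list[FeatureResult], list[Hotspot]]:
    """Run the noncoding pipeline; returns (feature results, hotspots)."""
    config.validate()
    features = load_regions(config.bed)
    manifest = load_cohort(config.vcf_list)
    source = VcfCohort(manifest, anno_field=None)
    results, hotspots = analyze_features(
        features, source, config, foreground_class=None, run_wap=True
    )
    return finalize(
        results,
        hotspots,
        config,
        {
            "pipeline": "noncoding",
            "n_features": len(features),
            "cohort_size": len(source.sample_ids),
        },
    )


def run_parallel(
    config: NoncodingConfig, n_workers: int
) -> tuple[list[FeatureResult], list[Hotspot]]:
    """run_noncoding partitioned over worker processes; output is worker-count invariant."""
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    config.processors = n_workers
    return run_noncoding(config)
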