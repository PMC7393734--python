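"""Shared fixtures: tiny hand-built VCF cohorts and synthetic cohorts."""

from __future__ import annotations

import os
from pathlib import Path

import pysam
import pytest

from mutburden.io import Feature
from mutburden.simulate import (
    CohortSpec,
    generate_cohort,
    generate_toy_annotations,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=chr1,length=1000000>\n"
    '##INFO=<ID=ANNO,Number=1,Type=String,Description="Coding impact">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def make_vcf(directory: Path, sample_id: str, rows: list[str]) -> Path:
    """Write rows (CHROM POS ID REF ALT QUAL FILTER INFO) as bgzip+tabix VCF."""
    plain = directory / f"{sample_id}.vcf"
    with open(plain, "w") as fh:
        fh.write(VCF_HEADER)
        for row in sorted(rows, key=lambda r: (r.split("\t")[0], int(r.split("\t")[1]))):
            fh.write(row + "\n")
    gz = Path(str(plain) + ".gz")
    pysam.tabix_compress(str(plain), str(gz), force=True)
    os.remove(plain)
    pysam.tabix_index(str(gz), preset="vcf", force=True)
    return gz


def make_cohort_list(directory: Path, entries: list[tuple[str, Path]]) -> Path:
    path = directory / "cohort.txt"
    with open(path, "w") as fh:
        for sid, vcf in entries:
            fh.write(f"{vcf.name}\t{sid}\n")
    return path


@pytest.fixture
def vcf_factory(tmp_path):
    def _build(sample_rows: dict[str, list[str]]) -> Path:
        entries = [
            (sid, make_vcf(tmp_path, sid, rows)) for sid, rows in sample_rows.items()
        ]
        return make_cohort_list(tmp_path, entries)

    return _build


@pytest.fixture(scope="session")
def coding_cohort(tmp_path_factory):
    """30-sample coding cohort: 10 toy genes, one at 10x, dense enough that
    every sample is mutated (used for MAF/VCF equivalence and pipeline tests)."""
    td = tmp_path_factory.mktemp("coding_cohort")
    spec = CohortSpec(
        n_samples=30,
        chrom_lengths={"chr1": 300_000},
        background_rate=4e-4,
        enriched_features={"gene_chr1_003": 10.0},
        silent_fraction=0.3,
        seed=7,
    )
    annos = generate_toy_annotations(spec, td, genes_per_chrom=10)
    files = generate_cohort(spec, annos.genes, td, fasta=annos.fasta, write_maf=True)
    return {"spec": spec, "annos": annos, "files": files, "dir": td}


def region(feature_id: str, chrom: str, start: int, end: int) -> Feature:
    return Feature(feature_id, "region", chrom, [(start, end)])
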