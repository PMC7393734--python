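"""Synthetic cohort and annotation generation.

Fully self-contained test inputs: a random toy genome (FASTA), tiled
multi-exon gene models (GTF), promoter and tiled-region definitions (BED),
and per-sample bgzip+tabix VCF cohorts with planted feature-level enrichment
and tight positional hotspots, plus a machine-readable truth table.

The generative model is deliberately simple and matches the assumptions of
the statistical machinery under test: per sample, each feature accrues
``Poisson(rate * multiplier * L)`` mutations placed uniformly within its
intervals (position-homogeneous, no sequence-context bias, SNVs with one
alternate allele). Hotspot plants add exactly one mutation per carrier sample
at a uniform position inside a short window. Defaults mirror a modest tumor
WGS cohort: 100 samples at 1e-6 mutations per nucleotide per sample (one per
megabase).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from .io import Feature

__all__ = [
    "CohortSpec",
    "HotspotPlant",
    "CohortFiles",
    "ToyAnnotations",
    "generate_cohort",
    "generate_toy_annotations",
    "tile_regions",
    "write_bed",
]

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class HotspotPlant:
    """A planted hotspot: one mutation per carrier inside a short window."""

    feature_id: str
    window_start: int  # 0-based genomic
    window_length: int
    n_carrier_samples: int


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults describe the reference synthetic condition used throughout the
    test suite: 100 tumor samples, background 1e-6 mutations/nt/sample,
    no enrichment, SNVs only.
    """

    n_samples: int = 100
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 2_200_000})
    background_rate: float = 1e-6
    enriched_features: dict[str, float] = field(default_factory=dict)
    hotspot_plants: list[HotspotPlant] = field(default_factory=list)
    silent_fraction: float = 0.0
    seed: int = 0

    def validate(self, features: Sequence[Feature]) -> None:
        by_id = {f.feature_id: f for f in features}
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not (0.0 <= self.background_rate <= 1.0):
            raise ValueError("background_rate must lie in [0, 1]")
        if not (0.0 <= self.silent_fraction <= 1.0):
            raise ValueError("silent_fraction must lie in [0, 1]")
        for fid, mult in self.enriched_features.items():
            if fid not in by_id:
                raise ValueError(f"enriched feature {fid!r} not in feature set")
            if mult < 1:
                raise ValueError(f"multiplier for {fid!r} must be >= 1")
        for plant in self.hotspot_plants:
            feat = by_id.get(plant.feature_id)
            if feat is None:
                raise ValueError(f"plant references unknown feature {plant.feature_id!r}")
            ws, we = plant.window_start, plant.window_start + plant.window_length
            if not any(s <= ws and we <= e for s, e in feat.intervals):
                raise ValueError(
                    f"planted window [{ws}, {we}) lies outside feature "
                    f"{plant.feature_id!r}"
                )
            if not (1 <= plant.n_carrier_samples <= self.n_samples):
                raise ValueError("n_carrier_samples must lie in [1, n_samples]")


@dataclass
class CohortFiles:
    list_file: Path
    vcf_paths: list[Path]
    truth_path: Path
    maf_path: Path | None = None


def _sample_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def _draw_offsets(rng: np.random.Generator, feature: Feature, count: int) -> list[int]:
    """Distinct uniform 0-based genomic positions within the feature."""
    lengths = np.array([e - s for s, e in feature.intervals])
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    starts = np.array([s for s, _ in feature.intervals])
    chosen: set[int] = set()
    while len(chosen) < count:
        flat = int(rng.integers(0, offsets[-1]))
        idx = int(np.searchsorted(offsets, flat, side="right")) - 1
        chosen.add(int(starts[idx] + (flat - offsets[idx])))
    return sorted(chosen)


MAF_CLASS = {
    "nonsynonymous_SNV": "Missense_Mutation",
    "synonymous_SNV": "Silent",
    None: "IGR",
}


def generate_cohort(
    spec: CohortSpec,
    features: Sequence[Feature],
    out_dir: str | Path,
    anno_field: str = "ANNO",
    fasta: str | Path | None = None,
    write_maf: bool = False,
) -> CohortFiles:
    """Write per-sample bgzip+tabix VCFs, a cohort list file, and a truth table.

    Mutations are Poisson-placed per feature per sample; planted hotspots add
    one mutation at a uniform position inside the window for each randomly
    chosen carrier. Genic mutations are labelled silent with probability
    ``silent_fraction`` via the ``anno_field`` INFO key; region features carry
    no annotation. Byte-identical output for a fixed spec and seed.
    """
    spec.validate(features)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    samples = _sample_ids(spec.n_samples)
    ref_lookup = None
    if fasta is not None:
        ref_lookup = pysam.FastaFile(str(fasta))

    # (sample -> (chrom, pos0) -> (ref, alt, anno))
    per_sample: dict[str, dict[tuple[str, int], tuple[str, str, str | None]]] = {
        sid: {} for sid in samples
    }

    def _alleles(chrom: str, pos0: int) -> tuple[str, str]:
        if ref_lookup is not None and chrom in ref_lookup.references:
            ref = ref_lookup.fetch(chrom, pos0, pos0 + 1).upper() or "N"
        else:
            ref = str(BASES[rng.integers(0, 4)])
        alt_choices = [b for b in "ACGT" if b != ref]
        return ref, alt_choices[int(rng.integers(0, len(alt_choices)))]

    def _annotation(feature: Feature) -> str | None:
        if feature.kind != "gene":
            return None
        silent = rng.random() < spec.silent_fraction
        return "synonymous_SNV" if silent else "nonsynonymous_SNV"

    for sid in samples:
        for feature in features:
            mult = spec.enriched_features.get(feature.feature_id, 1.0)
            lam = spec.background_rate * mult * feature.length
            count = int(rng.poisson(lam))
            if count == 0:
                continue
            for pos0 in _draw_offsets(rng, feature, min(count, feature.length)):
                key = (feature.chrom, pos0)
                if key in per_sample[sid]:
                    continue
                ref, alt = _alleles(feature.chrom, pos0)
                per_sample[sid][key] = (ref, alt, _annotation(feature))

    by_id = {f.feature_id: f for f in features}
    for plant in spec.hotspot_plants:
        feat = by_id[plant.feature_id]
        carriers = rng.choice(samples, size=plant.n_carrier_samples, replace=False)
        for sid in carriers:
            pos0 = int(
                rng.integers(plant.window_start, plant.window_start + plant.window_length)
            )
            ref, alt = _alleles(feat.chrom, pos0)
            anno = "nonsynonymous_SNV" if feat.kind == "gene" else None
            per_sample[str(sid)][(feat.chrom, pos0)] = (ref, alt, anno)

    if ref_lookup is not None:
        ref_lookup.close()

    chrom_order = sorted(spec.chrom_lengths)
    header_lines = ["##fileformat=VCFv4.2"]
    header_lines += [
        f"##contig=<ID={c},length={spec.chrom_lengths[c]}>" for c in chrom_order
    ]
    header_lines.append(
        f'##INFO=<ID={anno_field},Number=1,Type=String,Description="Coding impact">'
    )
    header_lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    vcf_paths: list[Path] = []
    maf_rows: list[str] = []
    for sid in samples:
        plain = out_dir / f"{sid}.vcf"
        rows = sorted(per_sample[sid].items())
        with open(plain, "w") as fh:
            fh.write("\n".join(header_lines) + "\n")
            for (chrom, pos0), (ref, alt, anno) in rows:
                info = f"{anno_field}={anno}" if anno is not None else "."
                fh.write(f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")
                maf_rows.append(
                    f"{chrom}\t{pos0 + 1}\t{pos0 + 1}\t{MAF_CLASS[anno]}\t{ref}\t{alt}\t{sid}"
                )
        gz = Path(str(plain) + ".gz")
        pysam.tabix_compress(str(plain), str(gz), force=True)
        os.remove(plain)
        pysam.tabix_index(str(gz), preset="vcf", force=True)
        vcf_paths.append(gz)

    list_file = out_dir / "cohort_vcfs.txt"
    with open(list_file, "w") as fh:
        for sid, path in zip(samples, vcf_paths):
            fh.write(f"{path.name}\t{sid}\n")

    planted = {p.feature_id for p in spec.hotspot_plants}
    truth_path = out_dir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("feature_id\ttrue_class\tmultiplier\thotspot_planted\n")
        for feat in features:
            mult = spec.enriched_features.get(feat.feature_id, 1.0)
            if mult > 1:
                cls = "enriched"
            elif feat.feature_id in planted:
                cls = "hotspot-only"
            else:
                cls = "null"
            fh.write(
                f"{feat.feature_id}\t{cls}\t{mult:g}\t"
                f"{'yes' if feat.feature_id in planted else 'no'}\n"
            )

    maf_path = None
    if write_maf:
        maf_path = out_dir / "cohort.maf"
        with open(maf_path, "w") as fh:
            fh.write(
                "Chromosome\tStart_Position\tEnd_Position\tVariant_Classification\t"
                "Reference_Allele\tTumor_Seq_Allele2\tTumor_Sample_Barcode\n"
            )
            for row in maf_rows:
                fh.write(row + "\n")

    return CohortFiles(list_file, vcf_paths, truth_path, maf_path)


# ---------------------------------------------------------------------------
# toy annotations


@dataclass
class ToyAnnotations:
    fasta: Path
    gtf: Path
    bed_short_promoters: Path
    bed_long_promoters: Path
    genes: list[Feature]
    short_promoters: list[Feature]
    long_promoters: list[Feature]


SHORT_PROMOTER_LENGTH = 100
LONG_PROMOTER_LENGTH = 2000


def generate_toy_annotations(
    spec: CohortSpec,
    out_dir: str | Path,
    genes_per_chrom: int = 10,
    gene_pitch: int = 10_000,
) -> ToyAnnotations:
    """Random-sequence FASTA plus tiled multi-exon genes and their promoters.

    Genes alternate strand and carry three 300-nt exons (used as CDS as well).
    Promoters come in the two standard definitions: 100 nt immediately
    upstream of the TSS, and 2000 nt upstream. For minus-strand genes the TSS
    is the rightmost coordinate, so promoters extend to the right.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    fasta_path = out_dir / "toy_genome.fa"
    with open(fasta_path, "w") as fh:
        for chrom in sorted(spec.chrom_lengths):
            length = spec.chrom_lengths[chrom]
            seq = "".join(BASES[rng.integers(0, 4, size=length)])
            fh.write(f">{chrom}\n")
            for i in range(0, length, 60):
                fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(str(fasta_path))

    exon_layout = [(0, 300), (500, 800), (1000, 1300)]
    gene_span = 1300
    genes: list[Feature] = []
    short_proms: list[Feature] = []
    long_proms: list[Feature] = []
    gtf_path = out_dir / "toy_genes.gtf"
    with open(gtf_path, "w") as gtf:
        for chrom in sorted(spec.chrom_lengths):
            chrom_len = spec.chrom_lengths[chrom]
            first = LONG_PROMOTER_LENGTH + 100
            if first + genes_per_chrom * gene_pitch + LONG_PROMOTER_LENGTH > chrom_len:
                raise ValueError(
                    f"{genes_per_chrom} genes at pitch {gene_pitch} do not fit on "
                    f"{chrom} ({chrom_len} nt)"
                )
            for i in range(genes_per_chrom):
                gid = f"gene_{chrom}_{i + 1:03d}"
                strand = "+" if i % 2 == 0 else "-"
                gstart = first + i * gene_pitch
                exons = [(gstart + a, gstart + b) for a, b in exon_layout]
                attrs = f'gene_id "{gid}"; transcript_id "{gid}.t1"; gene_biotype "protein_coding";'
                gtf.write(
                    f"{chrom}\ttoy\tgene\t{gstart + 1}\t{gstart + gene_span}\t.\t{strand}\t.\t{attrs}\n"
                )
                gtf.write(
                    f"{chrom}\ttoy\ttranscript\t{gstart + 1}\t{gstart + gene_span}\t.\t{strand}\t.\t{attrs}\n"
                )
                for es, ee in exons:
                    gtf.write(
                        f"{chrom}\ttoy\texon\t{es + 1}\t{ee}\t.\t{strand}\t.\t{attrs}\n"
                    )
                    gtf.write(
                        f"{chrom}\ttoy\tCDS\t{es + 1}\t{ee}\t.\t{strand}\t.\t{attrs}\n"
                    )
                genes.append(Feature(gid, "gene", chrom, exons, strand))
                gend = gstart + gene_span
                if strand == "+":
                    short_iv = (gstart - SHORT_PROMOTER_LENGTH, gstart)
                    long_iv = (gstart - LONG_PROMOTER_LENGTH, gstart)
                else:
                    short_iv = (gend, gend + SHORT_PROMOTER_LENGTH)
                    long_iv = (gend, gend + LONG_PROMOTER_LENGTH)
                short_proms.append(
                    Feature(f"{gid}_prom_short", "region", chrom, [short_iv], strand)
                )
                long_proms.append(
                    Feature(f"{gid}_prom_long", "region", chrom, [long_iv], strand)
                )
    bed_short = out_dir / "promoters_short.bed"
    bed_long = out_dir / "promoters_long.bed"
    write_bed(short_proms, bed_short)
    write_bed(long_proms, bed_long)
    return ToyAnnotations(
        fasta_path, gtf_path, bed_short, bed_long, genes, short_proms, long_proms
    )


def tile_regions(
    chrom_lengths: Mapping[str, int],
    n_regions: int,
    region_length: int = 2000,
    spacing: int = 2000,
    prefix: str = "region",
) -> list[Feature]:
    """Evenly tiled non-overlapping regions across the toy genome."""
    features: list[Feature] = []
    chroms = sorted(chrom_lengths)
    pitch = region_length + spacing
    i = 0
    for chrom in chroms:
        start = spacing
        while start + region_length + spacing <= chrom_lengths[chrom] and i < n_regions:
            i += 1
            features.append(
                Feature(
                    f"{prefix}_{i:04d}", "region", chrom, [(start, start + region_length)]
                )
            )
            start += pitch
        if i >= n_regions:
            break
    if i < n_regions:
        raise ValueError(
            f"genome too small: placed {i} of {n_regions} requested regions"
        )
    return features


def write_bed(features: Sequence[Feature], path: str | Path) -> Path:
    """Write features as BED (one line per interval run; merged features only)."""
    path = Path(path)
    with open(path, "w") as fh:
        for feat in features:
            fh.write(
                f"{feat.chrom}\t{feat.start}\t{feat.end}\t{feat.feature_id}\t0\t{feat.strand}\n"
            )
    return path
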