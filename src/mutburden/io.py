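"""Input and output formats.

Readers for the standard genomic formats the pipelines consume -- per-sample
somatic VCFs (bgzip + tabix), cohort MAF tables, GTF gene models, BED regions,
covariate TSVs -- plus the TSV report writers.

Coordinate conventions: everything internal is 0-based half-open; GTF (1-based
inclusive) and VCF/MAF positions (1-based) are converted on the way in, and
all reported coordinates are 1-based inclusive. That single conversion
boundary lives in this module.
"""

from __future__ import annotations

import os
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

__all__ = [
    "MutationRecord",
    "Feature",
    "CohortManifest",
    "ImpactScheme",
    "PositionIndex",
    "CohortScan",
    "VcfCohort",
    "MafCohort",
    "load_cohort",
    "load_gene_models",
    "load_regions",
    "load_covariates",
    "fetch_mutations",
    "classify_coding_impact",
    "load_maf",
    "write_results",
]

IMPACT_CLASSES = ("nonsilent", "silent", "noncoding", "unknown")


@dataclass(frozen=True, order=True)
class MutationRecord:
    """One somatic variant from one sample (position is 1-based)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    impact_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError("ref and alt must be non-empty and different")
        if self.impact_class not in IMPACT_CLASSES:
            raise ValueError(f"unknown impact class {self.impact_class!r}")


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge 0-based half-open intervals (touching intervals merge)."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class Feature:
    """A gene (merged coding intervals) or a non-coding region.

    ``intervals`` are 0-based half-open, sorted and non-overlapping; ``length``
    (the testable length L) is their total size.
    """

    feature_id: str
    kind: str  # "gene" | "region"
    chrom: str
    intervals: list[tuple[int, int]]
    strand: str = "."

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)
        if not self.intervals or self.length <= 0:
            raise ValueError(f"feature {self.feature_id!r} has zero length")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return sum(end - start for start, end in self.intervals)

    @property
    def start(self) -> int:
        """0-based start of the leftmost interval."""
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        """0-based half-open end of the rightmost interval."""
        return self.intervals[-1][1]

    def contains(self, pos: int) -> bool:
        """Membership of a 1-based position in any interval."""
        z = pos - 1
        return any(start <= z < end for start, end in self.intervals)


@dataclass
class CohortManifest:
    """The cohort: one (sample_id, VCF path) entry per sample."""

    entries: list[tuple[str, str]]

    @property
    def cohort_size(self) -> int:
        return len(self.entries)

    @property
    def sample_ids(self) -> list[str]:
        return [sid for sid, _ in self.entries]


# ---------------------------------------------------------------------------
# impact classification


def _normalize_term(term: str) -> str:
    return term.strip().lower().replace(" ", "_")


#: ANNOVAR-style coding impact terms
DEFAULT_NONSILENT_TERMS = frozenset(
    map(
        _normalize_term,
        [
            "nonsynonymous_SNV",
            "stopgain",
            "stoploss",
            "startloss",
            "frameshift_insertion",
            "frameshift_deletion",
            "nonframeshift_insertion",
            "nonframeshift_deletion",
            "frameshift_substitution",
            "nonframeshift_substitution",
            "splicing",
        ],
    )
)
DEFAULT_SILENT_TERMS = frozenset(map(_normalize_term, ["synonymous_SNV"]))
DEFAULT_NONCODING_TERMS = frozenset(
    map(
        _normalize_term,
        [
            "intronic",
            "intergenic",
            "UTR3",
            "UTR5",
            "upstream",
            "downstream",
            "ncRNA_exonic",
            "ncRNA_intronic",
            "ncRNA_splicing",
        ],
    )
)

#: MAF Variant_Classification terms
MAF_NONSILENT_TERMS = frozenset(
    map(
        _normalize_term,
        [
            "Missense_Mutation",
            "Nonsense_Mutation",
            "Nonstop_Mutation",
            "Translation_Start_Site",
            "Frame_Shift_Ins",
            "Frame_Shift_Del",
            "In_Frame_Ins",
            "In_Frame_Del",
            "Splice_Site",
        ],
    )
)
MAF_SILENT_TERMS = frozenset(map(_normalize_term, ["Silent"]))
MAF_NONCODING_TERMS = frozenset(
    map(
        _normalize_term,
        ["3'UTR", "5'UTR", "Intron", "IGR", "RNA", "3'Flank", "5'Flank", "lincRNA"],
    )
)


@dataclass(frozen=True)
class ImpactScheme:
    """Term table mapping annotation strings to impact classes."""

    nonsilent: frozenset[str] = DEFAULT_NONSILENT_TERMS
    silent: frozenset[str] = DEFAULT_SILENT_TERMS
    noncoding: frozenset[str] = DEFAULT_NONCODING_TERMS

    def classify(self, annotation_value: str | None) -> str:
        if annotation_value is None:
            return "unknown"
        terms = [
            _normalize_term(t)
            for chunk in str(annotation_value).split(";")
            for t in chunk.split(",")
            if t.strip()
        ]
        if any(t in self.nonsilent for t in terms):
            return "nonsilent"
        if any(t in self.silent for t in terms):
            return "silent"
        if any(t in self.noncoding for t in terms):
            return "noncoding"
        return "unknown"


DEFAULT_SCHEME = ImpactScheme()
MAF_SCHEME = ImpactScheme(
    nonsilent=MAF_NONSILENT_TERMS,
    silent=MAF_SILENT_TERMS,
    noncoding=MAF_NONCODING_TERMS,
)


def classify_coding_impact(
    annotation_value: str | None, scheme: ImpactScheme = DEFAULT_SCHEME
) -> str:
    """Map an annotation string (e.g. ANNOVAR ExonicFunc) to an impact class.

    Unmatched terms map to ``unknown``.
    """
    return scheme.classify(annotation_value)


# ---------------------------------------------------------------------------
# cohort list / VCF access


def _sample_id_from_path(path: str) -> str:
    name = os.path.basename(path)
    for suffix in (".vcf.gz", ".vcf.bgz", ".vcf", ".gz"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def load_cohort(list_file: str | Path) -> CohortManifest:
    """Read a cohort list file: one VCF path per line, optional tab-separated id.

    Every file must exist and carry a tabix (``.tbi``/``.csi``) index; sample
    ids must be unique.
    """
    entries: list[tuple[str, str]] = []
    seen: set[str] = set()
    base = Path(list_file).parent
    with open(list_file) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            path = parts[0]
            if not os.path.isabs(path):
                path = str(base / path)
            sid = parts[1].strip() if len(parts) > 1 and parts[1].strip() else _sample_id_from_path(path)
            if not os.path.exists(path):
                raise FileNotFoundError(f"cohort entry not found: {path}")
            if not (os.path.exists(path + ".tbi") or os.path.exists(path + ".csi")):
                raise FileNotFoundError(f"missing tabix index for cohort entry: {path}")
            if sid in seen:
                raise ValueError(f"duplicate sample id in cohort list: {sid!r}")
            seen.add(sid)
            entries.append((sid, path))
    if not entries:
        raise ValueError(f"empty cohort: no usable entries in {list_file}")
    return CohortManifest(entries)


# ---------------------------------------------------------------------------
# gene models and regions


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in attr_field.strip().rstrip(";").split(";"):
        item = item.strip()
        if not item:
            continue
        if " " not in item:
            continue
        key, _, value = item.partition(" ")
        attrs[key.strip()] = value.strip().strip('"')
    return attrs


def load_gene_models(
    gtf: str | Path,
    feature_types: Sequence[str] = ("CDS", "exon"),
    biotype_filter: str = "all",
) -> list[Feature]:
    """Build one merged :class:`Feature` per gene from a GTF file.

    GTF coordinates (1-based inclusive) become 0-based half-open intervals.
    Per gene, the first feature type in ``feature_types`` with any rows wins
    (default: CDS when present, otherwise exons), and intervals are merged
    across transcripts. Unparseable lines are skipped with a warning; genes
    spanning multiple chromosomes are dropped with a warning.
    """
    per_gene: dict[str, dict[str, list]] = {}
    usable_types = set(feature_types)
    n_bad = 0
    with open(gtf) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                n_bad += 1
                continue
            ftype = fields[2]
            if ftype not in usable_types:
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
                if start1 < 1 or end1 < start1:
                    raise ValueError("bad coordinates")
                attrs = _parse_gtf_attributes(fields[8])
                gene_id = attrs["gene_id"]
            except (ValueError, KeyError):
                n_bad += 1
                continue
            if biotype_filter != "all":
                biotype = attrs.get("gene_biotype", attrs.get("gene_type", ""))
                if biotype != biotype_filter:
                    continue
            rec = per_gene.setdefault(
                gene_id,
                {"chroms": set(), "strand": fields[6], "by_type": defaultdict(list)},
            )
            rec["chroms"].add(fields[0])
            rec["by_type"][ftype].append((start1 - 1, end1))
    if n_bad:
        warnings.warn(f"skipped {n_bad} unparseable GTF line(s)", stacklevel=2)
    features: list[Feature] = []
    for gene_id in sorted(per_gene):
        rec = per_gene[gene_id]
        if len(rec["chroms"]) != 1:
            warnings.warn(
                f"gene {gene_id!r} spans multiple chromosomes; dropped", stacklevel=2
            )
            continue
        intervals: list[tuple[int, int]] = []
        for ftype in feature_types:
            if rec["by_type"].get(ftype):
                intervals = rec["by_type"][ftype]
                break
        if not intervals:
            continue
        strand = rec["strand"] if rec["strand"] in ("+", "-") else "."
        features.append(
            Feature(gene_id, "gene", next(iter(rec["chroms"])), intervals, strand)
        )
    if not features:
        raise ValueError(f"no usable genes parsed from {gtf}")
    return features


def load_regions(bed: str | Path) -> list[Feature]:
    """Read BED3/BED4 regions (0-based half-open) into Features.

    Unnamed lines get ``chrom:start-end`` ids; duplicate identical lines are
    deduplicated; lines with ``end <= start`` or unparseable coordinates are
    skipped with a warning. Regions sharing a name get ``#2``, ``#3`` ...
    suffixes so feature ids stay unique; overlapping regions are kept
    independent.
    """
    features: list[Feature] = []
    seen_lines: set[tuple[str, int, int, str]] = set()
    name_counts: dict[str, int] = {}
    with open(bed) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except (IndexError, ValueError):
                warnings.warn(f"skipping malformed BED line {lineno}", stacklevel=2)
                continue
            if end <= start or start < 0:
                warnings.warn(
                    f"skipping BED line {lineno}: empty or negative interval",
                    stacklevel=2,
                )
                continue
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            key = (chrom, start, end, name)
            if key in seen_lines:
                continue
            seen_lines.add(key)
            count = name_counts.get(name, 0) + 1
            name_counts[name] = count
            fid = name if count == 1 else f"{name}#{count}"
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
            features.append(Feature(fid, "region", chrom, [(start, end)], strand))
    if not features:
        raise ValueError(f"no usable regions parsed from {bed}")
    return features


def load_covariates(path: str | Path) -> pd.DataFrame:
    """Read a covariate TSV: header row, column 1 = feature_id, rest numeric."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric covariate column(s): {non_numeric}")
    return df


# ---------------------------------------------------------------------------
# cohort mutation access


class PositionIndex:
    """Sorted per-sample, per-chromosome positions of all cohort mutations.

    Backs the local (windowed) background method: ``count`` answers how many
    mutations of the requested impact classes a sample carries in a 0-based
    half-open window.
    """

    def __init__(self) -> None:
        self._raw: dict[tuple[str, str], list[tuple[int, str]]] = defaultdict(list)
        self._sorted: dict[tuple[str, str], dict[str | None, np.ndarray]] | None = None

    def add(self, sample_id: str, chrom: str, pos: int, impact_class: str) -> None:
        self._raw[(sample_id, chrom)].append((pos - 1, impact_class))
        self._sorted = None

    def _ensure_sorted(self) -> dict:
        if self._sorted is None:
            self._sorted = {}
            for key, items in self._raw.items():
                by_class: dict[str | None, np.ndarray] = {
                    None: np.sort(np.array([p for p, _ in items], dtype=np.int64))
                }
                for cls in IMPACT_CLASSES:
                    sub = np.sort(
                        np.array([p for p, c in items if c == cls], dtype=np.int64)
                    )
                    if sub.size:
                        by_class[cls] = sub
                self._sorted[key] = by_class
        return self._sorted

    def count(
        self,
        sample_id: str,
        chrom: str,
        start: int,
        end: int,
        impact_classes: Sequence[str] | None = None,
    ) -> int:
        """Number of mutations in [start, end) (0-based half-open)."""
        table = self._ensure_sorted().get((sample_id, chrom))
        if table is None:
            return 0
        total = 0
        keys: Iterable[str | None] = (
            [None] if impact_classes is None else impact_classes
        )
        for cls in keys:
            arr = table.get(cls)
            if arr is None:
                continue
            total += int(np.searchsorted(arr, end) - np.searchsorted(arr, start))
        return total


@dataclass
class CohortScan:
    """Everything a pipeline needs after one pass over the cohort."""

    mutations_by_feature: dict[str, list[MutationRecord]]
    position_index: PositionIndex
    chrom_lengths: dict[str, int] = field(default_factory=dict)


def _feature_trees(features: Sequence[Feature]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for feat in features:
        for start, end in feat.intervals:
            trees[feat.chrom][start:end] = feat.feature_id
    return trees


class VcfCohort:
    """Cohort backed by per-sample bgzip+tabix VCF files."""

    def __init__(
        self,
        manifest: CohortManifest,
        anno_field: str | None = None,
        scheme: ImpactScheme = DEFAULT_SCHEME,
    ) -> None:
        self.manifest = manifest
        self.anno_field = anno_field
        self.scheme = scheme

    @property
    def sample_ids(self) -> list[str]:
        return self.manifest.sample_ids

    def _records(
        self, sample_id: str, vcf: pysam.VariantFile, variant_iter
    ) -> Iterator[MutationRecord]:
        for rec in variant_iter:
            if rec.ref is None or not rec.alts:
                continue
            if self.anno_field is not None:
                raw = rec.info.get(self.anno_field)
                if isinstance(raw, tuple):
                    raw = ",".join(str(v) for v in raw)
                impact = self.scheme.classify(raw)
            else:
                impact = "unknown"
            for alt in rec.alts:
                if alt is None or alt == rec.ref or alt.startswith("<"):
                    continue
                yield MutationRecord(sample_id, rec.chrom, rec.pos, rec.ref, alt, impact)

    def fetch_feature(self, feature: Feature) -> list[MutationRecord]:
        """Tabix-fetch all cohort mutations whose position lies in the feature."""
        out: set[MutationRecord] = set()
        for sid, path in self.manifest.entries:
            try:
                with pysam.VariantFile(path) as vcf:
                    for start, end in feature.intervals:
                        try:
                            it = vcf.fetch(feature.chrom, start, end)
                        except ValueError:
                            continue  # contig absent from this VCF
                        for rec in self._records(sid, vcf, it):
                            if feature.contains(rec.pos):
                                out.add(rec)
            except (OSError, ValueError) as exc:
                warnings.warn(
                    f"query failed for sample {sid!r} ({exc}); treating as zero "
                    "mutations in this feature",
                    stacklevel=2,
                )
        return sorted(out)

    def scan(self, features: Sequence[Feature]) -> CohortScan:
        """One linear pass per VCF: assign mutations to features, index positions."""
        trees = _feature_trees(features)
        muts: dict[str, list[MutationRecord]] = {f.feature_id: [] for f in features}
        index = PositionIndex()
        chrom_lengths: dict[str, int] = {}
        for sid, path in self.manifest.entries:
            with pysam.VariantFile(path) as vcf:
                for contig in vcf.header.contigs.values():
                    if contig.length:
                        chrom_lengths[contig.name] = max(
                            chrom_lengths.get(contig.name, 0), contig.length
                        )
                seen: set[tuple] = set()
                for rec in self._records(sid, vcf, vcf):
                    key = (rec.chrom, rec.pos, rec.ref, rec.alt)
                    if key in seen:
                        continue
                    seen.add(key)
                    index.add(sid, rec.chrom, rec.pos, rec.impact_class)
                    tree = trees.get(rec.chrom)
                    if tree is None:
                        continue
                    for hit in tree[rec.pos - 1]:
                        muts[hit.data].append(rec)
        for fid in muts:
            muts[fid].sort()
        return CohortScan(muts, index, chrom_lengths)


def fetch_mutations(
    manifest: CohortManifest,
    feature: Feature,
    anno_field: str | None = None,
    scheme: ImpactScheme = DEFAULT_SCHEME,
) -> list[MutationRecord]:
    """All cohort variants inside a feature (multi-allelic rows split, deduplicated)."""
    return VcfCohort(manifest, anno_field, scheme).fetch_feature(feature)


# ---------------------------------------------------------------------------
# MAF ingestion

MAF_REQUIRED_COLUMNS = (
    "Chromosome",
    "Start_Position",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
)


class MafCohort:
    """Cohort held in memory from one MAF table; same interface as VcfCohort."""

    def __init__(self, records: list[MutationRecord], sample_ids: list[str]) -> None:
        self._records = sorted(set(records))
        self._sample_ids = sample_ids
        self._trees: dict[str, IntervalTree] | None = None

    @property
    def sample_ids(self) -> list[str]:
        return self._sample_ids

    def fetch_feature(self, feature: Feature) -> list[MutationRecord]:
        return [r for r in self._records if r.chrom == feature.chrom and feature.contains(r.pos)]

    def scan(self, features: Sequence[Feature]) -> CohortScan:
        trees = _feature_trees(features)
        muts: dict[str, list[MutationRecord]] = {f.feature_id: [] for f in features}
        index = PositionIndex()
        for rec in self._records:
            index.add(rec.sample_id, rec.chrom, rec.pos, rec.impact_class)
            tree = trees.get(rec.chrom)
            if tree is None:
                continue
            for hit in tree[rec.pos - 1]:
                muts[hit.data].append(rec)
        for fid in muts:
            muts[fid].sort()
        return CohortScan(muts, index, {})


def load_maf(
    maf: str | Path, scheme: ImpactScheme = MAF_SCHEME
) -> tuple[CohortManifest, MafCohort]:
    """Read a cohort MAF file into an in-memory mutation store.

    Samples are the distinct Tumor_Sample_Barcode values; impact classes come
    from Variant_Classification via the MAF term table.
    """
    df = pd.read_csv(maf, sep="\t", comment="#", dtype=str, low_memory=False)
    missing = [c for c in MAF_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF is missing required column(s): {missing}")
    records: list[MutationRecord] = []
    for row in df.itertuples(index=False):
        ref = str(getattr(row, "Reference_Allele", "N") or "N")
        alt = str(getattr(row, "Tumor_Seq_Allele2", "") or "")
        if not alt or alt == ref:
            alt = "A" if ref != "A" else "C"
        records.append(
            MutationRecord(
                sample_id=str(row.Tumor_Sample_Barcode),
                chrom=str(row.Chromosome),
                pos=int(float(row.Start_Position)),
                ref=ref,
                alt=alt,
                impact_class=scheme.classify(row.Variant_Classification),
            )
        )
    sample_ids = sorted({r.sample_id for r in records})
    manifest = CohortManifest([(sid, str(maf)) for sid in sample_ids])
    return manifest, MafCohort(records, sample_ids)


# ---------------------------------------------------------------------------
# output


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


FEATURE_COLUMNS = [
    "feature_id",
    "chrom",
    "start",
    "end",
    "length",
    "n_samples",
    "cohort_size",
    "n_mutations",
    "bg_rate",
    "burden_p",
    "burden_q",
    "hotspot_p",
    "hotspot_q",
    "wap_p",
    "wap_q",
    "combined_p",
    "combined_q",
    "flags",
]

HOTSPOT_COLUMNS = [
    "feature_id",
    "chrom",
    "start",
    "end",
    "span",
    "n_mutations",
    "n_samples",
    "p",
    "q",
]


def write_results(results, hotspots, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write the feature-level and hotspot-level TSV reports.

    Feature rows are sorted by combined q, then combined p, then feature id;
    hotspot rows by p, then feature id, then position. Coordinates are printed
    1-based inclusive. Returns the two written paths.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    feat_path = Path(f"{out_prefix}_feature_results.tsv")
    hs_path = Path(f"{out_prefix}_hotspots.tsv")

    def sort_key(r):
        return (
            r.combined_q if r.combined_q is not None else 2.0,
            r.combined_p if r.combined_p is not None else 2.0,
            r.feature_id,
        )

    with open(feat_path, "w") as fh:
        fh.write("\t".join(FEATURE_COLUMNS) + "\n")
        for r in sorted(results, key=sort_key):
            fh.write(
                "\t".join(
                    _fmt(v)
                    for v in [
                        r.feature_id,
                        r.chrom,
                        r.start + 1,
                        r.end,
                        r.feature_length,
                        r.n_mutated_samples,
                        r.cohort_size,
                        r.total_mutations,
                        r.aggregate_rate,
                        r.burden_p,
                        r.burden_q,
                        r.best_hotspot_p,
                        r.best_hotspot_q,
                        r.wap_p,
                        r.wap_q,
                        r.combined_p,
                        r.combined_q,
                        ",".join(sorted(r.flags)) if r.flags else "NA",
                    ]
                )
                + "\n"
            )
    with open(hs_path, "w") as fh:
        fh.write("\t".join(HOTSPOT_COLUMNS) + "\n")
        for h in sorted(
            hotspots,
            key=lambda h: (
                h.p_value if h.p_value is not None else 2.0,
                h.feature_id,
                h.start,
            ),
        ):
            fh.write(
                "\t".join(
                    _fmt(v)
                    for v in [
                        h.feature_id,
                        h.chrom,
                        h.start + 1,
                        h.end,
                        h.span,
                        h.n_mutations,
                        h.n_samples,
                        h.p_value,
                        h.q_value,
                    ]
                )
                + "\n"
            )
    return feat_path, hs_path
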