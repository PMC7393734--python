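"""Background mutation-rate estimation.

Four per-sample, per-feature estimators of the per-nucleotide somatic
background rate, plus covariate utilities and the geometric-mean aggregation
that turns sample-wise rates into the single rate ``p`` the burden tests use:

* **global** -- one rate per sample: its mutation count summed over all
  features divided by the total feature length. Every feature of a sample
  shares this rate.
* **local** -- windows (default 1 Mb, allowed up to 2 Mb) are slid across each
  feature and the sample's rate for that feature is the *maximal* windowed
  mutation density, a deliberately conservative choice for regions sitting in
  locally hypermutated neighborhoods.
* **clustered** -- features are grouped by genomic covariates (GC content,
  replication timing, ...) with affinity propagation, and a sample's rate for
  a feature is the pooled mutation density over the feature's cluster.
* **local_clustered** -- per cluster member, the local windowed maximum is
  computed; the feature's rate is the length-weighted mean over members.

The aggregate per-feature rate is the geometric mean of sample-wise rates over
the foreground samples (samples carrying at least one foreground mutation in
the analyzed feature set), with a floor (default 1e-8/nt, about one mutation
per 100 Mb) preventing a single zero from annihilating the product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .io import Feature, PositionIndex

__all__ = [
    "BackgroundRate",
    "FeatureCluster",
    "global_rate",
    "local_rate",
    "prepare_covariates",
    "cluster_features",
    "clustered_rate",
    "local_clustered_rate",
    "aggregate_rate",
]

DEFAULT_WINDOW_LENGTH = 1_000_000
DEFAULT_RATE_FLOOR = 1e-8
BACKGROUND_METHODS = ("global", "local", "clustered", "local_clustered")


@dataclass
class BackgroundRate:
    """Per-sample rates and their geometric-mean aggregate for one feature."""

    feature_id: str
    per_sample_rates: dict[str, float]
    aggregate_rate: float | None
    method: str


@dataclass
class FeatureCluster:
    """A covariate-similarity cluster of features (exemplar is a member)."""

    cluster_id: str
    exemplar: str
    members: frozenset[str]
    total_length: int = 0


def global_rate(
    sample_id: str,
    features: Sequence[Feature],
    counts: Mapping[str, int],
) -> float:
    """One sample's pooled mutation density over all features.

    ``counts`` maps feature_id -> this sample's mutation count in the feature.
    Every feature of the sample receives this same rate.
    """
    total_length = sum(f.length for f in features)
    if total_length <= 0:
        raise ValueError("total feature length is zero")
    total = sum(counts.get(f.feature_id, 0) for f in features)
    return total / total_length


def candidate_windows(
    feature: Feature,
    window_length: int,
    step: int | None = None,
    chrom_length: int | None = None,
) -> list[tuple[int, int]]:
    """Window placements scanned by the local method (0-based half-open).

    Windows of ``window_length`` covering the feature's span are slid from
    "feature at the right edge" to "feature at the left edge" in increments of
    ``step`` (default window_length // 4), clipped at chromosome bounds. A
    feature longer than the window falls back to a single window equal to the
    feature span, with a warning.
    """
    if step is None:
        step = max(1, window_length // 4)
    span_start, span_end = feature.start, feature.end
    span = span_end - span_start
    if span > window_length:
        warnings.warn(
            f"feature {feature.feature_id!r} ({span} nt) exceeds the window "
            f"({window_length} nt); using the feature span as the only window",
            stacklevel=2,
        )
        return [(span_start, span_end)]
    max_start = chrom_length - window_length if chrom_length is not None else None
    starts = list(range(span_end - window_length, span_start + 1, step))
    if starts[-1] != span_start:
        starts.append(span_start)  # always include feature-at-left-edge
    windows: list[tuple[int, int]] = []
    for ws in starts:
        if max_start is not None:
            ws = min(ws, max_start)
        ws = max(0, ws)
        we = ws + window_length
        if chrom_length is not None:
            we = min(we, chrom_length)
        if we - ws > 0 and (ws, we) not in windows:
            windows.append((ws, we))
    return windows


def local_rate(
    sample_id: str,
    feature: Feature,
    mutation_index: PositionIndex,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    step: int | None = None,
    chrom_length: int | None = None,
    impact_classes: Sequence[str] | None = None,
) -> float:
    """Maximal windowed mutation density around a feature for one sample."""
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    best = 0.0
    for ws, we in candidate_windows(feature, window_length, step, chrom_length):
        count = mutation_index.count(
            sample_id, feature.chrom, ws, we, impact_classes
        )
        best = max(best, count / (we - ws))
    return best


# ---------------------------------------------------------------------------
# covariates and clustering


def _gc_fraction(seq: str) -> float:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def prepare_covariates(
    features: Sequence[Feature],
    genome: str | None = None,
    tracks: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-feature covariates: GC fraction plus length-weighted track means.

    ``genome`` is a FASTA path (indexed on demand) used for GC content;
    ``tracks`` maps covariate name -> BED4 file with a numeric score column.
    Features with no overlapping track interval receive the cohort median for
    that track (counted and warned).
    """
    data: dict[str, dict[str, float]] = {f.feature_id: {} for f in features}
    if genome is not None:
        with pysam.FastaFile(str(genome)) as fasta:
            present = set(fasta.references)
            for feat in features:
                if feat.chrom not in present:
                    raise ValueError(
                        f"chromosome {feat.chrom!r} absent from FASTA {genome}"
                    )
                seq = "".join(
                    fasta.fetch(feat.chrom, start, end) for start, end in feat.intervals
                )
                data[feat.feature_id]["gc"] = _gc_fraction(seq)
    for name, path in (tracks or {}).items():
        trees: dict[str, IntervalTree] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if len(parts) < 4 or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                trees.setdefault(chrom, IntervalTree())[start:end] = value
        values: dict[str, float] = {}
        for feat in features:
            tree = trees.get(feat.chrom)
            weighted = 0.0
            covered = 0
            if tree is not None:
                for start, end in feat.intervals:
                    for hit in tree.overlap(start, end):
                        olap = min(end, hit.end) - max(start, hit.begin)
                        if olap > 0:
                            weighted += hit.data * olap
                            covered += olap
            if covered > 0:
                values[feat.feature_id] = weighted / covered
        missing = [f.feature_id for f in features if f.feature_id not in values]
        if missing:
            if not values:
                raise ValueError(f"track {name!r} overlaps no feature")
            median = float(np.median(list(values.values())))
            warnings.warn(
                f"{len(missing)} feature(s) missing track {name!r}; "
                "assigned the cohort median",
                stacklevel=2,
            )
            for fid in missing:
                values[fid] = median
        for fid, val in values.items():
            data[fid][name] = val
    df = pd.DataFrame.from_dict(data, orient="index")
    df.index.name = "feature_id"
    return df.sort_index()


def cluster_features(
    profiles: pd.DataFrame,
    lengths: Mapping[str, int] | None = None,
    damping: float = 0.9,
    max_iter: int = 1000,
    random_state: int = 0,
) -> tuple[list[FeatureCluster], bool]:
    """Group features by covariate similarity with affinity propagation.

    Covariates are z-scored per column; similarity is the negative squared
    Euclidean distance with the median-similarity preference. Rows are sorted
    by feature id first, so the partition is independent of input order. On
    non-convergence the fallback is a single all-features cluster.

    Returns ``(clusters, fallback_used)``.
    """
    profiles = profiles.sort_index()
    ids = [str(i) for i in profiles.index]
    lengths = lengths or {}

    def _single() -> list[FeatureCluster]:
        total = sum(lengths.get(fid, 0) for fid in ids)
        return [FeatureCluster("cluster_0", ids[0], frozenset(ids), total)]

    if len(ids) < 2:
        return _single(), False
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd
    ap = AffinityPropagation(
        damping=damping, max_iter=max_iter, random_state=random_state
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        labels = ap.fit_predict(X)
    if ap.cluster_centers_indices_ is None or len(ap.cluster_centers_indices_) == 0:
        warnings.warn(
            "affinity propagation did not converge; falling back to a single "
            "all-features cluster",
            stacklevel=2,
        )
        return _single(), True
    clusters: list[FeatureCluster] = []
    for ci, center_idx in enumerate(ap.cluster_centers_indices_):
        members = frozenset(ids[i] for i in range(len(ids)) if labels[i] == ci)
        total = sum(lengths.get(fid, 0) for fid in members)
        clusters.append(
            FeatureCluster(f"cluster_{ci}", ids[center_idx], members, total)
        )
    return clusters, False


def _cluster_of(feature_id: str, clusters: Sequence[FeatureCluster]) -> FeatureCluster:
    for cluster in clusters:
        if feature_id in cluster.members:
            return cluster
    raise KeyError(f"feature {feature_id!r} belongs to no cluster")


def clustered_rate(
    sample_id: str,
    feature: Feature,
    clusters: Sequence[FeatureCluster],
    counts: Mapping[str, int],
    features_by_id: Mapping[str, Feature],
) -> float:
    """Pooled mutation density of the feature's cluster members for one sample."""
    cluster = _cluster_of(feature.feature_id, clusters)
    total_count = sum(counts.get(fid, 0) for fid in cluster.members)
    total_length = sum(features_by_id[fid].length for fid in cluster.members)
    if total_length <= 0:
        raise ValueError(f"cluster {cluster.cluster_id!r} has zero total length")
    return total_count / total_length


def local_clustered_rate(
    sample_id: str,
    feature: Feature,
    clusters: Sequence[FeatureCluster],
    mutation_index: PositionIndex,
    features_by_id: Mapping[str, Feature],
    window_length: int = DEFAULT_WINDOW_LENGTH,
    step: int | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
    impact_classes: Sequence[str] | None = None,
) -> float:
    """Length-weighted mean of cluster members' local windowed maxima."""
    cluster = _cluster_of(feature.feature_id, clusters)
    chrom_lengths = chrom_lengths or {}
    weighted = 0.0
    total_length = 0
    for fid in sorted(cluster.members):
        member = features_by_id[fid]
        rate = local_rate(
            sample_id,
            member,
            mutation_index,
            window_length,
            step,
            chrom_lengths.get(member.chrom),
            impact_classes,
        )
        weighted += rate * member.length
        total_length += member.length
    return weighted / total_length


def aggregate_rate(
    per_sample_rates: Mapping[str, float],
    foreground_samples: set[str] | frozenset[str],
    floor: float = DEFAULT_RATE_FLOOR,
) -> float:
    """Geometric mean of per-sample rates over foreground samples.

    Each rate is floored (default 1e-8/nt) before the log so a single zero
    cannot annihilate the mean. Raises on an empty foreground set -- the
    caller reports the feature as untestable.
    """
    if not foreground_samples:
        raise ValueError("empty foreground sample set: feature is untestable")
    if not (0.0 < floor <= 1.0):
        raise ValueError("floor must lie in (0, 1]")
    logs = []
    for sid in foreground_samples:
        rate = per_sample_rates.get(sid, 0.0)
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"rate for sample {sid!r} outside [0, 1]: {rate!r}")
        logs.append(np.log(max(rate, floor)))
    return float(np.exp(np.mean(logs)))
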