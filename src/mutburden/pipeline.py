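"""Shared orchestration for the coding and noncoding analyses.

One engine drives both pipelines: collect cohort mutations per feature,
estimate background rates by the configured method, run the burden test,
detect and test hotspots (plus the WAP permutation test for regions), combine
component p-values with Fisher's method, and apply Benjamini-Hochberg
correction within three separate families (feature burden p-values, feature
combined p-values, hotspot p-values; WAP p-values form a fourth when run).

Feature-level computations are independent, so they can be partitioned across
worker processes; per-feature permutation seeds are derived from the master
seed by stable hashing of the feature id, which makes outputs byte-identical
for any worker count.
"""

from __future__ import annotations

import multiprocessing
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import __version__
from .background import (
    DEFAULT_RATE_FLOOR,
    DEFAULT_WINDOW_LENGTH,
    aggregate_rate,
    cluster_features,
    clustered_rate,
    global_rate,
    local_clustered_rate,
    local_rate,
)
from .hotspots import (
    Hotspot,
    find_candidate_hotspots,
    hotspot_pvalue,
    wap_permutation_pvalue,
)
from .io import (
    CohortScan,
    Feature,
    MutationRecord,
    load_covariates,
    write_results,
)
from .stats import bh_fdr, fisher_combine

__all__ = ["RunConfig", "FeatureResult", "analyze_features", "feature_seed"]

BG_METHODS = ("global", "local", "clustered", "local_clustered")
STAT_TESTS = ("binomial", "negbinom")


@dataclass
class RunConfig:
    """Options shared by both pipelines (CLI defaults live here)."""

    out_prefix: str | None = None
    bg_method: str = "global"
    bg_count_class: str = "all"  # "all" | "foreground"
    covariates: str | None = None
    window_size: int = DEFAULT_WINDOW_LENGTH
    window_step: int | None = None
    stat_test: str = "binomial"
    max_gap: int = 50
    min_hs_muts: int = 5
    min_hs_samples: int = 3
    rate_floor: float = DEFAULT_RATE_FLOOR
    processors: int = 1
    seed: int = 0
    # noncoding extras (ignored by the coding pipeline)
    wap: bool = True
    wap_scale: float = 30.0
    n_permutations: int = 10_000
    combine_wap: bool = False

    def validate(self) -> None:
        if self.bg_method not in BG_METHODS:
            raise ValueError(f"unknown background method {self.bg_method!r}")
        if self.stat_test not in STAT_TESTS:
            raise ValueError(f"unknown statistical test {self.stat_test!r}")
        if self.bg_count_class not in ("all", "foreground"):
            raise ValueError(f"unknown bg_count_class {self.bg_count_class!r}")
        if self.bg_method in ("clustered", "local_clustered") and not self.covariates:
            raise ValueError(
                f"background method {self.bg_method!r} requires a covariates table"
            )
        if not (1_000_000 <= self.window_size <= 2_000_000) and self.bg_method in (
            "local",
            "local_clustered",
        ):
            raise ValueError("window_size must lie in [1e6, 2e6]")
        if self.processors < 1:
            raise ValueError("processors must be >= 1")


@dataclass
class FeatureResult:
    """Per-feature burden, hotspot, WAP and combined significance."""

    feature_id: str
    chrom: str
    start: int  # 0-based leftmost
    end: int  # 0-based half-open rightmost
    feature_length: int
    n_mutated_samples: int
    cohort_size: int
    total_mutations: int
    aggregate_rate: float | None
    burden_p: float
    burden_q: float | None = None
    best_hotspot_p: float | None = None
    best_hotspot_q: float | None = None
    wap_p: float | None = None
    wap_q: float | None = None
    combined_p: float | None = None
    combined_q: float | None = None
    flags: set[str] = field(default_factory=set)


def feature_seed(master_seed: int, feature_id: str) -> int:
    """Stable per-feature permutation seed, independent of worker assignment."""
    return (master_seed * 1_000_003 + zlib.crc32(feature_id.encode())) % (2**31 - 1)


def _foreground(records: Sequence[MutationRecord], foreground_class: str | None):
    if foreground_class is None:
        return list(records)
    return [r for r in records if r.impact_class == foreground_class]


def _per_sample_counts(records: Sequence[MutationRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.sample_id] = counts.get(rec.sample_id, 0) + 1
    return counts


def compute_rates(
    features: Sequence[Feature],
    scan: CohortScan,
    sample_ids: Sequence[str],
    cfg: RunConfig,
    bg_classes: Sequence[str] | None,
) -> tuple[dict[str, dict[str, float]], bool]:
    """Per-feature, per-sample background rates by the configured method.

    ``bg_classes`` restricts which impact classes count toward the background
    (None = all). Returns ``(rates, ap_fallback_used)``.
    """
    by_id = {f.feature_id: f for f in features}
    bg_counts: dict[str, dict[str, int]] = {}
    for feat in features:
        records = scan.mutations_by_feature.get(feat.feature_id, [])
        if bg_classes is not None:
            records = [r for r in records if r.impact_class in bg_classes]
        bg_counts[feat.feature_id] = _per_sample_counts(records)

    rates: dict[str, dict[str, float]] = {f.feature_id: {} for f in features}
    fallback = False

    if cfg.bg_method == "global":
        for sid in sample_ids:
            counts = {fid: c.get(sid, 0) for fid, c in bg_counts.items()}
            rate = global_rate(sid, features, counts)
            for feat in features:
                rates[feat.feature_id][sid] = rate
        return rates, fallback

    if cfg.bg_method == "local":
        for feat in features:
            chrom_len = scan.chrom_lengths.get(feat.chrom)
            for sid in sample_ids:
                rates[feat.feature_id][sid] = local_rate(
                    sid,
                    feat,
                    scan.position_index,
                    cfg.window_size,
                    cfg.window_step,
                    chrom_len,
                    bg_classes,
                )
        return rates, fallback

    profiles = load_covariates(cfg.covariates)
    missing = [f.feature_id for f in features if f.feature_id not in profiles.index]
    if missing:
        raise ValueError(
            f"{len(missing)} feature(s) missing from the covariate table, "
            f"e.g. {missing[:3]}"
        )
    profiles = profiles.loc[[f.feature_id for f in features]]
    lengths = {f.feature_id: f.length for f in features}
    clusters, fallback = cluster_features(profiles, lengths)

    if cfg.bg_method == "clustered":
        for sid in sample_ids:
            counts = {fid: c.get(sid, 0) for fid, c in bg_counts.items()}
            # pool counts once per cluster, then assign to members
            for cluster in clusters:
                total = sum(counts.get(fid, 0) for fid in cluster.members)
                tot_len = sum(lengths[fid] for fid in cluster.members)
                rate = total / tot_len
                for fid in cluster.members:
                    rates[fid][sid] = rate
        return rates, fallback

    # local_clustered: per-member local maxima, pooled per cluster
    member_rate: dict[tuple[str, str], float] = {}
    for cluster in clusters:
        for sid in sample_ids:
            weighted, tot_len = 0.0, 0
            for fid in sorted(cluster.members):
                member = by_id[fid]
                key = (sid, fid)
                if key not in member_rate:
                    member_rate[key] = local_rate(
                        sid,
                        member,
                        scan.position_index,
                        cfg.window_size,
                        cfg.window_step,
                        scan.chrom_lengths.get(member.chrom),
                        bg_classes,
                    )
                weighted += member_rate[key] * member.length
                tot_len += member.length
            pooled = weighted / tot_len
            for fid in cluster.members:
                rates[fid][sid] = pooled
    return rates, fallback


def _feature_job(payload: dict) -> dict:
    """Burden + hotspot (+ WAP) statistics for one feature; pure and picklable."""
    from .stats import binomial_burden_pvalue, negbin_pvalue, per_feature_success_prob

    feature: Feature = payload["feature"]
    fg: list[MutationRecord] = payload["fg"]
    rate: float | None = payload["rate"]
    N: int = payload["cohort_size"]
    cfg: RunConfig = payload["cfg"]
    n = len({r.sample_id for r in fg})
    k = len(fg)
    flags: set[str] = set(payload["flags"])
    out: dict = {"feature_id": feature.feature_id, "n": n, "k": k, "hotspots": []}

    if rate is None or n == 0:
        out["burden_p"] = 1.0
        if rate is None:
            flags.add("untestable")
    elif cfg.stat_test == "binomial":
        p_n = per_feature_success_prob(rate, feature.length)
        out["burden_p"] = binomial_burden_pvalue(n, N, p_n)
    else:
        out["burden_p"] = negbin_pvalue(k, feature.length, N, rate)

    if rate is not None:
        candidates = find_candidate_hotspots(
            fg,
            max_gap=cfg.max_gap,
            min_mutations=cfg.min_hs_muts,
            min_samples=cfg.min_hs_samples,
            feature_id=feature.feature_id,
        )
        for hs in candidates:
            hs.p_value = hotspot_pvalue(hs, N, rate, cfg.stat_test)
        out["hotspots"] = candidates
    if not out["hotspots"]:
        flags.add("no_hotspot")

    out["wap"] = None
    if payload["run_wap"] and k >= 2 and feature.length >= k:
        positions = [r.pos for r in fg]
        out["wap"] = wap_permutation_pvalue(
            feature,
            positions,
            n_permutations=cfg.n_permutations,
            scale=cfg.wap_scale,
            seed=feature_seed(cfg.seed, feature.feature_id),
        )
    out["flags"] = flags
    return out


def analyze_features(
    features: Sequence[Feature],
    source,
    cfg: RunConfig,
    foreground_class: str | None,
    run_wap: bool = False,
) -> tuple[list[FeatureResult], list[Hotspot]]:
    """Run the full per-feature analysis and multiple-testing correction."""
    cfg.validate()
    sample_ids = list(source.sample_ids)
    N = len(sample_ids)
    scan: CohortScan = source.scan(features)

    fg_by_feature = {
        f.feature_id: _foreground(
            scan.mutations_by_feature.get(f.feature_id, []), foreground_class
        )
        for f in features
    }
    foreground_samples = {
        r.sample_id for recs in fg_by_feature.values() for r in recs
    }

    bg_classes = None
    if cfg.bg_count_class == "foreground" and foreground_class is not None:
        bg_classes = (foreground_class,)
    rates, ap_fallback = compute_rates(features, scan, sample_ids, cfg, bg_classes)

    base_flags = {"ap_fallback"} if ap_fallback else set()
    payloads = []
    for feat in features:
        if foreground_samples:
            agg = aggregate_rate(
                rates[feat.feature_id], foreground_samples, cfg.rate_floor
            )
        else:
            agg = None
        payloads.append(
            {
                "feature": feat,
                "fg": fg_by_feature[feat.feature_id],
                "rate": agg,
                "cohort_size": N,
                "cfg": cfg,
                "run_wap": run_wap and cfg.wap,
                "flags": base_flags,
            }
        )

    if cfg.processors > 1 and len(payloads) > 1:
        with multiprocessing.get_context("fork").Pool(cfg.processors) as pool:
            jobs = pool.map(_feature_job, payloads, chunksize=8)
    else:
        jobs = [_feature_job(p) for p in payloads]

    results: list[FeatureResult] = []
    all_hotspots: list[Hotspot] = []
    for feat, payload, job in zip(features, payloads, jobs):
        best_hs_p = None
        if job["hotspots"]:
            best_hs_p = min(h.p_value for h in job["hotspots"])
            all_hotspots.extend(job["hotspots"])
        wap_p = job["wap"].p_value if job["wap"] is not None else None
        components = [job["burden_p"]]
        if best_hs_p is not None:
            components.append(best_hs_p)
        if cfg.combine_wap and wap_p is not None:
            components.append(wap_p)
        combined_p = fisher_combine(components) if len(components) > 1 else components[0]
        results.append(
            FeatureResult(
                feature_id=feat.feature_id,
                chrom=feat.chrom,
                start=feat.start,
                end=feat.end,
                feature_length=feat.length,
                n_mutated_samples=job["n"],
                cohort_size=N,
                total_mutations=job["k"],
                aggregate_rate=payload["rate"],
                burden_p=job["burden_p"],
                best_hotspot_p=best_hs_p,
                wap_p=wap_p,
                combined_p=combined_p,
                flags=set(job["flags"]),
            )
        )

    for q, r in zip(bh_fdr([r.burden_p for r in results]), results):
        r.burden_q = q
    for q, r in zip(bh_fdr([r.combined_p for r in results]), results):
        r.combined_q = q
    if all_hotspots:
        for q, hs in zip(bh_fdr([h.p_value for h in all_hotspots]), all_hotspots):
            hs.q_value = q
        by_feature: dict[str, list[Hotspot]] = {}
        for hs in all_hotspots:
            by_feature.setdefault(hs.feature_id, []).append(hs)
        for r in results:
            if r.best_hotspot_p is not None:
                best = min(
                    by_feature[r.feature_id], key=lambda h: (h.p_value, h.start)
                )
                r.best_hotspot_q = best.q_value
    wap_results = [r for r in results if r.wap_p is not None]
    if wap_results:
        for q, r in zip(bh_fdr([r.wap_p for r in wap_results]), wap_results):
            r.wap_q = q

    return results, all_hotspots


def write_run_log(cfg: RunConfig, extra: Mapping[str, object], out_prefix: str) -> str:
    """Echo the resolved configuration (no timestamps: outputs stay reproducible)."""
    path = f"{out_prefix}_runlog.txt"
    lines = [f"mutburden version {__version__}"]
    params = {**vars(cfg), **dict(extra)}
    for key in sorted(params):
        lines.append(f"{key} = {params[key]}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def finalize(results, hotspots, cfg: RunConfig, extra: Mapping[str, object]):
    if cfg.out_prefix:
        write_results(results, hotspots, cfg.out_prefix)
        write_run_log(cfg, extra, cfg.out_prefix)
    return results, hotspots
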