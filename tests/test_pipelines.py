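"""End-to-end pipeline behavior on small constructed and synthetic cohorts."""

from __future__ import annotations

from pathlib import Path

import pytest

from mutburden.coding import CodingConfig, run_coding, run_parallel
from mutburden.noncoding import NoncodingConfig, run_noncoding
from mutburden.simulate import CohortSpec, generate_cohort, generate_toy_annotations
from mutburden.stats import binomial_burden_pvalue, per_feature_success_prob

from conftest import make_cohort_list, make_vcf


def write_bed_text(path: Path, lines: list[str]) -> Path:
    path.write_text("\n".join(lines) + "\n")
    return path


def build_burden_cohort(tmp_path, n_target_samples: int, per_sample: int = 1):
    """20 samples; every sample has one anchor mutation in a 100 kb region;
    the first n_target_samples carry `per_sample` mutations in a 1 kb target."""
    rows = {}
    for i in range(20):
        sid = f"s{i:02d}"
        entries = [f"chr1\t{500_000 + i * 7 + 1}\t.\tA\tT\t.\tPASS\t."]
        if i < n_target_samples:
            entries += [
                f"chr1\t{10_000 + i * 11 + j + 1}\t.\tG\tC\t.\tPASS\t."
                for j in range(per_sample)
            ]
        rows[sid] = entries
    entries = [(sid, make_vcf(tmp_path, sid, r)) for sid, r in rows.items()]
    lst = make_cohort_list(tmp_path, entries)
    bed = write_bed_text(
        tmp_path / "regions.bed",
        ["chr1\t10000\t11000\ttarget", "chr1\t500000\t600000\tanchor"],
    )
    return lst, bed


def test_burden_pvalue_composition_and_monotonicity(tmp_path):
    """Pipeline burden_p is exactly the closed-form binomial on (n, N, p_n),
    and injecting more mutated samples never weakens the target's burden."""
    pvals = []
    for idx, m in enumerate([1, 3, 6]):
        sub = tmp_path / f"m{m}"
        sub.mkdir()
        lst, bed = build_burden_cohort(sub, n_target_samples=m)
        results, _ = run_noncoding(
            NoncodingConfig(vcf_list=str(lst), bed=str(bed), wap=False, seed=1)
        )
        target = next(r for r in results if r.feature_id == "target")
        assert target.n_mutated_samples == m
        p_n = per_feature_success_prob(target.aggregate_rate, target.feature_length)
        assert target.burden_p == pytest.approx(
            binomial_burden_pvalue(m, 20, p_n), rel=1e-12
        )
        pvals.append(target.burden_p)
    assert pvals[0] > pvals[1] > pvals[2]


def test_negbinom_counts_mutations_not_samples(tmp_path):
    """One sample with many mutations: invisible to the binomial (n=1),
    glaring to the negative binomial (k=10)."""
    lst, bed = build_burden_cohort(tmp_path, n_target_samples=1, per_sample=10)
    res_bin, _ = run_noncoding(
        NoncodingConfig(vcf_list=str(lst), bed=str(bed), wap=False, seed=1)
    )
    res_nb, _ = run_noncoding(
        NoncodingConfig(
            vcf_list=str(lst), bed=str(bed), wap=False, seed=1, stat_test="negbinom"
        )
    )
    t_bin = next(r for r in res_bin if r.feature_id == "target")
    t_nb = next(r for r in res_nb if r.feature_id == "target")
    assert t_bin.n_mutated_samples == 1 and t_nb.total_mutations == 10
    assert t_nb.burden_p < t_bin.burden_p / 100


def test_growing_unmutated_flanks_weakens_burden(tmp_path):
    lst, _ = build_burden_cohort(tmp_path, n_target_samples=4)
    short_bed = write_bed_text(
        tmp_path / "short.bed",
        ["chr1\t10000\t10100\ttarget", "chr1\t500000\t600000\tanchor"],
    )
    long_bed = write_bed_text(
        tmp_path / "long.bed",
        ["chr1\t10000\t12000\ttarget", "chr1\t500000\t600000\tanchor"],
    )
    p = {}
    for name, bed in [("short", short_bed), ("long", long_bed)]:
        results, _ = run_noncoding(
            NoncodingConfig(vcf_list=str(lst), bed=str(bed), wap=False, seed=1)
        )
        p[name] = next(r for r in results if r.feature_id == "target").burden_p
    assert p["short"] < p["long"]


def test_zero_foreground_cohort_all_untestable(tmp_path):
    """All-silent cohort: no coding foreground, burden p = 1 everywhere."""
    spec = CohortSpec(
        n_samples=6,
        chrom_lengths={"chr1": 150_000},
        background_rate=2e-4,
        silent_fraction=1.0,
        seed=5,
    )
    annos = generate_toy_annotations(spec, tmp_path, genes_per_chrom=6)
    files = generate_cohort(spec, annos.genes, tmp_path, fasta=annos.fasta)
    results, hotspots = run_coding(
        CodingConfig(
            vcf_list=str(files.list_file), gtf=str(annos.gtf), anno_field="ANNO", seed=1
        )
    )
    assert hotspots == []
    assert all(r.burden_p == 1.0 for r in results)
    assert all("untestable" in r.flags for r in results)


def test_hotspots_lie_within_their_feature(tmp_path):
    from mutburden.simulate import HotspotPlant, tile_regions, write_bed

    regions = tile_regions({"chr1": 300_000}, n_regions=50, region_length=2000)
    spec = CohortSpec(
        n_samples=40,
        chrom_lengths={"chr1": 300_000},
        background_rate=1e-5,
        hotspot_plants=[HotspotPlant("region_0010", 39_000, 40, 8)],
        seed=9,
    )
    files = generate_cohort(spec, regions, tmp_path)
    bed = write_bed(regions, tmp_path / "regions.bed")
    results, hotspots = run_noncoding(
        NoncodingConfig(vcf_list=str(files.list_file), bed=str(bed), wap=False, seed=2)
    )
    assert any(h.feature_id == "region_0010" for h in hotspots)
    by_id = {r.feature_id: r for r in regions}
    for hs in hotspots:
        feat = by_id[hs.feature_id]
        assert feat.contains(hs.start + 1) and feat.contains(hs.end)
    # the planted region's combined evidence beats its burden alone
    planted = next(r for r in results if r.feature_id == "region_0010")
    assert planted.best_hotspot_p is not None
    assert planted.combined_p < planted.burden_p


def test_wap_reported_but_not_combined_by_default(tmp_path):
    from mutburden.simulate import HotspotPlant, tile_regions, write_bed

    regions = tile_regions({"chr1": 300_000}, n_regions=30, region_length=2000)
    spec = CohortSpec(
        n_samples=30,
        chrom_lengths={"chr1": 300_000},
        background_rate=1e-5,
        hotspot_plants=[HotspotPlant("region_0005", 19_000, 30, 6)],
        seed=3,
    )
    files = generate_cohort(spec, regions, tmp_path)
    bed = write_bed(regions, tmp_path / "regions.bed")
    base_cfg = dict(vcf_list=str(files.list_file), bed=str(bed), seed=4,
                    n_permutations=500)
    plain, _ = run_noncoding(NoncodingConfig(**base_cfg))
    combined, _ = run_noncoding(NoncodingConfig(**base_cfg, combine_wap=True))
    for a, b in zip(plain, combined):
        # component columns are unchanged by the combination policy
        assert a.burden_p == b.burden_p and a.best_hotspot_p == b.best_hotspot_p
        assert a.wap_p == b.wap_p
    target_a = next(r for r in plain if r.feature_id == "region_0005")
    target_b = next(r for r in combined if r.feature_id == "region_0005")
    assert target_a.wap_p is not None and target_a.wap_p < 0.05
    assert target_b.combined_p != target_a.combined_p  # WAP joined the combination


def test_parallel_and_rerun_outputs_byte_identical(coding_cohort, tmp_path):
    files = coding_cohort["files"]
    annos = coding_cohort["annos"]

    def run(prefix, workers):
        cfg = CodingConfig(
            vcf_list=str(files.list_file),
            gtf=str(annos.gtf),
            anno_field="ANNO",
            seed=3,
            out_prefix=str(tmp_path / prefix),
        )
        return run_parallel(cfg, workers)

    run("w1", 1)
    run("w4", 4)
    run("w1b", 1)
    for suffix in ("_feature_results.tsv", "_hotspots.tsv"):
        a = (tmp_path / f"w1{suffix}").read_bytes()
        assert a == (tmp_path / f"w4{suffix}").read_bytes()
        assert a == (tmp_path / f"w1b{suffix}").read_bytes()


def test_maf_and_vcf_ingestion_agree(coding_cohort, tmp_path):
    files = coding_cohort["files"]
    annos = coding_cohort["annos"]
    common = dict(gtf=str(annos.gtf), seed=3)
    run_coding(
        CodingConfig(
            vcf_list=str(files.list_file),
            anno_field="ANNO",
            out_prefix=str(tmp_path / "vcf"),
            **common,
        )
    )
    run_coding(
        CodingConfig(maf=str(files.maf_path), out_prefix=str(tmp_path / "maf"), **common)
    )
    assert (tmp_path / "vcf_feature_results.tsv").read_bytes() == (
        tmp_path / "maf_feature_results.tsv"
    ).read_bytes()


def test_config_validation_fails_fast(tmp_path):
    with pytest.raises(ValueError, match="covariates"):
        run_noncoding(
            NoncodingConfig(vcf_list="x", bed="y", bg_method="clustered", seed=1)
        )
    with pytest.raises(ValueError, match="anno_field"):
        run_coding(CodingConfig(vcf_list="x", gtf="y", seed=1))
    with pytest.raises(ValueError, match="exactly one"):
        run_coding(CodingConfig(vcf_list="x", maf="z", gtf="y", anno_field="A"))


def test_cli_end_to_end(tmp_path):
    from click.testing import CliRunner

    from mutburden.cli import main

    conf = tmp_path / "sim.conf"
    conf.write_text(
        "mode=noncoding\nn_samples=10\nchrom=chr1:100000\nbackground_rate=5e-5\n"
        "n_regions=20\nregion_length=2000\nregion_spacing=2000\n"
        "plant=region_0003:11000:40:4\n"
    )
    runner = CliRunner()
    sim = runner.invoke(
        main, ["simulate", "--config", str(conf), "--seed", "8", "--out-dir", str(tmp_path / "sim")]
    )
    assert sim.exit_code == 0, sim.output
    out = runner.invoke(
        main,
        [
            "noncoding",
            "--vcf-list", str(tmp_path / "sim" / "cohort_vcfs.txt"),
            "--bed", str(tmp_path / "sim" / "regions.bed"),
            "--n-permutations", "200",
            "--seed", "5",
            "--out-prefix", str(tmp_path / "run"),
        ],
    )
    assert out.exit_code == 0, out.output
    header = (tmp_path / "run_feature_results.tsv").read_text().splitlines()[0]
    assert header.split("\t")[0] == "feature_id"
    assert (tmp_path / "run_runlog.txt").exists()
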