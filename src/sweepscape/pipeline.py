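"""End-to-end orchestration: configuration, seeds, manifest, stage chaining.

A run directory receives one subdirectory per stage plus a ``manifest.json``
recording the package version, per-stage parameters, seeds and output
checksums; deterministic stages are bit-for-bit reproducible from the
config.  Stages read the previous stage's files, so each is re-runnable
independently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, clr, enrichment, filtering, gstats, io, locus
from . import popgen, relatedness, simulate
from .types import CohortPanel, GenotypeMatrix


@dataclass
class RunConfig:
    """Flat configuration with namespaced per-stage keys.

    Defaults mirror the pipeline's canonical thresholds: GQ 20, 5-of-6 hard
    filters, 75% call rate in >= (cohorts - 1) cohorts, kinship cutoffs
    0.20 (Americas) / 0.05 (Africa), 500 kb diversity windows, 99th
    percentile outliers with 1 kb gene flanks, 10,000 permutations and
    500/50-variant G-statistic windows.
    """

    out_dir: str
    seed: int = 0
    # simulate stage (small partial-sweep demo by default)
    sim_N: int = 200
    sim_L: int = 100_000
    sim_mu: float = 1.25e-5
    sim_r: float = 1.25e-6
    sim_s: float = 0.1
    sim_sweep_pos: int = 50_000
    sim_stop_freq: float = 0.6
    sim_sample_n: int = 30
    sim_bad_fraction: float = 0.2
    sim_low_gq_fraction: float = 0.02
    sim_n_genes: int = 40
    sim_masked_fraction: float = 0.05
    # filtering
    min_gq: int = 20
    min_rate: float = 0.75
    min_cohorts: int | None = None
    # kinship
    cutoff_americas: float = 0.20
    cutoff_africa: float = 0.05
    # stats
    pi_window: int = 10_000
    gstat_window: int = 100
    gstat_step: int = 10
    # scan
    grid_spacing: int = 1000
    lambda_points: int = 32
    folded: bool = True
    # enrichment
    quantile: float = 0.99
    flank: int = 1000
    n_perm: int = 1000
    # region report
    region_halfwidth: int = 20_000

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        valid = set(cls.__dataclass_fields__)
        bad = set(data) - valid
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "out_dir" not in data:
            raise ValueError("config missing required key 'out_dir'")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> filter -> kinship -> stats -> scan -> gstats ->
    enrich -> region; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": asdict(config),
                      "stages": {}}

    def finish(stage: str, files: dict[str, Path], **params):
        manifest["stages"][stage] = {
            "params": params,
            "outputs": {k: {"path": str(p), "sha256": _sha256(p)}
                        for k, p in files.items()},
        }

    # --- simulate ------------------------------------------------------
    sim_dir = out / "simulate"
    sim_dir.mkdir(exist_ok=True)
    hap, pos, gm, truth = simulate.simulate_wf_sweep(
        N=config.sim_N, L=config.sim_L, mu=config.sim_mu, r=config.sim_r,
        s=config.sim_s, sweep_pos=config.sim_sweep_pos,
        stop_freq=config.sim_stop_freq, sample_n=config.sim_sample_n,
        seed=config.seed,
    )
    rng = np.random.default_rng(config.seed + 1)
    panel_df = pd.DataFrame(
        {
            "sample": gm.sample_ids,
            "cohort": ["cohortA" if i < gm.n_samples // 2 else "cohortB"
                       for i in range(gm.n_samples)],
            "continent": "Americas",
            "mean_coverage": np.round(rng.uniform(15, 40, gm.n_samples), 1),
        }
    ).set_index("sample")
    panel = CohortPanel(panel_df)
    sq, q_truth = simulate.synthesize_site_quality(
        gm.n_sites, config.sim_bad_fraction, seed=config.seed + 2)
    gm, _ = simulate.synthesize_gq(gm, config.sim_low_gq_fraction,
                                   seed=config.seed + 3)
    genes, catalog = simulate.make_gene_annotation(
        config.sim_L, config.sim_n_genes,
        cluster_spec={"term": "clustered_set", "n_genes": 8, "span": 20_000,
                      "start": max(1, config.sim_sweep_pos - 10_000)},
        seed=config.seed + 4)
    mask = simulate.make_masks(config.sim_L, config.sim_masked_fraction,
                               seed=config.seed + 5)
    vcf_path = sim_dir / "sim.vcf"
    io.write_vcf(gm, sq, vcf_path, contig_lengths={"1": config.sim_L})
    io.write_panel(panel, sim_dir / "panel.tsv")
    io.write_gff3(genes, sim_dir / "genes.gff3")
    io.write_bed(mask, sim_dir / "mask.bed")
    truth.to_json(sim_dir / "truth.json")
    finish("simulate",
           {"vcf": vcf_path, "panel": sim_dir / "panel.tsv",
            "gff3": sim_dir / "genes.gff3", "bed": sim_dir / "mask.bed",
            "truth": sim_dir / "truth.json"},
           seed=config.seed, N=config.sim_N, L=config.sim_L, s=config.sim_s,
           stop_freq=config.sim_stop_freq, restarts=truth.restarts)

    # --- filter --------------------------------------------------------
    filt_dir = out / "filter"
    filt_dir.mkdir(exist_ok=True)
    gm_in, sq_in = io.read_vcf(vcf_path)
    panel = io.read_panel(sim_dir / "panel.tsv")
    mask = io.read_intervals(sim_dir / "mask.bed", "BED")
    fgm, fsq, report = filtering.run_site_filters(
        gm_in, sq_in, panel=panel, mask=mask, min_gq=config.min_gq,
        min_rate=config.min_rate, min_cohorts=config.min_cohorts)
    io.write_vcf(fgm, fsq, filt_dir / "filtered.vcf",
                 contig_lengths={"1": config.sim_L})
    with open(filt_dir / "filter_report.json", "w") as fh:
        json.dump({"n_input": report.n_input, "n_kept": report.n_kept,
                   "failing_per_filter": report.failing_per_filter,
                   "stage_counts": report.stage_counts}, fh, indent=1)
    finish("filter", {"vcf": filt_dir / "filtered.vcf",
                      "report": filt_dir / "filter_report.json"},
           min_gq=config.min_gq, min_rate=config.min_rate)

    # --- kinship -------------------------------------------------------
    kin_dir = out / "kinship"
    kin_dir.mkdir(exist_ok=True)
    gm_f, _ = io.read_vcf(filt_dir / "filtered.vcf")
    kin = relatedness.kinship_table(gm_f)
    removed = relatedness.prune_related(
        kin, panel, cutoffs={"Americas": config.cutoff_americas,
                             "Africa": config.cutoff_africa})
    kin.to_csv(kin_dir / "kinship.tsv", sep="\t", index=False)
    pd.Series(sorted(removed), name="sample").to_csv(
        kin_dir / "removed.tsv", sep="\t", index=False)
    finish("kinship", {"kinship": kin_dir / "kinship.tsv",
                       "removed": kin_dir / "removed.tsv"},
           cutoff_americas=config.cutoff_americas,
           cutoff_africa=config.cutoff_africa, n_removed=len(removed))
    keep_samples = [s for s in gm_f.sample_ids if s not in removed]
    gm_k = gm_f.take_samples(keep_samples)

    # --- stats ---------------------------------------------------------
    stat_dir = out / "stats"
    stat_dir.mkdir(exist_ok=True)
    pi = popgen.windowed_pi(gm_k, window=config.pi_window,
                            chrom_length=config.sim_L)
    tajd = popgen.windowed_tajimas_d(gm_k, window=config.pi_window,
                                     chrom_length=config.sim_L)
    pi.to_csv(stat_dir / "pi.tsv", sep="\t", index=False)
    tajd.to_csv(stat_dir / "tajd.tsv", sep="\t", index=False)
    finish("stats", {"pi": stat_dir / "pi.tsv", "tajd": stat_dir / "tajd.tsv"},
           window=config.pi_window)

    # --- scan ----------------------------------------------------------
    scan_dir = out / "scan"
    scan_dir.mkdir(exist_ok=True)
    cohortA = [s for s in panel.samples_in("cohortA") if s in keep_samples]
    panelA = CohortPanel(panel.table.loc[[s for s in panel.sample_ids
                                          if s in keep_samples]])
    spec = clr.empirical_sfs(gm_k, panelA, "cohortA", folded=config.folded)
    scan = clr.clr_scan(gm_k, panelA, "cohortA", spec,
                        grid_spacing=config.grid_spacing,
                        lambda_points=config.lambda_points)
    scan.to_frame().to_csv(scan_dir / "clr.tsv", sep="\t", index=False)
    finish("scan", {"clr": scan_dir / "clr.tsv"},
           grid_spacing=config.grid_spacing, folded=config.folded,
           n_background=spec.n_background)

    # --- gstats --------------------------------------------------------
    g_dir = out / "gstats"
    g_dir.mkdir(exist_ok=True)
    windows = gstats.mlg_windows(gm_k, window=config.gstat_window,
                                 step=config.gstat_step)
    gstats.gstats_frame(windows).to_csv(g_dir / "gstats.tsv", sep="\t",
                                        index=False)
    finish("gstats", {"gstats": g_dir / "gstats.tsv"},
           window=config.gstat_window, step=config.gstat_step)

    # --- enrich --------------------------------------------------------
    enr_dir = out / "enrich"
    enr_dir.mkdir(exist_ok=True)
    genes = io.read_intervals(sim_dir / "genes.gff3", "GFF3")
    results = enrichment.rotation_test(
        scan, catalog, genes, quantile=config.quantile, flank=config.flank,
        n_perm=config.n_perm, seed=config.seed + 6)
    pd.DataFrame(
        {"term_id": [r.term_id for r in results],
         "observed": [r.observed for r in results],
         "p_value": [r.p_value for r in results],
         "q_value": [r.q_value for r in results]}
    ).to_csv(enr_dir / "enrichment.tsv", sep="\t", index=False)
    finish("enrich", {"enrichment": enr_dir / "enrichment.tsv"},
           quantile=config.quantile, flank=config.flank, n_perm=config.n_perm,
           seed=config.seed + 6)

    # --- region --------------------------------------------------------
    reg_dir = out / "region"
    reg_dir.mkdir(exist_ok=True)
    start = max(1, config.sim_sweep_pos - config.region_halfwidth)
    end = min(config.sim_L, config.sim_sweep_pos + config.region_halfwidth)
    try:
        res = locus.region_pca(gm_k, "1", start, end)
        assignment = locus.assign_pca_clusters(res, k=3, seed=config.seed + 7)
        coords = pd.DataFrame(res.coords[:, :2], columns=["PC1", "PC2"])
        coords.insert(0, "sample", res.sample_ids)
        coords["cluster"] = [assignment.labels[s] for s in res.sample_ids]
        coords.to_csv(reg_dir / "region_pca.tsv", sep="\t", index=False)
        finish("region", {"pca": reg_dir / "region_pca.tsv"},
               chrom="1", start=start, end=end, seed=config.seed + 7)
    except ValueError as exc:  # degenerate demo region; report, don't fail
        with open(reg_dir / "region_skipped.txt", "w") as fh:
            fh.write(str(exc) + "\n")
        finish("region", {"note": reg_dir / "region_skipped.txt"},
               chrom="1", start=start, end=end)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
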