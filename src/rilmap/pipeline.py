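"""End-to-end driver: simulate (optional) -> bin calling -> genetic map
-> QTL scan -> report, with a manifest for reproducibility.

Every source of randomness derives from the single config seed, so the
same config produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import bincall, datasets, genmap, io, qtlscan, simpop
from .config import PipelineConfig


class PipelineStageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as e:
                raise PipelineStageError(name, e) from e
        return wrapper
    return deco


def _sub_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31, reproducibly from one seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def simulation_inputs(cfg: PipelineConfig):
    """Chromosome lengths and QTL effects for the configured simulation.

    Physical and genetic lengths come from the rice reference values
    (optionally shrunk by ``genome_scale``); QTL effects are the published
    eleven-QTL set (signed additive weights), with positions scaled along
    with the genome.
    """
    sim = cfg.sim
    chroms = [str(i + 1) for i in range(sim.n_chrom)]
    phys = datasets.rice_chrom_lengths_bp()
    gen = datasets.rice_genetic_lengths_cm()
    chrom_bp = {c: max(1, int(phys[c] * sim.genome_scale)) for c in chroms}
    chrom_cm = {c: gen[c] * sim.genome_scale for c in chroms}
    qtls = datasets.reported_ltg_qtls()
    qtls = qtls[qtls["chrom"].astype(str).isin(chroms)]
    effects = pd.DataFrame(
        {
            "chrom": qtls["chrom"].astype(str),
            "pos_bp": (qtls["peak_mb"] * 1e6 * sim.genome_scale).astype(int).clip(lower=1),
            "effect": qtls["add_effect"].astype(float),
            "name": qtls["name"],
        }
    ).reset_index(drop=True)
    return chrom_bp, chrom_cm, effects


@_stage("simulate")
def _run_simulate(cfg: PipelineConfig, out: Path):
    sim = cfg.sim
    chrom_bp, chrom_cm, effects = simulation_inputs(cfg)
    s_par, s_mos, s_calls, s_phe = _sub_seeds(cfg.seed, 4)
    snps = simpop.simulate_parents(sim.n_chrom, chrom_bp, sim.snp_density_per_kb, s_par)
    mosaics = simpop.simulate_ril_mosaics(
        chrom_cm, chrom_bp, sim.n_lines, sim.n_generations, s_mos
    )
    ocm = simpop.sample_origin_calls(mosaics, snps, sim.mean_depth, sim.error_rate, s_calls)
    pheno = simpop.simulate_phenotypes(
        mosaics, effects[["chrom", "pos_bp", "effect"]], sim.parent_means,
        sim.residual_sd, s_phe, trait=sim.trait,
    )
    io.write_calls_vcf(out / "calls.vcf", ocm)
    io.write_phenotypes_csv(out / "phenotypes.csv", pheno)
    effects.to_csv(out / "true_qtls.tsv", sep="\t", index=False)
    return ocm, pheno, mosaics


@_stage("callbins")
def _run_callbins(cfg: PipelineConfig, ocm, out: Path):
    if ocm.chrom_lengths is None:
        raise ValueError("origin calls carry no chromosome lengths")
    segs = bincall.call_all_segments(
        ocm, ocm.chrom_lengths, cfg.window_size, cfg.min_informative, cfg.min_run
    )
    bm = bincall.build_bin_map(segs, ocm.chrom_lengths, cfg.grid_bp, ocm.line_ids)
    io.write_bins_tsv(out / "bins.tsv", bm)
    return bm


@_stage("map")
def _run_map(cfg: PipelineConfig, bm, out: Path):
    gm = genmap.build_genetic_map(bm, cfg.map_function, cfg.ceiling_cm)
    io.write_map_tsv(out / "map.tsv", gm)
    summary = bincall.binmap_summary(bm, gm)
    summary.to_csv(out / "map_summary.tsv", sep="\t", index=False)
    return gm


@_stage("scan")
def _run_scan(cfg: PipelineConfig, bm, gm, pheno, out: Path):
    y = qtlscan.phenotype_vector(pheno, bm.line_ids, trait=cfg.sim.trait)
    grid = qtlscan.genotype_probabilities(bm, gm, cfg.step_cm)
    method = cfg.method.upper()
    covs = (
        qtlscan.select_cim_covariates(bm, gm, y, cfg.max_cov) if method == "CIM" else []
    )
    res = qtlscan.scan(grid, y, covs, method, cfg.exclusion_window_cm, cfg.lod_ceiling)
    s_perm = _sub_seeds(cfg.seed, 5)[4]
    threshold, max_lods = qtlscan.permutation_threshold(
        grid, y, cfg.n_perm, cfg.alpha, s_perm, method,
        bin_matrix=bm, genetic_map=gm, max_cov=cfg.max_cov,
        exclusion_window_cm=cfg.exclusion_window_cm,
    )
    io.write_scan_tsv(out / "scan.tsv", res)
    io.write_json(
        out / "threshold.json",
        {
            "alpha": cfg.alpha,
            "n_perm": cfg.n_perm,
            "threshold": threshold,
            "max_lod_quantiles": {
                "q50": float(np.quantile(max_lods, 0.5)),
                "q95": float(np.quantile(max_lods, 0.95)),
            },
        },
    )
    return res, threshold


@_stage("report")
def _run_report(cfg: PipelineConfig, res, threshold, n_lines, out: Path):
    report = qtlscan.qtl_report(res, threshold, n_lines, cfg.drop)
    io.write_report_tsv(out / "report.tsv", report)
    return report


@_stage("load_inputs")
def _load_inputs(cfg: PipelineConfig):
    if cfg.calls_vcf is None or cfg.phenotypes_csv is None:
        raise ValueError("simulate=false requires calls_vcf and phenotypes_csv")
    ocm = io.read_calls_vcf(cfg.calls_vcf)
    pheno = io.read_phenotypes_csv(cfg.phenotypes_csv)
    return ocm, pheno


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> dict:
    """Execute the pipeline; returns the in-memory artefacts.

    Writes calls.vcf / phenotypes.csv (when simulating), bins.tsv,
    map.tsv, map_summary.tsv, scan.tsv, threshold.json, report.tsv and
    manifest.json under ``out_dir`` (default: config out_dir).
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.simulate:
        ocm, pheno, mosaics = _run_simulate(cfg, out)
    else:
        ocm, pheno = _load_inputs(cfg)
        mosaics = None
    bm = _run_callbins(cfg, ocm, out)
    gm = _run_map(cfg, bm, out)
    res, threshold = _run_scan(cfg, bm, gm, pheno, out)
    report = _run_report(cfg, res, threshold, len(bm.line_ids), out)

    cfg_yaml = cfg.to_yaml()
    io.write_json(
        out / "manifest.json",
        {
            "package": "rilmap",
            "version": _pkg_version,
            "seed": cfg.seed,
            "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
            "config": cfg.to_dict(),
        },
    )
    return {
        "calls": ocm,
        "phenotypes": pheno,
        "mosaics": mosaics,
        "bin_matrix": bm,
        "genetic_map": gm,
        "scan": res,
        "threshold": threshold,
        "report": report,
    }
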