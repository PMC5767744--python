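"""End-to-end pipeline: simulate or load inputs, then run every stage.

The run configuration is a plain mapping (usually parsed from YAML):

    outdir: results/
    seed: 1
    k: 2
    alpha: 0.05
    calling: {min_depth_exclusive: 10, noise_freq: 0.2, ...}
    simulation: {n_accessions: 383, ...}          # or:
    inputs: {pileup: ..., gene_order: ..., expression: ...,
             trait: ..., linkage: ...}
    flags: {gc_on_snp: false, run_loo: true, fast_loo: false,
            dendrogram: true}

Every stage writes its artifacts under ``outdir`` and appends its exclusion
and marker counts to ``run_log.json``; reruns of the same configuration are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from . import io
from .association import GEMAssociation, SNPAssociation
from .calling import CallingParams, call_snps
from .prediction import TakeOneOutGEM, TakeOneOutSNP
from .simulate import PanelConfig, simulate_panel
from .structure import (
    build_dendrogram,
    encode_genotypes,
    estimate_q,
    jc69_matrix,
    kinship,
    ld_scan,
)


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("run configuration must be a mapping")
    return cfg


def _require(path_str: str, role: str) -> Path:
    p = Path(path_str)
    if not p.exists():
        raise FileNotFoundError(f"{role} file not found: {p}")
    return p


def run_all(config: dict, outdir: str | Path | None = None) -> Path:
    """Run the full associative-transcriptomics workflow.

    Returns the output directory. Any stage failure raises with the stage
    name prepended.
    """
    outdir = Path(outdir or config.get("outdir", "at_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 1))
    k = int(config.get("k", 2))
    alpha = float(config.get("alpha", 0.05))
    flags = dict(config.get("flags") or {})
    params = CallingParams(**(config.get("calling") or {}))
    log: dict = {"seed": seed, "k": k, "alpha": alpha}

    stage = "inputs"
    try:
        if "inputs" in config:
            inputs = config["inputs"]
            pileup = io.read_pileup(_require(inputs["pileup"], "pileup"))
            gene_order = io.read_gene_order(
                _require(inputs["gene_order"], "gene order"))
            expression = io.read_expression(
                _require(inputs["expression"], "expression"))
            trait = io.read_trait(_require(inputs["trait"], "trait"))
            linkage = (io.read_linkage_evidence(
                _require(inputs["linkage"], "linkage evidence"))
                if inputs.get("linkage") else set())
        else:
            stage = "simulate"
            sim_cfg = dict(config.get("simulation") or {})
            sim_cfg.setdefault("seed", seed)
            panel = simulate_panel(PanelConfig(**sim_cfg))
            pileup, gene_order = panel.pileup, panel.gene_order
            expression, trait = panel.expression, panel.trait
            linkage = panel.linkage_evidence
            io.write_pileup(pileup, outdir / "pileup.tsv")
            io.write_gene_order(gene_order, outdir / "gene_order.tsv")
            io.write_trait(trait, outdir / "trait.csv")
            io.write_linkage_evidence(linkage, outdir / "linkage.tsv")
            with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
                json.dump(panel.truth.to_jsonable(), fh, indent=2)

        stage = "call-snps"
        matrix, annotations, call_log = call_snps(pileup, gene_order,
                                                  linkage, params)
        io.write_site_calls(matrix, outdir / "markers.tsv")
        io.write_annotations(annotations, outdir / "annotations.tsv")
        log["calling"] = call_log

        stage = "quantify"
        io.write_expression(expression, outdir / "rpkm.tsv")

        stage = "structure"
        geno = encode_genotypes(matrix)
        Q = estimate_q(geno, k=k, seed=seed)
        K = kinship(geno)
        io.write_matrix(Q, outdir / "q_matrix.tsv")
        io.write_matrix(K, outdir / "kinship.tsv")
        if flags.get("dendrogram", True):
            dist = jc69_matrix(matrix)
            _, newick = build_dendrogram(dist)
            io.write_matrix(dist, outdir / "jc69_distances.tsv")
            io.write_newick(newick, outdir / "dendrogram.nwk")

        stage = "ld"
        ld = ld_scan(geno, annotations, seed=seed,
                     maf_min=params.maf_min_exclusive)
        ld.pairs.to_csv(outdir / "ld_pairs.tsv", sep="\t", index=False,
                        float_format="%.6g")
        means = ld.chromosome_means.rename("mean_r2").to_frame()
        means.index.name = "chromosome"
        means.to_csv(outdir / "ld_means.tsv", sep="\t", float_format="%.6g")
        log["ld"] = {"genome_mean_r2": ld.genome_mean,
                     "n_sites": len(ld.sites_used)}

        stage = "assoc-snp"
        snp_res = SNPAssociation(
            trait, geno, annotations, Q=Q, K=K,
            maf_min=params.maf_min_exclusive,
        ).fit(alpha=alpha, apply_gc=bool(flags.get("gc_on_snp", False)))
        io.write_scan(snp_res.to_scan_frame(), outdir / "snp_scan.tsv")
        snp_res.manhattan_table(gene_order).to_csv(
            outdir / "snp_manhattan.tsv", sep="\t", index=False,
            float_format="%.6g")
        log["snp_association"] = {
            "n_tested": snp_res.n_tested,
            "h2": snp_res.h2,
            "lambda_gc": snp_res.lambda_gc,
            "bonferroni": snp_res.bonferroni,
            "n_significant": int(len(snp_res.significant())),
        }

        stage = "assoc-gem"
        gem_res = GEMAssociation(trait, expression, Q=Q).fit(alpha=alpha)
        gem_res.fits.to_csv(outdir / "gem_fits.tsv", sep="\t", index=False,
                            float_format="%.6g")
        gem_res.manhattan_table(gene_order).to_csv(
            outdir / "gem_manhattan.tsv", sep="\t", index=False,
            float_format="%.6g")
        log["gem_association"] = {
            "n_tested": gem_res.n_tested,
            "lambda_gc": gem_res.lambda_gc,
            "bonferroni": gem_res.bonferroni,
            "n_significant": int(len(gem_res.significant())),
        }

        thresholds = {
            "alpha": alpha,
            "snp_bonferroni": snp_res.bonferroni,
            "snp_fdr_line": snp_res.fdr,
            "gem_bonferroni": gem_res.bonferroni,
            "gem_fdr_line": gem_res.fdr,
        }
        with open(outdir / "thresholds.json", "w", encoding="utf-8") as fh:
            json.dump({k_: (v if np.isfinite(v) else None)
                       for k_, v in thresholds.items()}, fh, indent=2)

        if flags.get("run_loo", True):
            stage = "predict-loo"
            fast = bool(flags.get("fast_loo", False))
            snp_loo = TakeOneOutSNP(trait, matrix, annotations, k=k,
                                    alpha=alpha,
                                    maf_min=params.maf_min_exclusive,
                                    seed=seed).run(fast=fast)
            gem_loo = TakeOneOutGEM(trait, expression, Q=Q,
                                    alpha=alpha).run(fast=fast)
            snp_loo.frame.to_csv(outdir / "loo_snp.tsv", sep="\t",
                                 index=False, float_format="%.6g")
            gem_loo.frame.to_csv(outdir / "loo_gem.tsv", sep="\t",
                                 index=False, float_format="%.6g")
            log["prediction"] = {
                "snp_r2": snp_loo.r2, "gem_r2": gem_loo.r2,
                "snp_fallback_fraction": snp_loo.fallback_fraction,
                "gem_fallback_fraction": gem_loo.fallback_fraction,
            }
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, default=float)
    return outdir
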