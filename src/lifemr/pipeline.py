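"""Orchestration of the full summary-statistics causal-inference workflow.

Stages: read inputs -> genomic loci on the outcome GWAS -> FDR-filtered
cis/trans SNP-gene pairs -> per-gene instrument selection and
harmonization -> IVW with Cochran's Q -> MR-PRESSO rescue of
heterogeneous hits -> Egger sensitivity -> colocalization of causal
genes' regions -> optional enrichment. Every stage logs one structured
event with record counts in/out/excluded, and re-running with the same
configuration and seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import loci as loci_mod
from .instruments import require_min_instruments, select_instruments
from .ld import read_ld
from .mr import MRResult, classify_causal, egger, ivw
from .presso import run_presso
from .sumstats import TraitMeta, beta_to_years, read_sumstats
from .coloc import RegionStats, TraitRegion

log = logging.getLogger("lifemr.pipeline")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "run_mr_stage", "STAGES"]

STAGES = ("read", "loci", "eqtl_pairs", "instruments", "mr", "presso", "egger", "coloc", "enrich")

_DEFAULT_GWAS_COLUMNS = {
    "variant_id": "variant_id", "chrom": "chrom", "pos": "pos",
    "effect_allele": "effect_allele", "other_allele": "other_allele",
    "eaf": "eaf", "beta": "beta", "se": "se", "p": "p", "n": "n",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage={stage}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative configuration; defaults mirror the published thresholds,
    so running on real data is a config-only change."""

    gwas_path: str = ""
    eqtl_path: str = ""
    ld_path: str = ""
    genes_path: str = ""
    gene_sets_path: str | None = None
    out_dir: str = "lifemr_out"
    gwas_columns: dict = field(default_factory=lambda: dict(_DEFAULT_GWAS_COLUMNS))
    gwas_n: int | None = None
    # locus definition
    gwas_p_thresh: float = 5e-8
    r2_ind_sig: float = 0.6
    r2_lead: float = 0.1
    maf_min: float = 0.01
    locus_merge_bp: int = 250_000
    # eQTL mapping
    cis_window_bp: int = 1_000_000
    trans_min_bp: int = 5_000_000
    eqtl_fdr: float = 0.05
    # instruments
    instrument_window_bp: int = 500_000
    instrument_p: float = 1e-3
    instrument_r2: float = 0.1
    min_instruments: int = 3
    palindromic_policy: str = "strict"
    # MR decision thresholds
    alpha: float = 0.05
    heterogeneity_alpha: float = 0.05
    presso_n_sim: int = 1000
    presso_n_boot: int = 1000
    # colocalization
    coloc_pp_thresh: float = 0.8
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    seed: int = 0
    outcome_is_lifespan: bool = True

    def __post_init__(self) -> None:
        positive = (
            "gwas_p_thresh r2_ind_sig r2_lead maf_min locus_merge_bp cis_window_bp "
            "trans_min_bp eqtl_fdr instrument_window_bp instrument_p instrument_r2 "
            "min_instruments alpha heterogeneity_alpha presso_n_sim presso_n_boot "
            "coloc_pp_thresh coloc_p1 coloc_p2 coloc_p12"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("gwas_p_thresh", "r2_ind_sig", "r2_lead", "eqtl_fdr", "alpha",
                     "heterogeneity_alpha", "coloc_pp_thresh", "instrument_p",
                     "coloc_p1", "coloc_p2", "coloc_p12"):
            if getattr(self, name) > 1:
                raise ValueError(f"{name} must be <= 1")
        if not 0 < self.maf_min < 0.5:
            raise ValueError("maf_min must lie in (0, 0.5)")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _stage_log(report: dict, stage: str, n_in: int, n_out: int, excluded: dict | None = None) -> None:
    event = {"stage": stage, "in": n_in, "out": n_out, "excluded": dict(excluded or {})}
    report["stages"].append(event)
    log.info("stage=%s in=%d out=%d excluded=%s", stage, n_in, n_out, event["excluded"])


def run_mr_stage(
    instrument_sets: dict,
    alpha: float = 0.05,
    heterogeneity_alpha: float = 0.05,
    m: int | None = None,
    n_sim: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
    model: str = "auto",
) -> tuple[list[MRResult], dict, pd.DataFrame]:
    """IVW + Q across genes, MR-PRESSO for heterogeneous Bonferroni hits,
    and the causal-call table. Per-gene PRESSO seeds derive from ``seed``.

    This is the pipeline's decision core; it also serves in-memory
    simulation studies that skip the file-reading stages.
    """
    genes = sorted(instrument_sets)
    if m is None:
        m = len(genes)
    ivw_results = [ivw(instrument_sets[g], model=model) for g in genes]
    thresh = alpha / m
    presso_results = {}
    for k, (g, res) in enumerate(zip(genes, ivw_results)):
        if res.p < thresh and res.Q_p is not None and res.Q_p < heterogeneity_alpha:
            gene_seed = (seed * 1_000_003 + 7 * k + 1) % (2**31)
            presso_results[g] = run_presso(
                instrument_sets[g], res, n_sim=n_sim, n_boot=n_boot, seed=gene_seed,
                alpha=heterogeneity_alpha,
            )
    calls = classify_causal(ivw_results, presso_results, alpha=alpha, m=m,
                            q_alpha=heterogeneity_alpha)
    return ivw_results, presso_results, calls


def run_pipeline(config: PipelineConfig, through: str = "enrich") -> dict:
    """Execute the workflow from files through the stage named ``through``.

    Writes tab-delimited stage tables plus ``summary.json`` under
    ``config.out_dir`` and returns the report dictionary (per-stage
    counts, causal calls, seeds).
    """
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}")
    last = STAGES.index(through)
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict = {"stages": [], "seed": config.seed, "config": asdict(config)}

    # -- read ------------------------------------------------------------
    try:
        meta = TraitMeta("outcome", "quantitative", config.gwas_n)
        colmap = {k: v for k, v in config.gwas_columns.items()}
        gwas = read_sumstats(config.gwas_path, colmap, meta)
    except (OSError, KeyError, ValueError) as err:
        raise PipelineError("read", str(err)) from err
    gwas_df = pd.DataFrame(
        [
            {"variant_id": r.variant_id, "chrom": r.chrom, "pos": r.pos,
             "eaf": r.eaf, "beta": r.beta, "se": r.se, "z": r.z, "p": r.p}
            for r in gwas.records
        ]
    )
    gwas_by_id = {r.variant_id: r for r in gwas.records}
    try:
        eqtl = pd.read_csv(config.eqtl_path, sep="\t")
        ld = read_ld(config.ld_path, check=False)
        genes = pd.read_csv(config.genes_path, sep="\t")
    except OSError as err:
        raise PipelineError("read", str(err)) from err
    if {"beta", "se"} - set(eqtl.columns):
        from .sumstats import zscore_to_beta_se

        beta, se = zscore_to_beta_se(eqtl["z"].to_numpy(), eqtl["eaf"].to_numpy(),
                                     eqtl["n"].to_numpy())
        eqtl = eqtl.assign(beta=beta, se=se)
    _stage_log(report, "read", gwas.n_rows, len(gwas.records), gwas.skipped)
    if last == STAGES.index("read"):
        return _finish(report, config)

    # -- loci ------------------------------------------------------------
    loci = loci_mod.define_loci(
        gwas_df, ld, p_thresh=config.gwas_p_thresh, r2_ind=config.r2_ind_sig,
        r2_lead=config.r2_lead, maf_min=config.maf_min, max_gap=config.locus_merge_bp,
    )
    loci_df = pd.DataFrame(
        [
            {"lead_snp": l.lead_snp, "chrom": l.chrom, "start": l.start, "end": l.end,
             "lead_p": l.lead_p, "n_ind_sig": len(l.ind_sig_snps),
             "n_candidates": len(l.candidate_snps)}
            for l in loci
        ]
    )
    loci_df.to_csv(os.path.join(config.out_dir, "loci.tsv"), sep="\t", index=False)
    _bed(loci, os.path.join(config.out_dir, "loci.bed"))
    _stage_log(report, "loci", len(gwas_df), len(loci))
    if last == STAGES.index("loci"):
        return _finish(report, config)

    # -- eQTL pair mapping ----------------------------------------------
    pairs = loci_mod.map_eqtl_pairs(eqtl, genes, fdr=config.eqtl_fdr)
    pairs.to_csv(os.path.join(config.out_dir, "eqtl_pairs.tsv"), sep="\t", index=False)
    _stage_log(report, "eqtl_pairs", len(eqtl), len(pairs),
               {"fdr_filtered": len(eqtl) - len(pairs)})
    if last == STAGES.index("eqtl_pairs"):
        return _finish(report, config)

    # -- instruments ------------------------------------------------------
    from .sumstats import VariantAssoc

    cis_genes = sorted(pairs.loc[pairs["category"] == "cis", "gene_id"].unique())
    gene_index = genes.set_index("gene_id")
    instrument_sets = {}
    excluded: dict[str, int] = {}
    iv_rows = []
    for gene_id in cis_genes:
        sub = eqtl[eqtl["gene_id"] == gene_id]
        records = [
            VariantAssoc(
                variant_id=r.variant_id, chrom=str(r.chrom), pos=int(r.pos),
                effect_allele=r.effect_allele, other_allele=r.other_allele,
                eaf=float(r.eaf), beta=float(r.beta), se=float(r.se),
                z=float(r.beta / r.se), p=float(r.p), n=int(r.n),
            )
            for r in sub.itertuples(index=False)
        ]
        grow = gene_index.loc[gene_id]
        try:
            iset = select_instruments(
                {"gene_id": gene_id, "chrom": grow["chrom"], "tss": grow["tss"]},
                records, ld, gwas_by_id,
                window=config.instrument_window_bp, p_thresh=config.instrument_p,
                r2_thresh=config.instrument_r2,
                palindromic_policy=config.palindromic_policy,
            )
        except ValueError:
            excluded["no_instrument"] = excluded.get("no_instrument", 0) + 1
            continue
        if not require_min_instruments(iset, config.min_instruments):
            excluded["below_min_instruments"] = excluded.get("below_min_instruments", 0) + 1
            continue
        instrument_sets[gene_id] = iset
        iv_rows.append(iset.to_frame())
    if iv_rows:
        pd.concat(iv_rows, ignore_index=True).to_csv(
            os.path.join(config.out_dir, "instruments.tsv"), sep="\t", index=False
        )
    report["excluded_genes"] = excluded
    _stage_log(report, "instruments", len(cis_genes), len(instrument_sets), excluded)
    if last == STAGES.index("instruments") or not instrument_sets:
        return _finish(report, config)

    # -- MR + PRESSO + calls ----------------------------------------------
    ivw_results, presso_results, calls = run_mr_stage(
        instrument_sets, alpha=config.alpha,
        heterogeneity_alpha=config.heterogeneity_alpha,
        n_sim=config.presso_n_sim, n_boot=config.presso_n_boot, seed=config.seed,
    )
    mr_df = pd.DataFrame([dataclasses.asdict(r) for r in ivw_results])
    if config.outcome_is_lifespan:
        mr_df["years_per_sd"] = beta_to_years(mr_df["theta"])
    mr_df.to_csv(os.path.join(config.out_dir, "mr_results.tsv"), sep="\t", index=False)
    _stage_log(report, "mr", len(instrument_sets), len(mr_df))
    if last == STAGES.index("mr"):
        report["causal_calls"] = calls.to_dict(orient="records")
        return _finish(report, config)

    presso_df = pd.DataFrame(
        [
            {
                "gene_id": g, "global_p": r.global_p, "outliers": ",".join(r.outlier_ids),
                "theta_corrected": r.theta_corrected, "p_corrected": r.p_corrected,
                "distortion_coeff": r.distortion_coeff, "distortion_p": r.distortion_p,
                "verdict": r.verdict, "failed_gate": r.failed_gate, "seed": r.seed,
            }
            for g, r in sorted(presso_results.items())
        ]
    )
    presso_df.to_csv(os.path.join(config.out_dir, "presso.tsv"), sep="\t", index=False)
    calls.to_csv(os.path.join(config.out_dir, "causal_calls.tsv"), sep="\t", index=False)
    report["causal_calls"] = calls.to_dict(orient="records")
    _stage_log(report, "presso", len(presso_results), len(presso_df))
    if last == STAGES.index("presso"):
        return _finish(report, config)

    # -- Egger sensitivity -------------------------------------------------
    causal_genes = list(calls.loc[calls["causal"], "gene_id"])
    egger_rows = []
    for g in causal_genes:
        try:
            e = egger(instrument_sets[g])
        except ValueError:
            continue
        egger_rows.append(
            {"gene_id": g, "theta": e.theta, "se": e.se, "p": e.p,
             "intercept": e.egger_intercept, "intercept_p": e.egger_intercept_p}
        )
    pd.DataFrame(egger_rows).to_csv(os.path.join(config.out_dir, "egger.tsv"),
                                    sep="\t", index=False)
    _stage_log(report, "egger", len(causal_genes), len(egger_rows))
    if last == STAGES.index("egger"):
        return _finish(report, config)

    # -- colocalization ----------------------------------------------------
    coloc_rows = []
    for g in causal_genes:
        grow = gene_index.loc[g]
        lo, hi = int(grow["tss"]) - config.instrument_window_bp, int(grow["tss"]) + config.instrument_window_bp
        sub = eqtl[(eqtl["gene_id"] == g) & (eqtl["pos"].between(lo, hi))]
        shared = [v for v in sub["variant_id"] if v in gwas_by_id]
        if len(shared) < 2:
            continue
        sub = sub.set_index("variant_id").loc[shared]
        z1 = (sub["beta"] / sub["se"]).to_numpy()
        se1 = sub["se"].to_numpy()
        z2 = np.array([gwas_by_id[v].z for v in shared])
        se2 = np.array([gwas_by_id[v].se for v in shared])
        region = RegionStats(
            chrom=str(grow["chrom"]), start=lo, end=hi, variant_ids=shared,
            traits={
                "expression": TraitRegion("expression", z1, se1),
                "outcome": TraitRegion("outcome", z2, se2),
            },
        )
        res = coloc_mod.coloc_posteriors(
            region, "expression", "outcome",
            p1=config.coloc_p1, p2=config.coloc_p2, p12=config.coloc_p12,
        )
        coloc_rows.append(
            {"gene_id": g, "pp_h0": res.pp_h0, "pp_h1": res.pp_h1, "pp_h2": res.pp_h2,
             "pp_h3": res.pp_h3, "pp_h4": res.pp_h4,
             "top_shared_variant": res.top_shared_variant,
             "shared": res.pp_h4 > config.coloc_pp_thresh}
        )
    coloc_df = pd.DataFrame(coloc_rows)
    coloc_df.to_csv(os.path.join(config.out_dir, "coloc.tsv"), sep="\t", index=False)
    report["coloc"] = coloc_rows
    _stage_log(report, "coloc", len(causal_genes), len(coloc_rows))
    if last == STAGES.index("coloc"):
        return _finish(report, config)

    # -- enrichment (optional) --------------------------------------------
    if config.gene_sets_path:
        from .netstats import hypergeom_enrichment

        sets_df = pd.read_csv(config.gene_sets_path, sep="\t")
        universe = set(instrument_sets)
        rows = []
        for set_name, members in sets_df.groupby(sets_df.columns[0])[sets_df.columns[1]]:
            target = set(members) & universe
            if not target or not causal_genes:
                continue
            res = hypergeom_enrichment(set(causal_genes), target, universe)
            rows.append({"set": set_name, "k": res.k, "n": res.n, "K": res.K,
                         "N": res.N, "fold": res.fold, "p": res.p})
        pd.DataFrame(rows).to_csv(os.path.join(config.out_dir, "enrichment.tsv"),
                                  sep="\t", index=False)
        _stage_log(report, "enrich", len(sets_df), len(rows))
    return _finish(report, config)


def _bed(loci, path) -> None:
    """Locus boundaries as BED (0-based, half-open); internal coordinates
    stay 1-based closed."""
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start - 1}\t{l.end}\t{l.lead_snp}\n")


def _finish(report: dict, config: PipelineConfig) -> dict:
    report.setdefault("causal_calls", [])
    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
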