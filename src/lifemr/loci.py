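"""Genomic-locus definition from GWAS summary statistics and cis/trans
classification of SNP-gene pairs.

Locus vocabulary follows the FUMA convention: *independent significant*
SNPs are genome-wide significant variants mutually pruned at r^2 < 0.6;
*candidate* SNPs are their r^2 >= 0.6 LD companions; *lead* SNPs are
independent-significant SNPs further pruned at r^2 < 0.1. Loci closer
than 250 kb are merged. Positions are 1-based; windows are closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LDMatrix

__all__ = [
    "Locus",
    "ind_sig_snps",
    "candidate_snps",
    "lead_snps",
    "merge_loci",
    "define_loci",
    "classify_cis_trans",
    "map_eqtl_pairs",
    "bh_adjust",
]


@dataclass
class Locus:
    lead_snp: str
    ind_sig_snps: list[str]
    candidate_snps: list[str]
    chrom: str
    start: int
    end: int
    lead_p: float = np.nan

    def __post_init__(self) -> None:
        if self.lead_snp not in self.ind_sig_snps:
            raise ValueError("lead SNP must be one of the independent significant SNPs")
        if self.start > self.end:
            raise ValueError("locus start exceeds end")


def _sorted_candidates(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Deterministic ordering: ascending (p, chrom, pos, variant_id)."""
    return stats_df.sort_values(
        ["p", "chrom", "pos", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)


def _greedy_prune(ordered_ids: list[str], ld: LDMatrix, r2_thresh: float) -> list[str]:
    kept: list[str] = []
    kept_idx: list[int] = []
    for vid in ordered_ids:
        i = ld.index_of(vid)
        if all(ld.r[i, j] ** 2 < r2_thresh for j in kept_idx):
            kept.append(vid)
            kept_idx.append(i)
    return kept


def ind_sig_snps(
    stats_df: pd.DataFrame,
    ld: LDMatrix,
    p_thresh: float = 5e-8,
    r2_thresh: float = 0.6,
    maf_min: float = 0.01,
) -> list[str]:
    """Independent significant SNPs: p < p_thresh, MAF >= maf_min, greedily
    pruned in ascending p so that kept variants are pairwise r^2 < r2_thresh."""
    df = stats_df.copy()
    df["maf"] = np.minimum(df["eaf"], 1 - df["eaf"])
    df = df[(df["p"] < p_thresh) & (df["maf"] >= maf_min)]
    df = _sorted_candidates(df)
    return _greedy_prune(list(df["variant_id"]), ld, r2_thresh)


def candidate_snps(
    ind_sig: list[str],
    stats_df: pd.DataFrame,
    ld: LDMatrix,
    r2_thresh: float = 0.6,
    maf_min: float = 0.01,
) -> list[str]:
    """All variants (significant or not) with MAF >= maf_min and r^2 >=
    r2_thresh to at least one independent significant SNP. The independent
    significant SNPs themselves are included (r^2 = 1 with self)."""
    if not ind_sig:
        raise ValueError("candidate_snps requires a nonempty independent-significant set")
    sig_idx = [ld.index_of(v) for v in ind_sig]
    out = []
    for row in stats_df.itertuples(index=False):
        maf = min(row.eaf, 1 - row.eaf)
        if maf < maf_min:
            continue
        i = ld.index_of(row.variant_id)
        if any(ld.r[i, j] ** 2 >= r2_thresh for j in sig_idx):
            out.append(row.variant_id)
    return out


def lead_snps(
    ind_sig: list[str],
    stats_df: pd.DataFrame,
    ld: LDMatrix,
    r2_thresh: float = 0.1,
) -> list[str]:
    """Lead SNPs: independent significant SNPs mutually pruned at r^2 < 0.1,
    greedily in ascending p."""
    df = _sorted_candidates(stats_df[stats_df["variant_id"].isin(ind_sig)])
    return _greedy_prune(list(df["variant_id"]), ld, r2_thresh)


def merge_loci(loci: list[Locus], max_gap: int = 250_000) -> list[Locus]:
    """Transitively merge same-chromosome loci separated by < max_gap bp.

    The merged locus's lead is the member lead with the smallest GWAS p.
    Idempotent: merging already-merged loci is a no-op.
    """
    ordered = sorted(loci, key=lambda l: (l.chrom, l.start, l.end, l.lead_snp))
    merged: list[Locus] = []
    for loc in ordered:
        if merged and merged[-1].chrom == loc.chrom and loc.start - merged[-1].end < max_gap:
            prev = merged[-1]
            lead, lead_p = prev.lead_snp, prev.lead_p
            if loc.lead_p < lead_p or (loc.lead_p == lead_p and loc.lead_snp < lead):
                lead, lead_p = loc.lead_snp, loc.lead_p
            merged[-1] = Locus(
                lead_snp=lead,
                ind_sig_snps=prev.ind_sig_snps + [v for v in loc.ind_sig_snps if v not in prev.ind_sig_snps],
                candidate_snps=prev.candidate_snps + [v for v in loc.candidate_snps if v not in prev.candidate_snps],
                chrom=prev.chrom,
                start=min(prev.start, loc.start),
                end=max(prev.end, loc.end),
                lead_p=lead_p,
            )
        else:
            merged.append(loc)
    return merged


def define_loci(
    stats_df: pd.DataFrame,
    ld: LDMatrix,
    p_thresh: float = 5e-8,
    r2_ind: float = 0.6,
    r2_lead: float = 0.1,
    maf_min: float = 0.01,
    max_gap: int = 250_000,
) -> list[Locus]:
    """Full locus definition: independent significant SNPs, candidate
    expansion, lead selection, per-lead grouping, and proximity merging.

    Each independent significant SNP is assigned to the first (smallest-p)
    lead it is in LD with (r^2 >= r2_lead); locus bounds span the member
    independent-significant and candidate SNPs.
    """
    ind = ind_sig_snps(stats_df, ld, p_thresh, r2_ind, maf_min)
    if not ind:
        return []
    leads = lead_snps(ind, stats_df, ld, r2_lead)
    pos = stats_df.set_index("variant_id")
    groups: dict[str, list[str]] = {l: [] for l in leads}
    ordered_ind = _sorted_candidates(stats_df[stats_df["variant_id"].isin(ind)])["variant_id"]
    for vid in ordered_ind:
        i = ld.index_of(vid)
        for lead in leads:
            if ld.r[i, ld.index_of(lead)] ** 2 >= r2_lead or vid == lead:
                groups[lead].append(vid)
                break
    loci = []
    for lead, members in groups.items():
        cands = candidate_snps(members, stats_df, ld, r2_ind, maf_min)
        span = [int(pos.loc[v, "pos"]) for v in set(members) | set(cands)]
        loci.append(
            Locus(
                lead_snp=lead,
                ind_sig_snps=members,
                candidate_snps=cands,
                chrom=str(pos.loc[lead, "chrom"]),
                start=min(span),
                end=max(span),
                lead_p=float(pos.loc[lead, "p"]),
            )
        )
    return merge_loci(loci, max_gap)


# ---------------------------------------------------------------------------
# cis/trans classification and eQTL pair mapping
# ---------------------------------------------------------------------------


def classify_cis_trans(
    variant_chrom: str,
    variant_pos: int,
    gene_chrom: str,
    gene_tss: int,
    cis_window: int = 1_000_000,
    trans_min: int = 5_000_000,
) -> str:
    """Classify a SNP-gene pair as 'cis', 'trans' or 'unclassified'.

    cis: same chromosome and |pos - TSS| <= 1 Mb. trans: different
    chromosome, or same chromosome and distance > 5 Mb. The intermediate
    zone (1-5 Mb) is reported as 'unclassified', never silently assigned.
    """
    if variant_chrom is None or variant_pos is None or gene_chrom is None or gene_tss is None:
        raise ValueError("classification requires chromosome and position/TSS")
    if str(variant_chrom) != str(gene_chrom):
        return "trans"
    d = abs(int(variant_pos) - int(gene_tss))
    if d <= cis_window:
        return "cis"
    if d > trans_min:
        return "trans"
    return "unclassified"


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    return stats.false_discovery_control(np.asarray(p, dtype=float), method="bh")


def map_eqtl_pairs(
    snp_gene_stats: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """FDR-filter SNP-gene association pairs and classify each as cis/trans.

    ``snp_gene_stats`` needs columns (variant_id, gene_id, chrom, pos, p)
    and gains gene coordinates by merging ``genes`` (gene_id, chrom, tss)
    unless columns gene_chrom/tss are already present. BH adjustment runs
    across all supplied pairs; pairs with p_fdr < ``fdr`` are retained.
    """
    if snp_gene_stats.empty:
        raise ValueError("no SNP-gene pairs supplied")
    df = snp_gene_stats.copy()
    if "gene_chrom" not in df.columns or "tss" not in df.columns:
        if genes is None:
            raise ValueError("gene annotation required to classify cis/trans")
        ann = genes.rename(columns={"chrom": "gene_chrom"})[["gene_id", "gene_chrom", "tss"]]
        df = df.merge(ann, on="gene_id", how="left")
    df["p_fdr"] = bh_adjust(df["p"].to_numpy())
    df = df[df["p_fdr"] < fdr].copy()
    df["category"] = [
        classify_cis_trans(r.chrom, r.pos, r.gene_chrom, r.tss) for r in df.itertuples(index=False)
    ]
    return df.reset_index(drop=True)
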