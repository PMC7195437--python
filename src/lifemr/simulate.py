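"""Synthetic summary-statistics generators with recorded ground truth.

Simulation operates at the Z-score level: for a locus with LD matrix R
and standardized joint (causal) effects b, the expected marginal Z-scores
are sqrt(n) * R @ b and the observed vector is multivariate normal with
covariance R. This is exact for the summary-statistics methods under
test, and orders of magnitude faster than genotype-level simulation; it
deliberately carries no population-genetic realism (no MAF-LD coupling,
no selection).

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import block_diag

from .instruments import InstrumentSet
from .ld import LDMatrix
from .sumstats import AlignedPair, TraitMeta, VariantAssoc, two_sided_p, zscore_to_beta_se
from .coloc import RegionStats, TraitRegion

__all__ = [
    "SimTruth",
    "sim_ld",
    "sim_locus",
    "sim_mr_dataset",
    "sim_coloc_region",
    "sim_network",
    "sim_gene_disease",
    "sim_study",
    "write_study",
]

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]


@dataclass
class SimTruth:
    """Ground-truth parameters fully determining a generated dataset."""

    scenario: str
    seed: int | None
    theta_true: float | None = None
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    outlier_ids: list[str] = field(default_factory=list)
    outlier_magnitudes: list[float] = field(default_factory=list)
    causal_variant_index: dict[str, int | None] = field(default_factory=dict)
    ld_rho: float | None = None
    n_exposure: int | None = None
    n_outcome: int | None = None
    extra: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def sim_ld(M: int, rho: float) -> LDMatrix:
    """AR(1) LD matrix: r_ij = rho^|i-j| (positive definite for |rho|<1)."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    idx = np.arange(M)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    return LDMatrix([f"v{i+1}" for i in range(M)], r, check=False)


def sim_locus(
    ld: LDMatrix,
    n: int,
    joint_effects,
    eaf_range: tuple[float, float] = (0.05, 0.95),
    seed: int | None = None,
    chrom: str = "1",
    pos_start: int = 1_000_000,
    spacing: int = 1000,
    rng: np.random.Generator | None = None,
    eaf: np.ndarray | None = None,
) -> tuple[list[VariantAssoc], SimTruth]:
    """Simulate one locus's marginal summary statistics under LD.

    Expected marginal Z = sqrt(n) * R @ b for standardized joint effects
    b; observed Z ~ MVN(expected, R). EAFs are uniform in ``eaf_range``
    (or supplied); beta/SE derive from the Z/EAF/n conversion.
    """
    b = np.asarray(joint_effects, dtype=float)
    m = len(ld)
    if b.shape != (m,):
        raise ValueError("joint_effects must align with the LD matrix")
    rng = np.random.default_rng(seed) if rng is None else rng
    mu = np.sqrt(n) * ld.r @ b
    chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(m))
    z = mu + chol @ rng.standard_normal(m)
    if eaf is None:
        eaf = rng.uniform(*eaf_range, size=m)
    beta, se = zscore_to_beta_se(z, eaf, np.full(m, n))
    p = two_sided_p(z)
    alleles = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(m)]
    records = [
        VariantAssoc(
            variant_id=ld.variant_ids[i],
            chrom=chrom,
            pos=pos_start + i * spacing,
            effect_allele=alleles[i][0],
            other_allele=alleles[i][1],
            eaf=float(eaf[i]),
            beta=float(beta[i]),
            se=float(se[i]),
            z=float(z[i]),
            p=float(p[i]),
            n=int(n),
        )
        for i in range(m)
    ]
    causal = {int(i) for i in np.flatnonzero(b)}
    truth = SimTruth(
        scenario="locus",
        seed=seed,
        causal_variant_index={"trait": int(np.argmax(np.abs(b))) if causal else None},
        n_exposure=n,
        extra={"causal_indices": sorted(causal)},
    )
    return records, truth


def sim_mr_dataset(
    J: int,
    theta: float,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
    outlier_spec: list[tuple[int, float]] | None = None,
    bx_range: tuple[float, float] = (0.05, 0.2),
    sex_range: tuple[float, float] = (0.005, 0.015),
    sey_range: tuple[float, float] = (0.003, 0.01),
    sign_mix: bool = False,
    seed: int | None = None,
    gene_id: str = "SIMGENE",
) -> tuple[InstrumentSet, SimTruth]:
    """Simulate a harmonized two-sample MR instrument set with known truth.

    True exposure effects |bX| are uniform in ``bx_range`` (bounded away
    from zero), positive unless ``sign_mix``. Observed effects add
    N(0, se^2) noise; outcome effects are theta*bX + alpha_j + noise with
    per-instrument pleiotropy alpha_j ~ N(pleiotropy_mean,
    pleiotropy_sd^2). ``outlier_spec`` plants gross pleiotropy: a list of
    (instrument index, multiple) adding ``multiple * se_outcome_j`` to
    that instrument's outcome effect (signed multiples allowed).
    """
    if J < 3:
        raise ValueError("J must be >= 3")
    rng = np.random.default_rng(seed)
    bx_true = rng.uniform(*bx_range, size=J)
    if sign_mix:
        bx_true *= rng.choice([-1.0, 1.0], size=J)
    sx = rng.uniform(*sex_range, size=J)
    sy = rng.uniform(*sey_range, size=J)
    alpha = rng.normal(pleiotropy_mean, pleiotropy_sd, size=J) if pleiotropy_sd or pleiotropy_mean else np.zeros(J)
    outlier_ids, outlier_mags = [], []
    if outlier_spec:
        for idx, mult in outlier_spec:
            if not 0 <= idx < J:
                raise ValueError(f"outlier index {idx} outside 0..{J-1}")
            alpha[idx] += mult * sy[idx]
            outlier_ids.append(f"iv{idx+1}")
            outlier_mags.append(float(mult * sy[idx]))
    bx_obs = bx_true + sx * rng.standard_normal(J)
    by_obs = theta * bx_true + alpha + sy * rng.standard_normal(J)
    p_exp = two_sided_p(bx_obs / sx)
    pairs = [
        AlignedPair(
            variant_id=f"iv{j+1}",
            exposure_beta=float(bx_obs[j]),
            exposure_se=float(sx[j]),
            outcome_beta=float(by_obs[j]),
            outcome_se=float(sy[j]),
            exposure_p=float(p_exp[j]),
            outcome_p=float(two_sided_p(by_obs[j] / sy[j])),
        )
        for j in range(J)
    ]
    iset = InstrumentSet(gene_id, pairs, p_thresh=1.0, r2_thresh=1.0)
    truth = SimTruth(
        scenario="mr_dataset",
        seed=seed,
        theta_true=theta,
        pleiotropy_mean=pleiotropy_mean,
        pleiotropy_sd=pleiotropy_sd,
        outlier_ids=outlier_ids,
        outlier_magnitudes=outlier_mags,
        extra={"bx_true": bx_true.tolist()},
    )
    return iset, truth


def sim_coloc_region(
    M: int,
    scenario: str,
    z_target: float = 8.0,
    rho: float = 0.9,
    n1: int = 30_000,
    n2: int = 30_000,
    seed: int | None = None,
) -> tuple[RegionStats, SimTruth]:
    """Simulate a two-trait region under a colocalization scenario.

    Scenarios: ``null`` (no causal variant), ``shared`` (one variant
    causal for both traits), ``distinct`` (two causal variants in
    negligible LD, r^2 < 0.01), ``one_trait`` (causal for trait 1 only).
    The causal joint effect is scaled so the expected marginal Z at the
    causal variant is ``z_target``.
    """
    if scenario not in ("null", "shared", "distinct", "one_trait"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "distinct" and M < 2:
        raise ValueError("distinct scenario needs at least 2 variants")
    ld = sim_ld(M, rho)
    rng = np.random.default_rng(seed)
    c1 = c2 = None
    if scenario in ("shared", "one_trait"):
        c1 = M // 2
        c2 = M // 2 if scenario == "shared" else None
    elif scenario == "distinct":
        c1, c2 = M // 4, (3 * M) // 4
        if ld.r[c1, c2] ** 2 >= 0.01:
            raise ValueError("distinct causal variants are in LD; increase M or lower rho")
    b1 = np.zeros(M)
    b2 = np.zeros(M)
    if c1 is not None:
        b1[c1] = z_target / np.sqrt(n1)
    if c2 is not None:
        b2[c2] = z_target / np.sqrt(n2)
    eaf = rng.uniform(0.1, 0.9, size=M)
    rec1, _ = sim_locus(ld, n1, b1, rng=rng, eaf=eaf)
    rec2, _ = sim_locus(ld, n2, b2, rng=rng, eaf=eaf)
    region = RegionStats(
        chrom="1",
        start=rec1[0].pos,
        end=rec1[-1].pos,
        variant_ids=list(ld.variant_ids),
        traits={
            "trait1": TraitRegion("trait1", np.array([r.z for r in rec1]),
                                  np.array([r.se for r in rec1]),
                                  TraitMeta("trait1", "quantitative", n1)),
            "trait2": TraitRegion("trait2", np.array([r.z for r in rec2]),
                                  np.array([r.se for r in rec2]),
                                  TraitMeta("trait2", "quantitative", n2)),
        },
    )
    truth = SimTruth(
        scenario=scenario,
        seed=seed,
        causal_variant_index={"trait1": c1, "trait2": c2},
        ld_rho=rho,
        n_exposure=n1,
        n_outcome=n2,
        extra={"z_target": z_target},
    )
    return region, truth


def sim_network(
    n_nodes: int,
    n_edges: int,
    model: str = "preferential",
    seed: int | None = None,
) -> nx.Graph:
    """Simple random graph with exactly ``n_edges`` edges.

    ``preferential``: a degree-weighted attachment tree plus degree-
    weighted extra edges (hubby, like co-expression networks);
    ``random``: uniform G(n, m).
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError("too many edges for a simple graph")
    if model == "random":
        return nx.gnm_random_graph(n_nodes, n_edges, seed=seed)
    if model != "preferential":
        raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    # degree-proportional sampling via a repeated-endpoint pool (O(E));
    # each node enters the pool once on arrival so isolated nodes can attach
    pool: list[int] = [0]
    m = 0
    for v in range(1, n_nodes):
        if m >= n_edges:
            break
        u = pool[rng.integers(len(pool))]
        g.add_edge(u, v)
        m += 1
        pool.extend((u, v, v))
    while m < n_edges:
        u = pool[rng.integers(len(pool))]
        v = pool[rng.integers(len(pool))]
        if u != v and not g.has_edge(u, v):
            g.add_edge(u, v)
            m += 1
            pool.extend((u, v))
    return g


def sim_gene_disease(
    genes: list[str],
    diseases: list[str],
    density: float,
    seed: int | None = None,
) -> pd.DataFrame:
    """Gene-disease membership pairs by independent Bernoulli(density)."""
    if not 0 <= density <= 1:
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    hits = rng.random((len(genes), len(diseases))) < density
    rows = [
        {"gene": g, "disease": d}
        for i, g in enumerate(genes)
        for j, d in enumerate(diseases)
        if hits[i, j]
    ]
    return pd.DataFrame(rows, columns=["gene", "disease"])


# ---------------------------------------------------------------------------
# Whole synthetic study (drives the end-to-end pipeline)
# ---------------------------------------------------------------------------


@dataclass
class StudyData:
    """A complete synthetic study: eQTL + GWAS summary statistics, LD,
    gene annotation, and the generating truth."""

    gwas: pd.DataFrame
    eqtl: pd.DataFrame
    ld: LDMatrix
    genes: pd.DataFrame
    truth: SimTruth
    gwas_meta: TraitMeta
    eqtl_meta: TraitMeta


def sim_study(
    seed: int | None = None,
    n_genes: int = 50,
    n_causal: int = 5,
    eqtl_per_gene: int = 8,
    block_size: int = 6,
    rho: float = 0.8,
    n_exposure: int = 31_684,
    n_outcome: int = 1_000_000,
    theta_magnitude: float = 0.03,
    eqtl_z: float = 40.0,
    hetero_outlier_z: float = 5.0,
    flip_fraction: float = 0.2,
) -> StudyData:
    """Simulate a gene-expression -> lifespan study with known truth.

    ``n_genes`` genes sit on one chromosome, TSSs 3 Mb apart (loci never
    merge). Each gene's locus holds ``eqtl_per_gene`` independent LD
    blocks of ``block_size`` variants (AR(1) rho within a block, zero
    between blocks) with one causal eQTL variant per block of expected
    |Z| = ``eqtl_z`` — so the standard instrument filter (p < 1e-3,
    r^2 < 0.1) deterministically selects the causal variants as mutually
    independent instruments. The first ``n_causal`` genes causally
    affect the outcome with slope +/- ``theta_magnitude`` (alternating
    signs); the first causal gene is additionally *heterogeneous but
    rescuable*: two of its instruments carry opposite-sign pleiotropy of
    ``hetero_outlier_z`` outcome-Z units, inflating heterogeneity while
    leaving the pooled slope unbiased. A ``flip_fraction`` of GWAS
    records have swapped alleles (sign-flipped effects) to exercise
    harmonization.
    """
    rng = np.random.default_rng(seed)
    m = eqtl_per_gene * block_size
    causal_offset = block_size // 2 - 1 if block_size >= 4 else 0
    causal_idx = [b * block_size + causal_offset for b in range(eqtl_per_gene)]
    gene_rows = []
    eqtl_frames = []
    gwas_records: list[VariantAssoc] = []
    blocks = []
    all_ids: list[str] = []
    truth_genes = {}
    thetas = {}
    one_block = sim_ld(block_size, rho)
    ld_block = LDMatrix(
        [f"v{i+1}" for i in range(m)],
        block_diag(*([one_block.r] * eqtl_per_gene)),
        check=False,
    )

    for g in range(n_genes):
        gene_id = f"GENE{g+1:03d}"
        tss = 2_000_000 + g * 3_000_000
        gene_rows.append({"gene_id": gene_id, "symbol": gene_id, "chrom": "1",
                          "tss": tss, "strand": "+"})
        ids = [f"rs{g+1:03d}_{i+1:02d}" for i in range(m)]
        ld_g = LDMatrix(ids, ld_block.r, check=False)
        all_ids.extend(ids)
        blocks.append(ld_block.r)

        theta_g = 0.0
        if g < n_causal:
            theta_g = theta_magnitude * (1.0 if g % 2 == 0 else -1.0)
        thetas[gene_id] = theta_g

        b_exp = np.zeros(m)
        b_exp[causal_idx] = eqtl_z / np.sqrt(n_exposure)
        b_out = theta_g * b_exp
        outlier_ids = []
        if g == 0 and n_causal > 0:
            # plant opposite-sign pleiotropy on two causal instruments
            for k, s in ((1, 1.0), (3, -1.0)):
                b_out[causal_idx[k]] += s * hetero_outlier_z / np.sqrt(n_outcome)
                outlier_ids.append(ids[causal_idx[k]])

        eaf = rng.uniform(0.1, 0.9, size=m)
        pos0 = tss - (m // 2) * 1000
        exp_rec, _ = sim_locus(ld_g, n_exposure, b_exp, rng=rng, eaf=eaf,
                               chrom="1", pos_start=pos0)
        out_rec, _ = sim_locus(ld_g, n_outcome, b_out, rng=rng, eaf=eaf,
                               chrom="1", pos_start=pos0)
        eqtl_frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_id,
                    "variant_id": ids,
                    "chrom": "1",
                    "pos": [r.pos for r in exp_rec],
                    "effect_allele": [r.effect_allele for r in exp_rec],
                    "other_allele": [r.other_allele for r in exp_rec],
                    "eaf": [r.eaf for r in exp_rec],
                    "z": [r.z for r in exp_rec],
                    "p": [r.p for r in exp_rec],
                    "n": n_exposure,
                }
            )
        )
        for r in out_rec:
            if rng.random() < flip_fraction:
                r.effect_allele, r.other_allele = r.other_allele, r.effect_allele
                r.eaf = 1.0 - r.eaf
                r.beta, r.z = -r.beta, -r.z
            gwas_records.append(r)
        truth_genes[gene_id] = {
            "theta": theta_g,
            "causal_variants": [ids[i] for i in causal_idx],
            "outlier_variants": outlier_ids,
        }

    gwas = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in gwas_records],
            "chrom": [r.chrom for r in gwas_records],
            "pos": [r.pos for r in gwas_records],
            "effect_allele": [r.effect_allele for r in gwas_records],
            "other_allele": [r.other_allele for r in gwas_records],
            "eaf": [r.eaf for r in gwas_records],
            "beta": [r.beta for r in gwas_records],
            "se": [r.se for r in gwas_records],
            "p": [r.p for r in gwas_records],
            "n": n_outcome,
        }
    )
    ld = LDMatrix(all_ids, block_diag(*blocks), check=False)
    truth = SimTruth(
        scenario="study",
        seed=seed,
        theta_true=theta_magnitude,
        ld_rho=rho,
        n_exposure=n_exposure,
        n_outcome=n_outcome,
        extra={
            "genes": truth_genes,
            "causal_genes": {g: t for g, t in thetas.items() if t != 0.0},
            "hetero_gene": "GENE001" if n_causal > 0 else None,
        },
    )
    return StudyData(
        gwas=gwas,
        eqtl=pd.concat(eqtl_frames, ignore_index=True),
        ld=ld,
        genes=pd.DataFrame(gene_rows),
        truth=truth,
        gwas_meta=TraitMeta("lifespan", "quantitative", n_outcome),
        eqtl_meta=TraitMeta("expression", "quantitative", n_exposure),
    )


def write_study(study: StudyData, outdir) -> dict[str, str]:
    """Write a StudyData bundle as tab-delimited files + a JSON truth file.

    Returns the mapping of logical names to paths (gwas, eqtl, ld, genes,
    truth).
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "gwas": os.path.join(outdir, "gwas.tsv"),
        "eqtl": os.path.join(outdir, "eqtl.tsv"),
        "ld": os.path.join(outdir, "ld.tsv"),
        "genes": os.path.join(outdir, "genes.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    study.gwas.to_csv(paths["gwas"], sep="\t", index=False)
    study.eqtl.to_csv(paths["eqtl"], sep="\t", index=False)
    study.ld.to_tsv(paths["ld"])
    study.genes.to_csv(paths["genes"], sep="\t", index=False)
    study.truth.to_json(paths["truth"])
    return paths
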