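"""Selection of independent cis instruments per gene and assembly of
harmonized exposure/outcome sets for two-sample MR.

Instruments are eQTL variants within a closed 500 kb window either side
of the gene's TSS, strongly associated with expression (p < 1e-3,
approximately F > 10 for a single instrument) and mutually independent
(r^2 < 0.1, greedy pruning in ascending p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld import LDMatrix
from .sumstats import AlignedPair, Exclusion, VariantAssoc, harmonize

__all__ = ["InstrumentSet", "select_instruments", "f_approx", "require_min_instruments"]


@dataclass
class InstrumentSet:
    """Harmonized exposure/outcome effect pairs for one gene, ready for MR."""

    gene_id: str
    pairs: list[AlignedPair]
    window_bp: int = 500_000
    p_thresh: float = 1e-3
    r2_thresh: float = 0.1
    exclusions: list[Exclusion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError(f"instrument set for {self.gene_id} is empty")
        for pair in self.pairs:
            if pair.exposure_p is not None and pair.exposure_p >= self.p_thresh:
                raise ValueError(
                    f"{self.gene_id}: instrument {pair.variant_id} exposure p "
                    f"{pair.exposure_p:.3g} >= {self.p_thresh}"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def variant_ids(self) -> list[str]:
        return [p.variant_id for p in self.pairs]

    def arrays(self):
        """(beta_exposure, se_exposure, beta_outcome, se_outcome) arrays."""
        bx = np.array([p.exposure_beta for p in self.pairs])
        sx = np.array([p.exposure_se for p in self.pairs])
        by = np.array([p.outcome_beta for p in self.pairs])
        sy = np.array([p.outcome_se for p in self.pairs])
        return bx, sx, by, sy

    def subset(self, keep_ids) -> "InstrumentSet":
        keep = set(keep_ids)
        return InstrumentSet(
            self.gene_id,
            [p for p in self.pairs if p.variant_id in keep],
            self.window_bp,
            self.p_thresh,
            self.r2_thresh,
        )

    def check_independence(self, ld: LDMatrix) -> None:
        ids = self.variant_ids
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if ld.r2(a, b) >= self.r2_thresh:
                    raise ValueError(
                        f"{self.gene_id}: instruments {a},{b} r2 {ld.r2(a, b):.3f} "
                        f">= {self.r2_thresh}"
                    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": self.gene_id,
                    "variant_id": p.variant_id,
                    "beta_exposure": p.exposure_beta,
                    "se_exposure": p.exposure_se,
                    "p_exposure": p.exposure_p,
                    "beta_outcome": p.outcome_beta,
                    "se_outcome": p.outcome_se,
                    "p_outcome": p.outcome_p,
                    "flipped": p.flipped,
                    "f_approx": f_approx(p.exposure_beta / p.exposure_se),
                }
                for p in self.pairs
            ]
        )


def f_approx(z) -> float:
    """Approximate single-instrument F statistic, F ~= Z^2 (large n).

    Z ~= 3.29 (two-sided p ~= 0.001) corresponds to F ~= 10.8, i.e. the
    conventional weak-instrument bar F > 10.
    """
    return np.square(z)


def require_min_instruments(iset: InstrumentSet, k: int = 3) -> bool:
    """True when the set holds at least ``k`` instruments (MR feasibility)."""
    return len(iset.pairs) >= k


def select_instruments(
    gene,
    eqtl_stats: list[VariantAssoc],
    ld: LDMatrix,
    outcome_stats: dict[str, VariantAssoc] | None = None,
    window: int = 500_000,
    p_thresh: float = 1e-3,
    r2_thresh: float = 0.1,
    palindromic_policy: str = "strict",
) -> InstrumentSet:
    """Select independent cis instruments for one gene and harmonize them.

    ``gene`` is a mapping with gene_id, chrom and tss. ``eqtl_stats`` are
    that gene's expression associations. Variants within TSS +/- window
    (closed interval) with exposure p < p_thresh are greedily pruned at
    r^2 < r2_thresh in ascending p; survivors are harmonized against
    ``outcome_stats`` (variant_id -> record); harmonization exclusions
    and out-of-outcome variants are recorded with reasons.
    """
    gene_id = gene["gene_id"]
    tss = int(gene["tss"])
    chrom = str(gene["chrom"])
    in_window = [
        r
        for r in eqtl_stats
        if r.chrom is not None and str(r.chrom) == chrom and r.pos is not None
        and abs(r.pos - tss) <= window
    ]
    if not in_window:
        raise ValueError(f"no eQTL variant within {window} bp of {gene_id} TSS")
    eligible = [r for r in in_window if r.p is not None and r.p < p_thresh]
    eligible.sort(key=lambda r: (r.p, r.chrom, r.pos, r.variant_id))

    kept: list[VariantAssoc] = []
    exclusions: list[Exclusion] = []
    for rec in eligible:
        if any(ld.r2(rec.variant_id, k.variant_id) >= r2_thresh for k in kept):
            exclusions.append(Exclusion(rec.variant_id, "ld_pruned"))
            continue
        kept.append(rec)
    if not kept:
        raise ValueError(f"no instrument for {gene_id} passes p < {p_thresh} in window")

    pairs: list[AlignedPair] = []
    for rec in kept:
        if outcome_stats is None:
            # exposure-only assembly: mirror the exposure as a null outcome
            raise ValueError("outcome_stats required to assemble harmonized pairs")
        out = outcome_stats.get(rec.variant_id)
        if out is None:
            exclusions.append(Exclusion(rec.variant_id, "absent_from_outcome"))
            continue
        aligned = harmonize(rec, out, palindromic_policy)
        if isinstance(aligned, Exclusion):
            exclusions.append(aligned)
            continue
        pairs.append(aligned)
    if not pairs:
        raise ValueError(f"no harmonizable instrument for {gene_id}")
    iset = InstrumentSet(gene_id, pairs, window, p_thresh, r2_thresh, exclusions)
    iset.check_independence(ld)
    return iset
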