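"""Per-variant summary statistics: data model, I/O, unit conversions,
harmonization and Gaussian Z-score imputation.

Effect sizes for the lifespan trait are on the -log_e(Cox hazard ratio)
scale, i.e. the log protection ratio: positive effects mean longer life.
Expression effects are in standard deviations of expression per effect
allele. Positions are 1-based and all windows are closed intervals.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LDMatrix

__all__ = [
    "VariantAssoc",
    "TraitMeta",
    "AlignedPair",
    "Exclusion",
    "SumstatsReadResult",
    "read_sumstats",
    "zscore_to_beta_se",
    "beta_to_years",
    "two_sided_p",
    "harmonize",
    "impute_zscores",
    "assoc_frame",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def two_sided_p(z):
    """Two-sided standard-normal tail probability of a Z-score."""
    p = 2.0 * stats.norm.sf(np.abs(z))
    # keep p in (0, 1] even for extreme Z
    return np.maximum(p, np.finfo(float).tiny)


@dataclass
class TraitMeta:
    """Descriptive metadata for one trait's summary statistics."""

    trait_name: str
    trait_type: str = "quantitative"  # "quantitative" | "binary"
    n: int | None = None
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            if self.case_fraction is None or not 0 < self.case_fraction < 1:
                raise ValueError("binary traits require case_fraction in (0, 1)")
        elif self.case_fraction is not None:
            raise ValueError("case_fraction only applies to binary traits")


@dataclass
class VariantAssoc:
    """One variant's association record for one trait."""

    variant_id: str
    effect_allele: str
    other_allele: str
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    beta: float | None = None
    se: float | None = None
    z: float | None = None
    p: float | None = None
    n: int | None = None

    def validate(self) -> None:
        """Raise ValueError (message = reason code) on any invariant breach."""
        if not self.effect_allele or not self.other_allele:
            raise ValueError("empty_allele")
        if self.effect_allele == self.other_allele:
            raise ValueError("identical_alleles")
        if self.effect_allele != self.effect_allele.upper() or self.other_allele != self.other_allele.upper():
            raise ValueError("lowercase_allele")
        if self.eaf is not None and not 0 < self.eaf < 1:
            raise ValueError("eaf_out_of_range")
        if self.beta is not None and (self.se is None or self.se <= 0):
            raise ValueError("nonpositive_se")
        if self.se is not None and self.se <= 0:
            raise ValueError("nonpositive_se")
        if self.z is not None and self.beta is not None and self.se is not None:
            if abs(self.z - self.beta / self.se) > 1e-6 * max(1.0, abs(self.z)):
                raise ValueError("z_beta_se_inconsistent")
        if self.p is not None:
            if not 0 < self.p <= 1:
                raise ValueError("p_out_of_range")
            if self.z is not None:
                pz = float(two_sided_p(self.z))
                if abs(self.p - pz) > 1e-6 * max(pz, 1e-300):
                    raise ValueError("p_z_inconsistent")
        if self.n is not None and self.n <= 0:
            raise ValueError("nonpositive_n")

    @property
    def maf(self) -> float | None:
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    def is_palindromic(self) -> bool:
        return _COMPLEMENT.get(self.effect_allele) == self.other_allele


@dataclass
class AlignedPair:
    """Harmonized exposure/outcome effects for one variant.

    The outcome effect is expressed per copy of the exposure's effect
    allele; ``flipped`` records that the outcome record's alleles had to
    be swapped (and its effect negated) to achieve this.
    """

    variant_id: str
    exposure_beta: float
    exposure_se: float
    outcome_beta: float
    outcome_se: float
    flipped: bool = False
    exposure_p: float | None = None
    outcome_p: float | None = None

    def __post_init__(self) -> None:
        if self.exposure_se <= 0 or self.outcome_se <= 0:
            raise ValueError("aligned pair requires positive standard errors")


@dataclass
class Exclusion:
    """A record dropped from an operation, with the reason."""

    variant_id: str
    reason: str


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------


def zscore_to_beta_se(z, eaf, n):
    """Recover (beta, se) from a Z-score, allele frequency and sample size.

    se = 1 / sqrt(2 * eaf * (1 - eaf) * (n + z^2)) and beta = z * se,
    placing beta on the standardized (SD of trait) per-allele scale.
    """
    z = np.asarray(z, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise ValueError("eaf must lie strictly in (0, 1)")
    if np.any(n < 1):
        raise ValueError("sample size must be >= 1")
    se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * (n + z**2))
    beta = z * se
    if beta.ndim == 0:
        return float(beta), float(se)
    return beta, se


def beta_to_years(beta):
    """Convert a log protection-ratio effect to years of life.

    years = log_e(protection ratio) * 10; the protection ratio is the
    reciprocal of the Cox hazard ratio, so positive effects gain years.
    """
    return np.multiply(beta, 10.0)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


@dataclass
class SumstatsReadResult:
    records: list[VariantAssoc]
    skipped: Counter
    n_rows: int

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


_FIELDS = ("variant_id", "chrom", "pos", "effect_allele", "other_allele",
           "eaf", "beta", "se", "z", "p", "n")


def read_sumstats(path, column_map: dict, trait_meta: TraitMeta | None = None) -> SumstatsReadResult:
    """Read tab-delimited summary statistics into VariantAssoc records.

    ``column_map`` maps VariantAssoc field names to source column names.
    At minimum (variant_id, effect_allele, other_allele) plus either
    (beta, se) or (z, eaf, n) must be mapped. Rows violating record
    invariants are dropped and counted by reason; Z and p are back-filled
    from beta/se where absent; input order is preserved.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in column_map.values() if c not in df.columns]
    if missing:
        raise KeyError(f"column_map references absent columns: {missing}")
    if "variant_id" not in column_map or "effect_allele" not in column_map or "other_allele" not in column_map:
        raise KeyError("column_map must name variant_id, effect_allele and other_allele")
    has_beta = "beta" in column_map and "se" in column_map
    has_z = all(f in column_map for f in ("z", "eaf", "n"))
    if not (has_beta or has_z):
        raise KeyError("column_map must provide (beta, se) or (z, eaf, n)")

    records: list[VariantAssoc] = []
    skipped: Counter = Counter()
    meta_n = trait_meta.n if trait_meta is not None else None
    for row in df.itertuples(index=False):
        raw = {f: getattr(row, column_map[f]) for f in _FIELDS if f in column_map}
        kw = {}
        bad = None
        for f, v in raw.items():
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            if f in ("eaf", "beta", "se", "z", "p"):
                try:
                    v = float(v)
                except (TypeError, ValueError):
                    bad = f"unparseable_{f}"
                    break
            elif f in ("pos", "n"):
                try:
                    v = int(v)
                except (TypeError, ValueError):
                    bad = f"unparseable_{f}"
                    break
            else:
                v = str(v)
            kw[f] = v
        if bad:
            skipped[bad] += 1
            continue
        for f in ("variant_id", "effect_allele", "other_allele"):
            if f not in kw:
                bad = f"missing_{f}"
        if bad:
            skipped[bad] += 1
            continue
        if "n" not in kw and meta_n is not None:
            kw["n"] = meta_n
        rec = VariantAssoc(**kw)
        # back-fill z and p from beta/se; recompute p from z when inconsistent
        if rec.z is None and rec.beta is not None and rec.se is not None and rec.se > 0:
            rec.z = rec.beta / rec.se
        if rec.z is not None:
            pz = float(two_sided_p(rec.z))
            if rec.p is None or abs(rec.p - pz) > 1e-6 * max(pz, 1e-300):
                if rec.p is not None:
                    skipped["p_recomputed_from_z"] += 1
                rec.p = pz
        try:
            rec.validate()
        except ValueError as err:
            skipped[str(err)] += 1
            continue
        if rec.beta is None and rec.se is None and rec.z is None:
            skipped["no_effect_information"] += 1
            continue
        records.append(rec)
    if not records:
        raise ValueError(f"no parseable summary-statistics rows in {path}")
    return SumstatsReadResult(records, skipped, len(df))


def assoc_frame(records) -> pd.DataFrame:
    """Tabulate VariantAssoc records as a DataFrame (input order kept)."""
    return pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "z": r.z,
                "p": r.p,
                "n": r.n,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


def harmonize(
    exposure: VariantAssoc,
    outcome: VariantAssoc,
    palindromic_policy: str = "strict",
) -> AlignedPair | Exclusion:
    """Align an outcome record to the exposure's effect allele.

    Matching allele sets are kept as-is; swapped sets flip the outcome
    effect's sign (and complement its frequency). Palindromic variants
    (A/T, C/G) follow ``palindromic_policy``:

    - ``"strict"`` (default): keep only if both EAFs are on the same side
      of 0.5 and both outside [0.4, 0.6]; otherwise exclude;
    - ``"drop"``: always exclude;
    - ``"keep"``: treat like any other variant.
    """
    if exposure.variant_id != outcome.variant_id:
        raise ValueError("harmonize requires matching variant_id")
    if palindromic_policy not in ("strict", "drop", "keep"):
        raise ValueError(f"unknown palindromic policy {palindromic_policy!r}")
    vid = exposure.variant_id
    if exposure.beta is None or exposure.se is None or outcome.beta is None or outcome.se is None:
        return Exclusion(vid, "missing_effect")

    if exposure.is_palindromic() and palindromic_policy != "keep":
        if palindromic_policy == "drop":
            return Exclusion(vid, "palindromic")
        e, o = exposure.eaf, outcome.eaf
        ambiguous = (
            e is None
            or o is None
            or 0.4 <= e <= 0.6
            or 0.4 <= o <= 0.6
            or (e - 0.5) * (o - 0.5) <= 0
        )
        if ambiguous:
            return Exclusion(vid, "palindromic_ambiguous")

    if (exposure.effect_allele, exposure.other_allele) == (outcome.effect_allele, outcome.other_allele):
        return AlignedPair(vid, exposure.beta, exposure.se, outcome.beta, outcome.se,
                           flipped=False, exposure_p=exposure.p, outcome_p=outcome.p)
    if (exposure.effect_allele, exposure.other_allele) == (outcome.other_allele, outcome.effect_allele):
        return AlignedPair(vid, exposure.beta, exposure.se, -outcome.beta, outcome.se,
                           flipped=True, exposure_p=exposure.p, outcome_p=outcome.p)
    return Exclusion(vid, "allele_mismatch")


# ---------------------------------------------------------------------------
# Gaussian imputation of Z-scores
# ---------------------------------------------------------------------------


def impute_zscores(
    observed,
    ld: LDMatrix,
    targets: list[str],
    lam: float = 0.1,
) -> pd.DataFrame:
    """Conditional-mean Gaussian imputation of unobserved Z-scores.

    Under the multivariate-normal model of GWAS Z-scores with correlation
    equal to LD, the conditional mean of a target given the observed block
    is ``S_tu (S_uu + lam I)^-1 z_u``; the reported per-target imputation
    quality is ``r2 = S_tu (S_uu + lam I)^-1 S_ut``. The ridge ``lam``
    (default 0.1) stabilizes the observed-block inverse.

    Returns a DataFrame (variant_id, z, r2) over ``targets``.
    """
    obs = list(observed)
    obs_ids = [r.variant_id for r in obs]
    z_obs = np.array([r.z for r in obs], dtype=float)
    if np.any(np.isnan(z_obs)):
        raise ValueError("observed records must carry Z-scores")
    overlap = set(obs_ids) & set(targets)
    if overlap:
        raise ValueError(f"targets overlap observed variants: {sorted(overlap)[:5]}")
    oi = [ld.index_of(v) for v in obs_ids]
    ti = [ld.index_of(v) for v in targets]
    S_uu = ld.r[np.ix_(oi, oi)] + lam * np.eye(len(oi))
    S_tu = ld.r[np.ix_(ti, oi)]
    try:
        w = np.linalg.solve(S_uu, S_tu.T)  # (n_obs, n_targets)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"observed LD block is singular (lam={lam}): {err}") from None
    z_imp = w.T @ z_obs
    r2 = np.einsum("ij,ji->i", S_tu, w)
    return pd.DataFrame({"variant_id": list(targets), "z": z_imp, "r2": r2})
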