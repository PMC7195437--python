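"""Two-sample Mendelian randomization estimators and sensitivity tests.

Implements the Wald ratio, inverse-variance-weighted (IVW) meta-analysis
of Wald ratios (equivalently, weighted regression of outcome on exposure
effects through the origin), Cochran's Q heterogeneity test, MR-Egger
regression with the intercept test for directional pleiotropy, multiple
testing control, and the causal-call decision logic combining IVW
significance, heterogeneity gating, and MR-PRESSO rescue.

The default model is multiplicative random effects: standard errors are
inflated by max(1, sqrt(Q/df)), never deflated. Estimate p-values use the
standard-normal reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import InstrumentSet
from .loci import bh_adjust
from .sumstats import AlignedPair

__all__ = [
    "MRResult",
    "wald_ratio",
    "ivw",
    "cochran_q",
    "egger",
    "bonferroni_threshold",
    "adjust_pvalues",
    "classify_causal",
]

_Z975 = stats.norm.ppf(0.975)


@dataclass
class MRResult:
    gene_id: str
    method: str  # "IVW" | "Egger" | "Wald"
    theta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_iv: int
    model: str | None = None  # "fixed" | "random"
    Q: float | None = None
    Q_df: int | None = None
    Q_p: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None

    def __post_init__(self) -> None:
        if not self.ci_low < self.ci_high:
            raise ValueError("confidence interval is degenerate")
        if self.Q is not None and self.Q < -1e-12:
            raise ValueError("negative Q")


def _norm_p(z: float) -> float:
    return float(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny))


def wald_ratio(pair: AlignedPair) -> tuple[float, float]:
    """Single-instrument causal estimate and first-order delta-method SE.

    theta = beta_outcome / beta_exposure; se = se_outcome / |beta_exposure|
    (exposure uncertainty ignored, matching the IVW weighting).
    """
    if pair.exposure_beta == 0:
        raise ZeroDivisionError("Wald ratio undefined for zero exposure effect")
    theta = pair.outcome_beta / pair.exposure_beta
    se = pair.outcome_se / abs(pair.exposure_beta)
    return theta, se


def _ivw_arrays(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float]:
    """Fixed-effect IVW point estimate and SE from raw arrays."""
    w = sy**-2.0
    denom = float(np.sum(w * bx**2))
    if denom <= 0:
        raise ValueError("degenerate instrument set: zero exposure information")
    theta = float(np.sum(w * bx * by)) / denom
    se = denom**-0.5
    return theta, se


def cochran_q(iset: InstrumentSet, theta: float) -> tuple[float, int, float]:
    """Cochran's Q about a causal estimate: Q = sum w_j (by_j - theta*bx_j)^2
    with w_j = se_outcome_j^-2; df = n_iv - 1; chi-square upper-tail p."""
    bx, _, by, sy = iset.arrays()
    if len(bx) < 2:
        raise ValueError("Cochran's Q requires at least 2 instruments")
    q = float(np.sum(sy**-2.0 * (by - theta * bx) ** 2))
    df = len(bx) - 1
    p = float(max(stats.chi2.sf(q, df), np.finfo(float).tiny))
    return q, df, p


def ivw(iset: InstrumentSet, model: str = "auto") -> MRResult:
    """Inverse-variance-weighted causal estimate across the instrument set.

    ``model="fixed"`` reports the fixed-effect SE; ``"auto"`` (default)
    applies multiplicative random effects, inflating the SE by
    max(1, sqrt(Q / (n_iv - 1))). A single instrument degenerates to the
    Wald ratio.
    """
    if model not in ("auto", "fixed", "random"):
        raise ValueError(f"unknown model {model!r}")
    bx, _, by, sy = iset.arrays()
    n_iv = len(bx)
    if n_iv == 1:
        theta, se = wald_ratio(iset.pairs[0])
        p = _norm_p(theta / se)
        return MRResult(iset.gene_id, "Wald", theta, se, theta - _Z975 * se,
                        theta + _Z975 * se, p, 1, model="fixed")
    theta, se_fixed = _ivw_arrays(bx, by, sy)
    q, df, q_p = cochran_q(iset, theta)
    if model == "fixed":
        se, used = se_fixed, "fixed"
    else:
        se = se_fixed * max(1.0, np.sqrt(q / df))
        used = "random"
    p = _norm_p(theta / se)
    return MRResult(iset.gene_id, "IVW", theta, se, theta - _Z975 * se,
                    theta + _Z975 * se, p, n_iv, model=used, Q=q, Q_df=df, Q_p=q_p)


def egger(iset: InstrumentSet) -> MRResult:
    """MR-Egger regression: weighted regression of outcome on exposure
    effects with an intercept (average directional pleiotropy).

    Pairs are oriented so that every exposure effect is non-negative
    (jointly negating flipped pairs); weights are se_outcome^-2; SEs use
    multiplicative random-effects inflation max(1, sqrt(Q_egger/(n-2)));
    the intercept p-value is a two-sided normal test.
    """
    bx, _, by, sy = iset.arrays()
    n_iv = len(bx)
    if n_iv < 3:
        raise ValueError("Egger regression requires at least 3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.allclose(bx, bx[0]):
        raise ValueError("Egger slope unidentifiable: all exposure effects equal after orientation")
    w = sy**-2.0
    X = np.column_stack([np.ones(n_iv), bx])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    q_e = float(np.sum(w * resid**2))
    df = n_iv - 2
    scale = max(1.0, np.sqrt(q_e / df))
    cov = np.linalg.inv(xtwx) * scale**2
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    return MRResult(
        iset.gene_id, "Egger", slope, se_slope,
        slope - _Z975 * se_slope, slope + _Z975 * se_slope,
        _norm_p(slope / se_slope), n_iv, model="random",
        Q=q_e, Q_df=df, Q_p=float(max(stats.chi2.sf(q_e, df), np.finfo(float).tiny)),
        egger_intercept=intercept, egger_intercept_se=se_int,
        egger_intercept_p=_norm_p(intercept / se_int),
    )


# ---------------------------------------------------------------------------
# Multiple testing and the causal call
# ---------------------------------------------------------------------------


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m (e.g. 0.05/116 = 4.3e-4)."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return alpha / m


def adjust_pvalues(p_list, method: str = "bh") -> np.ndarray:
    """Adjusted p-values: 'bonferroni' (min(p*m, 1)) or 'bh' step-up."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "bh":
        return bh_adjust(p)
    raise ValueError(f"unknown adjustment method {method!r}")


def classify_causal(
    ivw_results: list[MRResult],
    presso_results: dict | None = None,
    alpha: float = 0.05,
    m: int | None = None,
    q_alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the causal-call decision logic over a family of IVW results.

    A gene is called causal iff its IVW p passes the Bonferroni gate
    (p < alpha/m) AND either (a) no heterogeneity (Q_p >= q_alpha), or
    (b) heterogeneity with a successful MR-PRESSO rescue. A heterogeneous
    Bonferroni-significant gene lacking a PRESSO result is flagged
    incomplete, not called.

    Returns one row per gene with the evidence path.
    """
    if m is None:
        m = len(ivw_results)
    thresh = bonferroni_threshold(alpha, m)
    presso_results = presso_results or {}
    rows = []
    for res in ivw_results:
        path, causal = "not_significant", False
        if res.p < thresh:
            if res.Q_p is None or res.Q_p >= q_alpha:
                path, causal = "ivw_homogeneous", True
            else:
                pres = presso_results.get(res.gene_id)
                if pres is None:
                    path, causal = "incomplete_presso_missing", False
                elif getattr(pres, "verdict", None) == "rescued":
                    path, causal = "presso_rescued", True
                else:
                    path = f"heterogeneous_not_rescued:{getattr(pres, 'failed_gate', '')}"
        rows.append(
            {
                "gene_id": res.gene_id,
                "theta": res.theta,
                "se": res.se,
                "p": res.p,
                "Q_p": res.Q_p,
                "n_iv": res.n_iv,
                "causal": causal,
                "evidence_path": path,
                "bonferroni_threshold": thresh,
            }
        )
    return pd.DataFrame(rows)
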