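"""Simulation-based detection and correction of horizontal-pleiotropy
outliers (MR-PRESSO style): Global, Outlier and Distortion tests.

The Global test compares the observed leave-one-out residual sum of
squares against parametric replicates drawn under the fitted
no-pleiotropy model. The Outlier test compares each instrument's observed
squared residual with its simulated distribution (Bonferroni-corrected).
The Distortion test compares the change in the IVW estimate after outlier
removal with removals of random instrument subsets of the same size.

All empirical p-values use the (1 + #{exceedances}) / (n + 1) estimator
and therefore never reach 0; the floor is 1/(n_sim + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instruments import InstrumentSet
from .mr import MRResult, _ivw_arrays, ivw

__all__ = [
    "PressoGlobal",
    "PressoOutlier",
    "PressoDistortion",
    "PressoResult",
    "presso_global",
    "presso_outlier",
    "presso_distortion",
    "run_presso",
]

_MIN_SIM = 100


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes theta_{-j}, vectorized.

    Supports batched input of shape (n_sim, J) for the parametric
    replicates; weights are shared across the batch.
    """
    s1 = np.sum(w * bx * by, axis=-1, keepdims=True)
    s2 = np.sum(w * bx**2, axis=-1, keepdims=True)
    return (s1 - w * bx * by) / (s2 - w * bx**2)


@dataclass
class PressoGlobal:
    rss_obs: float
    global_p: float
    sim_rss: np.ndarray
    obs_resid2: np.ndarray
    sim_resid2: np.ndarray  # (n_sim, J)
    n_sim: int
    seed: int | None


@dataclass
class PressoOutlier:
    p_raw: np.ndarray
    p_corrected: np.ndarray
    outlier_ids: list[str]


@dataclass
class PressoDistortion:
    theta_all: float
    theta_corrected: float
    se_corrected: float
    p_corrected: float
    distortion_coeff: float  # percent change, NaN when theta_all == 0
    distortion_p: float
    undefined: bool = False


@dataclass
class PressoResult:
    gene_id: str
    rss_obs: float
    global_p: float
    per_iv_outlier_p: dict[str, float]
    outlier_ids: list[str]
    theta_corrected: float | None
    se_corrected: float | None
    p_corrected: float | None
    distortion_coeff: float | None
    distortion_p: float | None
    n_sim: int
    seed: int | None
    verdict: str  # "rescued" | "not_rescued" | "not_applicable"
    failed_gate: str | None = None


def presso_global(iset: InstrumentSet, n_sim: int = 1000, seed: int | None = None) -> PressoGlobal:
    """MR-PRESSO Global heterogeneity test.

    Observed statistic: RSS_obs = sum_j (by_j - theta_{-j} bx_j)^2 with
    leave-one-out IVW slopes theta_{-j}. Replicates redraw
    bx* ~ N(bx_j, se_x_j) and by* ~ N(theta_{-j} bx_j, se_y_j) and are
    scored by the same leave-one-out RSS. Reproducible under ``seed``.
    """
    if n_sim < _MIN_SIM:
        raise ValueError(f"n_sim must be >= {_MIN_SIM}")
    bx, sx, by, sy = iset.arrays()
    j = len(bx)
    if j < 4:
        raise ValueError("the global test requires at least 4 instruments")
    w = sy**-2.0
    theta_loo = _loo_slopes(bx, by, w)
    obs_resid = by - theta_loo * bx
    rss_obs = float(np.sum(obs_resid**2))

    rng = np.random.default_rng(seed)
    bx_sim = bx + sx * rng.standard_normal((n_sim, j))
    by_sim = theta_loo * bx + sy * rng.standard_normal((n_sim, j))
    theta_sim = _loo_slopes(bx_sim, by_sim, w)
    sim_resid2 = (by_sim - theta_sim * bx_sim) ** 2
    sim_rss = sim_resid2.sum(axis=1)
    global_p = (1.0 + float(np.sum(sim_rss >= rss_obs))) / (n_sim + 1.0)
    return PressoGlobal(rss_obs, global_p, sim_rss, obs_resid**2, sim_resid2, n_sim, seed)


def presso_outlier(iset: InstrumentSet, global_sim: PressoGlobal, alpha: float = 0.05) -> PressoOutlier:
    """Per-instrument outlier test from the stored Global-test replicates.

    p_j = (1 + #{simulated resid^2_j >= observed resid^2_j}) / (n_sim + 1),
    Bonferroni-corrected by the instrument count; outliers have corrected
    p < ``alpha``.
    """
    if global_sim.sim_resid2 is None or global_sim.sim_resid2.size == 0:
        raise ValueError("global test replicates unavailable")
    n_sim, j = global_sim.sim_resid2.shape
    exceed = (global_sim.sim_resid2 >= global_sim.obs_resid2).sum(axis=0)
    p_raw = (1.0 + exceed) / (n_sim + 1.0)
    p_corr = np.minimum(p_raw * j, 1.0)
    ids = iset.variant_ids
    outliers = [ids[k] for k in range(j) if p_corr[k] < alpha]
    return PressoOutlier(p_raw, p_corr, outliers)


def presso_distortion(
    iset: InstrumentSet,
    outlier_ids: list[str],
    n_boot: int = 1000,
    seed: int | None = None,
) -> PressoDistortion:
    """MR-PRESSO Distortion test.

    The corrected estimate is IVW on the non-outlier subset; the
    distortion coefficient is the percent change relative to the all-
    instrument estimate; its null distribution removes ``len(outlier_ids)``
    uniformly random instruments (without replacement) n_boot times; the
    p-value is the two-sided empirical exceedance of |coefficient|.
    """
    ids = iset.variant_ids
    k = len(outlier_ids)
    j = len(ids)
    if k == 0:
        raise ValueError("distortion test requires a nonempty outlier set")
    if j - k < 3:
        raise ValueError("removing outliers leaves fewer than 3 instruments")
    unknown = set(outlier_ids) - set(ids)
    if unknown:
        raise ValueError(f"outlier ids not in instrument set: {sorted(unknown)}")
    bx, _, by, sy = iset.arrays()
    w = sy**-2.0
    theta_all, _ = _ivw_arrays(bx, by, sy)

    sub = iset.subset([v for v in ids if v not in set(outlier_ids)])
    corrected = ivw(sub)

    if theta_all == 0.0:
        return PressoDistortion(theta_all, corrected.theta, corrected.se, corrected.p,
                                float("nan"), float("nan"), undefined=True)
    s1 = np.sum(w * bx * by)
    s2 = np.sum(w * bx**2)

    def _removal_coeff(drop: np.ndarray) -> float:
        # one shared expression so identical subsets tie bit-for-bit
        t = (s1 - np.sum(w[drop] * bx[drop] * by[drop])) / (s2 - np.sum(w[drop] * bx[drop] ** 2))
        return 100.0 * (t - theta_all) / abs(theta_all)

    out_idx = np.sort([ids.index(v) for v in outlier_ids])
    coeff = _removal_coeff(out_idx)

    rng = np.random.default_rng(seed)
    null = np.empty(n_boot)
    for b in range(n_boot):
        null[b] = _removal_coeff(np.sort(rng.choice(j, size=k, replace=False)))
    p = (1.0 + float(np.sum(np.abs(null) >= abs(coeff)))) / (n_boot + 1.0)
    return PressoDistortion(theta_all, corrected.theta, corrected.se, corrected.p, coeff, p)


def run_presso(
    iset: InstrumentSet,
    ivw_result: MRResult | None = None,
    n_sim: int = 1000,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> PressoResult:
    """Run the three MR-PRESSO components with the rescue gating.

    Intended for genes already IVW-significant but heterogeneous
    (Q_p < 0.05). Gates, in order: the correction is attempted only if
    the Global test p < 0.05 and at least one instrument's corrected
    Outlier-test p < 0.05; the rescue succeeds iff the outlier-corrected
    IVW p < 0.05 and the Distortion-test p > 0.05.
    """
    glob = presso_global(iset, n_sim=n_sim, seed=seed)
    ids = iset.variant_ids
    base = dict(
        gene_id=iset.gene_id, rss_obs=glob.rss_obs, global_p=glob.global_p,
        n_sim=n_sim, seed=seed,
    )
    if glob.global_p >= alpha:
        return PressoResult(
            per_iv_outlier_p={}, outlier_ids=[], theta_corrected=None,
            se_corrected=None, p_corrected=None, distortion_coeff=None,
            distortion_p=None, verdict="not_applicable", failed_gate="global", **base,
        )
    out = presso_outlier(iset, glob, alpha=alpha)
    per_iv = dict(zip(ids, out.p_corrected))
    if not out.outlier_ids:
        return PressoResult(
            per_iv_outlier_p=per_iv, outlier_ids=[], theta_corrected=None,
            se_corrected=None, p_corrected=None, distortion_coeff=None,
            distortion_p=None, verdict="not_rescued", failed_gate="outlier", **base,
        )
    if len(ids) - len(out.outlier_ids) < 3:
        return PressoResult(
            per_iv_outlier_p=per_iv, outlier_ids=out.outlier_ids, theta_corrected=None,
            se_corrected=None, p_corrected=None, distortion_coeff=None,
            distortion_p=None, verdict="not_rescued", failed_gate="too_few_instruments_after_removal",
            **base,
        )
    dist = presso_distortion(iset, out.outlier_ids, n_boot=n_boot, seed=None if seed is None else seed + 1)
    ok = dist.p_corrected < alpha and (not np.isnan(dist.distortion_p)) and dist.distortion_p > alpha
    failed = None if ok else ("corrected_ivw" if dist.p_corrected >= alpha else "distortion")
    return PressoResult(
        per_iv_outlier_p=per_iv, outlier_ids=out.outlier_ids,
        theta_corrected=dist.theta_corrected, se_corrected=dist.se_corrected,
        p_corrected=dist.p_corrected, distortion_coeff=dist.distortion_coeff,
        distortion_p=dist.distortion_p,
        verdict="rescued" if ok else "not_rescued", failed_gate=failed, **base,
    )
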