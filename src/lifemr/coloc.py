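"""Bayesian colocalization of two summary-statistic traits over a region.

Per-variant evidence uses Wakefield approximate Bayes factors; the five
hypotheses are the standard enumeration assuming at most one causal
variant per trait in the region:

- H0: no association with either trait;
- H1 / H2: association with trait 1 / trait 2 only;
- H3: both traits associated, two distinct causal variants;
- H4: both traits associated, one shared causal variant.

All sums run in log space. A shared signal is called when PP(H4) > 0.8.
More than two traits are composed pairwise: traits joined by edges with
pairwise PP(H4) > 0.8 form colocalized clusters (an explicit
approximation to a joint multi-trait analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sumstats import TraitMeta

__all__ = [
    "TraitRegion",
    "RegionStats",
    "ColocResult",
    "wakefield_log_abf",
    "coloc_posteriors",
    "pairwise_multitrait",
    "DEFAULT_W_QUANTITATIVE",
    "DEFAULT_W_BINARY",
]

# prior variance of the causal effect (squared prior SD)
DEFAULT_W_QUANTITATIVE = 0.15**2
DEFAULT_W_BINARY = 0.2**2


def wakefield_log_abf(z, se, w) -> np.ndarray | float:
    """Log approximate Bayes factor for association at one variant.

    With v = se^2 and shrinkage r = w/(v + w):
    log ABF = 0.5 * (log(1 - r) + r * z^2), where ``w`` is the prior
    variance of the true effect. Positive values favour association.
    """
    z = np.asarray(z, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if w <= 0:
        raise ValueError("prior effect variance must be positive")
    v = se**2
    r = w / (v + w)
    out = 0.5 * (np.log1p(-r) + r * z**2)
    return float(out) if out.ndim == 0 else out


@dataclass
class TraitRegion:
    """One trait's Z-scores and SEs over the region's shared variant list."""

    name: str
    z: np.ndarray
    se: np.ndarray
    meta: TraitMeta | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.z.shape != self.se.shape:
            raise ValueError("z and se must be aligned")
        if np.any(self.se <= 0):
            raise ValueError("standard errors must be positive")

    def default_w(self) -> float:
        if self.meta is not None and self.meta.trait_type == "binary":
            return DEFAULT_W_BINARY
        return DEFAULT_W_QUANTITATIVE


@dataclass
class RegionStats:
    """Aligned per-variant statistics for >= 2 traits over one region."""

    chrom: str
    start: int
    end: int
    variant_ids: list[str]
    traits: dict[str, TraitRegion] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = len(self.variant_ids)
        if m == 0:
            raise ValueError("region has no variants")
        for tr in self.traits.values():
            if tr.z.shape[0] != m:
                raise ValueError(f"trait {tr.name}: statistics not aligned to variant list")

    def add_trait(self, region: TraitRegion) -> None:
        if region.z.shape[0] != len(self.variant_ids):
            raise ValueError("trait statistics not aligned to variant list")
        self.traits[region.name] = region


@dataclass
class ColocResult:
    pp_h0: float
    pp_h1: float
    pp_h2: float
    pp_h3: float
    pp_h4: float
    priors: tuple[float, float, float]
    top_shared_variant: str | None
    trait_pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        pp = self.pp
        if np.any((pp < -1e-9) | (pp > 1 + 1e-9)):
            raise ValueError("posterior probabilities outside [0, 1]")
        if abs(pp.sum() - 1.0) > 1e-9:
            raise ValueError("posterior probabilities do not sum to 1")

    @property
    def pp(self) -> np.ndarray:
        return np.array([self.pp_h0, self.pp_h1, self.pp_h2, self.pp_h3, self.pp_h4])

    @property
    def shared(self) -> bool:
        return self.pp_h4 > 0.8


def _log_h3(l1: np.ndarray, l2: np.ndarray) -> float:
    """log sum_{i != j} exp(l1_i + l2_j), stable in log space."""
    a = logsumexp(l1) + logsumexp(l2)
    b = logsumexp(l1 + l2)
    if len(l1) < 2 or b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_posteriors(
    region: RegionStats,
    trait1: str | None = None,
    trait2: str | None = None,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    w1: float | None = None,
    w2: float | None = None,
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    Per-variant priors: ``p1``/``p2`` for a variant causal for one trait
    only, ``p12`` for a shared causal variant. Prior effect variances
    ``w1``/``w2`` default to 0.15^2 for quantitative and 0.2^2 for binary
    traits (from trait metadata).
    """
    names = list(region.traits)
    if trait1 is None or trait2 is None:
        if len(names) != 2:
            raise ValueError("specify trait1/trait2 when the region holds more than two traits")
        trait1, trait2 = names
    t1, t2 = region.traits[trait1], region.traits[trait2]
    w1 = t1.default_w() if w1 is None else w1
    w2 = t2.default_w() if w2 is None else w2
    l1 = np.atleast_1d(wakefield_log_abf(t1.z, t1.se, w1))
    l2 = np.atleast_1d(wakefield_log_abf(t2.z, t2.se, w2))

    log_terms = np.array(
        [
            0.0,
            np.log(p1) + logsumexp(l1),
            np.log(p2) + logsumexp(l2),
            np.log(p1) + np.log(p2) + _log_h3(l1, l2),
            np.log(p12) + logsumexp(l1 + l2),
        ]
    )
    pp = np.exp(log_terms - logsumexp(log_terms))
    top = region.variant_ids[int(np.argmax(l1 + l2))]
    return ColocResult(*pp, priors=(p1, p2, p12), top_shared_variant=top,
                       trait_pair=(trait1, trait2))


@dataclass
class ColocClusters:
    pairs: pd.DataFrame  # one row per trait pair with pp_h0..pp_h4
    clusters: list[set[str]]  # connected components over PP(H4) > 0.8 edges


def pairwise_multitrait(region: RegionStats, pp_thresh: float = 0.8, **priors) -> ColocClusters:
    """Pairwise composition of two-trait colocalization over k >= 2 traits.

    Builds a graph over traits with an edge wherever the pairwise
    PP(H4) exceeds ``pp_thresh`` and reports connected components as
    colocalized clusters. This composition approximates, and does not
    reproduce, a joint multi-trait analysis.
    """
    names = list(region.traits)
    if len(names) < 2:
        raise ValueError("pairwise colocalization requires at least 2 traits")
    g = nx.Graph()
    g.add_nodes_from(names)
    rows = []
    for a, b in combinations(names, 2):
        res = coloc_posteriors(region, a, b, **priors)
        rows.append(
            {
                "trait1": a, "trait2": b,
                "pp_h0": res.pp_h0, "pp_h1": res.pp_h1, "pp_h2": res.pp_h2,
                "pp_h3": res.pp_h3, "pp_h4": res.pp_h4,
                "top_shared_variant": res.top_shared_variant,
                "shared": res.pp_h4 > pp_thresh,
            }
        )
        if res.pp_h4 > pp_thresh:
            g.add_edge(a, b)
    comps = [set(c) for c in nx.connected_components(g) if len(c) > 1]
    return ColocClusters(pd.DataFrame(rows), comps)
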