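import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from lifemr.sumstats import AlignedPair, VariantAssoc, two_sided_p


def make_assoc(variant_id="rs1", ea="A", oa="G", **kw):
    kw.setdefault("chrom", "1")
    kw.setdefault("pos", 1000)
    rec = VariantAssoc(variant_id, ea, oa, **kw)
    if rec.z is None and rec.beta is not None and rec.se:
        rec.z = rec.beta / rec.se
    if rec.p is None and rec.z is not None:
        rec.p = float(two_sided_p(rec.z))
    return rec


def make_pair(bx, sx, by, sy, vid="iv1", **kw):
    return AlignedPair(vid, bx, sx, by, sy, **kw)


@pytest.fixture
def simple_pairs():
    """Two instruments with identical Wald ratios (theta = 0.1, Q = 0)."""
    return [
        make_pair(0.2, 0.02, 0.02, 0.01, "iv1"),
        make_pair(0.4, 0.02, 0.04, 0.01, "iv2"),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
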