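"""Two-sample MR with heterogeneity, Egger and MR-PRESSO sensitivity.

A gene with 26 instruments and true causal slope 0.05 is simulated three
ways: clean, with one gross pleiotropic outlier, and with a pair of
opposite-sign outliers (heterogeneous but rescuable). IVW estimates the
slope; Cochran's Q flags heterogeneity; Egger's intercept tests
directional pleiotropy; MR-PRESSO detects, removes and re-tests.
"""

from lifemr import egger, ivw, run_presso
from lifemr.simulate import sim_mr_dataset

for label, spec in [("clean", None),
                    ("one gross outlier", [(0, 10.0)]),
                    ("opposite outlier pair", [(0, 10.0), (1, -10.0)])]:
    iset, truth = sim_mr_dataset(26, 0.05, outlier_spec=spec, seed=42)
    res = ivw(iset)
    egg = egger(iset)
    print(f"\n[{label}] true theta = {truth.theta_true}")
    print(f"  IVW theta = {res.theta:.4f} (se {res.se:.4f}, p={res.p:.2e}), "
          f"Q={res.Q:.1f} (p={res.Q_p:.3g})")
    print(f"  Egger intercept = {egg.egger_intercept:+.4f} (p={egg.egger_intercept_p:.3g})")
    if res.Q_p < 0.05:
        pres = run_presso(iset, res, seed=1)
        print(f"  MR-PRESSO: global p={pres.global_p:.3g}, outliers={pres.outlier_ids}, "
              f"verdict={pres.verdict}"
              + (f", corrected theta={pres.theta_corrected:.4f}" if pres.theta_corrected else ""))

# The opposite pair inflates Q without biasing the slope: both outliers are
# flagged, their removal does not distort the estimate, and the gene is rescued.
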