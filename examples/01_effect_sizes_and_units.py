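"""Recover effect sizes from Z-scores and express lifespan effects in years.

eQTL consortia often release only Z-scores with allele frequencies and
sample sizes; beta and SE are recovered as beta = Z*SE with
SE = 1/sqrt(2p(1-p)(n+Z^2)). Lifespan effects on the log protection-ratio
scale convert to years of life as 10x the effect.
"""

from lifemr import beta_to_years, zscore_to_beta_se

beta, se = zscore_to_beta_se(z=5.0, eaf=0.3, n=10_000)
print(f"Z=5.0, EAF=0.30, n=10000  ->  beta={beta:.6f} (SD per allele), se={se:.6f}")

for effect in (0.075, -0.05):
    print(f"log protection ratio {effect:+.3f} per 1 SD expression "
          f"-> {beta_to_years(effect):+.2f} years of life")

# A gene whose expression raises the lifespan effect by 0.075 per SD
# corresponds to a gain of about 9 months of life per SD of expression.
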