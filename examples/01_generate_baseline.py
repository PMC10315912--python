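"""Generate the synthetic baseline world and inspect its aggregate anchors.

The generator solves a ground-truth parameter set so the simulated
no-intervention epidemic reproduces the published aggregate anchors, then
tabulates sex x age-band x year calibration targets from that simulation.
"""

from t2dmsim import BaselineConfig, generate_baseline, write_targets

config = BaselineConfig()
targets = generate_baseline(config)

print(f"rows: {len(targets.frame)} (2 sexes x 20 age bands x 30 years)")
for year in (2021, 2030, 2050):
    prev = targets.aggregate("t2dm_prev", year)
    pop = targets.aggregate("population", year)
    ob = targets.aggregate("obesity_prev", year)
    print(f"{year}: T2DM prevalence {100 * prev:.1f}%  population {pop:,.0f}  "
          f"obesity {100 * ob:.1f}%")

write_targets(targets, "targets.csv")
print("wrote targets.csv")
# The 2021 prevalence (17.1%) and the obesity level in 2030 (53.3%) are the
# anchors the downstream calibration must reproduce; the population totals
# are implied by the published prevalent-case counts (33,821 and 84,516).
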