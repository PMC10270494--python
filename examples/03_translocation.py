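"""The fecal-translocation proportion: how fecal are blood and liver profiles?

Per disease group, the fecal core signature is the set of genera at >= 0.1%
relative abundance in >= 5% of that group's fecal samples. A blood or liver
sample's proportion T is the summed relative abundance of its own group's
signature genera; groups are contrasted against NAFLD with Mann-Whitney
tests, BH-adjusted per compartment.
"""

import gutliver as gl

config = gl.SimConfig(n_subjects_per_group={g: 12 for g in gl.GROUPS}, seed=3)
table, truth = gl.simulate_cohort(config)

report = gl.translocation_report(table)
print("fecal core signature sizes:")
for group, sig in report.signatures.items():
    print(f"  {group:10s} {len(sig.genera)} genera "
          f"(from {sig.n_fecal_samples} fecal samples)")

print("\nmedian proportion of fecal bacteria (T):")
print(report.samples.groupby(["compartment", "group"])["proportion"]
      .median().unstack().round(3))
print("\ncontrasts vs NAFLD (BH-adjusted within compartment):")
print(report.contrasts[["compartment", "group", "p", "q"]].to_string(index=False))
# T should recover the planted gradient pi: NAFLD 0.03 < cirrhosis 0.12 <
# HCC 0.22, with q < 0.05 for both contrasts in both compartments.
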