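"""Alpha and beta diversity of a simulated cohort.

Shannon index and Pielou evenness per sample with pairwise Mann-Whitney group
tests; Bray-Curtis distances with global and pairwise PERMANOVA per
compartment. In the simulated cohort fecal communities differ directly
between groups (cirrhosis/HCC profiles are sharpened and depleted), and
blood/liver profiles separate indirectly because their fecal admixture
differs by group.
"""

import gutliver as gl

config = gl.SimConfig(n_subjects_per_group={g: 12 for g in gl.GROUPS}, seed=2)
table, _ = gl.simulate_cohort(config)

alpha = gl.alpha_diversity_report(table)
print("mean Shannon index (nats) per compartment and group:")
print(alpha.per_sample.groupby(["compartment", "group"])["shannon"]
      .mean().unstack().round(2))
print("\nfecal Mann-Whitney p-values (shannon):")
t = alpha.tests
print(t[(t["compartment"] == "feces") & (t["metric"] == "shannon")]
      [["group1", "group2", "p"]].to_string(index=False))

for comp in ("feces", "blood"):
    beta = gl.beta_diversity_report(table, comp, n_perm=999, seed=2)
    g = beta.global_test
    print(f"\n{comp}: global PERMANOVA pseudo-F={g.f:.2f} "
          f"R2={g.r2:.3f} p={g.p:.3f} ({g.n_permutations} permutations)")
# A small fecal p with modest R2 mirrors the typical picture in patient
# cohorts: significant but partial compositional separation between groups.
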