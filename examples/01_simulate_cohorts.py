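"""Simulate the two study cohorts and look at what they contain.

Builds a discovery cohort (13 preclinical-SSc cases, 7 of whom progress to
definite disease, and 8 healthy controls) and a validation cohort
(50 subjects followed yearly for 5 years), each with planted marker
effects, then prints the realized fold changes and progression counts.
"""

import numpy as np

import pressc as pc

# --- discovery cohort: abundance matrix + case/control metadata ----------
design = pc.DiscoveryDesign(n_proteins=40, seed=1)
effects = pc.default_discovery_effects(["P0001", "P0002", "P0003"])
matrix, meta = pc.generate_discovery_cohort(design, effects)

fc = pc.log_fold_change(matrix, meta)
print(f"discovery matrix: {matrix.shape[0]} samples x {matrix.shape[1]} proteins")
print("planted log2 fold changes (target +1, -1, -1):")
print(fc[["P0001", "P0002", "P0003"]].round(2).to_string())
print(f"proteins passing the |1.5|-fold filter: {len(pc.filter_by_fc(fc, 0.585))}")

# --- validation cohort: abundance matrix + censoring intervals -----------
vdesign = pc.ValidationDesign(seed=2)
vmatrix, obs = pc.generate_validation_cohort(
    vdesign, pc.default_validation_effects(["P0001", "P0002"])
)
n_prog = sum(not o.right_censored for o in obs)
print(f"\nvalidation cohort: {len(obs)} subjects, {n_prog} progressors "
      f"({100 * n_prog / len(obs):.0f}% observed 5-year progression)")
print("first three censoring intervals (years from blood draw):")
for o in obs[:3]:
    r = "inf" if np.isinf(o.R) else f"{o.R:g}"
    print(f"  {o.sample_id}: ({o.L:g}, {r}]")
# A finite interval (L, R] means progression was first seen at the R-year
# visit; R = inf means the subject was progression-free at last follow-up.
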