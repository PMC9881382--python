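"""Stage-2 validation: interval-censored survival analysis of candidate
markers in a 50-subject cohort.

Plants one harmful (HR 2.5 per SD) and one protective (HR 0.4 per SD)
marker, then runs the full pipeline: kNN imputation, Box-Cox
normalization, interval-censored Cox regression, Contal-O'Quigley cutpoint
dichotomization, Turnbull curves per stratum and the generalized logrank
test.
"""

import pressc as pc

design = pc.ValidationDesign(missing_rate=0.03, seed=11)
effects = pc.default_validation_effects(["P0001", "P0002"])
matrix, obs = pc.generate_validation_cohort(design, effects)

res = pc.run_validation(matrix, obs, config=pc.ValidationConfig(seed=1))
cols = ["protein_id", "hr", "ci_low", "ci_high", "p_wald", "cutpoint",
        "direction", "glrt_p"]
print(res.table[cols].round(4).to_string(index=False))

print(
    "\nhr is the hazard ratio per SD of the Box-Cox-normalized marker"
    " (P0001 should exceed 1, P0002 fall below 1); for Wald-significant"
    " markers, 'cutpoint' dichotomizes the cohort on the original"
    " concentration scale and glrt_p tests the two Turnbull curves."
)
for pid, strata in res.curves.items():
    s_high = strata["high"].survival_at(4.9)[0]
    s_low = strata["low"].survival_at(4.9)[0]
    print(f"{pid}: 5-year progression-free fraction high={s_high:.2f} low={s_low:.2f}")
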