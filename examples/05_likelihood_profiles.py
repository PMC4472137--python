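"""Likelihood-difference profiles over the parameter grid.

After a full-grid fit, the profile of a parameter is the minimum
likelihood difference Δ = (−2 log L) − min at each of its grid values,
minimizing over the other four parameters.  Steep profiles mean the
data pin the parameter down; the near-flat profile of k shows the
initial old-bone proportion is barely identified.
"""

import bonecycle as bc

data = bc.generate_cohort(bc.CohortConfig(n_subjects=100, seed=3))
result = bc.fit(bc.ParameterGrid(), data)

for name in ("r_R", "r_F", "f_MAT", "f_BMD", "k"):
    prof = bc.profile_table(result, name)
    cells = "  ".join(
        f"{100 * v:.0f}%:{d:8.1f}" for v, d in zip(prof[name], prof["delta_min"])
    )
    print(f"{name:6s} {cells}")

k_range = bc.profile_table(result, "k")["delta_min"].max()
print(
    f"\nDelta range across k values: {k_range:.1f} — orders of magnitude "
    "flatter than the rate parameters, whose wrong grid values cost "
    "thousands of deviance units."
)
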