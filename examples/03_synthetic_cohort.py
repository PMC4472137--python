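"""Generate a synthetic trial cohort and summarize it.

Draws 100 subjects on the full trial schedule (markers at weeks 0, 1,
4, 12, 24, 48, 72; lumbar BMD at weeks 0, 24, 48, 72) with
multiplicative assay noise and subject-level correlated errors, then
prints the mean percent change from baseline with 95% CIs per outcome
and week — the shape clinicians plot for a teriparatide arm.
"""

import bonecycle as bc

config = bc.CohortConfig(n_subjects=100, seed=42, include_unfitted_marker_weeks=True)
data = bc.generate_cohort(config)
summary = bc.summarize_cohort(data)

print(f"{len(data.data)} records for {data.n_subjects} subjects\n")
with_fmt = summary.copy()
for col in ("mean_value", "pct_change_mean", "ci_low", "ci_high"):
    with_fmt[col] = with_fmt[col].round(2)
print(with_fmt.to_string(index=False))

p1np4 = summary.query("outcome == 'P1NP' and week == 4").iloc[0]
print(
    f"\nFormation marker at week 4: {p1np4.pct_change_mean:+.1f}% "
    f"(95% CI {p1np4.ci_low:+.1f} to {p1np4.ci_high:+.1f}) — the early "
    "anabolic rise; by week 72 it falls below baseline while BMD keeps "
    "climbing."
)
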