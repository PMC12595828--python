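"""Group statistics on a simulated aging / injury cohort.

Draws a young-vs-aged thickness cohort (3 animals x 16 sites per group,
targets 0.821 vs 0.512 µm) and a post-hemorrhage coverage time course
(sham / day 3 / day 7), then applies the unpaired t test and one-way ANOVA
with Dunnett's comparisons against sham.
"""

from gcxquant import RunConfig, run_pipeline

# young vs aged thickness (LEL lectin preset): unpaired t
report = run_pipeline(RunConfig(kind="cohort", seed=4, preset="AGING_THICKNESS_LEL"))
for group, s in report.summaries.items():
    print(f"{group:6s}: {s['mean']:.3f} ± {s['sem']:.3f} µm (n = {s['n']} sites)")
t = report.tests["unpaired_t"]
print(f"unpaired t: t = {t['t']:.2f}, df = {t['df']:.0f}, p = {t['p']:.2g}\n")

# coverage time course after intraventricular hemorrhage: ANOVA + Dunnett
report = run_pipeline(
    RunConfig(kind="cohort", seed=4, preset="IVH_COVERAGE_PNA", control="sham")
)
for group, s in report.summaries.items():
    print(f"{group:6s}: {s['mean']:5.1f} ± {s['sem']:4.1f} % (n = {s['n']} animals)")
d = report.tests["anova_dunnett"]
print(f"ANOVA F = {d['F']:.1f}, p = {d['p_anova']:.2g}; Dunnett vs {d['control']}:")
for label, p in d["adjusted_p"].items():
    print(f"  {label}: adjusted p = {p:.3g}")
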