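"""A full two-group study: simulate, analyse, and print the report tables.

Two cohorts share a cubic base template but differ in heterogeneity
(template dispersion), mimicking a clinical group with more variable
mental representations than its comparison group.
"""

import revpitch as rp

config = rp.PipelineConfig(
    cohorts=[
        rp.CohortSpec(group="ASD", n_observers=32, base_shape="cubic",
                      template_dispersion=0.8, seed=0),
        rp.CohortSpec(group="nonASD", n_observers=32, base_shape="cubic",
                      template_dispersion=0.4, seed=0),
    ],
    conditions={
        "speech": rp.speech_config(),
        "melody": rp.melody_config(),
    },
    seed=2024,
    reference_group="nonASD",
)
report = rp.run_pipeline(config)

print("== per-group metrics (mean) ==")
print(report.metrics.groupby(["condition", "group"])[["rms", "agreement"]]
      .mean().round(3))

print("\n== RMS group tests (Welch) ==")
print(report.rms_tests[["condition", "mean_1", "mean_2", "t_stat", "df",
                        "p_value"]].round(3).to_string(index=False))

print("\n== intra-group variability (pairwise kernel correlations) ==")
for cond, res in report.intragroup.items():
    print(f"{cond}: mean r ASD = {res.mean_1:.3f}, nonASD = {res.mean_2:.3f}, "
          f"t({res.df:.0f}) = {res.t_stat:.2f}, p = {res.p_value:.2g}")

print("\n== exceptional-sensitivity subgroup (RMS > mean + 2 SD of nonASD) ==")
print(report.subgroup.round(2).to_string(index=False))

print("\n== melody prototype correlation of the mean kernel ==")
print(report.prototype.round(3).to_string(index=False))
# Higher dispersion in the first cohort shows up as lower pairwise kernel
# correlations (greater intra-group variability), while mean RMS and
# agreement stay comparable between groups.
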