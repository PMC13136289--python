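"""Classify an activity-vs-dose profile as flat, monotonic or biphasic.

Simulates the hormetic default profile (+30% at 2 nM, +15% at 10 nM,
-30% at 50-100 nM, CV 5%, n = 3), Welch-tests each dose against the
control with Holm adjustment, and classifies the shape.
"""

from abatune import DoseResponseSpec, biphasic_test, gen_dose_response

table, truth = gen_dose_response(DoseResponseSpec(seed=0))
profile = biphasic_test(
    {lvl: grp["activity"].tolist() for lvl, grp in table.groupby("modulator_M")}
)

print(f"generating classification: {truth['classification']}")
print(f"recovered classification:  {profile.classification}")
print(profile.tests[["level", "relative", "p_raw", "p_adj", "significant"]]
      .to_string(index=False))
# 'biphasic' requires a dose significantly above the control AND a strictly
# higher dose significantly below it - stimulation then inhibition.
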