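"""A miniature seasonal study: summer vs winter conditions across subjects.

Simulates a small cohort in which every "winter" subject walks part of the
trial on cleared ground (W1) and part on snow/ice (W2); the W2 strides
carry a +4 cm forward-margin offset, emulating the more cautious stepping
strategy on slippery ground.  The per-condition subject means are then
compared with the study's statistical workflow (one-way ANOVA, Holm-Sidak
post-hoc t-tests, eta^2) after nondimensionalization, and the local
divergence exponent is computed per subject.
"""

import numpy as np

from gaitstab import (
    SimConfig,
    analyze_recording,
    compare_conditions,
    lde_from_analysis,
    nondimensionalize,
    NondimScales,
    simulate_walker,
)

N_SUBJECTS = 6
N_STRIDES = 90
scales = NondimScales(leg_length=0.91)

subject_means: dict[str, list[float]] = {"S": [], "W1": [], "W2": []}
ldes = []
for subj in range(N_SUBJECTS):
    # summer trial
    cfg_s = SimConfig(n_strides=N_STRIDES, seed=100 + subj)
    kin, insole, _ = simulate_walker(cfg_s)
    an = analyze_recording(kin, insole)
    subject_means["S"].append(an.steps["fw_mos"].mean())
    ldes.append(lde_from_analysis(kin, an, "AP", n_strides=60).lde)

    # winter trial: first 60% of strides W1, remainder W2 with extra margin
    n_w1 = int(0.6 * N_STRIDES)
    tags = ("W1",) * n_w1 + ("W2",) * (N_STRIDES - n_w1)
    cfg_w = SimConfig(
        n_strides=N_STRIDES,
        seed=200 + subj,
        condition_tags=tags,
        condition_fw_offsets={"W2": 0.04},
    )
    kin, insole, _ = simulate_walker(cfg_w)
    an = analyze_recording(kin, insole, conditions=list(tags))
    for cond in ("W1", "W2"):
        sel = an.steps["condition"] == cond
        subject_means[cond].append(an.steps.loc[sel, "fw_mos"].mean())

groups = {
    cond: nondimensionalize(np.asarray(v), "length", scales)
    for cond, v in subject_means.items()
}
for cond, vals in groups.items():
    print(f"{cond}: nondim FW MoS {vals.mean():+.4f} +/- {vals.std(ddof=1):.4f} "
          f"(N = {len(vals)})")

res = compare_conditions(groups)
print(f"one-way ANOVA: F = {res.statistic:.2f}, p = {res.pvalue:.2g}, "
      f"eta^2 = {res.eta_squared:.3f}")
for ph in res.posthoc:
    print(f"  {ph.groups[0]} vs {ph.groups[1]}: "
          f"p = {ph.pvalue:.2g}, Holm-Sidak adjusted p = {ph.adjusted_pvalue:.2g}")

print(f"AP local divergence exponent, summer: "
      f"{np.mean(ldes):.3f} +/- {np.std(ldes, ddof=1):.3f} per stride")

# The W2 condition separates from S and W1 by roughly the injected 4 cm
# (0.044 nondimensional units), and the post-hoc tests attribute the ANOVA
# effect to exactly the W2 contrasts.
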