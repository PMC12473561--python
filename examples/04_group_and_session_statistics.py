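"""The statistical layer: group t-tests, speed regressions, session contrast.

Subject-level metric means are compared between groups with pooled-variance
t-tests at a Bonferroni-corrected threshold (0.05 / 13 metrics); each metric
is also regressed on gait speed.  A within-subject pair of recordings is
compared at stride level, which is what gives a single subject enough power.
"""

import numpy as np

import treadgait as tg
from treadgait.stats import bonferroni_threshold, regress_on_speed

rng = np.random.default_rng(4)
thr = bonferroni_threshold(0.05, 13)
print(f"Bonferroni-corrected threshold for 13 metrics: {thr:.3g}")

# two small synthetic cohorts differing only in ML sway amplitude
cohorts = {"A": dict(a_ml=21.0), "B": dict(a_ml=27.0)}
summaries, speeds = {}, {}
for label, tweak in cohorts.items():
    summaries[label], speeds[label] = [], []
    for i in range(4):
        belt = float(rng.uniform(500, 900))
        seq, _ = tg.simulate(tg.SimConfig(duration=45.0, belt_speed=belt, noise_sd=2.0,
                                          seed=100 + i + (0 if label == "A" else 50), **tweak))
        res = tg.analyze_sequence(seq, spectral=False)
        summaries[label].append({m: res.summary.metrics[m][0] for m in tg.METRIC_NAMES})
        speeds[label].append(res.summary.gait_speed)

for metric in ("com_width", "step_width", "left_stride_length"):
    a = [s[metric] for s in summaries["A"]]
    b = [s[metric] for s in summaries["B"]]
    res = tg.two_sample_ttest(a, b, metric=metric, threshold=thr)
    print(f"  {metric:>18}: t = {res.t:6.2f}, p = {res.p:.4f}"
          f"{'  *' if res.significant else ''}")

reg = regress_on_speed(
    [s["left_stride_length"] for s in summaries["A"] + summaries["B"]],
    speeds["A"] + speeds["B"], metric="left_stride_length",
)
print(f"stride length vs speed: slope {reg.slope:.0f} mm per m/s, R^2 = {reg.r_squared:.2f}")
print("(longer strides at higher speed: stride length = belt speed x stride time)")

# within-subject pair: session 2 has a wider ML sway
(s1, _), (s2, _) = tg.synthetic_gait.two_session_pair(seed=9)
r1, r2 = tg.analyze_sequence(s1, spectral=False), tg.analyze_sequence(s2, spectral=False)
out = tg.compare_sessions(r1.stride_values(), r2.stride_values())
w = out["com_width"]
print(f"session contrast, CoM width: {w.mean_a:.1f} -> {w.mean_b:.1f} mm, p = {w.p:.2g}")
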