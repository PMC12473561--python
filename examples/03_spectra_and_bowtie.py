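"""Spectral structure of the CoM and the figure-eight projection.

In steady walking the CoM sways side-to-side once per stride but bobs
vertically (and surges fore-aft) once per step — twice per stride.  The
dominant-frequency ratio ML/vertical is therefore ~0.5, and plotting
phase-aligned ML against vertical traces the characteristic "bowtie".
"""

import treadgait as tg
from treadgait.com_kinematics import bowtie_projection

seq, truth = tg.simulate(tg.SimConfig(seed=3))  # default: 3 min at 15 Hz
result = tg.analyze_sequence(seq)

spec = result.spectral
T = truth.config.stride_time
print(f"stride time {T} s -> stride frequency {1 / T:.2f} Hz, step frequency {2 / T:.2f} Hz")
for axis in ("ml", "vert", "ap"):
    print(f"  dominant {axis:>4} frequency: {spec.dominant_hz[axis]:.3f} Hz")
print(f"ML / vertical dominant-frequency ratio: {spec.ml_to_vertical_frequency_ratio:.3f}")

proj = bowtie_projection(result.normalized)
print(f"mean-stride ML-vs-vertical projection self-intersections: "
      f"{proj.self_intersections_vert} (>=1 means the bowtie/figure-eight shape)")
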