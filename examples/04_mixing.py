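"""Two-colour mixing assay: does active pinching homogenise the lumen?

Particles in the left half of a honeycomb network are blue, the right half
red; Var(ϕ) — the variance over 20 vertical strips of (blue − red) counts —
measures segregation (0 = perfectly mixed).  Original pinch parameters mix no
faster than diffusion; maximally long pinches sped up tenfold mix visibly
faster.
"""

import numpy as np

from lumenflow import build_honeycomb, mixing_experiment
from lumenflow.contractions import (ContractionSchedule,
                                    PinchParameterDistributions,
                                    sample_pinch_schedule)
from lumenflow.particles import TransportConfig

net = build_honeycomb(5, 5, edge_length=1.0)
cfg = TransportConfig(seed=11, store_flow=False)
T_END, N = 1.5, 250


def var_curve(schedule):
    times, var, _ = mixing_experiment(net, schedule, N, t_end=T_END,
                                      config=cfg)
    return times, var


t, v_diff = var_curve(None)
sched = ContractionSchedule(t_end=T_END, pinch_sites=sample_pinch_schedule(
    net, t_end=T_END, seed=5))
_, v_act = var_curve(sched)
fast = ContractionSchedule(t_end=T_END, pinch_sites=sample_pinch_schedule(
    net, PinchParameterDistributions(alpha=10, beta=10), t_end=T_END, seed=5,
    length_policy="full-tubule"))
_, v_fast = var_curve(fast)

print("time (s)   Var diffusion   Var active   Var fast-long-pinches")
for k in range(0, len(t), 10):
    print(f"{t[k]:7.2f}   {v_diff[k]:13.1f}   {v_act[k]:10.1f}   "
          f"{v_fast[k]:10.1f}")
print(f"\nmean Var over the run: diffusion {v_diff.mean():.0f}, "
      f"active {v_act.mean():.0f}, fast {v_fast.mean():.0f}")
print("Active ≈ diffusion (original parameters do not help mixing); the"
      "\nfast/long-pinch network homogenises markedly faster.")
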