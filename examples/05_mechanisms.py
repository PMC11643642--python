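"""Alternative flow-generation mechanisms: junctions and sheet reservoirs.

Compares transport driven by (a) tubule pinches alone, (b) contracting
tubular junctions (truncated-normal volumes ~0.0045 µm³), and (c) a
perinuclear sheet reservoir expelling 10 µm³ over 5 s through designated
sheet nodes — and shows the sheet's short spatial range via the V(x) profile.
"""

import numpy as np

from lumenflow import build_honeycomb, spatial_speed_profile
from lumenflow.particles import TransportConfig
from lumenflow.scenarios import (ScenarioConfig, configure_perinuclear,
                                 run_scenario)

net = build_honeycomb(5, 5, edge_length=1.0)
cfg = TransportConfig(t_end=2.0, n_particles=150, seed=21)

for label, scfg, network in [
    ("tubule pinches", ScenarioConfig(mechanism="tubule-pinch"), net),
    ("junctions (α=2.5, β=2)", ScenarioConfig(mechanism="junction",
                                              alpha=2.5, beta=2.0), net),
]:
    s = run_scenario(network, scfg, cfg)
    print(f"{label:24s}: mean AETS = {s.mean_aets:6.2f} µm/s, "
          f"mean flow speed = {s.flow['mean_flow_speed']:.3f} µm/s")

# perinuclear sheet: pick exit nodes on the left edge of the network as the
# sheet connection, keep the rest as exits
exits = net.exit_nodes
xs = net.pos[[net.node_index(n) for n in exits], 0]
sheet_ids = [int(n) for n, x in zip(exits, xs) if x < np.median(xs)][:5]
net_sheet, scfg = configure_perinuclear(net, sheet_ids, v_sheet=10.0,
                                        two_T=5.0)
s = run_scenario(net_sheet, scfg, cfg)
print(f"{'perinuclear sheet':24s}: mean AETS = {s.mean_aets:6.2f} µm/s, "
      f"mean flow speed = {s.flow['mean_flow_speed']:.3f} µm/s")

prof = spatial_speed_profile(s.edge_mean_speeds, net_sheet, n_bins=5)
print("\nV(x): traversal speed vs distance from the sheet (left side):")
for _, row in prof.iterrows():
    if not np.isnan(row.V):
        print(f"  x = {row.x:5.2f} µm : V = {row.V:6.2f} µm/s "
              f"({int(row.n_edges)} edges)")
print("Sheet-driven speeds decay with distance from the sheet nodes; "
      "junction-driven\ntransport is spatially uniform.")
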