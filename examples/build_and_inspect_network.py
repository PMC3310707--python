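"""Grow one dense and one sparse FRC network and characterize them.

Builds both network types at the same FRC frequency and prints the
structural metrics used throughout the study: the fraction of the volume
the network occupies and surveys, random-walk centrality, FRC
connectivity, and the spacing of filament intersections.
"""

import numpy as np

from frcsim import (
    LatticeConfig,
    NetworkParams,
    WeightParams,
    build_network,
    centrality,
    mean_intersection_distance,
    surveyed_fraction,
)

lat = LatticeConfig()  # 20^3 nodes, one node = one 7-um cell body
f_frc = 0.03

for mode in ("dense", "sparse"):
    net = build_network(
        NetworkParams(f_frc=f_frc, mode=mode), WeightParams(), lat,
        np.random.default_rng(2012),
    )
    c = centrality(net)
    print(f"--- {mode} network, f_FRC = {f_frc}")
    print(f"FRC placed:              {len(net.frc_nodes)}")
    print(f"min fibres per FRC:      {min(net.frc_degree(u) for u in net.frc_nodes)}")
    print(f"volume on network:       {net.on_network.mean():.3f}")
    print(f"surveyed fraction:       {surveyed_fraction(net):.3f}")
    print(f"mean centrality (all):   {c.mean():.4f}  (uniform lattice: {1/26:.4f})")
    print(f"mean centrality (FRC):   {c[net.frc_nodes].mean():.4f}")
    print(f"intersection spacing:    {mean_intersection_distance(net):.1f} um")
    print()

print(
    "A dense network guarantees every FRC at least two fibre partners (an\n"
    "intact reticular network); the sparse variant drops that constraint,\n"
    "mimicking disruption: it surveys less volume at the same FRC count."
)
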