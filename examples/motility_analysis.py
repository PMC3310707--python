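"""Motility of simulated T cells: turning angles and displacement.

Follows single motile cells (no target) for 400 steps on a calibrated
dense network, computes the turning-angle distribution, the fraction of
time spent following the network, and the motility coefficient from the
mean displacement against sqrt(time).
"""

import numpy as np

from frcsim import (
    LatticeConfig,
    NetworkParams,
    PopulationConfig,
    SimulationConfig,
    WeightParams,
    build_network,
    motility_coefficient,
    run_single,
    turning_angle_distribution,
    unwrapped_displacement,
)
from frcsim.lattice import DIRECTIONS

lat = LatticeConfig()
cfg = SimulationConfig(
    lattice=lat,
    network=NetworkParams(f_frc=0.015, mode="dense"),
    population=PopulationConfig(scenario="walker"),
)
net = build_network(cfg.network, WeightParams(), lat, np.random.default_rng(5))

paths, disps, follow = [], [], []
for i in range(120):
    r = run_single(cfg, net, seed=[5, 0, i], collect_moves=True)
    dirs = [d for (_t, _node, d) in r.moves]
    paths.append(dirs)
    steps = DIRECTIONS[dirs].astype(float) * lat.edge_length_um
    disps.append(np.linalg.norm(np.cumsum(steps, axis=0), axis=1))
    follow.append(r.on_network_time_fraction)

n_min = min(len(d) for d in disps)
summary = motility_coefficient(np.array([d[:n_min] for d in disps]), cfg.minutes_per_step)
angles = turning_angle_distribution(paths)

print("turning-angle distribution (radians -> frequency):")
print(angles.round(3).to_string())
print()
print(f"time following the network: {np.mean(follow):.2f}")
print(f"motility coefficient:       {summary.motility_coefficient:.1f} um^2/min")
print()
print(
    "Small turning angles carry the most weight (the composite-ellipsoid\n"
    "bias), while the network adds a secondary reversal peak: cells\n"
    "shuttle back and forth along fibres they are attracted to.  The\n"
    "long-run displacement still grows linearly in sqrt(t) -- a\n"
    "persistent random walk with a motility coefficient in the tens of\n"
    "um^2/min, as reported for naive T cells in lymph nodes."
)
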