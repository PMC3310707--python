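"""How network density and disruption change the chance two cells meet.

Sweeps the FRC frequency for dense (intact) and sparse (disrupted)
networks in the moving-target scenario (a CTL hunting a motile infected
cell) at a reduced scale: 10 networks x 20 runs per setting, so the
whole sweep takes about a minute.  The study-scale version uses 100
networks x 50 runs per setting.
"""

from frcsim import NetworkParams, PopulationConfig, SimulationConfig, sweep

cfg = SimulationConfig(
    population=PopulationConfig(scenario="moving_target"),
    networks_per_setting=10,
    runs_per_network=20,
    master_seed=42,
)
table = sweep(cfg, f_frc_grid=[0.0, 0.005, 0.015, 0.05], modes=("dense", "sparse"))
cols = ["f_frc", "mode", "contact_fraction", "mean_t_contact_min", "rate_per_1e3min"]
print(table[cols].to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print()
print(
    "Contact probability rises from the no-network baseline (~52%) to a\n"
    "maximum of ~64-66% at low-to-intermediate dense densities and falls\n"
    "back toward the baseline when filaments saturate the volume.\n"
    "Sparse (disrupted) networks sit below their dense counterparts: the\n"
    "guidance structure helps most exactly where losing it hurts most."
)
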