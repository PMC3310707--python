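"""Run orchestration: single runs, batches, and parameter sweeps.

A run couples one FRC network with one freshly initialized cell lattice and
iterates time steps of 0.7 min: every motile cell samples a direction from
the combined network/turning-angle multinomial and moves (possibly several
sub-moves while on the network if ``nu > 1``), the DC extends and retracts
a dendrite, and the specific pair is checked for contact.  A run ends at
first contact or after ``steps_max`` (default 400 steps = 280 min, the
lower bound of T-cell dwell-time estimates in lymphoid organs).

Seeding is hierarchical and fully reproducible: ``master_seed`` ->
per-network stream -> per-run stream, so a batch is bit-for-bit identical
across reruns.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .agents import (
    FREE,
    UNSPECIFIC,
    PopulationConfig,
    initialize_population,
    update_dendrites,
)
from .contact import ContactParams
from .lattice import DIRECTIONS, LatticeConfig
from .movement import (
    EllipsoidParams,
    TrappedCellError,
    VelocityParams,
    turning_weight_table,
)
from .network import FrcNetwork, NetworkParams, WeightParams, build_network

__all__ = ["SimulationConfig", "RunResult", "run_single", "run_batch", "sweep"]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce a batch of runs."""

    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    network: NetworkParams = field(default_factory=NetworkParams)
    weights: WeightParams = field(default_factory=WeightParams)
    ellipsoid: EllipsoidParams = field(default_factory=EllipsoidParams)
    velocity: VelocityParams = field(default_factory=VelocityParams)
    contact: ContactParams = field(default_factory=ContactParams)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    steps_max: int = 400
    minutes_per_step: float = 0.7
    runs_per_network: int = 50
    networks_per_setting: int = 100
    master_seed: int = 0

    @property
    def total_minutes(self) -> float:
        return self.steps_max * self.minutes_per_step

    @property
    def total_runs(self) -> int:
        return self.runs_per_network * self.networks_per_setting

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        sub = {
            "lattice": LatticeConfig,
            "network": NetworkParams,
            "weights": WeightParams,
            "ellipsoid": EllipsoidParams,
            "velocity": VelocityParams,
            "contact": ContactParams,
            "population": PopulationConfig,
        }
        kwargs = {}
        for key, typ in sub.items():
            if key in d:
                val = d.pop(key)
                kwargs[key] = typ(**val) if isinstance(val, dict) else val
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text: str | Path) -> "SimulationConfig":
        p = Path(path_or_text)
        text = p.read_text() if p.exists() else str(path_or_text)
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class RunResult:
    """Outcome and covariates of one simulated cell-pair run."""

    contacted: bool
    t_contact: int | None
    t_reach_network: int | None
    d_initial_um: float
    on_network_fraction: float
    on_network_time_fraction: float
    boundary_crossing_fraction: float
    n_moves: int
    seed: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "contacted": self.contacted,
            "t_contact": self.t_contact,
            "t_reach_network": self.t_reach_network,
            "d_initial_um": self.d_initial_um,
            "on_network_fraction": self.on_network_fraction,
            "on_network_time_fraction": self.on_network_time_fraction,
            "boundary_crossing_fraction": self.boundary_crossing_fraction,
            "n_moves": self.n_moves,
            "seed": "-".join(str(s) for s in self.seed),
        }


# per-LatticeConfig caches of coordinate and boundary-crossing tables
_GEOM_CACHE: dict[LatticeConfig, tuple[np.ndarray, np.ndarray]] = {}


def _geometry(cfg: LatticeConfig) -> tuple[np.ndarray, np.ndarray]:
    cached = _GEOM_CACHE.get(cfg)
    if cached is None:
        s = cfg.side_length
        coords = np.indices((s, s, s)).reshape(3, -1).T.astype(np.int16)
        raw = coords[:, None, :] + DIRECTIONS[None, :, :]
        crossing = ((raw < 0) | (raw >= s)).any(axis=2)
        cached = (coords, crossing)
        _GEOM_CACHE[cfg] = cached
    return cached


def _min_image_cheb(coords: np.ndarray, nodes: np.ndarray, pos: int, s: int) -> np.ndarray:
    diff = np.abs(coords[nodes] - coords[pos])
    return np.minimum(diff, s - diff).max(axis=1)


def run_single(
    cfg: SimulationConfig,
    net: FrcNetwork,
    seed: int | Sequence[int] | np.random.Generator,
    collect_moves: bool = False,
    _probs_cache: dict | None = None,
) -> RunResult:
    """One simulated cell-pair run; deterministic given ``(net, seed)``.

    With ``collect_moves=True`` the result gains a ``moves`` attribute:
    the searcher's executed moves as ``(step, node, direction)`` triples
    (used by the turning-angle and displacement analyses).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_id = tuple(np.atleast_1d(seed).tolist()) if not isinstance(seed, np.random.Generator) else ()
    lat = cfg.lattice
    s = lat.side_length
    coords, crossing = _geometry(lat)
    nbr = net.nbr
    w1 = net.w1
    filament = net.filament
    on_net = net.on_network
    w2 = turning_weight_table(cfg.ellipsoid)
    nu = cfg.velocity.nu
    nu_base = int(np.floor(nu))
    nu_frac = nu - nu_base
    cache = _probs_cache

    grid = initialize_population(lat, net, cfg.population, rng)
    occupancy = grid.occupancy
    cells = grid.cells
    dc = grid.dc
    searcher = cells[0]

    if cfg.population.scenario == "static_target":
        other_pos = dc.core
    elif cfg.population.scenario == "moving_target":
        other_pos = cells[1].position
    else:
        other_pos = None  # walker: no target
    if other_pos is not None:
        diff = np.abs(coords[searcher.position] - coords[other_pos])
        d_initial = float(np.linalg.norm(np.minimum(diff, s - diff)) * lat.edge_length_um)
    else:
        d_initial = float("nan")

    t_reach = 0 if on_net[searcher.position] else None
    n_moves = 0
    n_fil = 0
    n_cross = 0
    n_steps_on_net = 0
    n_steps = 0
    moves: list[tuple[int, int, int]] = []

    contacted = False
    t_contact: int | None = None
    delta_max = cfg.contact.delta_max

    for t in range(1, cfg.steps_max + 1):
        for cell in cells:
            if nu > 1.0 and on_net[cell.position]:
                nsub = nu_base + (1 if (nu_frac > 0 and rng.random() < nu_frac) else 0)
            else:
                nsub = 1
            for _ in range(nsub):
                pos = cell.position
                dp = cell.d_prev
                if cache is not None:
                    cs = cache.get((pos, dp))
                    if cs is None:
                        cs = np.cumsum(w1[pos] * w2[dp])
                        cache[pos, dp] = cs
                else:
                    cs = np.cumsum(w1[pos] * w2[dp])
                total = cs[-1]
                if total <= 0.0:
                    raise TrappedCellError(f"cell trapped at node {pos}")
                d = int(np.searchsorted(cs, rng.random() * total, side="right"))
                target = int(nbr[pos, d])
                occ = occupancy[target]
                if occ == FREE or occ == UNSPECIFIC:
                    occupancy[target] = cell.code
                    occupancy[pos] = FREE if occ == FREE else UNSPECIFIC
                    cell.position = target
                    cell.d_prev = d
                    if cell is searcher:
                        n_moves += 1
                        if filament[pos, d]:
                            n_fil += 1
                        if crossing[pos, d]:
                            n_cross += 1
                        if collect_moves:
                            moves.append((t, pos, d))
                        if t_reach is None and on_net[target]:
                            t_reach = t
                # refused moves change nothing, not even d_prev

        n_steps += 1
        if on_net[searcher.position]:
            n_steps_on_net += 1
        if other_pos is None:
            continue  # walker: no contact to check
        if dc is not None:
            update_dendrites(dc, occupancy, nbr, rng)
            dc_nodes = np.array(dc.nodes, dtype=np.int64)
            cheb = _min_image_cheb(coords, dc_nodes, searcher.position, s)
            if (cheb <= 1).any():
                contacted = True
            elif delta_max > 1 and dc.tips:
                tips = np.array(dc.tips, dtype=np.int64)
                delta = int(_min_image_cheb(coords, tips, searcher.position, s).min())
                if delta <= delta_max and rng.random() < cfg.contact.p_contact(delta):
                    contacted = True
        else:
            a, b = cells[0].position, cells[1].position
            diff = np.abs(coords[a] - coords[b])
            if np.minimum(diff, s - diff).max() <= 1:
                contacted = True
        if contacted:
            t_contact = t
            break

    result = RunResult(
        contacted=contacted,
        t_contact=t_contact,
        t_reach_network=t_reach,
        d_initial_um=d_initial,
        on_network_fraction=(n_fil / n_moves) if n_moves else float("nan"),
        on_network_time_fraction=(n_steps_on_net / n_steps) if n_steps else float("nan"),
        boundary_crossing_fraction=(n_cross / n_moves) if n_moves else float("nan"),
        n_moves=n_moves,
        seed=seed_id,
    )
    if collect_moves:
        result.moves = moves  # type: ignore[attr-defined]
    return result


_NETWORK_STREAM = 1_000_003  # offset separating network-build from run streams


def run_batch(
    cfg: SimulationConfig,
    out_path: str | Path | None = None,
    networks: Iterable[FrcNetwork] | None = None,
) -> pd.DataFrame:
    """Run ``networks_per_setting`` fresh networks x ``runs_per_network``.

    Child seeds derive from ``(master_seed, network_index, run_index)``, so
    results are byte-for-byte reproducible.  If ``out_path`` is given the
    per-run table is streamed there as CSV, one network at a time.
    """
    rows: list[dict] = []
    handle = None
    header_written = False
    completed_networks = 0
    if out_path is not None:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        handle = open(out_path, "w")
    net_list = list(networks) if networks is not None else None
    try:
        for j in range(cfg.networks_per_setting):
            if net_list is not None:
                net = net_list[j]
            else:
                net_rng = np.random.default_rng([cfg.master_seed, j, _NETWORK_STREAM])
                net = build_network(cfg.network, cfg.weights, cfg.lattice, net_rng)
            cache: dict = {}
            batch_rows = []
            for i in range(cfg.runs_per_network):
                rr = run_single(cfg, net, seed=[cfg.master_seed, j, i], _probs_cache=cache)
                row = rr.to_dict()
                row["network"] = j
                row["run"] = i
                batch_rows.append(row)
            rows.extend(batch_rows)
            if handle is not None:
                df = pd.DataFrame(batch_rows)
                df.to_csv(handle, index=False, header=not header_written)
                header_written = True
                handle.flush()
            completed_networks = j + 1
    except Exception:
        if out_path is not None:
            # partial-results manifest so interrupted batches are diagnosable
            manifest = Path(out_path).with_suffix(".manifest.json")
            manifest.write_text(
                json.dumps(
                    {
                        "complete": False,
                        "networks_completed": completed_networks,
                        "networks_planned": cfg.networks_per_setting,
                        "runs_per_network": cfg.runs_per_network,
                        "master_seed": cfg.master_seed,
                    },
                    indent=2,
                )
            )
        raise
    finally:
        if handle is not None:
            handle.close()
    return pd.DataFrame(rows)


def summarize_batch(cfg: SimulationConfig, df: pd.DataFrame) -> dict:
    """Per-setting summary: contact fraction, conditional mean time, rate."""
    from .stats import fit_exponential

    n = len(df)
    contacted = df["contacted"].astype(bool)
    frac = float(contacted.mean()) if n else float("nan")
    times_min = df.loc[contacted, "t_contact"].astype(float) * cfg.minutes_per_step
    out = {
        "n_runs": n,
        "contact_fraction": frac,
        "mean_t_contact_min": float(times_min.mean()) if len(times_min) else float("nan"),
        "rate_per_1e3min": float("nan"),
        "rate_lo": float("nan"),
        "rate_hi": float("nan"),
    }
    if len(times_min) >= 2:
        fit = fit_exponential(times_min.to_numpy())
        out["rate_per_1e3min"] = fit.lambda_hat * 1e3
        out["rate_lo"] = fit.ci95[0] * 1e3
        out["rate_hi"] = fit.ci95[1] * 1e3
    return out


def sweep(
    cfg: SimulationConfig,
    f_frc_grid: Sequence[float],
    modes: Sequence[str] = ("dense",),
    nus: Sequence[float] = (1.0,),
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Sweep f_frc x mode x nu and summarize each setting in one row."""
    if not len(f_frc_grid):
        raise ValueError("empty f_frc grid")
    records = []
    for mode in modes:
        for nu in nus:
            for f in f_frc_grid:
                setting = cfg.replace(
                    network=dataclasses.replace(cfg.network, f_frc=f, mode=mode),
                    velocity=VelocityParams(nu=nu),
                )
                out_path = (
                    Path(out_dir) / f"runs_{mode}_nu{nu}_f{f:g}.csv" if out_dir else None
                )
                df = run_batch(setting, out_path=out_path)
                row = {"f_frc": f, "mode": mode, "nu": nu, "scenario": cfg.population.scenario}
                row.update(summarize_batch(setting, df))
                records.append(row)
    return pd.DataFrame(records)
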