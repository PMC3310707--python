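"""Cell populations on the movement lattice.

The movement lattice is densely packed, as lymphoid tissue is: after the
specific cell pair is placed, ~2.5% of the remaining nodes are left as free
space and everything else is filled with unspecific splenocytes.  Unspecific
cells are passive — they move only by being swapped with a motile cell.

A dendritic cell consists of a single core node plus dynamic dendrites:
edge-paths of occupied nodes rooted at the core that continuously extend and
retract while conserving their total segment count (the cell's volume).
Roughly two thirds of the DC volume is in its dendrites, so the default
budget of 6 dendrite segments accompanies a core counted as ~3 T-cell
volumes (a DC of ~9 T-cell volumes, within imaging-based estimates).
DC preferentially adhere to FRC, so the core is initialized on or
next to an FRC node whenever the network is non-empty.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .lattice import LatticeConfig
from .network import FrcNetwork

__all__ = [
    "FREE",
    "UNSPECIFIC",
    "MOTILE_A",
    "MOTILE_B",
    "DC_CORE",
    "DC_DENDRITE",
    "OCCUPANT_NAMES",
    "MotileCell",
    "DendriticCell",
    "PopulationConfig",
    "CellGrid",
    "initialize_population",
    "update_dendrites",
    "write_snapshot",
]

# occupancy codes (exactly one occupant per node)
FREE, UNSPECIFIC, MOTILE_A, MOTILE_B, DC_CORE, DC_DENDRITE = range(6)
OCCUPANT_NAMES = {
    FREE: "free",
    UNSPECIFIC: "unspecific",
    MOTILE_A: "motile_specific",
    MOTILE_B: "motile_target",
    DC_CORE: "dc_core",
    DC_DENDRITE: "dc_dendrite",
}

#: Default dendrite segment budget.  Tuned once against the no-network
#: static-target contact fraction and frozen; see docs/methods.md.
DEFAULT_DENDRITE_BUDGET = 6


@dataclass
class MotileCell:
    """A motile specific cell occupying exactly one node."""

    position: int
    d_prev: int
    role: str  # "naive_T" | "ctl" | "target"
    code: int = MOTILE_A


@dataclass
class DendriticCell:
    core: int
    dendrites: list[list[int]]
    volume_budget: int

    @property
    def segment_count(self) -> int:
        return sum(len(d) for d in self.dendrites)

    @property
    def nodes(self) -> list[int]:
        out = [self.core]
        for d in self.dendrites:
            out.extend(d)
        return out

    @property
    def tips(self) -> list[int]:
        return [d[-1] for d in self.dendrites if d]


@dataclass(frozen=True)
class PopulationConfig:
    """Composition of the cell lattice.

    ``scenario`` selects the cell pair: ``static_target`` is a naive T cell
    searching for a static DC with dynamic dendrites; ``moving_target`` is a
    CTL hunting a motile target cell (no DC).  One specific pair per run.
    ``walker`` places a single motile cell and no target at all — used for
    pure motility analyses (turning angles, displacement, network
    following), where runs always last the full simulated period.
    """

    scenario: str = "static_target"
    free_space_fraction: float = 0.025
    dendrite_budget: int = DEFAULT_DENDRITE_BUDGET
    n_dendrites: int = 4

    def __post_init__(self) -> None:
        if self.scenario not in ("static_target", "moving_target", "walker"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not 0.0 <= self.free_space_fraction < 1.0:
            raise ValueError("free_space_fraction must lie in [0, 1)")
        if self.dendrite_budget < 0 or self.n_dendrites < 1:
            raise ValueError("invalid DC geometry")


@dataclass
class CellGrid:
    """Node -> occupant map plus the specific agents living on it."""

    cfg: LatticeConfig
    occupancy: np.ndarray  # int8, one code per node
    cells: list[MotileCell]
    dc: DendriticCell | None = None

    def census(self) -> dict[str, int]:
        counts = np.bincount(self.occupancy, minlength=6)
        return {OCCUPANT_NAMES[k]: int(counts[k]) for k in range(6)}


def _init_dendrites(
    core: int,
    occupancy: np.ndarray,
    nbr: np.ndarray,
    budget: int,
    n_dendrites: int,
    rng: np.random.Generator,
) -> list[list[int]]:
    dendrites: list[list[int]] = [[] for _ in range(n_dendrites)]
    stuck: set[int] = set()
    placed = 0
    while placed < budget and len(stuck) < n_dendrites:
        i = int(rng.integers(n_dendrites))
        if i in stuck:
            continue
        tip = dendrites[i][-1] if dendrites[i] else core
        cand = [int(v) for v in nbr[tip] if occupancy[v] == FREE and v not in dendrites[i]]
        if not cand:
            stuck.add(i)
            continue
        node = cand[int(rng.integers(len(cand)))]
        dendrites[i].append(node)
        occupancy[node] = DC_DENDRITE
        placed += 1
    return dendrites


def initialize_population(
    cfg: LatticeConfig,
    net: FrcNetwork,
    pop: PopulationConfig,
    rng: np.random.Generator,
) -> CellGrid:
    """Place the specific pair, fill the lattice, leave some free space.

    Order: the pair (and, for a static target, the DC with fully extended
    dendrites) is placed on the empty lattice, then ``free_space_fraction``
    of the remaining nodes stay free and the rest become unspecific
    splenocytes.
    """
    n = cfg.n_nodes
    occupancy = np.zeros(n, dtype=np.int8)
    dc = None
    cells: list[MotileCell] = []

    if pop.scenario == "static_target":
        min_needed = 2 + pop.dendrite_budget
        if n < min_needed:
            raise ValueError(f"lattice of {n} nodes cannot host DC + pair")
        if len(net.frc_nodes) > 0:
            # adhere to the network: core on an FRC node or one of its neighbours
            anchors = np.unique(
                np.concatenate([net.frc_nodes, net.nbr[net.frc_nodes].ravel()])
            )
            core = int(anchors[rng.integers(len(anchors))])
        else:
            core = int(rng.integers(n))
        occupancy[core] = DC_CORE
        dendrites = _init_dendrites(
            core, occupancy, net.nbr, pop.dendrite_budget, pop.n_dendrites, rng
        )
        dc = DendriticCell(core=core, dendrites=dendrites, volume_budget=pop.dendrite_budget)
        free = np.flatnonzero(occupancy == FREE)
        t_pos = int(free[rng.integers(len(free))])
        occupancy[t_pos] = MOTILE_A
        cells.append(MotileCell(position=t_pos, d_prev=int(rng.integers(26)), role="naive_T"))
    elif pop.scenario == "walker":
        pos = int(rng.integers(n))
        occupancy[pos] = MOTILE_A
        cells.append(MotileCell(position=pos, d_prev=int(rng.integers(26)), role="naive_T"))
    else:
        if n < 2:
            raise ValueError("lattice too small for a cell pair")
        a, b = rng.choice(n, size=2, replace=False)
        occupancy[int(a)] = MOTILE_A
        occupancy[int(b)] = MOTILE_B
        cells.append(MotileCell(position=int(a), d_prev=int(rng.integers(26)), role="ctl"))
        cells.append(
            MotileCell(position=int(b), d_prev=int(rng.integers(26)), role="target", code=MOTILE_B)
        )

    remaining = np.flatnonzero(occupancy == FREE)
    n_free = int(round(pop.free_space_fraction * len(remaining)))
    keep_free = rng.choice(remaining, size=n_free, replace=False) if n_free else []
    occupancy[remaining] = UNSPECIFIC
    occupancy[np.asarray(keep_free, dtype=np.int64)] = FREE
    return CellGrid(cfg=cfg, occupancy=occupancy, cells=cells, dc=dc)


def update_dendrites(
    dc: DendriticCell,
    occupancy: np.ndarray,
    nbr: np.ndarray,
    rng: np.random.Generator,
) -> DendriticCell:
    """One extend/retract cycle, conserving the total segment count.

    A terminal segment of a uniformly chosen non-empty dendrite retracts
    and one segment extends from a uniformly chosen (possibly different)
    dendrite into a free neighbouring node.  Dendrites are self-avoiding
    and never displace cells: if the chosen dendrite has no free node to
    extend into, the whole update is skipped and the budget is preserved.
    """
    if dc.volume_budget == 0:
        return dc
    nonempty = [i for i, d in enumerate(dc.dendrites) if d]
    if not nonempty:
        return dc
    r = nonempty[int(rng.integers(len(nonempty)))]
    e = int(rng.integers(len(dc.dendrites)))
    retracted = dc.dendrites[r][-1]
    occupancy[retracted] = FREE  # tentative
    dc.dendrites[r].pop()
    tip = dc.dendrites[e][-1] if dc.dendrites[e] else dc.core
    cand = [
        int(v)
        for v in nbr[tip]
        if occupancy[v] == FREE and v not in dc.dendrites[e] and v != dc.core
    ]
    if not cand:
        # no extendable edge: defer by restoring the retracted segment
        dc.dendrites[r].append(retracted)
        occupancy[retracted] = DC_DENDRITE
        return dc
    node = cand[int(rng.integers(len(cand)))]
    dc.dendrites[e].append(node)
    occupancy[node] = DC_DENDRITE
    return dc


def write_snapshot(grid: CellGrid, path: str | Path) -> None:
    """Plain-text voxel table (x,y,z,occupant) for debugging/visualization."""
    lines = ["x,y,z,occupant"]
    for i in range(grid.cfg.n_nodes):
        x, y, z = grid.cfg.coords(i)
        lines.append(f"{x},{y},{z},{OCCUPANT_NAMES[int(grid.occupancy[i])]}")
    Path(path).write_text("\n".join(lines) + "\n")
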