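"""The cell movement rule.

A motile cell's next direction is drawn from a multinomial over the 26
lattice directions whose weights combine two factors:

* ``w1`` — the network attraction of the edge (chemokine level): high on
  filament edges, ~100x lower elsewhere, zero on blocked edges; and
* ``w2`` — a turning-angle weight equal to the radial distance to the
  surface of a composite ellipsoid elongated along the previous movement
  direction, so that small turning angles are preferred (reorienting the
  actin cytoskeleton is costly) and reversals are rare.

The drawn move is then executed against the occupancy grid: cells step into
free space, swap places with unspecific splenocytes, and are refused by
anything else.  While a cell sits on the network its speed can be enhanced
by a factor ``nu``, realized as extra sub-moves per time step.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np

from .agents import FREE, UNSPECIFIC, MotileCell
from .lattice import ANGLE_TABLE, N_DIRECTIONS
from .network import FrcNetwork

__all__ = [
    "EllipsoidParams",
    "VelocityParams",
    "TrappedCellError",
    "turning_weight",
    "turning_weight_table",
    "direction_probabilities",
    "attempt_move",
    "submoves_this_step",
    "on_network_fraction",
    "write_trajectory",
]


@dataclass(frozen=True)
class EllipsoidParams:
    """Semi-axes of the composite turning-angle ellipsoid.

    ``a`` points along the previous direction (forward), ``b`` is
    transverse, and ``c`` points backward; ``a > b >= c`` encodes the
    preference for small turning angles, and the defaults give a 4:1
    forward-to-reversal weight ratio.  The degenerate spherical case
    ``a = b = c`` (an unbiased walk) is allowed for validation against
    random-walk theory.
    """

    a: float = 2.0
    b: float = 1.0
    c: float = 0.5

    def __post_init__(self) -> None:
        if not (self.a >= self.b >= self.c > 0):
            raise ValueError(f"require a >= b >= c > 0, got {(self.a, self.b, self.c)}")


@dataclass(frozen=True)
class VelocityParams:
    """On-network velocity enhancement factor (moves per step while on
    the network have expectation ``nu``)."""

    nu: float = 1.0

    def __post_init__(self) -> None:
        if self.nu < 1:
            raise ValueError("nu must be >= 1")


class TrappedCellError(RuntimeError):
    """All 26 direction weights are zero (prevented by network invariants)."""


def turning_weight(theta: float, p: EllipsoidParams) -> float:
    """Radial distance from the centre to the composite spheroid surface.

    The forward half (theta <= pi/2) is a spheroid with semi-axes (a, b),
    the backward half one with (c, b); the two halves meet continuously at
    b for theta = pi/2.
    """
    if not 0.0 <= theta <= np.pi + 1e-12:
        raise ValueError(f"theta must lie in [0, pi], got {theta}")
    ax = p.a if theta <= np.pi / 2 else p.c
    s, co = np.sin(theta), np.cos(theta)
    return float(ax * p.b / np.sqrt(p.b**2 * co**2 + ax**2 * s**2))


@lru_cache(maxsize=8)
def turning_weight_table(p: EllipsoidParams) -> np.ndarray:
    """(26, 26) table ``W2[d_prev, d_new]`` of turning weights."""
    w2 = np.empty_like(ANGLE_TABLE)
    for i in range(N_DIRECTIONS):
        for j in range(N_DIRECTIONS):
            w2[i, j] = turning_weight(float(ANGLE_TABLE[i, j]), p)
    w2.setflags(write=False)
    return w2


def direction_probabilities(
    cell: MotileCell | int,
    net: FrcNetwork,
    p: EllipsoidParams | None = None,
    d_prev: int | None = None,
) -> np.ndarray:
    """Multinomial direction probabilities ``P_i = w1_i w2_i / sum_j w1_j w2_j``.

    Accepts either a :class:`MotileCell` or a flat node index with an
    explicit ``d_prev``.  Blocked edges get probability exactly 0.
    """
    if isinstance(cell, MotileCell):
        node, d_prev = cell.position, cell.d_prev
    else:
        node = int(cell)
        if d_prev is None:
            raise ValueError("d_prev required when passing a node index")
    w2 = turning_weight_table(p or EllipsoidParams())
    v = net.w1[node] * w2[d_prev]
    total = v.sum()
    if total <= 0.0:
        raise TrappedCellError(f"cell at node {node} has no positive direction weight")
    return v / total


def attempt_move(cell: MotileCell, d: int, grid) -> str:
    """Execute a sampled move: ``moved`` into free space, ``swapped`` with an
    unspecific splenocyte, or ``refused`` by any other occupant.

    ``d_prev`` is updated only when the cell actually changes position.
    """
    occupancy = grid.occupancy
    target = int(grid_nbr(grid)[cell.position, d])
    occ = int(occupancy[target])
    if occ == FREE:
        occupancy[target] = cell.code
        occupancy[cell.position] = FREE
        cell.position = target
        cell.d_prev = d
        return "moved"
    if occ == UNSPECIFIC:
        occupancy[target] = cell.code
        occupancy[cell.position] = UNSPECIFIC
        cell.position = target
        cell.d_prev = d
        return "swapped"
    return "refused"


def grid_nbr(grid) -> np.ndarray:
    """Neighbour table for a grid (kept on the grid after first use)."""
    nbr = getattr(grid, "_nbr", None)
    if nbr is None:
        from .lattice import neighbor_table

        nbr = neighbor_table(grid.cfg)
        grid._nbr = nbr
    return nbr


def submoves_this_step(
    on_network: bool, v: VelocityParams, rng: np.random.Generator
) -> int:
    """Number of sub-moves this time step: 1 off the network, otherwise an
    integer with expectation ``nu`` (floor plus a Bernoulli remainder)."""
    if not on_network or v.nu <= 1.0:
        return 1
    base = int(np.floor(v.nu))
    frac = v.nu - base
    return base + (1 if (frac > 0 and rng.random() < frac) else 0)


def on_network_fraction(moves: list[tuple[int, int]], net: FrcNetwork) -> float:
    """Fraction of executed moves that traverse a filament edge.

    ``moves`` is a list of ``(node, direction_index)`` pairs for moves that
    were actually executed (moved or swapped).
    """
    if not moves:
        raise ValueError("on_network_fraction is undefined for an empty path")
    hits = sum(bool(net.filament[node, d]) for node, d in moves)
    return hits / len(moves)


def write_trajectory(
    records: list[tuple[int, int, int, bool]], path: str | Path
) -> None:
    """Per-move CSV: step, node, direction, on_network flag."""
    lines = ["step,node,direction,on_network"]
    for step, node, d, flag in records:
        lines.append(f"{step},{node},{d},{int(flag)}")
    Path(path).write_text("\n".join(lines) + "\n")
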