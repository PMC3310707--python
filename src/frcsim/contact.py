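"""Contact rules for the specific cell pair.

One lattice edge is one T-cell diameter, so the membranes of cells on
neighbouring nodes touch: adjacency (wrapped Chebyshev distance 1) counts
as contact.  The same membrane-touch logic applies to a dendritic cell's
core and dendrite segments.  A dendrite tip that falls short of the T cell
by more than one node but no more than ``delta_max`` may still establish
contact with probability ``p(delta) = 1 - delta/delta_max`` — the model
does not resolve the flexible shape of the T-cell membrane, and this
Bernoulli rule stands in for it.  Contact is evaluated once per time step,
after all moves and the dendrite update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agents import DendriticCell, MotileCell
from .lattice import LatticeConfig, wrapped_chebyshev

__all__ = ["ContactParams", "motile_contact", "dc_contact"]


@dataclass(frozen=True)
class ContactParams:
    """Partial-reach rule for dendrite tips.

    ``delta_max`` is the largest tip-to-cell lattice distance at which a
    partial contact is possible; the default of 1 means adjacency (which
    is already deterministic contact) is required.
    """

    delta_max: int = 1

    def __post_init__(self) -> None:
        if self.delta_max < 1:
            raise ValueError("delta_max must be >= 1")

    def p_contact(self, delta: int) -> float:
        """Linear partial-contact probability, 1 at delta=0, 0 at delta_max."""
        if delta < 0:
            raise ValueError("delta must be >= 0")
        return max(0.0, 1.0 - delta / self.delta_max)


def motile_contact(a, b, cfg: LatticeConfig) -> bool:
    """Two motile cells are in contact iff they sit on neighbouring nodes."""
    a = cfg.coords(a) if np.isscalar(a) else a
    b = cfg.coords(b) if np.isscalar(b) else b
    d = wrapped_chebyshev(a, b, cfg)
    if d == 0:
        raise ValueError("two cells cannot occupy the same node")
    return d == 1


def dc_contact(
    t: MotileCell | int,
    dc: DendriticCell,
    params: ContactParams,
    cfg: LatticeConfig,
    rng: np.random.Generator,
) -> bool:
    """Contact between a naive T cell and a static DC.

    Deterministic if the T cell is adjacent to the core or is covered by or
    adjacent to a dendrite segment (membrane touch); otherwise, if the
    nearest dendrite tip is within ``delta_max`` lattice steps, contact is
    a Bernoulli draw with probability ``p(delta)``; otherwise no contact.
    """
    pos = t.position if isinstance(t, MotileCell) else int(t)
    tc = cfg.coords(pos)
    if wrapped_chebyshev(tc, cfg.coords(dc.core), cfg) <= 1:
        return True
    for dend in dc.dendrites:
        for node in dend:
            if wrapped_chebyshev(tc, cfg.coords(node), cfg) <= 1:
                return True
    tips = dc.tips
    if tips:
        delta = min(wrapped_chebyshev(tc, cfg.coords(tip), cfg) for tip in tips)
        if delta <= params.delta_max:
            return bool(rng.random() < params.p_contact(delta))
    return False
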