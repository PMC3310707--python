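"""Construction and characterization of fibroblastic reticular cell networks.

The FRC network lives on its own lattice grid, superimposed on the cell
movement grid.  It is grown procedurally: an FRC is seeded on a random node
and fibres grow from it along lattice edges for a fixed number of steps,
choosing a new direction uniformly at random at every node they reach; a new
FRC is placed at each fibre tip.  After a chain of ``chain_length`` FRC the
process re-roots at a fresh random node, until the target FRC frequency is
reached.

Two network categories are distinguished:

* **dense** — an intact network in which every FRC is connected by fibres to
  at least two other FRC (deficient FRC are repaired with straight fibres to
  randomly chosen FRC), and
* **sparse** — a disrupted network with no connectivity requirement, as
  observed in persistent infections that damage the reticular network.

Each lattice edge carries an attraction weight ``w1`` representing chemokine
released by the network: filament edges weigh ~100x more than plain edges,
and a random subset of non-filament edges incident to each FRC is blocked
(weight 0) to represent spatial obstruction by the filaments themselves.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .lattice import (
    N_DIRECTIONS,
    OPPOSITE,
    LatticeConfig,
    neighbor_table,
)

__all__ = [
    "NetworkParams",
    "WeightParams",
    "FrcNetwork",
    "grow_fibre",
    "build_network",
    "assign_blocked_edges",
    "centrality",
    "surveyed_fraction",
    "mean_intersection_distance",
    "calibrate_frc_frequency",
    "save_edge_list",
    "load_edge_list",
    "to_networkx",
    "save_graphml",
    "load_graphml",
]


@dataclass(frozen=True)
class NetworkParams:
    """Parameters of the network-growth procedure.

    ``f_frc`` is the fraction of lattice nodes occupied by an FRC.  In dense
    mode every FRC must end up with at least ``d_min = 2`` distinct fibre
    partners; sparse mode imposes no such constraint.  ``growth_steps`` is
    the fibre length in lattice edges between consecutive FRC (3 edges of
    7 um, i.e. up to ~21 um between FRC, chosen so that a 10% FRC frequency
    surveys the whole volume as observed for intact reticular networks).
    ``chain_length`` FRC are seeded per random root before re-rooting, and
    every FRC additionally launches ``short_filament_rate`` dangling
    filaments that need not connect to another FRC.
    """

    f_frc: float = 0.0
    mode: str = "dense"
    d_min: int = 2
    growth_steps: int = 3
    chain_length: int = 5
    short_filament_rate: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_frc <= 1.0:
            raise ValueError(f"f_frc must lie in [0, 1], got {self.f_frc}")
        if self.mode not in ("dense", "sparse"):
            raise ValueError(f"mode must be 'dense' or 'sparse', got {self.mode!r}")
        if self.growth_steps < 1:
            raise ValueError("growth_steps must be >= 1")
        if self.chain_length < 1:
            raise ValueError("chain_length must be >= 1")


@dataclass(frozen=True)
class WeightParams:
    """Directed edge attraction weights (chemokine levels).

    Weights grade with connection and distance to the network: ``w_high``
    on filament edges, ``w_attract`` on edges pointing *onto* a network
    node from anywhere (attraction toward an FRC is higher than movement
    away from it), and ``w_low`` — roughly 100x below ``w_high`` — on all
    other edges.  Blocked edges carry weight 0.
    """

    w_high: float = 1.0
    w_low: float = 0.01
    w_attract: float = 0.05

    def __post_init__(self) -> None:
        if not self.w_high > self.w_low > 0:
            raise ValueError("weights must satisfy w_high > w_low > 0")
        if not self.w_high > self.w_attract >= self.w_low:
            raise ValueError("require w_high > w_attract >= w_low")


@dataclass
class FrcNetwork:
    """An immutable-by-convention FRC network on the lattice.

    Attributes
    ----------
    frc_nodes : ndarray of flat node indices occupied by an FRC.
    filament : bool array (n_nodes, 26), symmetric; True where the lattice
        edge lies on a fibre path.
    w1 : float array (n_nodes, 26) of *directed* attraction weights:
        ``w1[u, d]`` applies to the move from ``u`` along direction ``d``
        and takes values in {0, w_low, w_attract, w_high}.
    partners : dict mapping each FRC to the set of FRC it shares a fibre
        with (``frc_degree`` is the size of that set).
    nbr : flat-index neighbour table shared with the movement lattice.
    """

    cfg: LatticeConfig
    params: NetworkParams
    weights: WeightParams
    frc_nodes: np.ndarray
    filament: np.ndarray
    w1: np.ndarray
    partners: dict[int, set[int]]
    nbr: np.ndarray = field(repr=False)

    @property
    def is_frc(self) -> np.ndarray:
        mask = np.zeros(self.cfg.n_nodes, dtype=bool)
        mask[self.frc_nodes] = True
        return mask

    @property
    def on_network(self) -> np.ndarray:
        """Nodes incident to at least one filament edge (the fibre paths)."""
        return self.filament.any(axis=1)

    def frc_degree(self, node: int) -> int:
        return len(self.partners.get(int(node), ()))


def grow_fibre(
    root: int, growth_steps: int, nbr: np.ndarray, rng: np.random.Generator
) -> tuple[list[tuple[int, int]], int]:
    """Grow one fibre from ``root`` for ``growth_steps`` lattice edges.

    At every node the fibre chooses a new direction uniformly at random from
    the 26 lattice directions.  Returns the path as a list of ``(node,
    direction_index)`` pairs and the tip node.
    """
    if growth_steps < 1:
        raise ValueError("growth_steps must be >= 1")
    path: list[tuple[int, int]] = []
    cur = int(root)
    for _ in range(growth_steps):
        d = int(rng.integers(N_DIRECTIONS))
        path.append((cur, d))
        cur = int(nbr[cur, d])
    return path, cur


def _mark_path(filament: np.ndarray, nbr: np.ndarray, path: list[tuple[int, int]]) -> None:
    for node, d in path:
        filament[node, d] = True
        filament[nbr[node, d], OPPOSITE[d]] = True


def _straight_path(a: int, b: int, cfg: LatticeConfig) -> list[tuple[int, int]]:
    """Deterministic shortest wrapped lattice path from a to b.

    Moves diagonally first (one Chebyshev-optimal step per move), choosing
    the wrap direction with the smaller displacement and breaking exact ties
    toward positive offsets (lexicographic direction order).
    """
    s = cfg.side_length
    ax, ay, az = cfg.coords(a)
    bx, by, bz = cfg.coords(b)
    deltas = []
    for ca, cb in ((ax, bx), (ay, by), (az, bz)):
        raw = (cb - ca) % s
        # minimum-image signed delta; tie (raw == s/2) broken positive
        deltas.append(raw if raw <= s - raw else raw - s)
    path = []
    cur = [ax, ay, az]
    rem = list(deltas)
    from .lattice import direction_index

    while any(rem):
        step = tuple(int(np.sign(r)) for r in rem)
        d = direction_index(step)
        path.append((cfg.flat(cur), d))
        cur = [(c + st) % s for c, st in zip(cur, step)]
        rem = [r - st for r, st in zip(rem, step)]
    return path


def build_network(
    params: NetworkParams,
    weights: WeightParams,
    cfg: LatticeConfig,
    rng: np.random.Generator,
    block_edges: bool = True,
) -> FrcNetwork:
    """Grow a full FRC network for the given parameters.

    The network is reproducible bit-for-bit from ``(params, weights, cfg)``
    and the generator state, and is kept constant during simulation runs.
    """
    n_nodes = cfg.n_nodes
    n_target = int(round(params.f_frc * n_nodes))
    if params.mode == "dense" and 0 < n_target < 3:
        raise ValueError(
            "dense mode needs at least 3 FRC to satisfy the minimum "
            f"connectivity of {params.d_min}; f_frc={params.f_frc} gives "
            f"{n_target}"
        )
    nbr = neighbor_table(cfg)
    is_frc = np.zeros(n_nodes, dtype=bool)
    filament = np.zeros((n_nodes, N_DIRECTIONS), dtype=bool)
    partners: dict[int, set[int]] = {}

    def _place(node: int) -> None:
        is_frc[node] = True
        partners.setdefault(node, set())

    def _link(u: int, v: int) -> None:
        if u != v:
            partners[u].add(v)
            partners[v].add(u)

    n_placed = 0
    while n_placed < n_target:
        root = int(rng.integers(n_nodes))
        if is_frc[root]:
            continue  # re-draw occupied roots
        _place(root)
        n_placed += 1
        chain = 1
        while chain < params.chain_length and n_placed < n_target:
            path, tip = grow_fibre(root, params.growth_steps, nbr, rng)
            _mark_path(filament, nbr, path)
            if is_frc[tip]:
                # fibre kept, but the chain re-roots to avoid looping
                _link(root, tip)
                break
            _place(tip)
            _link(root, tip)
            n_placed += 1
            root = tip
            chain += 1

    frc_nodes = np.flatnonzero(is_frc)

    if params.mode == "dense" and n_target >= 3:
        # repair pass: every FRC must reach >= d_min other FRC by fibres
        deficient = [u for u in frc_nodes if len(partners[int(u)]) < params.d_min]
        while deficient:
            u = int(deficient.pop())
            while len(partners[u]) < params.d_min:
                candidates = [int(v) for v in frc_nodes if int(v) != u and int(v) not in partners[u]]
                v = int(candidates[rng.integers(len(candidates))])
                _mark_path(filament, nbr, _straight_path(u, v, cfg))
                _link(u, v)

    # dangling short filaments launched by each FRC
    for u in frc_nodes:
        for _ in range(params.short_filament_rate):
            path, _tip = grow_fibre(int(u), params.growth_steps, nbr, rng)
            _mark_path(filament, nbr, path)

    # directed weights: w1[u, d] is the attraction of the move u -> nbr[u, d]
    on_network = filament.any(axis=1)
    w1 = np.where(on_network[nbr], weights.w_attract, weights.w_low)
    w1[filament] = weights.w_high

    net = FrcNetwork(
        cfg=cfg,
        params=params,
        weights=weights,
        frc_nodes=frc_nodes,
        filament=filament,
        w1=w1,
        partners=partners,
        nbr=nbr,
    )
    if block_edges:
        assign_blocked_edges(net, rng)
    return net


def assign_blocked_edges(net: FrcNetwork, rng: np.random.Generator) -> FrcNetwork:
    """Set a random subset of non-filament edges at each FRC to weight 0.

    For an FRC with ``n_f`` incident filaments, the number of blocked paths
    is drawn uniformly from {0, ..., n_f}: the more filaments converge on an
    FRC, the more directions are obstructed.  An edge whose removal would
    leave either endpoint with no positive-weight edge is skipped, so every
    lattice node remains reachable.
    """
    w1, filament, nbr = net.w1, net.filament, net.nbr
    for u in net.frc_nodes:
        u = int(u)
        n_f = int(filament[u].sum())
        if n_f == 0:
            continue
        b = int(rng.integers(n_f + 1))
        if b == 0:
            continue
        candidates = np.flatnonzero(~filament[u] & (w1[u] > 0))
        rng.shuffle(candidates)
        blocked = 0
        for d in candidates:
            if blocked == b:
                break
            d = int(d)
            v = int(nbr[u, d])
            w_saved = w1[u, d]
            w1[u, d] = 0.0
            w1[v, OPPOSITE[d]] = 0.0
            if not (w1[u] > 0).any() or not (w1[v] > 0).any():
                w1[u, d] = w_saved  # would isolate a node: re-sample
                w1[v, OPPOSITE[d]] = w_saved
                continue
            blocked += 1
    return net


def centrality(net: FrcNetwork, node: int | None = None) -> float | np.ndarray:
    """Random-walk centrality: weighted degree over neighbourhood degrees.

    ``c_i = k_i / sum_{j in N(i)} k_j`` with ``k_i`` the sum of incident
    edge weights, which is proportional to the stationary visit rate of a
    weighted random walker.  On a uniformly weighted periodic lattice every
    node has ``c_i = 1/26``.
    """
    k = net.w1.sum(axis=1)
    denom = k[net.nbr].sum(axis=1)
    if node is not None:
        if denom[node] == 0:
            raise ValueError(f"centrality undefined at node {node}: all neighbour degrees zero")
        return float(k[node] / denom[node])
    if np.any(denom == 0):
        raise ValueError("centrality undefined: some node has an all-zero neighbourhood")
    return k / denom


def surveyed_fraction(
    net: FrcNetwork, cfg: LatticeConfig | None = None, include_neighborhood: bool = True
) -> float:
    """Fraction of the volume surveyed by a cell crawling along the network.

    A crawling T cell occupies the nodes of the fibre paths and touches
    (membrane contact) their 26-neighbourhoods, so by default the surveyed
    set is the path nodes plus all their neighbours.  With
    ``include_neighborhood=False`` only the path nodes themselves count.
    """
    path_nodes = net.on_network
    if not include_neighborhood:
        return float(path_nodes.mean())
    covered = path_nodes | path_nodes[net.nbr].any(axis=1)
    return float(covered.mean())


def mean_intersection_distance(net: FrcNetwork) -> float:
    """Mean along-filament distance between adjacent intersections, in um.

    Intersections are nodes where at least three filaments meet.  Each
    filament segment between two intersections contributes its path length;
    dangling segments (ending at a filament tip) are ignored.
    """
    fil_deg = net.filament.sum(axis=1)
    intersections = np.flatnonzero(fil_deg >= 3)
    if len(intersections) < 2:
        raise ValueError(
            f"need >= 2 intersections to measure distances, found {len(intersections)}"
        )
    inter = set(int(i) for i in intersections)
    lengths: list[int] = []
    limit = 2 * net.cfg.n_nodes
    for i in inter:
        for d0 in np.flatnonzero(net.filament[i]):
            prev_dir = int(d0)
            cur = int(net.nbr[i, prev_dir])
            dist = 1
            while cur not in inter and dist < limit:
                outgoing = [
                    int(d)
                    for d in np.flatnonzero(net.filament[cur])
                    if int(d) != int(OPPOSITE[prev_dir])
                ]
                if not outgoing:
                    dist = -1  # dead end
                    break
                if len(outgoing) > 1:  # defensive; cur would be an intersection
                    dist = -1
                    break
                prev_dir = outgoing[0]
                cur = int(net.nbr[cur, prev_dir])
                dist += 1
            if dist > 0 and cur in inter:
                lengths.append(dist)
    if not lengths:
        raise ValueError("no intersection-to-intersection segments found")
    # each segment is walked once from each end; the mean is unaffected
    return float(np.mean(lengths) * net.cfg.edge_length_um)


def calibrate_frc_frequency(
    target_occupancy: float = 0.10,
    cfg: LatticeConfig | None = None,
    params: NetworkParams | None = None,
    weights: WeightParams | None = None,
    n_networks: int = 5,
    seed: int = 0,
    tol: float = 0.004,
) -> float:
    """FRC frequency at which the network occupies ``target_occupancy`` of
    the volume.

    Volume occupancy is measured as the fraction of lattice nodes lying on
    fibre paths (FRC bodies plus filament nodes), matching tracer-labelling
    estimates of the space taken by the reticular network in the spleen.
    Solved by bisection on ``f_frc``; the mean over ``n_networks`` builds is
    used at every evaluation.
    """
    cfg = cfg or LatticeConfig()
    base = params or NetworkParams(mode="dense")
    weights = weights or WeightParams()

    def occupancy(f: float) -> float:
        vals = []
        rng = np.random.default_rng([seed, int(round(f * 1e6))])
        for _ in range(n_networks):
            p = NetworkParams(
                f_frc=f,
                mode=base.mode,
                d_min=base.d_min,
                growth_steps=base.growth_steps,
                chain_length=base.chain_length,
                short_filament_rate=base.short_filament_rate,
            )
            net = build_network(p, weights, cfg, rng, block_edges=False)
            vals.append(net.on_network.mean())
        return float(np.mean(vals))

    n = cfg.n_nodes
    lo, hi = 3.0 / n, 0.5
    for _ in range(25):
        mid = 0.5 * (lo + hi)
        occ = occupancy(mid)
        if abs(occ - target_occupancy) < tol:
            return mid
        if occ < target_occupancy:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# serialization


def _iter_canonical_edges(net: FrcNetwork):
    for u in range(net.cfg.n_nodes):
        for d in range(N_DIRECTIONS):
            if d < OPPOSITE[d] or net.nbr[u, d] == u:
                yield u, int(d)


def save_edge_list(net: FrcNetwork, path: str | Path) -> None:
    """Write the network as a plain-text record (lossless round trip).

    Filament and blocked edges are listed explicitly as coordinate pairs;
    all remaining edges implicitly carry ``w_low``.
    """
    cfg = net.cfg
    buf = io.StringIO()
    buf.write("# frcsim network v1\n")
    buf.write(f"side {cfg.side_length}\n")
    buf.write(f"edge_um {cfg.edge_length_um}\n")
    buf.write(f"w_high {net.weights.w_high}\n")
    buf.write(f"w_low {net.weights.w_low}\n")
    buf.write(f"w_attract {net.weights.w_attract}\n")
    for u in net.frc_nodes:
        buf.write("frc %d %d %d\n" % cfg.coords(int(u)))
    for u, d in _iter_canonical_edges(net):
        v = int(net.nbr[u, d])
        if net.filament[u, d]:
            buf.write("filament %d %d %d %d %d %d\n" % (cfg.coords(u) + cfg.coords(v)))
        elif net.w1[u, d] == 0.0:
            buf.write("blocked %d %d %d %d %d %d\n" % (cfg.coords(u) + cfg.coords(v)))
    for u, ps in sorted(net.partners.items()):
        for v in sorted(ps):
            if u < v:
                buf.write("link %d %d %d %d %d %d\n" % (cfg.coords(u) + cfg.coords(v)))
    Path(path).write_text(buf.getvalue())


def _edge_dir(cfg: LatticeConfig, u: int, v: int, nbr: np.ndarray) -> int:
    for d in range(N_DIRECTIONS):
        if int(nbr[u, d]) == v:
            return d
    raise ValueError(f"nodes {u} and {v} are not lattice neighbours")


def _rebuild_weights(
    filament: np.ndarray,
    blocked_pairs: list[tuple[int, int]],
    weights: WeightParams,
    cfg: LatticeConfig,
    nbr: np.ndarray,
) -> np.ndarray:
    """Directed w1 array from filament topology plus blocked edges."""
    on_network = filament.any(axis=1)
    w1 = np.where(on_network[nbr], weights.w_attract, weights.w_low)
    w1[filament] = weights.w_high
    for u, v in blocked_pairs:
        d = _edge_dir(cfg, u, v, nbr)
        w1[u, d] = w1[v, OPPOSITE[d]] = 0.0
    return w1


def load_edge_list(path: str | Path) -> FrcNetwork:
    """Read a network written by :func:`save_edge_list`."""
    side = None
    edge_um = 7.0
    w_high, w_low, w_attract = 1.0, 0.01, 0.05
    frc: list[int] = []
    filament_pairs: list[tuple[int, int]] = []
    blocked_pairs: list[tuple[int, int]] = []
    links: list[tuple[int, int]] = []
    pending: list[tuple[str, list[str]]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, *rest = line.split()
        if key == "side":
            side = int(rest[0])
        elif key == "edge_um":
            edge_um = float(rest[0])
        elif key == "w_high":
            w_high = float(rest[0])
        elif key == "w_low":
            w_low = float(rest[0])
        elif key == "w_attract":
            w_attract = float(rest[0])
        else:
            pending.append((key, rest))
    if side is None:
        raise ValueError(f"{path}: missing 'side' header")
    cfg = LatticeConfig(side_length=side, edge_length_um=edge_um)
    for key, rest in pending:
        vals = [int(x) for x in rest]
        if key == "frc":
            frc.append(cfg.flat(vals))
        elif key in ("filament", "blocked", "link"):
            u, v = cfg.flat(vals[:3]), cfg.flat(vals[3:])
            {"filament": filament_pairs, "blocked": blocked_pairs, "link": links}[key].append((u, v))
        else:
            raise ValueError(f"{path}: unknown record {key!r}")
    nbr = neighbor_table(cfg)
    filament = np.zeros((cfg.n_nodes, N_DIRECTIONS), dtype=bool)
    for u, v in filament_pairs:
        d = _edge_dir(cfg, u, v, nbr)
        filament[u, d] = filament[v, OPPOSITE[d]] = True
    weights = WeightParams(w_high=w_high, w_low=w_low, w_attract=w_attract)
    w1 = _rebuild_weights(filament, blocked_pairs, weights, cfg, nbr)
    partners: dict[int, set[int]] = {int(u): set() for u in frc}
    for u, v in links:
        partners.setdefault(u, set()).add(v)
        partners.setdefault(v, set()).add(u)
    return FrcNetwork(
        cfg=cfg,
        params=NetworkParams(f_frc=len(frc) / cfg.n_nodes),
        weights=weights,
        frc_nodes=np.array(sorted(frc), dtype=np.int64),
        filament=filament,
        w1=w1,
        partners=partners,
        nbr=nbr,
    )


def to_networkx(net: FrcNetwork) -> nx.Graph:
    """The full lattice graph with filament/blocked edge attributes.

    Directed attraction weights are a deterministic function of the
    topology and the weight parameters, so only topology is stored.
    """
    g = nx.Graph(
        side=net.cfg.side_length,
        edge_um=net.cfg.edge_length_um,
        w_high=net.weights.w_high,
        w_low=net.weights.w_low,
        w_attract=net.weights.w_attract,
    )
    is_frc = net.is_frc
    for u in range(net.cfg.n_nodes):
        g.add_node(u, frc=bool(is_frc[u]))
    for u, d in _iter_canonical_edges(net):
        v = int(net.nbr[u, d])
        g.add_edge(
            u,
            v,
            filament=bool(net.filament[u, d]),
            blocked=bool(net.w1[u, d] == 0.0 and not net.filament[u, d]),
        )
    g.graph["links"] = ";".join(
        f"{u}-{v}" for u, ps in sorted(net.partners.items()) for v in sorted(ps) if u < v
    )
    return g


def save_graphml(net: FrcNetwork, path: str | Path) -> None:
    nx.write_graphml(to_networkx(net), str(path))


def load_graphml(path: str | Path) -> FrcNetwork:
    g = nx.read_graphml(str(path), node_type=int)
    cfg = LatticeConfig(
        side_length=int(g.graph["side"]), edge_length_um=float(g.graph["edge_um"])
    )
    weights = WeightParams(
        w_high=float(g.graph["w_high"]),
        w_low=float(g.graph["w_low"]),
        w_attract=float(g.graph.get("w_attract", 0.05)),
    )
    nbr = neighbor_table(cfg)
    filament = np.zeros((cfg.n_nodes, N_DIRECTIONS), dtype=bool)
    blocked_pairs: list[tuple[int, int]] = []
    for u, v, data in g.edges(data=True):
        d = _edge_dir(cfg, int(u), int(v), nbr)
        if data.get("filament"):
            filament[int(u), d] = filament[int(v), OPPOSITE[d]] = True
        if data.get("blocked"):
            blocked_pairs.append((int(u), int(v)))
    w1 = _rebuild_weights(filament, blocked_pairs, weights, cfg, nbr)
    frc = sorted(int(u) for u, data in g.nodes(data=True) if data.get("frc"))
    partners: dict[int, set[int]] = {u: set() for u in frc}
    link_str = g.graph.get("links", "")
    if link_str:
        for pair in link_str.split(";"):
            u, v = (int(x) for x in pair.split("-"))
            partners.setdefault(u, set()).add(v)
            partners.setdefault(v, set()).add(u)
    return FrcNetwork(
        cfg=cfg,
        params=NetworkParams(f_frc=len(frc) / cfg.n_nodes),
        weights=weights,
        frc_nodes=np.array(frc, dtype=np.int64),
        filament=filament,
        w1=w1,
        partners=partners,
        nbr=nbr,
    )
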