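"""Growth, weighting and characterization of FRC networks."""

import numpy as np
import pytest
from scipy import stats as sps

from frcsim.lattice import N_DIRECTIONS, OPPOSITE, LatticeConfig, neighbor_table
from frcsim.network import (
    FrcNetwork,
    NetworkParams,
    WeightParams,
    assign_blocked_edges,
    build_network,
    calibrate_frc_frequency,
    centrality,
    grow_fibre,
    load_edge_list,
    load_graphml,
    mean_intersection_distance,
    save_edge_list,
    save_graphml,
    surveyed_fraction,
)


def _manual_net(cfg: LatticeConfig, filament_edges, frc=(), weights=None) -> FrcNetwork:
    """Hand-built network from explicit filament edges (coordinate pairs)."""
    weights = weights or WeightParams()
    nbr = neighbor_table(cfg)
    filament = np.zeros((cfg.n_nodes, N_DIRECTIONS), dtype=bool)
    for a, b in filament_edges:
        u, v = cfg.flat(a), cfg.flat(b)
        d = next(dd for dd in range(N_DIRECTIONS) if nbr[u, dd] == v)
        filament[u, d] = filament[v, OPPOSITE[d]] = True
    on = filament.any(axis=1)
    w1 = np.where(on[nbr], weights.w_attract, weights.w_low)
    w1[filament] = weights.w_high
    return FrcNetwork(
        cfg=cfg,
        params=NetworkParams(),
        weights=weights,
        frc_nodes=np.array([cfg.flat(c) for c in frc], dtype=np.int64),
        filament=filament,
        w1=w1,
        partners={},
        nbr=nbr,
    )


def test_grow_fibre_lengths(small_lattice):
    nbr = neighbor_table(small_lattice)
    rng = np.random.default_rng(0)
    path, tip = grow_fibre(0, 1, nbr, rng)
    assert len(path) == 1 and tip == nbr[0, path[0][1]]
    path, tip = grow_fibre(0, 2, nbr, rng)
    assert len(path) == 2
    with pytest.raises(ValueError):
        grow_fibre(0, 0, nbr, rng)


def test_fibre_tip_uniform_over_26_neighbours(small_lattice):
    """Single-step fibre tips are uniform over the 26 directions (chi^2)."""
    nbr = neighbor_table(small_lattice)
    rng = np.random.default_rng(42)
    counts = np.zeros(26)
    for _ in range(10_000):
        path, _ = grow_fibre(0, 1, nbr, rng)
        counts[path[0][1]] += 1
    assert sps.chisquare(counts).pvalue > 0.01


def test_empty_network(small_lattice, empty_net):
    assert len(empty_net.frc_nodes) == 0
    assert not empty_net.filament.any()
    assert np.all(empty_net.w1 == empty_net.weights.w_low)
    assert surveyed_fraction(empty_net) == 0.0


def test_frc_count_matches_target_frequency(small_lattice):
    n = small_lattice.n_nodes
    for f in (0.05, 0.10):
        net = build_network(
            NetworkParams(f_frc=f, mode="sparse"), WeightParams(), small_lattice,
            np.random.default_rng(3),
        )
        assert len(net.frc_nodes) == round(f * n)


def test_invalid_params_rejected(small_lattice):
    with pytest.raises(ValueError):
        NetworkParams(f_frc=1.5)
    with pytest.raises(ValueError):
        # dense mode with fewer than 3 FRC cannot satisfy min connectivity
        build_network(
            NetworkParams(f_frc=1.5 / small_lattice.n_nodes, mode="dense"),
            WeightParams(), small_lattice, np.random.default_rng(0),
        )
    with pytest.raises(ValueError):
        WeightParams(w_high=0.01, w_low=0.01)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_dense_mode_minimum_connectivity(small_lattice, seed):
    """Every FRC in a dense network reaches at least 2 others by fibres."""
    net = build_network(
        NetworkParams(f_frc=0.08, mode="dense"), WeightParams(), small_lattice,
        np.random.default_rng(seed),
    )
    assert min(net.frc_degree(u) for u in net.frc_nodes) >= 2


def test_weight_partition_and_symmetry(dense_net):
    w = dense_net.weights
    allowed = {0.0, w.w_low, w.w_attract, w.w_high}
    assert set(np.unique(dense_net.w1)) <= allowed
    # filament mask is symmetric and filament edges are never blocked
    for u in range(dense_net.cfg.n_nodes):
        for d in range(N_DIRECTIONS):
            v = dense_net.nbr[u, d]
            assert dense_net.filament[u, d] == dense_net.filament[v, OPPOSITE[d]]
            if dense_net.filament[u, d]:
                assert dense_net.w1[u, d] == w.w_high
    # blocking is symmetric (physical obstacles block both directions)
    zero = dense_net.w1 == 0.0
    for u, d in zip(*np.nonzero(zero)):
        assert dense_net.w1[dense_net.nbr[u, d], OPPOSITE[d]] == 0.0


def test_every_node_reachable_despite_blocking(dense_net):
    """BFS over positive-weight edges reaches the whole lattice."""
    n = dense_net.cfg.n_nodes
    seen = np.zeros(n, dtype=bool)
    seen[0] = True
    frontier = [0]
    while frontier:
        nxt = []
        for u in frontier:
            for d in range(N_DIRECTIONS):
                if dense_net.w1[u, d] > 0:
                    v = int(dense_net.nbr[u, d])
                    if not seen[v]:
                        seen[v] = True
                        nxt.append(v)
        frontier = nxt
    assert seen.all()


def test_blocked_edges_bounded_by_filament_count(small_lattice):
    net = build_network(
        NetworkParams(f_frc=0.08, mode="dense"), WeightParams(), small_lattice,
        np.random.default_rng(11), block_edges=False,
    )
    before_zero = int((net.w1 == 0).sum())
    assert before_zero == 0
    assign_blocked_edges(net, np.random.default_rng(12))
    for u in net.frc_nodes:
        u = int(u)
        n_f = int(net.filament[u].sum())
        blocked_here = int((net.w1[u] == 0).sum())
        assert blocked_here <= n_f


def test_blocked_fraction_grows_with_density(small_lattice):
    """Denser networks obstruct more moving directions on average."""
    means = []
    for f in (0.02, 0.08):
        vals = [
            (build_network(
                NetworkParams(f_frc=f, mode="dense"), WeightParams(), small_lattice,
                np.random.default_rng([31, s]),
            ).w1 == 0).mean()
            for s in range(5)
        ]
        means.append(np.mean(vals))
    assert means[1] > means[0]


def test_centrality_uniform_lattice_is_1_over_26(empty_net):
    c = centrality(empty_net)
    assert np.allclose(c, 1 / 26)


def test_centrality_matches_naive_oracle(dense_net):
    """c_i = k_i / sum of neighbour degrees, recomputed by explicit loops."""
    c = centrality(dense_net)
    rng = np.random.default_rng(5)
    for u in rng.integers(dense_net.cfg.n_nodes, size=12):
        k_u = dense_net.w1[u].sum()
        denom = sum(dense_net.w1[int(v)].sum() for v in dense_net.nbr[u])
        assert c[u] == pytest.approx(k_u / denom)
        assert centrality(dense_net, int(u)) == pytest.approx(k_u / denom)


def test_frc_centrality_decreases_with_density():
    """Average centrality over all nodes is flat in f_frc, but a single
    FRC's centrality falls as the network gets denser around it."""
    cfg = LatticeConfig(side_length=10)
    frc_means, all_means = [], []
    for f in (0.02, 0.10):
        vals_frc, vals_all = [], []
        for seed in range(4):
            net = build_network(
                NetworkParams(f_frc=f, mode="dense"), WeightParams(), cfg,
                np.random.default_rng([13, seed]),
            )
            c = centrality(net)
            vals_frc.append(c[net.frc_nodes].mean())
            vals_all.append(c.mean())
        frc_means.append(np.mean(vals_frc))
        all_means.append(np.mean(vals_all))
    assert frc_means[1] < frc_means[0]
    assert all_means[0] == pytest.approx(all_means[1], rel=0.05)


def test_surveyed_fraction_trivial_cases(small_lattice, empty_net):
    assert surveyed_fraction(empty_net) == 0.0
    full = _manual_net(
        small_lattice,
        [((x, y, z), ((x + 1) % 6, y, z)) for x in range(6) for y in range(6) for z in range(6)],
    )
    assert surveyed_fraction(full) == 1.0
    assert surveyed_fraction(full, include_neighborhood=False) == 1.0


def test_surveyed_fraction_monotone_in_density(small_lattice):
    means = []
    for f in (0.02, 0.08):
        vals = [
            surveyed_fraction(
                build_network(
                    NetworkParams(f_frc=f, mode="sparse"), WeightParams(), small_lattice,
                    np.random.default_rng([17, s]),
                )
            )
            for s in range(6)
        ]
        means.append(np.mean(vals))
    assert means[1] > means[0]


def test_intersection_distance_hand_fixture(small_lattice):
    """Two 3-filament intersections joined by a 2-edge path are 14 um apart."""
    a, b = (0, 0, 0), (2, 0, 0)
    edges = [
        (a, (1, 0, 0)), ((1, 0, 0), b),   # the connecting path
        (a, (0, 1, 0)), (a, (0, 0, 1)),   # arms making A an intersection
        (b, (2, 1, 0)), (b, (2, 0, 1)),   # arms making B an intersection
    ]
    net = _manual_net(small_lattice, edges)
    assert mean_intersection_distance(net) == pytest.approx(2 * 7.0)


def test_intersection_distance_requires_intersections(small_lattice):
    chain = _manual_net(small_lattice, [((0, 0, 0), (1, 0, 0)), ((1, 0, 0), (2, 0, 0))])
    with pytest.raises(ValueError):
        mean_intersection_distance(chain)


def test_construction_reproducible(small_lattice):
    kw = dict(params=NetworkParams(f_frc=0.05, mode="dense"), weights=WeightParams())
    a = build_network(kw["params"], kw["weights"], small_lattice, np.random.default_rng(77))
    b = build_network(kw["params"], kw["weights"], small_lattice, np.random.default_rng(77))
    assert np.array_equal(a.w1, b.w1)
    assert np.array_equal(a.filament, b.filament)
    assert np.array_equal(a.frc_nodes, b.frc_nodes)
    assert a.partners == b.partners


def test_round_trips_lossless(tmp_path, dense_net):
    p = tmp_path / "net.txt"
    save_edge_list(dense_net, p)
    back = load_edge_list(p)
    assert np.array_equal(back.w1, dense_net.w1)
    assert np.array_equal(back.filament, dense_net.filament)
    assert np.array_equal(back.frc_nodes, dense_net.frc_nodes)
    assert back.partners == dense_net.partners
    g = tmp_path / "net.graphml"
    save_graphml(dense_net, g)
    back2 = load_graphml(g)
    assert np.array_equal(back2.w1, dense_net.w1)
    assert np.array_equal(back2.filament, dense_net.filament)
    assert np.array_equal(back2.frc_nodes, dense_net.frc_nodes)


def test_calibration_hits_target_occupancy():
    cfg = LatticeConfig(side_length=8)
    f = calibrate_frc_frequency(0.10, cfg=cfg, n_networks=3, seed=5)
    occ = [
        build_network(
            NetworkParams(f_frc=f, mode="dense"), WeightParams(), cfg,
            np.random.default_rng([23, s]),
        ).on_network.mean()
        for s in range(5)
    ]
    assert np.mean(occ) == pytest.approx(0.10, abs=0.03)
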