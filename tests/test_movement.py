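"""Direction sampling: ellipsoid turning weights, multinomial rule, moves."""

import numpy as np
import pytest
from scipy import stats as sps

from frcsim.agents import (
    DC_DENDRITE,
    FREE,
    UNSPECIFIC,
    PopulationConfig,
    initialize_population,
)
from frcsim.lattice import ANGLE_TABLE, DIRECTIONS, direction_index
from frcsim.movement import (
    EllipsoidParams,
    VelocityParams,
    attempt_move,
    direction_probabilities,
    on_network_fraction,
    submoves_this_step,
    turning_weight,
    turning_weight_table,
)
from frcsim.network import WeightParams


def test_turning_weight_closed_form():
    p = EllipsoidParams()  # a=2, b=1, c=0.5
    assert turning_weight(0.0, p) == pytest.approx(p.a)
    assert turning_weight(np.pi, p) == pytest.approx(p.c)
    # continuity at pi/2: both spheroid halves give b
    eps = 1e-9
    assert turning_weight(np.pi / 2 - eps, p) == pytest.approx(p.b, abs=1e-6)
    assert turning_weight(np.pi / 2 + eps, p) == pytest.approx(p.b, abs=1e-6)
    # forward bias: 4x more weight straight on than in reverse
    assert turning_weight(0.0, p) / turning_weight(np.pi, p) == pytest.approx(4.0)
    # closed form at 45 degrees on the forward half
    th = np.pi / 4
    expected = p.a * p.b / np.sqrt(p.b**2 * np.cos(th) ** 2 + p.a**2 * np.sin(th) ** 2)
    assert turning_weight(th, p) == pytest.approx(expected)


def test_ellipsoid_validation():
    with pytest.raises(ValueError):
        EllipsoidParams(a=1.0, b=2.0, c=0.5)
    EllipsoidParams(a=1.0, b=1.0, c=1.0)  # spherical limit allowed


def test_probabilities_normalized_and_match_weights(dense_net):
    p = EllipsoidParams()
    w2 = turning_weight_table(p)
    rng = np.random.default_rng(0)
    for _ in range(20):
        node = int(rng.integers(dense_net.cfg.n_nodes))
        dp = int(rng.integers(26))
        probs = direction_probabilities(node, dense_net, p, d_prev=dp)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        v = dense_net.w1[node] * w2[dp]
        assert np.allclose(probs, v / v.sum())
        # blocked edges receive exactly zero probability
        assert np.all(probs[dense_net.w1[node] == 0.0] == 0.0)


def test_uniform_w1_mode_is_forward(empty_net):
    probs = direction_probabilities(0, empty_net, EllipsoidParams(), d_prev=7)
    assert int(np.argmax(probs)) == 7


def test_single_filament_edge_dominates(empty_net):
    """One high-weight edge straight ahead concentrates the multinomial."""
    net = empty_net
    w = WeightParams()
    node, dp = 0, direction_index((1, 0, 0))
    w1_saved = net.w1[node].copy()
    try:
        net.w1[node] = w.w_low
        net.w1[node, dp] = w.w_high
        probs = direction_probabilities(node, net, EllipsoidParams(), d_prev=dp)
        assert probs[dp] > 0.79
        # oracle: direct evaluation of the two-factor formula
        w2 = turning_weight_table(EllipsoidParams())[dp]
        expected = (w.w_high * w2[dp]) / (
            w.w_high * w2[dp] + w.w_low * (w2.sum() - w2[dp])
        )
        assert probs[dp] == pytest.approx(expected)
    finally:
        net.w1[node] = w1_saved


def test_sampled_frequencies_match_probabilities(dense_net):
    """Multinomial draws agree with the computed probabilities (chi^2)."""
    node = int(dense_net.frc_nodes[0])
    probs = direction_probabilities(node, dense_net, EllipsoidParams(), d_prev=3)
    cs = np.cumsum(dense_net.w1[node] * turning_weight_table(EllipsoidParams())[3])
    rng = np.random.default_rng(123)
    draws = np.searchsorted(cs, rng.random(100_000) * cs[-1], side="right")
    counts = np.bincount(draws, minlength=26)
    keep = probs > 0
    assert counts[~keep].sum() == 0
    p = sps.chisquare(counts[keep], f_exp=probs[keep] * 100_000).pvalue
    assert p > 0.01


def test_attempt_move_outcomes(small_lattice, dense_net):
    grid = initialize_population(
        small_lattice, dense_net, PopulationConfig(scenario="static_target"),
        np.random.default_rng(1),
    )
    cell = grid.cells[0]
    nbrs = dense_net.nbr[cell.position]
    occ = grid.occupancy
    # free target -> moved, old node freed
    free_dirs = [d for d in range(26) if occ[nbrs[d]] == FREE]
    unspec_dirs = [d for d in range(26) if occ[nbrs[d]] == UNSPECIFIC]
    if free_dirs:
        d = free_dirs[0]
        old = cell.position
        assert attempt_move(cell, d, grid) == "moved"
        assert occ[old] == FREE and occ[cell.position] == cell.code
        assert cell.d_prev == d
    # unspecific target -> swapped, counts conserved
    before = np.bincount(occ, minlength=6)
    nbrs = dense_net.nbr[cell.position]
    unspec_dirs = [d for d in range(26) if occ[nbrs[d]] == UNSPECIFIC]
    d = unspec_dirs[0]
    old = cell.position
    assert attempt_move(cell, d, grid) == "swapped"
    assert occ[old] == UNSPECIFIC
    assert np.array_equal(np.bincount(occ, minlength=6), before)
    # DC dendrite -> refused, nothing changes
    dend = grid.dc.dendrites[0][0]
    occ[dense_net.nbr[cell.position, 0]] = DC_DENDRITE  # plant an obstacle
    pos, dp = cell.position, cell.d_prev
    assert attempt_move(cell, 0, grid) == "refused"
    assert cell.position == pos and cell.d_prev == dp


def test_submoves_expectation():
    rng = np.random.default_rng(5)
    assert all(submoves_this_step(True, VelocityParams(1.0), rng) == 1 for _ in range(100))
    assert submoves_this_step(False, VelocityParams(1.5), rng) == 1
    draws = [submoves_this_step(True, VelocityParams(2.5), rng) for _ in range(100_000)]
    assert set(draws) == {2, 3}
    assert np.mean(draws) == pytest.approx(2.5, abs=0.01)


def test_on_network_fraction_trivial(dense_net, empty_net):
    with pytest.raises(ValueError):
        on_network_fraction([], dense_net)
    assert on_network_fraction([(0, 0), (5, 3)], empty_net) == 0.0
    u, d = map(int, np.argwhere(dense_net.filament)[0])
    assert on_network_fraction([(u, d)], dense_net) == 1.0


def test_spherical_limit_is_unbiased_walk(empty_net):
    """With a=b=c and uniform w1, the turning-angle distribution matches the
    brute-force enumeration over all 26x26 direction pairs."""
    p = EllipsoidParams(a=1.0, b=1.0, c=1.0)
    probs = direction_probabilities(0, empty_net, p, d_prev=0)
    assert np.allclose(probs, 1 / 26)
    # empirical angles from iid uniform draws vs exact enumeration
    rng = np.random.default_rng(42)
    seq = rng.integers(26, size=200_000)
    angles = np.round(ANGLE_TABLE[seq[:-1], seq[1:]], 10)
    enum = np.round(ANGLE_TABLE, 10).ravel()  # uniform over all ordered pairs
    values = np.unique(enum)
    f_exp = np.array([(enum == v).mean() for v in values])
    f_obs = np.array([(angles == v).sum() for v in values])
    assert sps.chisquare(f_obs, f_exp * len(angles)).pvalue > 0.01
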