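# Methods

`frcsim` is a 3D cellular-automaton model of T-cell migration and cell–cell
encounter in the T-cell zone of a secondary lymphoid organ. Two coupled
lattices share one cubic geometry: one carries the fibroblastic reticular
cell (FRC) network, the other the cell populations that move along it.
This note records the model, its parameters and units, the calibrations
that fix them, and the limits of what the simulations show.

## Geometry and time

The lattice is a periodic cube of `side_length³` nodes (default 20³ =
8000). Each node holds exactly one cell body; the edge length is one
T-cell diameter, 7 µm, so one move per 0.7-min step gives a base speed of
10 µm/min, within the 9–12 µm/min range reported for naive T cells. Each
node has 26 Moore neighbours; a cell leaving one face reappears on the
opposite face. Runs last at most 400 steps = 280 min, the lower bound of
dwell-time estimates for T cells in lymphoid organs, so contact fractions
are success probabilities for the fastest-passage window.

The cube size is set by tissue bookkeeping rather than convenience: with
~97.5% of nodes occupied by cells and specific T cells at 1–2% of the
T-cell pool, a block of ~8000 nodes corresponds to the 60–120 labelled
specific T cells per imaging volume seen in two-photon experiments. A 30³
cube serves as the larger-volume robustness check. On substantially
smaller lattices a 400-step walk wraps the torus many times and finds any
target almost surely, which abolishes the contact-probability contrasts
the model is built to measure.

## FRC network growth

An FRC is seeded on a uniform random node. From it a fibre grows `l_g`
lattice edges (default 3), choosing a uniformly random direction at every
node; a new FRC is placed at the tip and becomes the next root. After
`chain_length` FRC (default 5) the process re-roots at a fresh random
node, until `round(f_frc · N)` FRC are placed. If a fibre tip lands on an
existing FRC the fibre is kept and the chain re-roots (this prevents
infinite loops at high density). Every FRC additionally launches one
dangling filament of `l_g` edges.

Two network categories model intact versus disrupted tissue:

* **dense** — after growth, any FRC with fewer than 2 distinct fibre
  partners gets a straight repair fibre (deterministic minimum-image
  shortest lattice path, ties broken toward positive offsets) to a
  uniformly chosen other FRC, until all FRC have ≥ 2 partners;
* **sparse** — no connectivity requirement.

`l_g = 3` (≤ 21 µm between FRC) was fixed by requiring the generator to
satisfy the observed saturation property of intact networks: at
`f_frc = 0.10` the network surveys the entire simulated volume in both
modes. With `l_g = 2` sparse networks plateau at ~98.4% coverage, short of
saturation. `chain_length = 5` produces connected sub-trees of the size
seen in schematic reconstructions; coverage and contact results are not
sensitive to it.

**Surveyed volume.** A cell crawling along every filament occupies the
fibre-path nodes and touches their 26-neighbourhoods (membrane contact),
so the surveyed set is the path nodes plus all their neighbours. "Covers
the entire volume" is operationalized as a mean surveyed fraction ≥ 0.995
over 100 networks — all but a handful of the 8000 nodes, the resolution at
which a saturation curve reads as 1. The path-nodes-only variant is
available via `surveyed_fraction(..., include_neighborhood=False)`.

**Volume occupancy and calibration.** The *calibrated density* is the FRC
frequency at which fibre-path nodes occupy 10% of the lattice — the
network share measured by tracer labelling in the white pulp of naive
mice. `calibrate_frc_frequency` solves this by bisection (default: mean of
5 builds per evaluation); at the defaults it returns `f_frc ≈ 0.015`. The
same FRC frequency in sparse mode occupies correspondingly less volume,
mimicking the network loss of persistent infection.

**Intersections.** `mean_intersection_distance` contracts degree-2
filament runs between nodes where ≥ 3 filaments meet and averages the
path lengths (× 7 µm); at the calibrated density it gives ~14 µm,
matching the observed spacing of reticular intersections (on the order of
one to two cell diameters).

## Edge weights (chemokine field)

Each *directed* lattice edge carries an attraction weight `w1`
representing the local CCR7-ligand level:

| edge class                            | weight      | default |
|---------------------------------------|-------------|---------|
| along a filament                      | `w_high`    | 1.0     |
| onto a network node (from anywhere)   | `w_attract` | 0.05    |
| all other moves                       | `w_low`     | 0.01    |
| blocked by spatial obstacles          | 0           |         |

`w_high : w_low = 100 : 1` encodes that cells preferentially crawl along
filaments. The intermediate `w_attract` implements the graded field around
the network — attraction *toward* an FRC is stronger than movement away
from it — and is what lets off-network cells rejoin the scaffold promptly.
It was set once, from a coarse scan, to the value that reproduces the
qualitative behaviour of the system (static-target success flat in
density; moving-target success with an interior maximum; disrupted
networks strictly worse), and then frozen. With `w_attract = w_low` cells
follow filaments only ~40% of the time and density sweeps flatten out;
with `w_attract` near `w_high` cells glue to arbitrarily small network
fragments and tiny networks dominate the sweep. Both regimes contradict
the observed phenomenology.

**Blocked edges.** For an FRC with `n_f` incident filaments, an integer
`b ~ Uniform{0,…,n_f}` of its non-filament edges is set to weight 0 (both
directions): the more filaments converge, the more directions are
physically obstructed. An edge is skipped (re-sampled) if blocking it
would leave either endpoint with no positive outgoing weight, so the
whole lattice stays reachable — asserted by BFS in the test suite.

**Centrality.** Node centrality is `c_i = k_i / Σ_{j∈N(i)} k_j` with
`k_i` the summed weight of node *i*'s outgoing edges — the weighted-degree
form of random-walk centrality. On the uniform lattice every node has
`c_i = 1/26`; averaged over all nodes it is insensitive to network
density, while the mean over FRC falls as the network densifies (each FRC
competes with more high-weight neighbourhood).

## Cell populations

One specific cell pair per run (a deliberately hard 1:1 ratio). Scenarios:

* `static_target` — a naive T cell and a static dendritic cell (DC). The
  DC core sits on or adjacent to an FRC (DC adhere to the network) and
  carries `dendrite_budget` dendrite segments (default 6) in up to 4
  dendrites, initialized fully extended. Each step one terminal segment
  of a random dendrite retracts and one segment extends from a random
  dendrite into a free neighbouring node; the segment count is conserved
  exactly (if no extension is possible the update is skipped). Dendrites
  are self-avoiding and never displace cells. With dendrites at 2/3 of DC
  volume, a budget of 6 corresponds to a DC of ~9 T-cell volumes, within
  imaging-based estimates.
* `moving_target` — a CTL and a motile target cell, both moving by the
  same rule; no DC.
* `walker` — a single motile cell and no target, for pure motility
  analyses.

After the pair (and dendrites) are placed, 2.5% of the remaining nodes are
left free — lymphoid tissue is densely packed — and the rest are filled
with unspecific splenocytes. Unspecific cells are passive: they move only
by swapping with a motile cell.

The dendrite budget is the one free parameter of the static scenario. It
was calibrated once against the no-network baseline: with `f_frc = 0` the
fraction of runs reaching contact within 280 min rises from 0.38 (no
dendrites) through 0.55/0.59 (budgets 2/4) to 0.64 at budget 6 and 0.69
at budget 8; 6 was frozen as the default.

## Movement rule

A motile cell keeps its previous direction `d_prev` (first step: uniform).
The next direction is sampled from

    P(d_i) = w1(edge_i) · w2(θ_i) / Σ_j w1(edge_j) · w2(θ_j)

where `θ_i` is the turning angle between `d_i` and `d_prev` and `w2` is
the radial distance from the centre to the surface of a composite
spheroid: semi-axes `(a, b)` for the forward half (θ ≤ π/2), `(c, b)` for
the backward half, continuous at `b` for θ = π/2:

    w2(θ) = a·b / sqrt(b²cos²θ + a²sin²θ)   (θ ≤ π/2; c replaces a beyond)

Defaults `a = 2, b = 1, c = 0.5` give a 4:1 forward-to-reversal ratio —
turning requires costly actin remodelling, so small angles are preferred —
and produce a turning-angle distribution with most mass below π/2 and
reversals rarest, the shape reported for naive T cells. The spherical
limit `a = b = c` is allowed and reduces the model to an unbiased
26-neighbour walk, which the tests verify against enumeration.

Execution: a sampled move into free space relocates the cell; into an
unspecific splenocyte it swaps the two (regardless of that cell's state);
anything else refuses the move (and leaves `d_prev` unchanged). While a
cell stands on a network node, velocity enhancement ν ∈ {1, 1.5, 2.5}
grants `⌊ν⌋` sub-moves plus one more with probability `ν − ⌊ν⌋`
(expectation ν); direction is re-sampled each sub-move, so persistence
acts through `d_prev` only. One step off the network is always one move.

Contact is evaluated once per time step, after all moves and the dendrite
update. Motile pairs are in contact at wrapped Chebyshev distance 1
(membranes of 7-µm cells on adjacent nodes touch). For the DC, adjacency
to the core or to any dendrite segment is contact by the same argument; a
dendrite tip more than one node away but within `delta_max` establishes
contact with probability `1 − δ/delta_max` (a stand-in for unresolved
membrane flexibility). At the default `delta_max = 1` this partial rule is
inert and contact is pure membrane touch.

## Runs, seeding, outputs

A run couples one network with one freshly initialized population and
iterates: motile cells (fixed order), DC dendrite update, contact check;
it ends at first contact or at 400 steps. Study scale is 100 networks ×
50 runs = 5000 runs per setting. Seeds are hierarchical —
`(master_seed, network_index, run_index)` — so every batch is byte-for-
byte reproducible; per-run CSVs record the contact flag and time, time to
first reach the network, initial pair distance, the fraction of moves
along filament edges, the fraction of time steps spent on network nodes,
and the fraction of moves crossing the periodic boundary.

Two network-following measures are reported deliberately: the *move*
measure (share of executed moves that traverse filament edges) and the
*time* measure (share of steps spent standing on network nodes). A cell
weaving along a fibre path takes occasional diagonal shortcuts between
path nodes, so the time measure — the natural reading of "fraction of
time following the filaments" — runs ~15 points higher; at the calibrated
density it is ~0.8.

## Statistics

* **Exponential fits.** Among successful runs, contact times in minutes
  are fitted by maximum likelihood with a plain exponential: `λ̂ = 1/mean`
  exactly, CI `λ̂(1 ± 1.96/√n)`. Truncation at 280 min is deliberately
  ignored (the histograms are success-conditioned); the closed form
  `conditional_rate_from_success` links a success fraction p over horizon
  T to the rate such a fit recovers under a constant hazard —
  p = 0.64, T = 280 gives 8.6×10⁻³ min⁻¹, which anchors the 10⁻³ min⁻¹
  reporting scale. Coverage of the asymptotic CI is verified ≥ 93% at
  n = 100 on synthetic data.
* **Motility.** The mean scalar displacement (unwrapped — circling the
  torus counts) is regressed through the origin against √t over the late
  75% of the path, where the diffusive law holds; `M = m²/6` in µm²/min.
  For the ideal unbiased walk this recovers the closed form
  `M = 4σ²/(9πΔt)` (the Maxwell factor enters because the fit uses the
  mean, not RMS, displacement).
* **Covariates.** Contacted and non-contacted runs are compared on time-
  to-network and initial distance with per-group quartiles and a
  Mann–Whitney rank test; the comparison table is the artifact.

## What the generator does and does not emulate

The synthetic tissue reproduces: dense packing with rare free space, a
reticular scaffold with realistic spacing and coverage, preferential
crawling along filaments with biologically shaped turning angles,
DC adhesion to the network, and dwell-time-bounded search windows. It
does not model: cell shape and deformation, chemokine diffusion dynamics
(the field is static), DC migration, contact duration or downstream
activation, multiple specific pairs, or network remodelling during a run.
Passing tests therefore support conclusions about *relative* effects of
network density, disruption and velocity enhancement on first-contact
statistics — not absolute encounter rates in real tissue.

## Numerical choices and degenerate inputs

Direction sampling uses cumulative sums and inverse-CDF lookup, so
blocked edges have probability exactly 0; probability vectors are
normalized to 1 within 10⁻¹²; a cell with no positive direction weight
raises a trapped-cell error (unreachable under the reachability guard).
Coordinates are exact integers until converted to µm. `side_length < 3`
is rejected (wrapped neighbours would collide). Networks with < 2
filament intersections make the intersection-distance undefined and raise.
Exponential fits require n ≥ 2 positive times. Dense mode with 0 < FRC < 3
is unsatisfiable and raises. A dendrite update with no free extension
node is skipped to conserve volume.

## Known limitations

Sweep optima are resolved only to the density grid used; the interior
maximum is broad, so the reported optimum is a plateau value rather than
a sharp point. The density sensitivity of disruption damage (dense minus
sparse success) is a robust ordering for moving targets — largest near
the calibrated density, smallest at saturation — but is not resolved for
static targets, whose success is dominated by the DC's dendrites rather
than the network. A saturating network also reshapes the turning-angle
histogram slightly (extra mass at 0 and π: cells run straight along
fibres and shuttle back), though the distribution stays within a
total-variation distance of ~0.15 of the free-tissue one. The 26-neighbourhood quantizes turning angles to 13
values, which makes fine-grained comparison with measured angle
histograms qualitative. At ν > 1 the choice to re-sample direction every
sub-move (rather than freezing it per step) is a modelling decision;
sensitivity was checked only informally. All headline numbers are
Monte-Carlo estimates at 5000 runs per setting: contact fractions carry
±1.4-point binomial error, rate constants ±3% at the observed success
rates.
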