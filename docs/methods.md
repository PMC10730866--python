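# Methods

## The game

Sixty agents occupy the nodes of an undirected simple graph. Time advances
in rounds with four stages:

1. **Offers & stage-1 decisions.** Each ego receives `round(φ·n)` = 12
   offered alters. Every slot first draws a tier — current neighbors with
   probability ψ = 0.5, neighbors-of-neighbors with ξ = 0.3, anyone else
   with the remaining 0.2 — then picks within the tier: with probability ω
   the not-yet-offered candidate whose risk score is closest to the ego's
   (ties to the lowest node id), otherwise uniformly. Exhausted tiers fall
   through in the order neighbor → second-neighbor → other → neighbor,
   which preserves the priority for nearby nodes. For an offered neighbor
   the ego chooses maintain/dissolve; for an offered non-neighbor,
   propose/skip.
2. **Stage-2 decisions.** Proposal recipients accept or decline each
   incoming proposal. Reciprocal simultaneous proposals already carry
   mutual consent and create the tie without a stage-2 item. Dissolution is
   unilateral; creation requires both sides.
3. **Rewards.** Each node is paid (in display points, scale 41.88)

       U = b1·t + b2·(1 − 2|x − α|/max(α, 1−α)) − (c1·t + c2·t²) − σ·[I]

   with the relation part floored at 0. Defaults b1 = 1, c1 = 0.2,
   c2 = 0.067 make six ties optimal (2.388 unscaled ≈ 100 points);
   b2 = 0.5 makes the triad bonus peak at 21 points for x = α; σ = 0.34
   costs an infected node 14 points per round. The triad term is *not*
   floored: maximal mis-clustering loses as much as the optimum gains.
4. **Disease.** Each susceptible node with k infectious neighbors becomes
   infected with probability 1 − (1−γ)^k, γ = 0.15. Within stage 4 the
   transmission draw uses the current infectious set first; then infection
   clocks decrement (reaching zero means permanent recovery); then the new
   infections activate with clock τ = 4. A node infected in stage 4 of
   round k is consequently in state I — penalized and infectious — in
   rounds k+1 … k+4 exactly.

The game ends when no infectious node remains, or after 20 rounds. The
index case is the "most average" node: the argmin of the summed absolute
z-scores of degree, local triad proportion, and risk score (ties to the
lowest id); quantities with zero variance contribute nothing.

## Decision model

Agents are myopic: each opportunity is scored by the one-round change in
*perceived* utility from toggling that single tie against the round-start
network, with no lookahead and no interaction between the 12 slots of a
round. For susceptible egos the infection bracket σ is replaced by the
perceived cost σ^r·π^(2−r): r > 1 amplifies both the perceived severity and
the perceived exposure, r < 1 discounts them, r = 1 recovers the expected
cost σ·π. Infected egos carry the constant σ (irrelevant to deltas);
recovered egos carry nothing. An exact-zero delta resolves to the status
quo (inertia). Note a structural subtlety of the perceived-cost form:
σ^r·π^(2−r) = π²·(σ/π)^r increases with r only while π < σ; with σ = 0.34
this covers one infectious neighbor (π = 0.15) but reverses for π > 0.34,
so avoidance is strictly ordered in r at the canonical single-exposure
margin while high-exposure states can locally reverse the ordering of
mildly risk-seeking vs risk-neutral agents. Aggregate avoidance over games
remains monotone within Monte-Carlo error, which is how the test suite
asserts it.

Three behavioral extensions, all off by default, widen the model:
`ext_risk_weight` multiplies the perceived cost; `ext_p_reward_seeking`
makes each decision reward-seeking only with the given probability (with
the complement, and a non-infected alter, the agent picks uniformly between
the two actions); `ext_penalty_all_egos` applies the perceived cost to
infected and recovered egos as well, modeling avoidance of infected alters
irrespective of the ego's own risk.

## Baseline networks

Both baselines have 60 nodes and exactly 178 edges — the only edge count
whose mean degree 2·178/60 = 5.9333 prints as 5.93 — and are connected.
They are built to be (near-)equilibria of the no-disease utility, so that
relational churn during a game is attributable to the epidemic, not to an
unrelaxed start. "Equilibrium" is operationalized as pairwise stability:
no ego strictly gains from dropping an incident tie, and no absent tie
would strictly benefit both endpoints. `equilibrium_fraction` reports the
fraction of nodes with no such improving move.

**LO** (α = 0, target mean local clustering 0.06) is constructed directly:

* three 3×3 "grid blocks" (27 nodes) wired with row and column triangles —
  each block node gets exactly two vertex-disjoint closed neighbor pairs,
  and 27·(2/15)/60 = 0.06 exactly;
* a hub with four degree-5 spokes, absorbing the 4-degree deficit below
  6-regularity (356 = 56·6 + 4·5 degree ends); the spokes sit pairwise at
  distance 2 through the hub, so connecting any two would close a triad
  and cost more than a sixth relation gains;
* a seeded, randomized triangle-free matching of all remaining stubs,
  retried until connected.

Every node is pairwise-stable (the fraction is 1.0), and the construction
reproduces the published closeness value (0.975) without targeting it.

**HI** (α = 0.67, target 0.62) cannot be an exact equilibrium at that
clustering level: full-stability analysis shows the stable homogeneous
configurations are bridged 6-cliques (mean local clustering 0.689) and
distance-≤3 circulant bands (0.600), and every interpolation needs
boundary nodes with a utility-improving move. The generator therefore uses
a hybrid scaffold — a 52-node circulant arc (stable at local clustering
0.6) plus one 8-node pocket wired as K8 minus a perfect matching (stable
at 0.8) — and places the ~20 junction edges where the arc meets the pocket
by a seeded, objective-driven annealed swap search followed by a greedy
single-swap descent. The objective penalizes utility-improving moves
(count and magnitude), deviation of total clustering from the target,
disconnection, and edge-count error. The accepted structure has 178 edges,
is connected, has mean local clustering 0.6223 and 59/60 pairwise-stable
nodes, and is cached per process (the search takes about a minute).
Per-seed variation applies a random node relabeling, which preserves every
structural metric exactly. Closeness lands at 0.93 against the published
0.955; closeness was kept a soft, untargeted objective because its
normalization (1 − (d̄−1)/(n−1)) is itself a modeling choice.

## Participants

Risk scores are drawn from a normal distribution with mean 1.27 and SD
0.45 truncated to (0, 2) (truncation pulls the realized mean to 1.22).
Assignment to nodes sorts the scores ascending and maps them onto a fixed
node ordering: under assortative mixing (AS) a spectral ordering — nodes
sorted by the Fiedler vector of the graph Laplacian, the classic relaxation
of minimum linear arrangement — so neighbors receive similar ranks (edge
correlation ≈ 0.7 on both baselines); under random mixing (RA) a fixed
stride-37 interleaving of the same ordering (|correlation| ≈ 0.03). The
staircase module converts five safe/gamble choices into one of 32 terminal
positions (binary path encoding) and linearly onto the score range, 2.0
(most risk-averse) to 0.0; amounts start at 160 and bisect with halving
steps 80/40/20/10. The simulated responder plays safe whenever the
guaranteed amount reaches its threshold 160·(2 − r), chosen so that every
terminal position is reachable and the recovered score is weakly monotone
in the true r.

## Experimental design

A batch runs 48 sessions × 2 games: clustering alternates within a session
and the first game's setting alternates between sessions; mixing alternates
every second session (LO:RA, HI:RA | HI:RA, LO:RA | LO:AS, HI:AS | …),
giving 24 games per condition. Scores are sampled once per session and
reused by both games. All randomness flows from one master seed through
`numpy.random.SeedSequence` spawning, so batches are bit-reproducible.

## What the simulations do and do not show

The agents are the model's idealized decision-makers; runs reproduce the
model's mechanism-level claims — susceptible egos dissolve ties to
infected alters, avoidance strengthens with risk aversion, ω-weighted
offers sustain assortative mixing — but not human behavior: real
participants avoided more strongly, isolated infected nodes further, and
neglected clustering, which is why simulated epidemics here are much larger
(final sizes routinely 0.3–0.9 on the low-clustering baseline) than the
experimentally observed medians. Reproducing the human decision tables
would require the human dataset and is out of scope; the exporter writes
regression-ready decision logs instead of fitting multilevel models.

## Numerical choices and test scale

Internal arithmetic is unrounded; printed points are rounded to integers.
Tie-breaks are always to the lowest node id; exact-zero deltas to the
status quo. The rank-sum comparison of final sizes uses the two-sided
normal approximation with tie correction. Monte-Carlo checks in the test
suite use 10⁴ offer slots (tier mixture, ±1 pp), 10⁴ transmission draws
(±0.01), 50 games per risk level for the avoidance-monotonicity check, and
12 ten-round runs per ω arm (with γ raised to 0.3 in that check so enough
rewiring occurs for the offer mechanism to express itself). The full-batch
check runs all 96 games at default parameters.

## Known limitations

* The HI baseline has one node short of full pairwise stability; its
  single improving move is worth ~0.5 unscaled utility, and the node
  typically rewires in round 1.
* Perceived risk uses the ego's current infectious-neighbor count only; no
  anticipation of alters' future states (by design — the model is myopic).
* The staircase responder is deterministic; no choice noise.
* Unresponsive participants are not modeled (all 60 agents act each
  round).
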