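"""Stage-4 disease dynamics: transmission, recovery, index-case choice.

Discrete-time SIR with per-contact transmission probability ``gamma`` and a
fixed infectious period of ``tau`` rounds.  Within a round's stage 4 the
order of operations is: (1) transmission draws against the current infectious
set, (2) clock decrement of currently infected nodes (reaching zero means
permanent recovery), (3) activation of the newly drawn infections with a
fresh clock.  A node infected in stage 4 of round *k* is therefore in state I
(and penalized, and infectious) during rounds *k+1* .. *k+tau* and recovered
from round *k+tau+1* on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set

import numpy as np

from .model_core import DiseaseState, ParamSet, SimNetwork, local_triad_proportion


@dataclass
class EpidemicTrace:
    """Per-round S/I/R counts and the infection/recovery event log."""

    counts: List[Dict[str, int]] = field(default_factory=list)
    ever_infected: Set[int] = field(default_factory=set)
    infection_round: Dict[int, int] = field(default_factory=dict)
    recovery_round: Dict[int, int] = field(default_factory=dict)

    def record_counts(self, net: SimNetwork) -> None:
        c = net.count_states()
        self.counts.append({s.value: c[s] for s in DiseaseState})


def infection_probability(k: int, p: ParamSet) -> float:
    """Per-round infection probability with *k* infectious neighbors:
    ``1 - (1 - gamma)^k``."""
    if k < 0:
        raise ValueError("infectious-neighbor count cannot be negative")
    return 1.0 - (1.0 - p.gamma) ** k


def transmission_step(net: SimNetwork, p: ParamSet, rng: np.random.Generator) -> Set[int]:
    """Draw new infections for every susceptible node (mutating the network).

    Each susceptible node independently becomes infected with probability
    ``infection_probability`` of its current count of infectious neighbors;
    newly infected nodes receive ``infection_clock = tau`` and count as
    infected from the next round on.  Draws are made in node-id order so a
    fixed generator state yields a fixed outcome.
    """
    newly: Set[int] = set()
    for i in net.nodes():
        if net.state[i] is not DiseaseState.S:
            continue
        k = net.infected_neighbor_count(i)
        if k == 0:
            continue
        if rng.random() < infection_probability(k, p):
            newly.add(i)
    for i in newly:
        net.set_infected(i, p.tau)
    return newly


def recovery_step(net: SimNetwork, p: ParamSet) -> Set[int]:
    """Decrement infection clocks; nodes reaching zero recover permanently."""
    recovered: Set[int] = set()
    for i in net.nodes():
        if net.state[i] is DiseaseState.I:
            net.infection_clock[i] -= 1
            if net.infection_clock[i] <= 0:
                net.infection_clock[i] = 0
                net.state[i] = DiseaseState.R
                recovered.add(i)
    return recovered


def stage4(net: SimNetwork, p: ParamSet, rng: np.random.Generator,
           trace: EpidemicTrace, round_no: int) -> None:
    """One full stage 4: transmissions, then recoveries, then activation.

    Transmission draws happen before the clock decrement so that a node is
    infectious in the draws of every round it spends in state I.
    """
    # transmission_step activates immediately; emulate draw-then-activate by
    # drawing against a frozen infectious set first.
    frozen = net.copy()
    newly = transmission_step(frozen, p, rng)
    recovered = recovery_step(net, p)
    for i in recovered:
        trace.recovery_round[i] = round_no
    for i in newly:
        net.set_infected(i, p.tau)
        trace.ever_infected.add(i)
        trace.infection_round[i] = round_no


def select_index_case(net: SimNetwork, scores: Sequence[float]) -> int:
    """Most average node: argmin of summed absolute z-scores of degree, local
    clustering, and risk aversion score; ties broken by lowest node id.

    A quantity with zero variance across nodes contributes nothing.
    """
    if net.n == 0:
        raise ValueError("empty network")
    if len(scores) != net.n:
        raise ValueError("scores must cover all nodes")
    feats = np.array(
        [
            [net.degree(i) for i in net.nodes()],
            [local_triad_proportion(net, i) for i in net.nodes()],
            list(scores),
        ],
        dtype=float,
    )
    total = np.zeros(net.n)
    for row in feats:
        sd = row.std()
        if sd > 0:
            total += np.abs((row - row.mean()) / sd)
    return int(np.argmin(total))  # argmin returns the first (lowest id) minimum
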