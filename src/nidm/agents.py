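"""Myopic decision policy over opportunities.

Agents evaluate each offered tie change by its immediate one-round effect on
their *perceived* utility: the objective relation and triad reward terms,
with the infection cost replaced by the risk-perceived cost for susceptible
egos.  Each opportunity is judged independently against the
round-start network (no combinatorial lookahead), dissolution is unilateral,
creation needs both sides to gain.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .epidemic import infection_probability
from .model_core import DiseaseState, ParamSet, SimNetwork, local_triad_proportion
from .opportunities import Opportunity, OpportunityKind
from .rewards import perceived_infection_cost, relation_value, triad_value


class Action(str, Enum):
    CREATE_PROPOSE = "create_propose"
    NOT_PROPOSE = "not_propose"
    ACCEPT = "accept"
    DECLINE = "decline"
    DISSOLVE = "dissolve"
    MAINTAIN = "maintain"


@dataclass(frozen=True)
class Decision:
    """An opportunity together with the ego's resolved action and the
    perceived utility delta that drove it (positive favors the tie)."""

    opportunity: Opportunity
    action: Action
    perceived_delta: float
    ego_state: DiseaseState
    alter_state: DiseaseState
    alter_has_infected_neighbor: bool


def perceived_utility(net: SimNetwork, i: int, p: ParamSet) -> float:
    """Unscaled perceived utility of node *i* on the given network.

    The infection bracket depends on the ego's state: susceptible egos incur
    the perceived cost ``sigma^r * pi^(2-r)`` with ``pi`` computed from their
    current infectious neighbors; infected egos incur the (decision-
    irrelevant) objective ``sigma``; recovered egos incur nothing.  With the
    ``ext_penalty_all_egos`` extension, infected and recovered egos incur the
    perceived cost as well.
    """
    t = net.degree(i)
    x = local_triad_proportion(net, i)
    value = relation_value(t, p) + triad_value(x, p)
    state = net.state[i]
    if state is DiseaseState.S:
        pi = infection_probability(net.infected_neighbor_count(i), p)
        value -= perceived_infection_cost(net.risk_score[i], pi, p)
    elif state is DiseaseState.I:
        value -= p.sigma
        if p.ext_penalty_all_egos:
            pi = infection_probability(net.infected_neighbor_count(i), p)
            value -= perceived_infection_cost(net.risk_score[i], pi, p)
    else:  # recovered
        if p.ext_penalty_all_egos:
            pi = infection_probability(net.infected_neighbor_count(i), p)
            value -= perceived_infection_cost(net.risk_score[i], pi, p)
    return value


def tie_delta(net: SimNetwork, ego: int, alter: int, p: ParamSet) -> float:
    """Perceived utility of the ego with the (ego, alter) tie present minus
    with it absent, all other ties fixed at the round-start state."""
    if ego == alter:
        raise ValueError("ego and alter must differ")
    had = net.has_edge(ego, alter)
    if had:
        with_tie = perceived_utility(net, ego, p)
        net.remove_edge(ego, alter)
        without_tie = perceived_utility(net, ego, p)
        net.add_edge(ego, alter)
    else:
        without_tie = perceived_utility(net, ego, p)
        net.add_edge(ego, alter)
        with_tie = perceived_utility(net, ego, p)
        net.remove_edge(ego, alter)
    return with_tie - without_tie


def _resolve(
    opp: Opportunity,
    delta: float,
    net: SimNetwork,
    p: ParamSet,
    rng: np.random.Generator,
) -> Action:
    """Map a delta to an action; exact zero resolves to the status quo.

    With probability ``1 - ext_p_reward_seeking`` and a non-infected alter,
    the action is instead drawn uniformly between the two options.
    """
    kind = opp.kind
    if kind is OpportunityKind.DISSOLVE_OR_MAINTAIN:
        pro, contra = Action.MAINTAIN, Action.DISSOLVE
        status_quo = Action.MAINTAIN
    elif kind is OpportunityKind.PROPOSE_OR_NOT:
        pro, contra = Action.CREATE_PROPOSE, Action.NOT_PROPOSE
        status_quo = Action.NOT_PROPOSE
    else:
        pro, contra = Action.ACCEPT, Action.DECLINE
        status_quo = Action.DECLINE
    if (
        p.ext_p_reward_seeking < 1.0
        and net.state[opp.alter] is not DiseaseState.I
        and rng.random() >= p.ext_p_reward_seeking
    ):
        return pro if rng.random() < 0.5 else contra
    if delta > 0:
        return pro
    if delta < 0:
        return contra
    return status_quo


def _decide(
    opportunities: Iterable[Opportunity],
    net: SimNetwork,
    p: ParamSet,
    rng: np.random.Generator,
) -> List[Decision]:
    decisions = []
    for opp in opportunities:
        delta = tie_delta(net, opp.ego, opp.alter, p)
        action = _resolve(opp, delta, net, p, rng)
        decisions.append(
            Decision(
                opportunity=opp,
                action=action,
                perceived_delta=delta,
                ego_state=net.state[opp.ego],
                alter_state=net.state[opp.alter],
                alter_has_infected_neighbor=net.infected_neighbor_count(opp.alter) > 0,
            )
        )
    return decisions


def stage1_decide(
    ego: int,
    opportunities: Sequence[Opportunity],
    net: SimNetwork,
    p: ParamSet,
    rng: np.random.Generator,
) -> List[Decision]:
    """Resolve one ego's stage-1 opportunities (maintain/dissolve existing
    ties, propose/skip absent ones), each against the round-start network."""
    return _decide(opportunities, net, p, rng)


def stage2_decide(
    ego: int,
    incoming: Sequence[Opportunity],
    net: SimNetwork,
    p: ParamSet,
    rng: np.random.Generator,
) -> List[Decision]:
    """Resolve one ego's incoming proposals: accept iff the tie delta is
    strictly positive, evaluated against the round-start network."""
    return _decide(incoming, net, p, rng)


def apply_round_decisions(
    net: SimNetwork,
    stage1_decisions: Sequence[Decision],
    stage2_decisions: Sequence[Decision],
    auto_created: Iterable[Tuple[int, int]] = (),
) -> SimNetwork:
    """Apply a round's resolved decisions to a copy of the network.

    Dissolutions first (unilateral: one endpoint choosing dissolve removes
    the tie), then consented creations (stage-1 proposal plus stage-2
    acceptance, or reciprocal simultaneous proposals).
    """
    out = net.copy()
    for d in stage1_decisions:
        if d.action is Action.DISSOLVE:
            out.remove_edge(d.opportunity.ego, d.opportunity.alter)
    accepted = [
        (d.opportunity.alter, d.opportunity.ego)
        for d in stage2_decisions
        if d.action is Action.ACCEPT
    ]
    for proposer, target in accepted:
        out.add_edge(proposer, target)
    for u, v in auto_created:
        out.add_edge(u, v)
    return out
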