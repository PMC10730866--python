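"""Stage-1 opportunity selection and stage-2 proposal collection.

Each round every ego is offered ``round(phi * n)`` distinct alters (12 for a
60-node network).  Every slot first draws a tier — current neighbors with
probability ``psi``, neighbors-of-neighbors with probability ``xi``, anyone
else with the remainder — and then picks within the tier: with probability
``omega`` the not-yet-offered candidate whose risk score is closest to the
ego's (this is the mechanism that sustains assortative mixing), otherwise
uniformly at random.  Exhausted tiers fall through in the order
neighbor -> second-neighbor -> other -> neighbor, preserving the rule that
nodes closer to the ego are prioritized.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from .model_core import ParamSet, SimNetwork


class OpportunityKind(str, Enum):
    DISSOLVE_OR_MAINTAIN = "dissolve_or_maintain"
    PROPOSE_OR_NOT = "propose_or_not"
    ACCEPT_OR_DECLINE = "accept_or_decline"


@dataclass(frozen=True)
class Opportunity:
    """One offered alter for one ego, with round/stage provenance."""

    round: int
    stage: int
    ego: int
    alter: int
    kind: OpportunityKind

    def __post_init__(self) -> None:
        if self.ego == self.alter:
            raise ValueError("ego and alter must differ")
        if self.stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")


def n_offers(net: SimNetwork, p: ParamSet) -> int:
    """Number of opportunity slots per ego: ``phi * n`` rounded to nearest.

    Networks with fewer than 12 other nodes (the experiment's offer count)
    degenerate to offering everyone.
    """
    if net.n - 1 < 12:
        return net.n - 1
    return int(round(p.phi * net.n))


def second_neighbors(net: SimNetwork, ego: int) -> Set[int]:
    """Neighbors of neighbors, excluding the ego and its direct neighbors."""
    out: Set[int] = set()
    for j in net.adj[ego]:
        out |= net.adj[j]
    out.discard(ego)
    return out - net.adj[ego]


def select_opportunities(
    ego: int,
    net: SimNetwork,
    scores: Sequence[float],
    p: ParamSet,
    rng: np.random.Generator,
    round_no: int = 1,
) -> List[Opportunity]:
    """Select the round's offered alters for one ego.

    Returns one :class:`Opportunity` per slot, of kind dissolve-or-maintain
    for existing ties and propose-or-not for absent ones.  If fewer than
    ``round(phi*n)`` other nodes exist, all of them are offered.
    """
    net._check_node(ego)
    k = n_offers(net, p)
    tiers: Dict[int, Set[int]] = {
        0: set(net.adj[ego]),
        1: second_neighbors(net, ego),
    }
    tiers[2] = set(net.nodes()) - {ego} - tiers[0] - tiers[1]
    probs = np.array([p.psi, p.xi, 1.0 - p.psi - p.xi])
    probs = probs / probs.sum()

    chosen: List[int] = []
    available = net.n - 1
    k = min(k, available)
    while len(chosen) < k:
        tier_idx = int(rng.choice(3, p=probs))
        # fall through exhausted tiers: neighbor -> second -> other -> neighbor
        for step in range(3):
            idx = (tier_idx + step) % 3
            if tiers[idx]:
                tier_idx = idx
                break
        else:
            break  # everything offered already
        pool = tiers[tier_idx]
        if p.omega > 0.0 and rng.random() < p.omega:
            alter = min(pool, key=lambda j: (abs(scores[j] - scores[ego]), j))
        else:
            alter = int(rng.choice(sorted(pool)))
        pool.discard(alter)
        chosen.append(alter)

    return [
        Opportunity(
            round=round_no,
            stage=1,
            ego=ego,
            alter=alter,
            kind=(
                OpportunityKind.DISSOLVE_OR_MAINTAIN
                if alter in net.adj[ego]
                else OpportunityKind.PROPOSE_OR_NOT
            ),
        )
        for alter in chosen
    ]


def collect_stage2_opportunities(
    proposals: Sequence[Tuple[int, int]],
    net: SimNetwork,
    round_no: int = 1,
) -> Tuple[Dict[int, List[Opportunity]], Set[Tuple[int, int]]]:
    """Group stage-1 proposals into per-target accept-or-decline opportunities.

    Reciprocal proposals (A proposed to B and B to A in the same round)
    already carry mutual consent and auto-resolve as created ties; they are
    returned separately and generate no stage-2 decision.  A proposal over an
    existing tie is a protocol violation and raises.
    """
    seen = set(proposals)
    incoming: Dict[int, List[Opportunity]] = {}
    auto_created: Set[Tuple[int, int]] = set()
    for proposer, target in proposals:
        if net.has_edge(proposer, target):
            raise ValueError(
                f"proposal over an existing tie ({proposer}, {target})"
            )
        if (target, proposer) in seen:
            auto_created.add((min(proposer, target), max(proposer, target)))
            continue
        incoming.setdefault(target, []).append(
            Opportunity(
                round=round_no,
                stage=2,
                ego=target,
                alter=proposer,
                kind=OpportunityKind.ACCEPT_OR_DECLINE,
            )
        )
    return incoming, auto_created
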