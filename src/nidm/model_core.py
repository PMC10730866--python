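"""Domain types and structural graph metrics.

The simulator operates on an undirected simple graph of 60 agents ("nodes"),
each carrying an SIR disease state, a remaining-infection clock, a risk
aversion score :math:`r_i \\in (0, 2)` and a running point total.  This module
holds the parameter container, the network container, the experimental
condition descriptor, and the four structural statistics used throughout:
local triad proportion (local clustering), mean degree, a normalized
closeness index, and the edgewise risk-score correlation (homophily).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from enum import Enum
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np


class DiseaseState(str, Enum):
    """SIR compartment of a node."""

    S = "S"
    I = "I"
    R = "R"


class Clustering(str, Enum):
    """Baseline-network setting: one large sparse cluster vs several dense ones."""

    LO = "LO"
    HI = "HI"


class Mixing(str, Enum):
    """Score-to-node assignment setting: random vs assortative mixing."""

    RA = "RA"
    AS = "AS"


#: Per-condition preferred triad proportion: LO rewards open neighborhoods,
#: HI rewards two thirds of neighbor pairs being closed.
ALPHA_BY_CLUSTERING = {Clustering.LO: 0.0, Clustering.HI: 0.67}

#: Per-condition similarity-pick probability for opportunity selection.
OMEGA_BY_MIXING = {Mixing.RA: 0.0, Mixing.AS: 0.8}


@dataclass(frozen=True)
class ParamSet:
    """All model constants.

    Defaults reproduce the published experiment settings: the relation-reward
    polynomial peaks at six relations, the triad bonus is worth up to half a
    relation-optimum, infection costs 0.34 unscaled utility per round, and
    points are displayed after multiplying by ``scale``.

    Attributes
    ----------
    b1, c1, c2 : float
        Benefit and (marginally increasing) cost weights for the number of
        relations ``t``; the relation term is ``b1*t - c1*t - c2*t**2``.
    b2 : float
        Weight of the triad-closure term.
    alpha : float
        Preferred proportion of closed triads in [0, 1].
    sigma : float
        Unscaled utility cost per round of being infected.
    gamma : float
        Per-infectious-neighbor transmission probability per round.
    tau : int
        Rounds a node remains infected before permanent recovery.
    phi : float
        Fraction of the network offered to each ego per round
        (``round(phi * n)`` opportunity slots).
    psi, xi : float
        Per-slot probabilities that an offered node is drawn from the
        neighbor tier resp. the neighbor-of-neighbor tier (remainder:
        anyone else).
    omega : float
        Probability that a slot picks the most risk-similar candidate in its
        tier instead of a uniform one.
    scale : float
        Point scaling factor applied to displayed/realized rewards.
    max_rounds : int
        Hard cap on game length.
    clamp_relation_reward : bool
        Floor the relation term at zero (the published rule: more than 11
        relations never costs points).
    ext_risk_weight : float
        Multiplicative weight on the perceived infection cost (behavioral
        extension; 1.0 recovers the base model).
    ext_p_reward_seeking : float
        Probability that a decision is reward-seeking; with the complementary
        probability (and a non-infected alter) the agent picks uniformly
        between the two available actions (behavioral extension; 1.0 recovers
        the base model).
    ext_penalty_all_egos : bool
        Apply the perceived infection cost to infected and recovered egos as
        well (behavioral extension; off recovers the base model).
    """

    b1: float = 1.0
    c1: float = 0.2
    c2: float = 0.067
    b2: float = 0.5
    alpha: float = 0.0
    sigma: float = 0.34
    gamma: float = 0.15
    tau: int = 4
    phi: float = 0.2
    psi: float = 0.5
    xi: float = 0.3
    omega: float = 0.0
    scale: float = 41.88
    max_rounds: int = 20
    clamp_relation_reward: bool = True
    ext_risk_weight: float = 1.0
    ext_p_reward_seeking: float = 1.0
    ext_penalty_all_egos: bool = False

    def __post_init__(self) -> None:
        for name in ("alpha", "gamma", "phi", "psi", "xi", "omega",
                     "ext_p_reward_seeking"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        if self.psi + self.xi > 1.0 + 1e-12:
            raise ValueError("psi + xi must not exceed 1")
        if self.tau < 1:
            raise ValueError(f"tau must be a positive integer, got {self.tau!r}")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be positive")
        if self.ext_risk_weight < 0:
            raise ValueError("ext_risk_weight must be nonnegative")
        if max(self.alpha, 1.0 - self.alpha) <= 0:
            raise ValueError("alpha is degenerate")

    def for_condition(self, condition: "Condition") -> "ParamSet":
        """Parameter set with alpha and omega resolved from a condition."""
        return replace(
            self,
            alpha=ALPHA_BY_CLUSTERING[condition.clustering],
            omega=OMEGA_BY_MIXING[condition.mixing],
        )


@dataclass(frozen=True)
class Condition:
    """One cell of the 2x2 design plus its position in the session schedule."""

    clustering: Clustering
    mixing: Mixing
    session_index: int = 1
    game_index_within_session: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.game_index_within_session not in (1, 2):
            raise ValueError("game_index_within_session must be 1 or 2")

    @property
    def label(self) -> str:
        return f"{self.clustering.value}:{self.mixing.value}"


class SimNetwork:
    """Undirected simple graph with per-node disease bookkeeping.

    Adjacency is kept as a dict of sets for fast tie toggling during utility
    evaluation; conversion to :class:`networkx.Graph` is provided for metrics
    and serialization.  Invariants: no self-loops, no multi-edges, symmetric
    adjacency, ``infection_clock[i] > 0`` iff ``state[i] == I``.
    """

    def __init__(
        self,
        n: int,
        edges: Iterable[Tuple[int, int]] = (),
        risk_scores: Optional[Sequence[float]] = None,
    ) -> None:
        if n <= 0:
            raise ValueError("network must have at least one node")
        self.n = n
        self.adj: Dict[int, Set[int]] = {i: set() for i in range(n)}
        self.state: List[DiseaseState] = [DiseaseState.S] * n
        self.infection_clock: List[int] = [0] * n
        self.risk_score: List[float] = (
            list(risk_scores) if risk_scores is not None else [1.0] * n
        )
        if len(self.risk_score) != n:
            raise ValueError("risk_scores length must equal n")
        self.cumulative_points: List[float] = [0.0] * n
        for u, v in edges:
            self.add_edge(u, v)

    # -- graph structure -------------------------------------------------

    def _check_node(self, i: int) -> None:
        if i not in self.adj:
            raise KeyError(f"unknown node id {i!r}")

    def nodes(self) -> range:
        return range(self.n)

    def has_edge(self, u: int, v: int) -> bool:
        self._check_node(u)
        self._check_node(v)
        return v in self.adj[u]

    def add_edge(self, u: int, v: int) -> None:
        self._check_node(u)
        self._check_node(v)
        if u == v:
            raise ValueError("self-loops are not allowed")
        self.adj[u].add(v)
        self.adj[v].add(u)

    def remove_edge(self, u: int, v: int) -> None:
        self._check_node(u)
        self._check_node(v)
        self.adj[u].discard(v)
        self.adj[v].discard(u)

    def degree(self, i: int) -> int:
        self._check_node(i)
        return len(self.adj[i])

    def neighbors(self, i: int) -> Set[int]:
        self._check_node(i)
        return self.adj[i]

    def edges(self) -> Iterator[Tuple[int, int]]:
        for u in range(self.n):
            for v in self.adj[u]:
                if u < v:
                    yield (u, v)

    @property
    def num_edges(self) -> int:
        return sum(len(s) for s in self.adj.values()) // 2

    # -- disease bookkeeping ---------------------------------------------

    def set_infected(self, i: int, clock: int) -> None:
        self._check_node(i)
        if clock < 1:
            raise ValueError("infection clock must be >= 1")
        self.state[i] = DiseaseState.I
        self.infection_clock[i] = clock

    def infected_neighbor_count(self, i: int) -> int:
        self._check_node(i)
        return sum(1 for j in self.adj[i] if self.state[j] is DiseaseState.I)

    def count_states(self) -> Dict[DiseaseState, int]:
        counts = {s: 0 for s in DiseaseState}
        for s in self.state:
            counts[s] += 1
        return counts

    # -- conversion / copying --------------------------------------------

    def copy(self) -> "SimNetwork":
        out = SimNetwork(self.n, risk_scores=self.risk_score)
        out.adj = {i: set(s) for i, s in self.adj.items()}
        out.state = list(self.state)
        out.infection_clock = list(self.infection_clock)
        out.cumulative_points = list(self.cumulative_points)
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges())
        for i in range(self.n):
            g.nodes[i]["disease_state"] = self.state[i].value
            g.nodes[i]["risk_score"] = self.risk_score[i]
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "SimNetwork":
        mapping = {node: idx for idx, node in enumerate(sorted(g.nodes()))}
        net = cls(g.number_of_nodes())
        for u, v in g.edges():
            net.add_edge(mapping[u], mapping[v])
        return net


# -- structural metrics ----------------------------------------------------


def local_triad_proportion(net: SimNetwork, i: int) -> float:
    """Proportion of the ego's neighbor pairs that are themselves connected.

    Nodes with fewer than two neighbors have no possible closed triads and
    return 0 (the triad utility term then evaluates at ``x = 0``).
    """
    net._check_node(i)
    neigh = net.adj[i]
    d = len(neigh)
    if d < 2:
        return 0.0
    closed = 0
    for u, v in itertools.combinations(neigh, 2):
        if v in net.adj[u]:
            closed += 1
    return closed / (d * (d - 1) / 2)


def network_clustering(net: SimNetwork) -> float:
    """Mean of the local triad proportion over all nodes."""
    return sum(local_triad_proportion(net, i) for i in net.nodes()) / net.n


def mean_degree(net: SimNetwork) -> float:
    """Average degree ``2|E| / n``."""
    if net.n == 0:
        raise ValueError("empty network")
    return 2.0 * net.num_edges / net.n


def closeness_index(net: SimNetwork) -> float:
    """Reversed, normalized mean geodesic distance: ``1 - (dbar - 1)/(n - 1)``.

    ``dbar`` is the mean shortest-path length over all unordered node pairs;
    a complete graph scores exactly 1.  Raises on disconnected input.
    """
    g = net.to_networkx()
    if net.n < 2:
        raise ValueError("closeness needs at least two nodes")
    if not nx.is_connected(g):
        raise ValueError("closeness index is undefined on a disconnected network")
    dbar = nx.average_shortest_path_length(g)
    return 1.0 - (dbar - 1.0) / (net.n - 1.0)


class UndefinedStatistic(ValueError):
    """A statistic whose value is undefined for the given input (e.g. zero
    variance), flagged explicitly rather than silently coerced to a number."""


def edgewise_risk_correlation(
    net: SimNetwork, scores: Optional[Sequence[float]] = None
) -> float:
    """Pearson correlation of risk scores across connected node pairs.

    Each undirected edge contributes both orientations ``(r_i, r_j)`` and
    ``(r_j, r_i)`` so the statistic is symmetric.  Raises
    :class:`UndefinedStatistic` when either margin has zero variance.
    """
    if scores is None:
        scores = net.risk_score
    if len(scores) != net.n:
        raise ValueError("scores must cover all nodes")
    pairs = [(scores[u], scores[v]) for u, v in net.edges()]
    if len(pairs) < 2:
        raise ValueError("need at least two edges")
    a = np.array([p for p, _ in pairs] + [q for _, q in pairs])
    b = np.array([q for _, q in pairs] + [p for p, _ in pairs])
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedStatistic("zero variance on an edge margin")
    return float(np.corrcoef(a, b)[0, 1])
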