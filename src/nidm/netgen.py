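"""Baseline network construction and participant assignment.

Both baseline networks have 60 nodes and 178 edges (mean degree 5.9333,
printed 5.93) and are connected.  The low-clustering baseline (LO) is one
large sparse cluster with mean local clustering 0.06; the high-clustering
baseline (HI) consists of densely connected regions with mean local
clustering 0.62.  Both are built so that (nearly) every node sits at a
local optimum of the no-disease utility — removing an incident tie never
helps the ego, and no absent tie would benefit both endpoints — so the
games start from relational equilibrium and any churn is attributable to
the epidemic.

LO is constructed directly: three 3x3 "grid blocks" whose row and column
triangles carry exactly the target clustering mass (27 nodes with two
vertex-disjoint closed pairs each: 27 * (2/15) / 60 = 0.06), a hub whose
four degree-5 spokes absorb the two-edge deficit below 6-regularity, and a
randomized triangle-free completion of all remaining stubs.

HI starts from a stable scaffold and runs a seeded, objective-driven edge
swap search (degree-preserving double swaps plus endpoint moves) minimizing
deviation from the clustering target and the number of nodes with a
utility-improving move, under a connectivity constraint.  The search result
is cached per process; per-seed variation enters through a random node
relabeling, which preserves every structural target exactly.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy import stats as _sstats

from .model_core import Clustering, Mixing, ParamSet, SimNetwork

N_NODES = 60
N_EDGES = 178
CLUSTERING_TARGET = {Clustering.LO: 0.06, Clustering.HI: 0.62}
CLOSENESS_TARGET = {Clustering.LO: 0.975, Clustering.HI: 0.955}
CLUSTERING_TOL = 0.01

_REL_PARAMS = ParamSet()  # b1, c1, c2, b2 defaults drive the stability check


class GenerationError(RuntimeError):
    """Raised when the swap search cannot reach the structural tolerances;
    carries the best-found metrics for diagnosis."""

    def __init__(self, message: str, metrics: Optional[dict] = None) -> None:
        super().__init__(message)
        self.metrics = metrics or {}


# -- vectorized no-disease utility and pairwise stability -------------------


def _rel_vec(t: np.ndarray, p: ParamSet = _REL_PARAMS) -> np.ndarray:
    t = np.asarray(t, float)
    v = p.b1 * t - p.c1 * t - p.c2 * t * t
    return np.maximum(0.0, v) if p.clamp_relation_reward else v


def _fx_vec(x: np.ndarray, alpha: float, p: ParamSet = _REL_PARAMS) -> np.ndarray:
    return p.b2 * (1.0 - 2.0 * np.abs(x - alpha) / max(alpha, 1.0 - alpha))


def _comb2(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, float)
    return np.maximum(d * (d - 1) / 2.0, 1e-12)


def stability_report(
    A: np.ndarray, alpha: float, eps: float = 1e-9
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Pairwise-stability analysis of an adjacency matrix under the
    no-disease utility.

    Returns ``(unstable_mask, excess, sum_x)``: which nodes have a strictly
    improving move (an incident removal that helps the ego, or an absent tie
    that helps both endpoints), the largest improvement available to each
    node, and the total local-clustering mass.
    """
    A = A.astype(np.int32)
    n = A.shape[0]
    deg = A.sum(1)
    M = A @ A
    T = np.einsum("ij,jk,ki->i", A, A, A) // 2
    x = np.where(deg >= 2, T / _comb2(deg), 0.0)
    U = _rel_vec(deg) + _fx_vec(x, alpha)

    degm = deg[:, None] - 1
    xm = np.where(degm >= 2, (T[:, None] - M) / _comb2(degm), 0.0)
    gain_rem = _rel_vec(degm) + _fx_vec(xm, alpha) - U[:, None]
    gain_rem = np.where(A == 1, gain_rem, -np.inf)

    degp = deg[:, None] + 1
    xp = (T[:, None] + M) / _comb2(degp)
    gain_add = _rel_vec(degp) + _fx_vec(xp, alpha) - U[:, None]
    nonedge = (A == 0) & ~np.eye(n, dtype=bool)
    mutual = np.where(nonedge, np.minimum(gain_add, gain_add.T), -np.inf)

    excess = np.maximum(
        np.maximum(gain_rem.max(1), mutual.max(1)), 0.0
    )
    return excess > eps, excess, float(x.sum())


def equilibrium_fraction(net: SimNetwork, alpha: float) -> float:
    """Fraction of nodes with no utility-improving single tie change under
    the no-disease utility (pairwise stability)."""
    A = _to_matrix(net)
    unstable, _, _ = stability_report(A, alpha)
    return 1.0 - unstable.sum() / net.n


def _to_matrix(net: SimNetwork) -> np.ndarray:
    A = np.zeros((net.n, net.n), np.int8)
    for u, v in net.edges():
        A[u, v] = A[v, u] = 1
    return A


def _from_matrix(A: np.ndarray) -> SimNetwork:
    n = A.shape[0]
    net = SimNetwork(n)
    for u in range(n):
        for v in range(u + 1, n):
            if A[u, v]:
                net.add_edge(u, v)
    return net


def _n_components(A: np.ndarray) -> int:
    n = A.shape[0]
    seen = np.zeros(n, bool)
    comps = 0
    for s in range(n):
        if not seen[s]:
            comps += 1
            stack = [s]
            seen[s] = True
            while stack:
                u = stack.pop()
                for v in np.nonzero(A[u])[0]:
                    if not seen[v]:
                        seen[v] = True
                        stack.append(v)
    return comps


# -- LO construction -------------------------------------------------------


def _build_lo_matrix(rng: np.random.Generator) -> np.ndarray:
    """Construct the LO baseline; see module docstring for the design."""
    A = np.zeros((N_NODES, N_NODES), np.int8)

    def add(u: int, v: int) -> None:
        A[u, v] = A[v, u] = 1

    # Three 3x3 grid blocks: each node gains a row triangle and a column
    # triangle, i.e. exactly two vertex-disjoint closed pairs.
    for b in range(3):
        ids = np.arange(9 * b, 9 * b + 9).reshape(3, 3)
        for r in range(3):
            for u, v in itertools.combinations(ids[r, :], 2):
                add(u, v)
        for c in range(3):
            for u, v in itertools.combinations(ids[:, c], 2):
                add(u, v)

    # Hub with four degree-5 spokes: the spokes are pairwise at distance 2
    # through the hub, so connecting any two of them would close a triad and
    # cost more than the sixth relation gains.
    hub, spokes = 27, (56, 57, 58, 59)
    for q in spokes:
        add(hub, q)
    target = np.full(N_NODES, 6)
    for q in spokes:
        target[q] = 5

    # Randomized triangle-free completion of the remaining stubs.
    for _ in range(500):
        B = A.copy()
        deg = B.sum(1)
        stubs = [i for i in range(N_NODES) for _ in range(target[i] - deg[i])]
        rng.shuffle(stubs)
        ok = True
        while stubs:
            u = stubs[0]
            cands = [
                s
                for s in sorted(set(stubs[1:]))
                if s != u and not B[u, s] and not (B[u] & B[s]).any()
            ]
            if not cands:
                ok = False
                break
            v = cands[rng.integers(len(cands))]
            stubs.remove(u)
            stubs.remove(v)
            B[u, v] = B[v, u] = 1
        if ok and _n_components(B) == 1:
            return B
    raise GenerationError("triangle-free completion of the LO baseline failed")


# -- HI search -------------------------------------------------------------
#
# Scaffold: one "pocket" of 8 nodes wired as K8 minus a perfect matching
# (every pocket node sits in a dense neighborhood, local clustering 0.8 at
# equilibrium) and an arc of 52 nodes with distance-<=3 band adjacency
# (local clustering 0.6 at equilibrium).  Both motifs are pairwise-stable
# under the no-disease utility with alpha = 0.67; only the junction where
# the arc ends meet the pocket has no closed-form stable wiring, so the
# junction edges are placed by an objective-driven annealed swap search and
# a greedy polish pass.

_POCKET = tuple(range(8))
_POCKET_MATCHING = frozenset({(0, 1), (2, 3), (4, 5), (6, 7)})
_ARC = tuple(range(8, 60))
_JUNCTION_REGION = frozenset(range(0, 14)) | frozenset(range(54, 60))
_HI_ALPHA = 0.67


def _hi_bulk() -> Tuple[np.ndarray, np.ndarray, List[Tuple[int, int]]]:
    """Fixed bulk adjacency, frozen-edge mask, and junction candidate pairs."""
    A = np.zeros((N_NODES, N_NODES), np.int8)
    for u, v in itertools.combinations(_POCKET, 2):
        if (u, v) not in _POCKET_MATCHING:
            A[u, v] = A[v, u] = 1
    for i in _ARC:
        for d in (1, 2, 3):
            if i + d <= 59:
                A[i, i + d] = A[i + d, i] = 1
    frozen = np.zeros((N_NODES, N_NODES), bool)
    for u in range(N_NODES):
        for v in range(N_NODES):
            if A[u, v] and not (u in _JUNCTION_REGION and v in _JUNCTION_REGION):
                frozen[u, v] = True
    cand = [
        (u, v)
        for u, v in itertools.combinations(sorted(_JUNCTION_REGION), 2)
        if (u, v) not in _POCKET_MATCHING
    ]
    return A, frozen, cand


def _hi_cost(A: np.ndarray, target_sx: float) -> Tuple[float, int, float]:
    unstable, excess, sx = stability_report(A, _HI_ALPHA)
    nu = int(unstable.sum())
    cost = (
        3.0 * nu
        + 40.0 * excess.sum()
        + 3.0 * abs(sx - target_sx)
        + 25.0 * (_n_components(A) - 1)
        + 10.0 * abs(int(A.sum() // 2) - N_EDGES)
    )
    return cost, nu, sx


def _junction_anneal(
    seed: int,
    iters: int = 25000,
    t0: float = 2.0,
    t1: float = 0.01,
    target_sx: float = 37.2,
) -> np.ndarray:
    """Anneal junction edges only (the bulk stays frozen)."""
    rng = np.random.default_rng(seed)
    A, frozen, cand = _hi_bulk()
    need = N_EDGES - int(A.sum() // 2)
    absent = [pq for pq in cand if not A[pq[0], pq[1]]]
    rng.shuffle(absent)
    for u, v in absent[:need]:
        A[u, v] = A[v, u] = 1
    cost, nu, sx = _hi_cost(A, target_sx)
    best = (cost, A.copy(), nu, sx)
    for it in range(iters):
        temp = t0 * (t1 / t0) ** (it / iters)
        present = [
            pq for pq in cand if A[pq[0], pq[1]] and not frozen[pq[0], pq[1]]
        ]
        absent = [pq for pq in cand if not A[pq[0], pq[1]]]
        if not present or not absent:
            break
        a, b = present[rng.integers(len(present))]
        u, v = absent[rng.integers(len(absent))]
        A[a, b] = A[b, a] = 0
        A[u, v] = A[v, u] = 1
        new_cost, new_nu, new_sx = _hi_cost(A, target_sx)
        if new_cost <= cost or rng.random() < np.exp((cost - new_cost) / temp):
            cost, nu, sx = new_cost, new_nu, new_sx
            if cost < best[0]:
                best = (cost, A.copy(), nu, sx)
                if nu == 0 and abs(sx - target_sx) <= 0.3:
                    break
        else:
            A[u, v] = A[v, u] = 0
            A[a, b] = A[b, a] = 1
    return best[1]


def _greedy_polish(A: np.ndarray, target_sx: float = 37.35, rounds: int = 6) -> np.ndarray:
    """Exhaustive single-swap descent over junction pairs."""
    _, frozen, cand = _hi_bulk()
    A = A.copy()
    cost, _, _ = _hi_cost(A, target_sx)
    for _ in range(rounds):
        present = [
            pq for pq in cand if A[pq[0], pq[1]] and not frozen[pq[0], pq[1]]
        ]
        absent = [pq for pq in cand if not A[pq[0], pq[1]]]
        best_move, best_cost = None, cost
        for a, b in present:
            A[a, b] = A[b, a] = 0
            for u, v in absent:
                A[u, v] = A[v, u] = 1
                c2, _, _ = _hi_cost(A, target_sx)
                if c2 < best_cost - 1e-12:
                    best_cost, best_move = c2, ((a, b), (u, v))
                A[u, v] = A[v, u] = 0
            A[a, b] = A[b, a] = 1
        if best_move is None:
            break
        (a, b), (u, v) = best_move
        A[a, b] = A[b, a] = 0
        A[u, v] = A[v, u] = 1
        cost = best_cost
        unstable, _, sx = stability_report(A, _HI_ALPHA)
        if unstable.sum() == 0 and 0.615 <= sx / N_NODES < 0.625:
            break
    return A


#: Internal seeds for the junction search, tried in order until the
#: structural targets are met (the first is known to converge).
_HI_SEARCH_SEEDS = (8, 11, 4, 3, 13)


@lru_cache(maxsize=1)
def _hi_template() -> np.ndarray:
    """Deterministic HI structure from the junction search; cached per
    process (the search takes on the order of a minute)."""
    best_metrics: dict = {}
    for seed in _HI_SEARCH_SEEDS:
        A = _greedy_polish(_junction_anneal(seed))
        unstable, _, sx = stability_report(A, _HI_ALPHA)
        metrics = {
            "seed": seed,
            "unstable": int(unstable.sum()),
            "clustering": sx / N_NODES,
            "edges": int(A.sum() // 2),
            "components": _n_components(A),
        }
        if (
            metrics["unstable"] <= 3
            and abs(metrics["clustering"] - CLUSTERING_TARGET[Clustering.HI])
            <= CLUSTERING_TOL
            and metrics["edges"] == N_EDGES
            and metrics["components"] == 1
        ):
            A.setflags(write=False)
            return A
        if not best_metrics or metrics["unstable"] < best_metrics["unstable"]:
            best_metrics = metrics
    raise GenerationError(
        "HI junction search did not reach tolerance", metrics=best_metrics
    )


def _relabel(A: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(A.shape[0])
    return A[np.ix_(perm, perm)]


def generate_baseline(setting: Clustering, seed: int) -> SimNetwork:
    """Generate the LO or HI baseline network, deterministic given the seed.

    Guarantees (or raises :class:`GenerationError`): 60 nodes, 178 edges,
    connected, mean local clustering within +-0.01 of the setting's target.
    The achieved fraction of utility-stable nodes is available through
    :func:`equilibrium_fraction`.
    """
    setting = Clustering(setting)
    rng = np.random.default_rng([seed, 0xB1D if setting is Clustering.LO else 0xB2D])
    if setting is Clustering.LO:
        A = _build_lo_matrix(rng)
    else:
        A = _relabel(_hi_template().copy(), rng)
    net = _from_matrix(A)
    _validate(net, setting)
    return net


def _validate(net: SimNetwork, setting: Clustering) -> None:
    from .model_core import mean_degree, network_clustering

    metrics = {
        "edges": net.num_edges,
        "mean_degree": mean_degree(net),
        "clustering": network_clustering(net),
        "connected": _n_components(_to_matrix(net)) == 1,
    }
    if net.num_edges != N_EDGES or not metrics["connected"]:
        raise GenerationError("baseline structure out of tolerance", metrics)
    if abs(metrics["clustering"] - CLUSTERING_TARGET[setting]) > CLUSTERING_TOL:
        raise GenerationError("baseline clustering out of tolerance", metrics)


# -- participants ----------------------------------------------------------


def sample_risk_scores(n: int, rng: np.random.Generator) -> List[float]:
    """Draw risk aversion scores from a normal distribution with mean 1.27
    and SD 0.45 truncated to (0, 2), the range used by the decision model."""
    if n < 1:
        raise ValueError("need at least one participant")
    lo, hi = (0.0 - 1.27) / 0.45, (2.0 - 1.27) / 0.45
    draws = _sstats.truncnorm.rvs(lo, hi, loc=1.27, scale=0.45, size=n,
                                  random_state=rng)
    # exclude the closed endpoints; scores live in the open interval
    draws = np.clip(draws, 1e-9, 2.0 - 1e-9)
    return [float(v) for v in draws]


def _locality_order(net: SimNetwork) -> List[int]:
    """Spectral (Fiedler-vector) ordering: sorting nodes by the second
    Laplacian eigenvector is the classic relaxation of the minimum linear
    arrangement, so consecutive positions tend to be adjacent or close.

    Deterministic: eigenvector sign is fixed by its first nonzero component
    and ties broken by node id.
    """
    g = net.to_networkx()
    lap = nx.laplacian_matrix(g, nodelist=sorted(g.nodes())).toarray().astype(float)
    _, vecs = np.linalg.eigh(lap)
    fiedler = vecs[:, 1]
    nonzero = fiedler[np.abs(fiedler) > 1e-12]
    if nonzero.size and nonzero[0] < 0:
        fiedler = -fiedler
    return sorted(net.nodes(), key=lambda i: (fiedler[i], i))


#: Fixed interleaving stride for the random-mixing assignment; coprime with
#: 60 so the rank sequence visits every node while adjacent ranks land far
#: apart in the locality order.
_RA_STRIDE = 37


def assign_participants(
    net: SimNetwork, scores: Sequence[float], mixing: Mixing
) -> Dict[int, float]:
    """Map sorted risk scores onto nodes under the mixing setting.

    Scores are sorted ascending and assigned to a fixed node ordering: under
    AS a locality-preserving (DFS) ordering, so neighbors receive similar
    ranks; under RA a fixed stride interleaving of that ordering, so
    neighbors receive unrelated ranks.  The graph itself is never changed.
    """
    mixing = Mixing(mixing)
    if len(scores) != net.n:
        raise ValueError(f"need exactly {net.n} scores, got {len(scores)}")
    ranked = sorted(scores)
    order = _locality_order(net)
    if mixing is Mixing.AS:
        node_order = order
    else:
        node_order = [order[(k * _RA_STRIDE) % net.n] for k in range(net.n)]
    return {node: ranked[k] for k, node in enumerate(node_order)}


# -- export ----------------------------------------------------------------


def export_edge_list_csv(net: SimNetwork, path) -> None:
    import pandas as pd

    pd.DataFrame(sorted(net.edges()), columns=["node_a", "node_b"]).to_csv(
        path, index=False
    )


def export_graphml(net: SimNetwork, path) -> None:
    nx.write_graphml(net.to_networkx(), path)
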