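"""Game/session/batch orchestration, serialization, and game-level metrics.

A *game* couples one baseline network with 60 risk-scored participants and
runs rounds of: stage 1 (maintain/dissolve + proposals), stage 2 (accept/
decline), stage 3 (point rewards), stage 4 (transmission + recovery), until
no infectious node remains or the round cap is reached.  A *batch* is the
full experimental design: 48 sessions of two games each, clustering
alternating within sessions and mixing alternating every second session,
24 games per condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .agents import (
    Action,
    Decision,
    apply_round_decisions,
    stage1_decide,
    stage2_decide,
)
from .epidemic import EpidemicTrace, recovery_step, select_index_case, transmission_step
from .model_core import (
    Clustering,
    Condition,
    DiseaseState,
    Mixing,
    ParamSet,
    SimNetwork,
    UndefinedStatistic,
)
from .netgen import assign_participants, generate_baseline, sample_risk_scores
from .opportunities import collect_stage2_opportunities, select_opportunities
from .rewards import RewardBreakdown, round_reward


@dataclass
class RoundSnapshot:
    """Network state of one round: round-start edges, post-decision (stage-3)
    edges, the round's disease states, and the rewards paid."""

    round: int
    edges: List[Tuple[int, int]]
    states: List[str]
    edges_stage3: List[Tuple[int, int]] = field(default_factory=list)
    rewards: List[RewardBreakdown] = field(default_factory=list)


@dataclass
class GameResult:
    condition: Condition
    scores: List[float]
    index_case: int
    snapshots: List[RoundSnapshot]
    decisions: List[Decision]
    trace: EpidemicTrace
    final_net: SimNetwork
    rounds_played: int

    @property
    def final_size(self) -> float:
        c = self.final_net.count_states()
        return (c[DiseaseState.I] + c[DiseaseState.R]) / self.final_net.n


def run_game(
    condition: Condition,
    scores: Sequence[float],
    p: ParamSet,
    seed: int,
) -> GameResult:
    """Run one full game, fully reproducible from (condition, scores, seed)."""
    p = p.for_condition(condition)
    rng = np.random.default_rng(seed)
    base = generate_baseline(condition.clustering, seed)
    assignment = assign_participants(base, scores, condition.mixing)
    net = base.copy()
    net.risk_score = [assignment[i] for i in range(net.n)]

    index_case = select_index_case(net, net.risk_score)
    net.set_infected(index_case, p.tau)
    trace = EpidemicTrace()
    trace.ever_infected.add(index_case)
    trace.infection_round[index_case] = 0

    snapshots: List[RoundSnapshot] = []
    decisions: List[Decision] = []
    rounds_played = 0

    for round_no in range(1, p.max_rounds + 1):
        rounds_played = round_no
        snap = RoundSnapshot(
            round=round_no,
            edges=list(net.edges()),
            states=[s.value for s in net.state],
        )

        # stage 1: per-ego opportunities and decisions on the round-start net
        stage1: List[Decision] = []
        proposals: List[Tuple[int, int]] = []
        for ego in net.nodes():
            opps = select_opportunities(
                ego, net, net.risk_score, p, rng, round_no=round_no
            )
            for d in stage1_decide(ego, opps, net, p, rng):
                stage1.append(d)
                if d.action is Action.CREATE_PROPOSE:
                    proposals.append((ego, d.opportunity.alter))

        # stage 2: accept/decline incoming proposals
        incoming, auto_created = collect_stage2_opportunities(
            proposals, net, round_no=round_no
        )
        stage2: List[Decision] = []
        for ego in sorted(incoming):
            stage2.extend(stage2_decide(ego, incoming[ego], net, p, rng))

        net = apply_round_decisions(net, stage1, stage2, auto_created)
        decisions.extend(stage1)
        decisions.extend(stage2)

        # stage 3: rewards on the post-decision network
        snap.edges_stage3 = list(net.edges())
        for i in net.nodes():
            rb = round_reward(net, i, p)
            net.cumulative_points[i] += rb.total
            snap.rewards.append(rb)
        snapshots.append(snap)

        # stage 4: transmissions against the current infectious set, then
        # recovery decrement, then activation of new infections
        frozen = net.copy()
        newly = transmission_step(frozen, p, rng)
        recovered = recovery_step(net, p)
        for i in recovered:
            trace.recovery_round[i] = round_no
        for i in newly:
            net.set_infected(i, p.tau)
            trace.ever_infected.add(i)
            trace.infection_round[i] = round_no
        trace.record_counts(net)

        if net.count_states()[DiseaseState.I] == 0:
            break

    return GameResult(
        condition=condition,
        scores=list(scores),
        index_case=index_case,
        snapshots=snapshots,
        decisions=decisions,
        trace=trace,
        final_net=net,
        rounds_played=rounds_played,
    )


def final_size(result: GameResult) -> float:
    """Proportion of ever-infected (I or R) nodes at game end."""
    return result.final_size


# -- experimental design ---------------------------------------------------


def session_plan(n_sessions: int = 48) -> List[List[Condition]]:
    """The alternation schedule: clustering alternates every session,
    mixing every second session (LO:RA, HI:RA | HI:RA, LO:RA | LO:AS, ...)."""
    plan: List[List[Condition]] = []
    for s in range(1, n_sessions + 1):
        mixing = Mixing.RA if ((s - 1) // 2) % 2 == 0 else Mixing.AS
        first = Clustering.LO if s % 2 == 1 else Clustering.HI
        second = Clustering.HI if first is Clustering.LO else Clustering.LO
        plan.append(
            [
                Condition(first, mixing, session_index=s, game_index_within_session=1),
                Condition(second, mixing, session_index=s, game_index_within_session=2),
            ]
        )
    return plan


def run_batch(
    p: ParamSet,
    master_seed: int,
    n_sessions: int = 48,
    n_participants: int = 60,
) -> List[GameResult]:
    """Run the full design: ``n_sessions`` sessions x 2 games; scores are
    sampled once per session and reused by both of its games."""
    ss = np.random.SeedSequence(master_seed)
    results: List[GameResult] = []
    for session, conditions in zip(ss.spawn(n_sessions), session_plan(n_sessions)):
        score_seed, *game_seeds = session.spawn(3)
        scores = sample_risk_scores(
            n_participants, np.random.default_rng(score_seed)
        )
        for cond, gseed in zip(conditions, game_seeds):
            seed = int(gseed.generate_state(1)[0] % (2**31))
            cond = Condition(
                cond.clustering,
                cond.mixing,
                session_index=cond.session_index,
                game_index_within_session=cond.game_index_within_session,
                seed=seed,
            )
            results.append(run_game(cond, scores, p, seed))
    return results


# -- analysis --------------------------------------------------------------

_CREATE_ACTIONS = {Action.CREATE_PROPOSE, Action.ACCEPT}
_NOT_CREATE_ACTIONS = {Action.NOT_PROPOSE, Action.DECLINE}


def decision_type(d: Decision) -> str:
    if d.action in _CREATE_ACTIONS:
        return "Create"
    if d.action in _NOT_CREATE_ACTIONS:
        return "Not create"
    if d.action is Action.DISSOLVE:
        return "Dissolve"
    return "Maintain"


def decision_matrix(
    decisions: Iterable[Decision], split_alter_s: bool = False
) -> pd.DataFrame:
    """Proportion of each decision type per (ego state, alter state) cell.

    Cells with no opportunities of the relevant kind hold NaN (undefined),
    never 0.  With ``split_alter_s`` susceptible alters are split by whether
    they have an infected neighbor.
    """
    rows = []
    for d in decisions:
        alter = d.alter_state.value
        if split_alter_s and alter == "S":
            alter = "S+inf" if d.alter_has_infected_neighbor else "S-inf"
        rows.append(
            {
                "ego": d.ego_state.value,
                "alter": alter,
                "type": decision_type(d),
            }
        )
    if not rows:
        raise ValueError("no decisions to tabulate")
    df = pd.DataFrame(rows)
    out = {}
    for (ego, alter), grp in df.groupby(["ego", "alter"]):
        cell = {}
        n_create_opps = grp["type"].isin(["Create", "Not create"]).sum()
        n_tie_opps = grp["type"].isin(["Dissolve", "Maintain"]).sum()
        for t in ("Create", "Not create"):
            cell[t] = (
                (grp["type"] == t).sum() / n_create_opps
                if n_create_opps
                else np.nan
            )
        for t in ("Dissolve", "Maintain"):
            cell[t] = (
                (grp["type"] == t).sum() / n_tie_opps if n_tie_opps else np.nan
            )
        out[(ego, alter)] = cell
    table = pd.DataFrame(out).T
    table.index.names = ["ego", "alter"]
    return table


def rewardingness(decision: Decision, result: GameResult, strict: bool = False) -> bool:
    """Did the realized decision yield at least (or, with ``strict``, more
    than) the stage-3 reward of the opposite decision, holding everything
    else about that round fixed?"""
    snap = next(
        s for s in result.snapshots if s.round == decision.opportunity.round
    )
    p = _params_for(result)
    net = SimNetwork(result.final_net.n, edges=snap.edges_stage3)
    for i, s in enumerate(snap.states):
        net.state[i] = DiseaseState(s)
    ego, alter = decision.opportunity.ego, decision.opportunity.alter

    # realized round-3 network: apply the decision's outcome to this pair
    realized_tie = decision.action in (Action.MAINTAIN, *(_CREATE_ACTIONS))
    if realized_tie and not net.has_edge(ego, alter):
        net.add_edge(ego, alter)
    if not realized_tie and net.has_edge(ego, alter):
        net.remove_edge(ego, alter)
    realized = round_reward(net, ego, p).total

    if net.has_edge(ego, alter):
        net.remove_edge(ego, alter)
    else:
        net.add_edge(ego, alter)
    counterfactual = round_reward(net, ego, p).total
    return realized > counterfactual if strict else realized >= counterfactual


def _params_for(result: GameResult) -> ParamSet:
    return ParamSet().for_condition(result.condition)


def rank_sum_test(sample_a: Sequence[float], sample_b: Sequence[float]):
    """Two-sided Wilcoxon rank-sum test (normal approximation with tie
    correction).  Returns (z-statistic, p-value); flags degenerate all-tied
    input."""
    a, b = np.asarray(sample_a, float), np.asarray(sample_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise UndefinedStatistic("all observations tied; rank-sum undefined")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    n1, n2 = len(a), len(b)
    mu = n1 * n2 / 2.0
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    sd = np.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    z = (res.statistic - mu) / sd
    return float(z), float(res.pvalue)


# -- serialization ---------------------------------------------------------


def write_outputs(
    results: Sequence[GameResult],
    directory,
    participants: Optional[pd.DataFrame] = None,
) -> Dict[str, Path]:
    """Write the three data categories as CSV plus per-game metrics JSON.

    Network data lists each edge in both orientations per round (isolated
    nodes appear once with an empty partner field); decision data carries one
    row per resolved opportunity; participant data is per-session when
    provided by the caller, otherwise reconstructed per game.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    net_rows, dec_rows, part_rows, metrics = [], [], [], []
    for g_idx, res in enumerate(results):
        cond = res.condition
        sid, gid = cond.session_index, g_idx
        for snap in res.snapshots:
            adj: Dict[int, List[int]] = {i: [] for i in range(res.final_net.n)}
            for u, v in snap.edges:
                adj[u].append(v)
                adj[v].append(u)
            for i in range(res.final_net.n):
                if adj[i]:
                    for j in sorted(adj[i]):
                        net_rows.append(
                            (sid, gid, cond.clustering.value, cond.mixing.value,
                             snap.round, i, snap.states[i], j)
                        )
                else:
                    net_rows.append(
                        (sid, gid, cond.clustering.value, cond.mixing.value,
                         snap.round, i, snap.states[i], "")
                    )
        for d in res.decisions:
            dec_rows.append(
                (sid, gid, d.opportunity.round, d.opportunity.ego,
                 d.opportunity.alter, d.opportunity.kind.value,
                 d.action.value, d.opportunity.stage, d.perceived_delta)
            )
        metrics.append(
            {
                "session_id": sid,
                "game_id": gid,
                "condition": cond.label,
                "final_size": res.final_size,
                "rounds_played": res.rounds_played,
                "index_case": res.index_case,
                "ever_infected": sorted(res.trace.ever_infected),
            }
        )

    paths = {}
    paths["network"] = directory / "network_data.csv"
    pd.DataFrame(
        net_rows,
        columns=["session_id", "game_id", "clustering_setting", "mixing_setting",
                 "round", "node_id", "disease_state", "connected_node_id"],
    ).to_csv(paths["network"], index=False)

    paths["decisions"] = directory / "decision_data.csv"
    pd.DataFrame(
        dec_rows,
        columns=["session_id", "game_id", "round", "ego_id", "alter_id",
                 "offer_type", "decision", "stage", "perceived_delta"],
    ).to_csv(paths["decisions"], index=False)

    paths["participants"] = directory / "participant_data.csv"
    if participants is not None:
        participants.to_csv(paths["participants"], index=False)
    else:
        # reconstruct: participant k is the k-th score in ascending order;
        # their node in each game is the node carrying that score
        sessions: Dict[int, List[Tuple[int, GameResult]]] = {}
        for g_idx, res in enumerate(results):
            sessions.setdefault(res.condition.session_index, []).append(
                (g_idx, res)
            )
        for sid in sorted(sessions):
            games = sessions[sid]
            ranked = sorted(games[0][1].scores)
            for k, score in enumerate(ranked):
                row = {"session_id": sid, "participant_id": k,
                       "risk_score": score, "staircase_position": ""}
                for slot, (_, res) in enumerate(games[:2], start=1):
                    nodes = [
                        i for i, s in enumerate(res.final_net.risk_score)
                        if s == score
                    ]
                    row[f"node_id_game{slot}"] = nodes[0] if nodes else ""
                part_rows.append(row)
        pd.DataFrame(
            part_rows,
            columns=["session_id", "participant_id", "node_id_game1",
                     "node_id_game2", "risk_score", "staircase_position"],
        ).to_csv(paths["participants"], index=False)

    paths["metrics"] = directory / "metrics.json"
    with open(paths["metrics"], "w") as fh:
        json.dump(metrics, fh, indent=1)
    return paths


def read_network_csv(path) -> Dict[Tuple[int, int, int], SimNetwork]:
    """Round-trip reader: reconstruct per-(session, game, round) networks."""
    df = pd.read_csv(path, keep_default_na=False)
    out: Dict[Tuple[int, int, int], SimNetwork] = {}
    for (sid, gid, rnd), grp in df.groupby(["session_id", "game_id", "round"]):
        n = grp["node_id"].max() + 1
        net = SimNetwork(int(n))
        for _, row in grp.iterrows():
            if row["connected_node_id"] != "":
                u, v = int(row["node_id"]), int(row["connected_node_id"])
                if not net.has_edge(u, v):
                    net.add_edge(u, v)
            net.state[int(row["node_id"])] = DiseaseState(row["disease_state"])
        out[(int(sid), int(gid), int(rnd))] = net
    return out
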