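"""Game orchestration, schedule bookkeeping, metrics, serialization."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nidm import (
    Action,
    Clustering,
    Condition,
    DiseaseState,
    Mixing,
    ParamSet,
    SimNetwork,
    UndefinedStatistic,
    decision_matrix,
    final_size,
    rank_sum_test,
    rewardingness,
    run_game,
    session_plan,
    write_outputs,
)
from nidm.agents import Decision
from nidm.opportunities import Opportunity, OpportunityKind
from nidm.runner_io import GameResult, read_network_csv, run_batch
from nidm.netgen import sample_risk_scores


@pytest.fixture(scope="module")
def lo_ra_game():
    scores = sample_risk_scores(60, np.random.default_rng(42))
    cond = Condition(Clustering.LO, Mixing.RA, seed=11)
    return run_game(cond, scores, ParamSet(), seed=11)


class TestRunGame:
    def test_gamma_zero_ends_when_index_recovers(self):
        scores = sample_risk_scores(60, np.random.default_rng(1))
        cond = Condition(Clustering.LO, Mixing.RA, seed=2)
        res = run_game(cond, scores, ParamSet(gamma=0.0), seed=2)
        assert res.rounds_played == 4  # index case infectious for tau rounds
        assert res.final_size == pytest.approx(1 / 60)
        assert res.final_net.state[res.index_case] is DiseaseState.R

    def test_round_cap_respected(self, lo_ra_game):
        assert lo_ra_game.rounds_played <= 20

    def test_final_size_bounds(self, lo_ra_game):
        assert 1 / 60 <= final_size(lo_ra_game) <= 1.0

    def test_game_is_reproducible(self):
        scores = sample_risk_scores(60, np.random.default_rng(5))
        cond = Condition(Clustering.LO, Mixing.AS, seed=3)
        a = run_game(cond, scores, ParamSet(), seed=3)
        b = run_game(cond, scores, ParamSet(), seed=3)
        assert a.final_size == b.final_size
        assert [d.action for d in a.decisions] == [d.action for d in b.decisions]
        assert sorted(a.final_net.edges()) == sorted(b.final_net.edges())
        assert a.final_net.cumulative_points == b.final_net.cumulative_points

    def test_reward_conservation(self, lo_ra_game):
        """Cumulative points equal the sum of per-round reward breakdowns."""
        totals = np.zeros(60)
        for snap in lo_ra_game.snapshots:
            for i, rb in enumerate(snap.rewards):
                totals[i] += rb.total
        assert np.allclose(totals, lo_ra_game.final_net.cumulative_points)

    def test_epidemic_trace_consistency(self, lo_ra_game):
        trace = lo_ra_game.trace
        assert len(trace.ever_infected) == round(lo_ra_game.final_size * 60)
        for counts in trace.counts:
            assert counts["S"] + counts["I"] + counts["R"] == 60


class TestEquilibriumChurn:
    @pytest.mark.parametrize("setting", [Clustering.LO, Clustering.HI])
    def test_baselines_are_near_equilibrium_without_disease(self, setting):
        """With reward-seeking agents and no infection, the baselines
        produce (near-)zero relational churn: changed ties < 5% of offered
        opportunities over ten rounds."""
        from nidm.netgen import generate_baseline
        from nidm.opportunities import collect_stage2_opportunities, select_opportunities
        from nidm.agents import apply_round_decisions, stage1_decide, stage2_decide

        p = ParamSet().for_condition(Condition(setting, Mixing.RA))
        net = generate_baseline(setting, 4)
        net.risk_score = sample_risk_scores(60, np.random.default_rng(4))
        rng = np.random.default_rng(4)
        churn = 0
        offered = 0
        for round_no in range(1, 11):
            stage1, proposals = [], []
            for ego in net.nodes():
                opps = select_opportunities(ego, net, net.risk_score, p, rng,
                                            round_no=round_no)
                offered += len(opps)
                for d in stage1_decide(ego, opps, net, p, rng):
                    stage1.append(d)
                    if d.action is Action.CREATE_PROPOSE:
                        proposals.append((ego, d.opportunity.alter))
            incoming, auto = collect_stage2_opportunities(proposals, net,
                                                          round_no=round_no)
            stage2 = []
            for ego in sorted(incoming):
                stage2.extend(stage2_decide(ego, incoming[ego], net, p, rng))
            new_net = apply_round_decisions(net, stage1, stage2, auto)
            before = set(net.edges())
            after = set(new_net.edges())
            churn += len(before ^ after)
            net = new_net
        assert churn / offered < 0.05


class TestSessionPlan:
    def test_published_alternation_prefix(self):
        plan = session_plan(5)
        labels = [[c.label for c in session] for session in plan]
        assert labels == [
            ["LO:RA", "HI:RA"],
            ["HI:RA", "LO:RA"],
            ["LO:AS", "HI:AS"],
            ["HI:AS", "LO:AS"],
            ["LO:RA", "HI:RA"],
        ]

    def test_full_design_counts(self):
        plan = session_plan(48)
        flat = [c for session in plan for c in session]
        assert len(flat) == 96
        combos = {(c.clustering, c.mixing) for c in flat}
        assert len(combos) == 4
        for combo in combos:
            assert sum((c.clustering, c.mixing) == combo for c in flat) == 24


class TestBatch:
    def test_small_batch_bookkeeping_and_score_reuse(self):
        results = run_batch(ParamSet(), master_seed=1, n_sessions=4)
        assert len(results) == 8
        for k in range(0, 8, 2):
            assert results[k].scores == results[k + 1].scores  # same session
        assert results[0].condition.label == "LO:RA"
        assert results[5].condition.label == "HI:AS"

    def test_batch_reproducible(self):
        a = run_batch(ParamSet(), master_seed=9, n_sessions=2)
        b = run_batch(ParamSet(), master_seed=9, n_sessions=2)
        assert [r.final_size for r in a] == [r.final_size for r in b]
        assert [sorted(r.final_net.edges()) for r in a] == [
            sorted(r.final_net.edges()) for r in b
        ]


class TestDecisionMatrix:
    def _decision(self, ego_state, alter_state, action, kind):
        return Decision(
            opportunity=Opportunity(round=1, stage=1, ego=0, alter=1, kind=kind),
            action=action,
            perceived_delta=0.0,
            ego_state=ego_state,
            alter_state=alter_state,
            alter_has_infected_neighbor=False,
        )

    def test_hand_tallied_proportions(self):
        DM, PN = OpportunityKind.DISSOLVE_OR_MAINTAIN, OpportunityKind.PROPOSE_OR_NOT
        S, I = DiseaseState.S, DiseaseState.I
        decisions = (
            [self._decision(S, I, Action.DISSOLVE, DM)] * 3
            + [self._decision(S, I, Action.MAINTAIN, DM)] * 1
            + [self._decision(S, S, Action.CREATE_PROPOSE, PN)] * 2
            + [self._decision(S, S, Action.NOT_PROPOSE, PN)] * 4
        )
        table = decision_matrix(decisions)
        assert table.loc[("S", "I"), "Dissolve"] == pytest.approx(0.75)
        assert table.loc[("S", "I"), "Maintain"] == pytest.approx(0.25)
        assert table.loc[("S", "S"), "Create"] == pytest.approx(2 / 6)
        assert np.isnan(table.loc[("S", "I"), "Create"])  # no such opportunities

    def test_complementary_types_sum_to_one(self, lo_ra_game):
        table = decision_matrix(lo_ra_game.decisions)
        for _, row in table.iterrows():
            if not np.isnan(row["Create"]):
                assert row["Create"] + row["Not create"] == pytest.approx(1.0)
            if not np.isnan(row["Dissolve"]):
                assert row["Dissolve"] + row["Maintain"] == pytest.approx(1.0)


class TestRewardingness:
    def test_consistent_with_direct_recomputation(self, lo_ra_game):
        from nidm.rewards import round_reward

        p = ParamSet().for_condition(lo_ra_game.condition)
        checked = 0
        for d in lo_ra_game.decisions[:200]:
            snap = next(s for s in lo_ra_game.snapshots
                        if s.round == d.opportunity.round)
            net = SimNetwork(60, edges=snap.edges_stage3)
            for i, s in enumerate(snap.states):
                net.state[i] = DiseaseState(s)
            ego, alter = d.opportunity.ego, d.opportunity.alter
            tie = d.action in (Action.MAINTAIN, Action.CREATE_PROPOSE, Action.ACCEPT)
            if net.has_edge(ego, alter) != tie:
                continue  # pair also touched by the counterpart's decision
            realized = round_reward(net, ego, p).total
            if tie:
                net.remove_edge(ego, alter)
            else:
                net.add_edge(ego, alter)
            counter = round_reward(net, ego, p).total
            assert rewardingness(d, lo_ra_game) == (realized >= counter)
            checked += 1
        assert checked > 50


class TestRankSumTest:
    def test_identical_samples(self):
        z, pval = rank_sum_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert pval > 0.9 and abs(z) < 0.2

    def test_fully_separated_samples(self):
        z, pval = rank_sum_test(list(range(24)), list(range(100, 124)))
        assert pval < 0.001

    def test_matches_permutation_oracle(self):
        """Exhaustive permutation distribution of the rank sum at n = 5+5."""
        a = [0.1, 0.9, 0.4, 0.7, 0.2]
        b = [0.8, 0.3, 0.6, 0.95, 0.5]
        pooled = np.array(a + b)
        from scipy.stats import rankdata

        ranks = rankdata(pooled)
        observed = ranks[:5].sum()
        perms = [
            sum(ranks[list(idx)])
            for idx in itertools.combinations(range(10), 5)
        ]
        p_exact = np.mean([
            abs(s - len(ranks) * (len(ranks) + 1) / 4) >=
            abs(observed - len(ranks) * (len(ranks) + 1) / 4) - 1e-12
            for s in perms
        ])
        _, p_normal = rank_sum_test(a, b)
        assert p_normal == pytest.approx(p_exact, abs=0.08)

    def test_all_tied_flagged(self):
        with pytest.raises(UndefinedStatistic):
            rank_sum_test([1.0, 1.0], [1.0, 1.0])


class TestSerialization:
    def test_three_csv_schemas_and_round_trip(self, lo_ra_game, tmp_path):
        paths = write_outputs([lo_ra_game], tmp_path)
        net_df = pd.read_csv(paths["network"], keep_default_na=False)
        assert list(net_df.columns) == [
            "session_id", "game_id", "clustering_setting", "mixing_setting",
            "round", "node_id", "disease_state", "connected_node_id",
        ]
        # per round: one row per edge orientation (plus isolate rows)
        r1 = net_df[net_df["round"] == 1]
        n_isolates = (r1["connected_node_id"] == "").sum()
        assert len(r1) == 2 * len(lo_ra_game.snapshots[0].edges) + n_isolates

        rebuilt = read_network_csv(paths["network"])
        key = (lo_ra_game.condition.session_index, 0, 1)
        assert sorted(rebuilt[key].edges()) == sorted(
            lo_ra_game.snapshots[0].edges
        )

        dec_df = pd.read_csv(paths["decisions"])
        assert len(dec_df) == len(lo_ra_game.decisions)
        assert {"round", "ego_id", "alter_id", "decision", "stage",
                "perceived_delta"} <= set(dec_df.columns)

    def test_headers_stable_across_runs(self, lo_ra_game, tmp_path):
        p1 = write_outputs([lo_ra_game], tmp_path / "a")
        p2 = write_outputs([lo_ra_game], tmp_path / "b")
        for k in p1:
            assert p1[k].read_bytes() == p2[k].read_bytes()
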