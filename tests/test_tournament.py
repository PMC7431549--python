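"""Matches, populations, summaries and replay verification."""

import dataclasses
import random

import pytest

from oracles import brute_mean_std
from rpskit.game import Move, Outcome, PayoffParams, competitive_score
from rpskit.opponents import default_population, make_strategy
from rpskit.tournament import (
    MatchSummary,
    PopulationSummary,
    hypothetical_totals,
    population_run,
    replay,
    run_match,
    standalone_model_scores,
)


def check_summary_invariants(summary: MatchSummary):
    assert summary.ai_wins + summary.draws + summary.ai_losses == summary.rounds
    assert summary.ai_score == summary.ai_wins - summary.ai_losses
    assert sum(summary.preference_counts) == summary.rounds
    assert summary.player_virtual_points == 2 * summary.ai_losses + summary.draws
    if summary.rounds:
        assert summary.score_trajectory[-1] == summary.ai_score


class TestRunMatch:
    def test_zero_rounds(self):
        history, summary = run_match(make_strategy("uniform", seed=0), rounds=0)
        assert history.rounds == 0
        assert summary.ai_score == 0
        assert summary.score_trajectory == ()

    def test_negative_rounds_rejected(self):
        with pytest.raises(ValueError, match="rounds"):
            run_match(make_strategy("uniform", seed=0), rounds=-1)

    @pytest.mark.parametrize("name,kwargs", [
        ("uniform", {}),
        ("wsls", {}),
        ("cycle", {"sequence": "RRPS"}),
        ("biased", {"probs": [0.6, 0.3, 0.1]}),
    ])
    def test_summary_invariants_and_identities(self, name, kwargs):
        strategy = make_strategy(name, seed=5, **kwargs)
        history, summary = run_match(strategy, rounds=200, master_seed=9)
        check_summary_invariants(summary)
        # zero-sum: the player's competitive score is the exact negation
        player_score = sum(
            competitive_score(Outcome(-int(r.outcome))) for r in history.records
        )
        assert summary.ai_score + player_score == 0
        # reward accounting at a = 2
        assert summary.player_reward == pytest.approx(
            summary.player_virtual_points * 0.15 + 5
        )

    def test_reproducible_from_config_and_seed(self):
        runs = [
            run_match(make_strategy("wsls", seed=4), rounds=120, master_seed=31)
            for _ in range(2)
        ]
        assert runs[0][0].records == runs[1][0].records
        assert runs[0][1] == runs[1][1]

    def test_constant_opponent_exploited_after_burn_in(self):
        for seed in range(20):
            _, summary = run_match(
                make_strategy("constant", move="R", seed=seed),
                orders=[1], focus=1, rounds=300, master_seed=seed,
            )
            assert summary.ai_score >= 296

    def test_match_totals_arithmetic(self):
        summary = MatchSummary.from_totals(198, 55, 47)
        assert summary.ai_score == 151
        assert summary.rounds == 300
        assert summary.player_virtual_points == 2 * 47 + 55


class TestStandaloneScores:
    def test_period_four_cycle_favours_order_four(self):
        frame = standalone_model_scores(
            make_strategy("cycle", sequence="RRPS", seed=0),
            orders=[1, 4], rounds=300, seeds=range(30),
        )
        assert (frame.loc[list(range(30)), "AI4"] > frame.loc[list(range(30)), "AI1"]).all()

    def test_nash_opponent_gives_no_edge_to_any_order(self):
        frame = standalone_model_scores(
            make_strategy("uniform", seed=1), orders=[1, 3], rounds=2000, seeds=range(4),
        )
        # mean per-round score within 3 sigma of 0 (sigma <= 1 per round)
        n = 2000 * 4
        for order in ("AI1", "AI3"):
            mean_per_round = frame.loc[list(range(4)), order].sum() / n
            assert abs(mean_per_round) < 3 / n**0.5

    def test_in_match_hypothetical_totals(self):
        history, _ = run_match(make_strategy("wsls", seed=2), rounds=150, master_seed=1)
        totals = hypothetical_totals(history)
        assert set(totals) == set(history.orders)
        for i, order in enumerate(history.orders):
            assert totals[order] == sum(
                r.hypothetical_scores[i] for r in history.records
            )


class TestPopulations:
    def test_aggregates_match_two_pass_oracle(self):
        rng = random.Random(0)
        matches = [
            MatchSummary.from_totals(w, 10, l)
            for w, l in [(rng.randrange(150), rng.randrange(150)) for _ in range(25)]
        ]
        summary = PopulationSummary.from_matches(matches)
        mean, std = brute_mean_std([m.ai_score for m in matches])
        assert summary.mean_score == pytest.approx(mean)
        assert summary.stdev_score == pytest.approx(std)
        assert summary.fraction_won == pytest.approx(
            sum(m.ai_score > 0 for m in matches) / len(matches)
        )

    def test_single_match_population_flags_undefined_stdev(self):
        summary = PopulationSummary.from_matches([MatchSummary.from_totals(10, 5, 3)])
        assert summary.mean_score == 7
        assert summary.stdev_score == 0.0
        assert not summary.stdev_defined

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            PopulationSummary.from_matches([])
        with pytest.raises(ValueError):
            population_run([])

    def test_default_population_run_and_preference_table(self):
        summary = population_run(default_population(0), rounds=120, master_seed=0)
        assert len(summary.matches) == 52
        for m in summary.matches:
            check_summary_invariants(m)
        table = summary.preference_table()
        assert list(table.index) == ["MEAN", "STDEV.S"]
        assert table.loc["MEAN"].sum() == pytest.approx(120)


class TestReplay:
    def test_self_produced_log_agrees_on_all_columns(self):
        history, _ = run_match(make_strategy("cycle", sequence="RPS", seed=3),
                               rounds=60, master_seed=17)
        report = replay(history)
        assert report.ok
        assert report.not_applicable == []
        for m, (got, want) in report.count_totals.items():
            assert got == want == max(0, 60 - m)

    def test_corrupted_dominant_cell_flags_exactly_one_round(self):
        history, _ = run_match(make_strategy("uniform", seed=5), rounds=50, master_seed=2)
        bad = dataclasses.replace(
            history.records[24],
            dominant_order=(history.records[24].dominant_order % 5) + 1,
        )
        history.records[24] = bad
        report = replay(history, verify_moves=False)
        flagged = report.mismatches["dominant_order"] + report.mismatches["ai_move_is_dominant"]
        assert set(flagged) == {25}
        assert not report.ok

    def test_count_conservation_on_any_twenty_round_log(self):
        history, _ = run_match(make_strategy("wsls", seed=9), rounds=20,
                               orders=[2], focus=3, master_seed=4)
        report = replay(history)
        assert report.count_totals[2] == (18, 18)

    def test_unknown_rng_provenance_marks_moves_not_applicable(self):
        history, _ = run_match(make_strategy("uniform", seed=1), rounds=30, master_seed=6)
        history.master_seed = None
        report = replay(history)
        assert "hypothetical_moves" in report.not_applicable
        assert report.ok
        with pytest.raises(ValueError, match="master seed"):
            replay(history, verify_moves=True)


def test_nash_uniform_opponent_is_unexploitable():
    """Mean multi-AI score per round against uniform play converges to 0."""
    n = 10_000
    _, summary = run_match(make_strategy("uniform", seed=123), rounds=n, master_seed=0)
    assert abs(summary.ai_score / n) < 3 / n**0.5


def test_deterministic_strategies_exploited_within_thirty_rounds():
    """Constant and short-cycle opponents are beaten permanently after burn-in."""
    strategies = [
        ("constant", {"move": "P"}),
        ("cycle", {"sequence": "RP"}),
        ("cycle", {"sequence": "RPS"}),
        ("cycle", {"sequence": "RRPPS"}),
    ]
    for name, kwargs in strategies:
        for seed in range(12):
            history, _ = run_match(
                make_strategy(name, seed=seed, **kwargs), rounds=120, master_seed=seed
            )
            scores = [int(r.outcome) for r in history.records]
            last_non_win = max(
                (i + 1 for i, s in enumerate(scores) if s != 1), default=0
            )
            assert last_non_win <= 30
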