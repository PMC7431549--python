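"""Matches, populations, and every summary the engine reports.

A match alternates three steps for the configured number of rounds:
the multi-AI proposes (all members play hypothetically, the dominant one
supplies the move), the opponent strategy emits its move from the
two-sided history, and the ensemble is updated. Everything downstream —
totals, win/draw/loss counts, cumulative-score trajectories, the
opponent's move-preference counts, virtual points and the money reward —
is recomputed from the resulting round records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble import MultiAI, RoundRecord, select_dominant, windowed_scores
from .game import (
    Move,
    Outcome,
    PayoffParams,
    competitive_score,
    resolve,
    reward,
    virtual_points,
)
from .opponents import OpponentStrategy

__all__ = [
    "MatchHistory",
    "MatchSummary",
    "PopulationSummary",
    "ReplayReport",
    "run_match",
    "standalone_model_scores",
    "hypothetical_totals",
    "population_run",
    "replay",
]


@dataclass
class MatchHistory:
    """Ordered round records plus the configuration that produced them."""

    records: list[RoundRecord]
    orders: tuple[int, ...]
    focus: int
    master_seed: int | None = None
    policy: str = "argmax"
    opponent_spec: dict | None = None

    @property
    def rounds(self) -> int:
        return len(self.records)

    @property
    def human_moves(self) -> list[Move]:
        return [r.human_move for r in self.records]

    @property
    def ai_moves(self) -> list[Move]:
        return [r.ai_move for r in self.records]


@dataclass(frozen=True)
class MatchSummary:
    """Per-match accounting; all fields derive from one outcome sequence.

    Invariants: wins + draws + losses = rounds; ai_score = wins - losses;
    the player's virtual points x = 2 * (player wins) + draws =
    2 * ai_losses + draws; preference counts sum to rounds.
    """

    rounds: int
    ai_wins: int
    draws: int
    ai_losses: int
    ai_score: int
    player_virtual_points: int
    player_reward: float
    preference_counts: tuple[int, int, int]  # opponent's R, P, S counts
    score_trajectory: tuple[int, ...]  # cumulative AI score after each round

    @classmethod
    def from_outcomes(
        cls,
        outcomes: Sequence[Outcome],
        human_moves: Sequence[Move] = (),
        payoff: PayoffParams = PayoffParams(),
    ) -> "MatchSummary":
        """Build the summary from an AI-perspective outcome sequence."""
        wins = sum(1 for o in outcomes if o == Outcome.WIN)
        losses = sum(1 for o in outcomes if o == Outcome.LOSS)
        draws = len(outcomes) - wins - losses
        # player-perspective outcome is the negation of the AI's
        x = sum(virtual_points(Outcome(-int(o))) for o in outcomes)
        prefs = [0, 0, 0]
        for mv in human_moves:
            prefs[int(mv)] += 1
        trajectory: list[int] = []
        total = 0
        for o in outcomes:
            total += competitive_score(o)
            trajectory.append(total)
        return cls(
            rounds=len(outcomes),
            ai_wins=wins,
            draws=draws,
            ai_losses=losses,
            ai_score=wins - losses,
            player_virtual_points=x,
            player_reward=reward(x, payoff),
            preference_counts=tuple(prefs),
            score_trajectory=tuple(trajectory),
        )

    @classmethod
    def from_history(
        cls, history: MatchHistory, payoff: PayoffParams = PayoffParams()
    ) -> "MatchSummary":
        return cls.from_outcomes(
            [r.outcome for r in history.records], history.human_moves, payoff
        )

    @classmethod
    def from_totals(
        cls, ai_wins: int, draws: int, ai_losses: int, payoff: PayoffParams = PayoffParams()
    ) -> "MatchSummary":
        """Summary arithmetic from printed match totals (no per-round data)."""
        outcomes = (
            [Outcome.WIN] * ai_wins + [Outcome.DRAW] * draws + [Outcome.LOSS] * ai_losses
        )
        return cls.from_outcomes(outcomes)


@dataclass(frozen=True)
class PopulationSummary:
    """A population of matches: per-match summaries plus aggregate score stats."""

    matches: tuple[MatchSummary, ...]
    mean_score: float
    stdev_score: float  # sample (n-1) standard deviation; 0.0 when undefined
    stdev_defined: bool  # False for a single-match population
    fraction_won: float  # fraction of matches with ai_score > 0

    @classmethod
    def from_matches(cls, matches: Sequence[MatchSummary]) -> "PopulationSummary":
        if not matches:
            raise ValueError("population must be nonempty")
        scores = np.array([m.ai_score for m in matches], dtype=float)
        defined = len(scores) > 1
        return cls(
            matches=tuple(matches),
            mean_score=float(scores.mean()),
            stdev_score=float(scores.std(ddof=1)) if defined else 0.0,
            stdev_defined=defined,
            fraction_won=float(np.mean(scores > 0)),
        )

    def preference_table(self) -> pd.DataFrame:
        """Per-move opponent preference mean and sample stdev across matches."""
        counts = np.array([m.preference_counts for m in self.matches], dtype=float)
        return pd.DataFrame(
            {
                "R": [counts[:, 0].mean(), counts[:, 0].std(ddof=1) if len(counts) > 1 else 0.0],
                "P": [counts[:, 1].mean(), counts[:, 1].std(ddof=1) if len(counts) > 1 else 0.0],
                "S": [counts[:, 2].mean(), counts[:, 2].std(ddof=1) if len(counts) > 1 else 0.0],
            },
            index=["MEAN", "STDEV.S"],
        )


def run_match(
    strategy: OpponentStrategy,
    orders: Sequence[int] = tuple(range(1, 6)),
    focus: int = 5,
    rounds: int = 300,
    master_seed: int = 0,
    policy: str = "argmax",
    payoff: PayoffParams = PayoffParams(),
) -> tuple[MatchHistory, MatchSummary]:
    """Play one full match of the multi-AI against an opponent strategy.

    Moves are simultaneous: the strategy never sees the AI's current-round
    move before committing its own. Fully reproducible from the
    configuration, the master seed and the strategy's own seed.
    """
    if rounds < 0:
        raise ValueError(f"rounds must be >= 0, got {rounds}")
    ensemble = MultiAI(orders=orders, focus=focus, seed=master_seed, policy=policy)
    human_moves: list[Move] = []
    ai_moves: list[Move] = []
    for _ in range(rounds):
        ensemble.propose()
        human = strategy.next_move(human_moves, ai_moves)
        record = ensemble.update(human)
        human_moves.append(record.human_move)
        ai_moves.append(record.ai_move)
    history = MatchHistory(
        records=ensemble.history,
        orders=ensemble.orders,
        focus=ensemble.focus,
        master_seed=master_seed,
        policy=policy,
        opponent_spec=strategy.spec(),
    )
    return history, MatchSummary.from_history(history, payoff)


def hypothetical_totals(history: MatchHistory) -> dict[int, int]:
    """In-match per-member hypothetical score totals (selection-coupled).

    The alternative reading of per-model performance: what each member
    *would* have scored on the rounds of one multi-AI match. Coupled to
    the ensemble's play through the shared opponent responses; for
    decoupled per-model totals use :func:`standalone_model_scores`.
    """
    totals = dict.fromkeys(history.orders, 0)
    for rec in history.records:
        for order, s in zip(history.orders, rec.hypothetical_scores):
            totals[order] += s
    return totals


def standalone_model_scores(
    strategy: OpponentStrategy,
    orders: Sequence[int] = tuple(range(1, 11)),
    rounds: int = 300,
    seeds: Sequence[int] = (0,),
    focus: int = 1,
    payoff: PayoffParams = PayoffParams(),
) -> pd.DataFrame:
    """Each single AI alone against fresh instances of the same strategy.

    Plays every order as a degenerate one-member ensemble, one independent
    match per (order, seed) with a freshly re-seeded opponent. Returns a
    DataFrame (rows = seeds, columns = ``AI{m}``) plus a ``mean`` row —
    the per-model score table, free of selection-bias coupling.
    """
    data: dict[str, list[int]] = {}
    for order in orders:
        col: list[int] = []
        for seed in seeds:
            fresh = strategy.spawn(seed=strategy.seed + 7919 * (seed + 1) + order)
            _, summary = run_match(
                fresh,
                orders=[order],
                focus=focus,
                rounds=rounds,
                master_seed=seed,
                payoff=payoff,
            )
            col.append(summary.ai_score)
        data[f"AI{order}"] = col
    frame = pd.DataFrame(data, index=list(seeds))
    frame.loc["mean"] = frame.mean()
    return frame


def population_run(
    population: Sequence[OpponentStrategy],
    orders: Sequence[int] = tuple(range(1, 6)),
    focus: int = 5,
    rounds: int = 300,
    master_seed: int = 0,
    policy: str = "argmax",
    payoff: PayoffParams = PayoffParams(),
) -> PopulationSummary:
    """One match per opponent; aggregate scores across the population.

    Each match gets its own ensemble seeded from (master_seed, match index)
    so no stream is shared between matches.
    """
    if not population:
        raise ValueError("population must be nonempty")
    matches = []
    for i, strategy in enumerate(population):
        _, summary = run_match(
            strategy,
            orders=orders,
            focus=focus,
            rounds=rounds,
            master_seed=master_seed * 10_007 + i,
            policy=policy,
            payoff=payoff,
        )
        matches.append(summary)
    return PopulationSummary.from_matches(matches)


# ---------------------------------------------------------------------------
# replay / verification


@dataclass
class ReplayReport:
    """Per-column agreement between a logged match and its recomputation.

    Each check maps to the list of 1-based round indices that disagree;
    checks that cannot run on the given log are listed in ``not_applicable``
    (e.g. exact move agreement when the log's RNG provenance is unknown).
    """

    rounds: int
    mismatches: dict[str, list[int]] = field(default_factory=dict)
    not_applicable: list[str] = field(default_factory=list)
    count_totals: dict[int, tuple[int, int]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not any(self.mismatches.values())

    def to_dict(self) -> dict:
        return {
            "rounds": self.rounds,
            "ok": self.ok,
            "mismatches": {k: list(v) for k, v in self.mismatches.items()},
            "not_applicable": list(self.not_applicable),
            "count_totals": {
                str(m): {"recomputed": got, "expected": want}
                for m, (got, want) in self.count_totals.items()
            },
        }


def replay(history: MatchHistory, verify_moves: bool | None = None) -> ReplayReport:
    """Re-feed a logged match through the engine and flag disagreements.

    Always recomputed from the logged columns alone (deterministic
    checks): outcomes from the move pair, each member's hypothetical score
    from its hypothetical move, the dominant order from the windowed
    hypothetical scores, and the AI move as the dominant member's
    hypothetical move. Transition-count conservation is re-derived by
    rebuilding every member's chain from the human-move column.

    When the log carries its master seed (``verify_moves`` defaults to
    that), the full match is re-simulated against the recorded human moves
    and the AI/hypothetical move columns are compared bit-for-bit; without
    RNG provenance those columns are marked not-applicable.
    """
    report = ReplayReport(rounds=history.rounds)
    recs = history.records
    mism = report.mismatches
    mism["outcome"] = [
        r.t for r in recs if resolve(r.ai_move, r.human_move) != r.outcome
    ]
    mism["hypothetical_scores"] = [
        r.t
        for r in recs
        if tuple(
            competitive_score(resolve(mv, r.human_move)) for mv in r.hypothetical_moves
        )
        != tuple(r.hypothetical_scores)
    ]
    # dominant order from a brute-force re-sum of the logged windows
    if history.orders:
        bad_dom = []
        bad_ai = []
        for r in recs:
            totals = windowed_scores(recs, r.t, history.focus)
            if select_dominant(totals, history.orders) != r.dominant_order:
                bad_dom.append(r.t)
            if r.dominant_order in history.orders:
                idx = history.orders.index(r.dominant_order)
                if r.hypothetical_moves[idx] != r.ai_move:
                    bad_ai.append(r.t)
        mism["dominant_order"] = bad_dom
        mism["ai_move_is_dominant"] = bad_ai
    else:
        report.not_applicable += ["dominant_order", "ai_move_is_dominant"]

    from .markov import TransitionCounts

    for m in history.orders:
        tc = TransitionCounts.from_history(m, history.human_moves)
        report.count_totals[m] = (tc.total(), max(0, history.rounds - m))

    if verify_moves is None:
        verify_moves = history.master_seed is not None
    if verify_moves and history.master_seed is None:
        raise ValueError("cannot verify move columns: log has no master seed")
    if verify_moves:
        ensemble = MultiAI(
            orders=history.orders,
            focus=history.focus,
            seed=history.master_seed,
            policy=history.policy,
        )
        bad_moves = []
        for r in recs:
            _, hyp, _ = ensemble.propose()
            ensemble.update(r.human_move)
            if hyp != tuple(r.hypothetical_moves):
                bad_moves.append(r.t)
        mism["hypothetical_moves"] = bad_moves
    else:
        report.not_applicable.append("hypothetical_moves")
    return report
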