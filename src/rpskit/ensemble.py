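"""The multi-AI: a bank of single Markov models selected by a focus window.

Every member plays hypothetically each round and is scored against the
opponent's actual move whether or not it is dominant (experts
bookkeeping). Before each round the dominant member is re-selected as the
one with the highest total hypothetical score over the last F completed
rounds (the focus window, which excludes the round about to be played);
ties go to the lowest order. With fewer than F completed rounds the
window is all rounds so far, so in round 1 — an empty window, all totals
zero — the multi-AI plays AI-1's uniform random move.

The focus length F controls the speed and sensitivity of adaptation to
the opponent's strategy changes; re-selection happens every round with no
hysteresis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .game import Move, Outcome, competitive_score, resolve
from .markov import SingleAI

__all__ = ["RoundRecord", "MultiAI", "windowed_scores", "select_dominant"]

#: Preset member banks named after the bank size: orders 1..5 with F=5,
#: orders 1..10 with F=10.
PRESETS = {
    "multi-5ai": (tuple(range(1, 6)), 5),
    "multi-10ai": (tuple(range(1, 11)), 10),
}


@dataclass(frozen=True)
class RoundRecord:
    """One completed round: the played moves plus every member's hypothetical play."""

    t: int  # 1-based round index
    human_move: Move
    ai_move: Move
    outcome: Outcome  # AI perspective
    dominant_order: int
    hypothetical_moves: tuple[Move, ...]  # aligned with the member order list
    hypothetical_scores: tuple[int, ...]


def windowed_scores(history: Sequence[RoundRecord], t: int, F: int) -> list[int]:
    """Per-member hypothetical-score totals over rounds max(1, t-F) .. t-1.

    ``t`` is the upcoming round; the window covers completed rounds only
    (empty at t=1, all rounds when fewer than F exist).
    """
    if t < 1:
        raise ValueError(f"round index must be >= 1, got {t}")
    if F < 1:
        raise ValueError(f"focus length must be >= 1, got {F}")
    window = history[max(0, t - 1 - F) : t - 1]
    if not window:
        n_members = len(history[0].hypothetical_scores) if history else 0
        return [0] * n_members
    totals = [0] * len(window[0].hypothetical_scores)
    for rec in window:
        for i, s in enumerate(rec.hypothetical_scores):
            totals[i] += s
    return totals


def select_dominant(totals: Sequence[int], member_orders: Sequence[int]) -> int:
    """Order of the member with the maximum windowed total; ties to the lowest order."""
    if not totals:
        raise ValueError("totals must be nonempty")
    best_order, best_total = member_orders[0], totals[0]
    for order, total in zip(member_orders[1:], totals[1:]):
        if total > best_total:
            best_order, best_total = order, total
    return best_order


class MultiAI:
    """Ensemble of AI-1..AI-M members with focus length F.

    Parameters
    ----------
    orders : sequence of int
        Distinct positive member orders (sorted internally).
    focus : int
        Focus length F >= 1.
    seed : int
        Master seed; each member derives an independent stream from
        (seed, order), so changing F never alters any member's
        hypothetical move sequence.
    policy : {"argmax", "sample"}
        Prediction rule passed to every member.
    """

    def __init__(
        self,
        orders: Sequence[int] = tuple(range(1, 6)),
        focus: int = 5,
        seed: int = 0,
        policy: str = "argmax",
    ) -> None:
        orders = sorted(int(m) for m in orders)
        if not orders:
            raise ValueError("orders must be nonempty")
        if len(set(orders)) != len(orders):
            raise ValueError(f"orders must be distinct, got {orders}")
        if orders[0] < 1:
            raise ValueError(f"orders must be positive, got {orders}")
        if focus < 1:
            raise ValueError(f"focus length must be >= 1, got {focus}")
        self.orders = tuple(orders)
        self.focus = int(focus)
        self.seed = int(seed)
        self.members = [SingleAI(m, seed=seed, policy=policy) for m in orders]
        self.history: list[RoundRecord] = []
        self.opponent_history: list[Move] = []
        # running focus-window totals, one per member
        self._window_totals = [0] * len(self.members)
        self._pending: tuple[tuple[Move, ...], int] | None = None

    @classmethod
    def from_preset(cls, name: str, seed: int = 0, policy: str = "argmax") -> "MultiAI":
        try:
            orders, focus = PRESETS[name.lower()]
        except KeyError:
            raise ValueError(
                f"unknown preset {name!r}; available: {sorted(PRESETS)}"
            ) from None
        return cls(orders=orders, focus=focus, seed=seed, policy=policy)

    @property
    def round_index(self) -> int:
        """Number of completed rounds."""
        return len(self.history)

    @property
    def dominant_order(self) -> int:
        """Dominant member for the upcoming round."""
        return select_dominant(self._window_totals, self.orders)

    def propose(self) -> tuple[Move, tuple[Move, ...], int]:
        """Generate the upcoming round's play.

        Every member produces a hypothetical move from the opponent-move
        history; the dominant member (highest focus-window total, ties to
        the lowest order) supplies the multi-AI move.
        """
        hist = self.opponent_history
        hyp = tuple(member.choose_move(hist) for member in self.members)
        dom = self.dominant_order
        ai_move = hyp[self.orders.index(dom)]
        self._pending = (hyp, dom)
        return ai_move, hyp, dom

    def update(self, human_move: Move) -> RoundRecord:
        """Close the round: score all members, grow their chains, log the record."""
        if self._pending is None:
            raise RuntimeError("update() called without a preceding propose()")
        hyp, dom = self._pending
        self._pending = None
        human_move = Move(human_move)
        scores = tuple(competitive_score(resolve(mv, human_move)) for mv in hyp)
        t = len(self.history) + 1
        ai_move = hyp[self.orders.index(dom)]
        record = RoundRecord(
            t=t,
            human_move=human_move,
            ai_move=ai_move,
            outcome=resolve(ai_move, human_move),
            dominant_order=dom,
            hypothetical_moves=hyp,
            hypothetical_scores=scores,
        )
        self.history.append(record)
        for member, s in zip(self.members, scores):
            member.record_score(s)
            member.observe(human_move)
        self.opponent_history.append(human_move)
        # slide the focus window: add round t, drop round t - F if present
        F = self.focus
        totals = self._window_totals
        old = self.history[t - 1 - F].hypothetical_scores if t > F else None
        for i, s in enumerate(scores):
            totals[i] += s
            if old is not None:
                totals[i] -= old[i]
        return record

    def play_round(self, human_move: Move) -> RoundRecord:
        """Convenience: propose and resolve one round against ``human_move``."""
        self.propose()
        return self.update(human_move)
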