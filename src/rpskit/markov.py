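"""Single fixed-memory Markov predictors (AI-m).

An order-m chain conditions the opponent's next move on their previous m
moves, estimated by raw transition counts accumulated over the match.
Prediction is the argmax continuation of the current context (ties broken
uniformly at random); the AI then plays the counter of the prediction.
With fewer than m moves observed, or a context never seen before, the
model falls back to a uniform 1/3-1/3-1/3 draw.

Counts are stored raw; normalisation is presentation-only. No smoothing
is applied — the uniform fallback IS the empty-context behaviour.
"""

from __future__ import annotations

import random
from collections import deque
from typing import Iterable, Sequence

import pandas as pd

from .game import MOVE_CHARS, Move, counter

__all__ = ["TransitionCounts", "SingleAI", "all_contexts", "context_label"]

_UNIFORM = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)


def all_contexts(m: int) -> list[tuple[Move, ...]]:
    """All 3**m length-m contexts in lexicographic R < P < S order."""
    contexts: list[tuple[Move, ...]] = [()]
    for _ in range(m):
        contexts = [c + (mv,) for c in contexts for mv in Move]
    return contexts


def context_label(context: Sequence[Move]) -> str:
    """Serialise a context oldest→newest, e.g. (P, S) → ``"PS"``."""
    return "".join(MOVE_CHARS[int(mv)] for mv in context)


class TransitionCounts:
    """Order-m context → next-move count table over one move sequence.

    Each full (context, next) pair in the observed history is counted
    exactly once, so the total count after n observed moves is
    ``max(0, n - m)``.
    """

    def __init__(self, order: int) -> None:
        if order < 1:
            raise ValueError(f"order must be a positive integer, got {order}")
        self.order = order
        self.n_obs = 0
        self._counts: dict[tuple[int, ...], list[int]] = {}
        self._recent: deque[int] = deque(maxlen=order)

    @classmethod
    def from_history(cls, order: int, history: Iterable[Move]) -> "TransitionCounts":
        tc = cls(order)
        tc.update(history)
        return tc

    def update(self, moves: Iterable[Move]) -> None:
        """Observe further opponent moves (incremental extension of the history)."""
        m = self.order
        counts = self._counts
        recent = self._recent
        for mv in moves:
            mv = int(mv)
            if not 0 <= mv <= 2:
                raise ValueError(f"invalid move: {mv!r}")
            if len(recent) == m:
                row = counts.get(ctx := tuple(recent))
                if row is None:
                    row = counts[ctx] = [0, 0, 0]
                row[mv] += 1
            recent.append(mv)
            self.n_obs += 1

    def total(self) -> int:
        return sum(sum(row) for row in self._counts.values())

    def counts_for(self, context: Sequence[Move]) -> tuple[int, int, int]:
        """Raw (R, P, S) continuation counts for a full context (zeros if unseen)."""
        row = self._counts.get(tuple(int(mv) for mv in context))
        return (0, 0, 0) if row is None else tuple(row)  # type: ignore[return-value]

    def distribution(self, context: Sequence[Move]) -> tuple[float, float, float]:
        """Predictive probabilities over the opponent's next move.

        Counts normalised within the context column when the context is
        complete (length m) and has been seen; uniform otherwise.
        """
        if len(context) < self.order:
            return _UNIFORM
        row = self._counts.get(tuple(int(mv) for mv in context[-self.order :]))
        if row is None:
            return _UNIFORM
        tot = row[0] + row[1] + row[2]
        if tot == 0:
            return _UNIFORM
        return (row[0] / tot, row[1] / tot, row[2] / tot)

    def to_frame(self, fractions: bool = False) -> pd.DataFrame:
        """Transition table: rows = next move R/P/S, columns = the 3**m contexts.

        With ``fractions=True`` every cell is divided by the whole-table
        total (the display convention for a printed transition matrix,
        e.g. 18 as the shared denominator after 20 observed moves at m=2).
        """
        cols = {}
        for ctx in all_contexts(self.order):
            row = self._counts.get(tuple(int(mv) for mv in ctx))
            cols[context_label(ctx)] = [0, 0, 0] if row is None else list(row)
        frame = pd.DataFrame(cols, index=list(MOVE_CHARS))
        if fractions:
            tot = self.total()
            frame = frame / tot if tot else frame.astype(float)
        return frame


class SingleAI:
    """One fixed-order predictor with its own deterministic random stream.

    Each AI-m owns an independent stream derived from (master seed, order),
    so replay is bit-stable and one model's draws never perturb another's.

    Parameters
    ----------
    order : int
        Memory length m.
    seed : int
        Master seed; the member stream is derived from (seed, order).
    policy : {"argmax", "sample"}
        How a prediction is drawn from the context column: the argmax
        continuation (default; ties uniform at random) or a sample from
        the normalised column.
    """

    def __init__(self, order: int, seed: int = 0, policy: str = "argmax") -> None:
        if policy not in ("argmax", "sample"):
            raise ValueError(f"policy must be 'argmax' or 'sample', got {policy!r}")
        self.order = order
        self.policy = policy
        self.counts = TransitionCounts(order)
        self.rng = random.Random(1_000_003 * seed + order)
        self.per_round_scores: list[int] = []
        self.last_hypothetical_move: Move | None = None

    def choose_move(self, opponent_history: Sequence[Move]) -> Move:
        """Hypothetical play for the upcoming round.

        Predict the opponent's next move from the current length-m context
        and return its counter; fall back to a uniform draw when the
        history is shorter than m or the context column is empty.
        """
        m = self.order
        n = len(opponent_history)
        if n >= m:
            row = self.counts._counts.get(
                tuple(int(mv) for mv in opponent_history[n - m :])
            )
            if row is not None:
                if self.policy == "sample":
                    pred = self.rng.choices((0, 1, 2), weights=row)[0]
                else:
                    best = max(row)
                    ties = [i for i in (0, 1, 2) if row[i] == best]
                    pred = ties[0] if len(ties) == 1 else self.rng.choice(ties)
                mv = Move((pred + 1) % 3)
                self.last_hypothetical_move = mv
                return mv
        mv = Move(self.rng.randrange(3))
        self.last_hypothetical_move = mv
        return mv

    def observe(self, opponent_move: Move) -> None:
        self.counts.update((opponent_move,))

    def record_score(self, score: int) -> None:
        self.per_round_scores.append(score)

    def predict_distribution(self, context: Sequence[Move]) -> tuple[float, float, float]:
        return self.counts.distribution(context)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SingleAI(order={self.order}, n_obs={self.counts.n_obs})"
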