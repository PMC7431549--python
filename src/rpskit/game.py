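"""Moves, outcome resolution and the two scoring conventions.

Two different currencies are used for the same outcome sequence:

* the *competitive score* (+1 win / 0 draw / -1 loss, from the AI's
  perspective), whose match total is wins minus losses — the headline
  metric for whether the AI beat its opponent; and
* the human player's *virtual points* (2 win / 1 draw / 0 loss, from the
  player's perspective), the experimental currency converted to money as
  ``y = x * r + show_up_fee`` with exchange rate ``r = 0.45 / (1 + a)``.

The payoff parameter ``a`` is the incentive for winning divided by the
incentive for drawing; ``a = 2`` defines the neutral RPS game, for which
the mixed-strategy Nash expectation is (1 + a)/3 = 1 virtual point per
round and a 300-round session is worth exactly 50 RMB in expectation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "Move",
    "Outcome",
    "PayoffParams",
    "counter",
    "resolve",
    "competitive_score",
    "virtual_points",
    "nash_points_per_round",
    "reward",
    "MOVE_CHARS",
    "parse_move",
]


class Move(enum.IntEnum):
    """One of the three RPS actions, with total cyclic dominance.

    The integer coding (R=0, P=1, S=2) makes ``counter(m) == (m + 1) % 3``:
    Paper beats Rock, Scissors beats Paper, Rock beats Scissors.
    """

    ROCK = 0
    PAPER = 1
    SCISSORS = 2

    @property
    def char(self) -> str:
        return MOVE_CHARS[self]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.char


MOVE_CHARS = "RPS"
_CHAR_TO_MOVE = {c: Move(i) for i, c in enumerate(MOVE_CHARS)}


def parse_move(symbol: str) -> Move:
    """Parse a single-character move symbol (``R``/``P``/``S``, case-insensitive)."""
    try:
        return _CHAR_TO_MOVE[symbol.strip().upper()]
    except KeyError:
        raise ValueError(f"invalid move symbol: {symbol!r} (expected one of R, P, S)") from None


class Outcome(enum.IntEnum):
    """Round outcome from the AI's perspective unless stated otherwise."""

    LOSS = -1
    DRAW = 0
    WIN = 1

    @property
    def char(self) -> str:
        return {Outcome.WIN: "W", Outcome.DRAW: "D", Outcome.LOSS: "L"}[self]


def counter(m: Move) -> Move:
    """The move that beats ``m`` (turns a prediction into play)."""
    return Move((int(m) + 1) % 3)


def resolve(ai: Move, opponent: Move) -> Outcome:
    """Outcome of one round, from the AI's perspective."""
    d = (int(ai) - int(opponent)) % 3
    if d == 0:
        return Outcome.DRAW
    return Outcome.WIN if d == 1 else Outcome.LOSS


def competitive_score(o: Outcome) -> int:
    """Win +1, draw 0, loss -1; a match total equals wins minus losses."""
    return int(o)


def virtual_points(o: Outcome) -> int:
    """The player's experimental currency: 2 per win, 1 per draw, 0 per loss.

    ``o`` is from the *player's* perspective: pass the inverse of the AI
    outcome (see :meth:`Outcome` antisymmetry) when working from AI logs.
    """
    return int(o) + 1


@dataclass(frozen=True)
class PayoffParams:
    """Session payoff configuration.

    Parameters
    ----------
    a : float
        Payoff parameter (incentive for winning / incentive for drawing);
        ``a = 2`` is the neutral game.
    rounds : int
        Number of rounds per session.
    show_up_fee : float
        Flat participation payment, in RMB.
    r : float, optional
        Exchange rate (RMB per virtual point). Derived as ``0.45 / (1 + a)``
        when not given explicitly.
    """

    a: float = 2.0
    rounds: int = 300
    show_up_fee: float = 5.0
    r: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"payoff parameter a must be positive, got {self.a}")
        if self.rounds < 0:
            raise ValueError(f"rounds must be non-negative, got {self.rounds}")
        if self.r is None:
            object.__setattr__(self, "r", 0.45 / (1.0 + self.a))


def nash_points_per_round(a: float) -> float:
    """Expected virtual points per round under uniform (Nash) play: (1 + a) / 3."""
    return (1.0 + a) / 3.0


def reward(x: float, params: PayoffParams = PayoffParams()) -> float:
    """Total session reward in RMB: ``x * r + show_up_fee``.

    ``x`` is the player's total virtual points for the session; negative
    totals are impossible and rejected.
    """
    if x < 0:
        raise ValueError(f"virtual points must be non-negative, got {x}")
    return x * params.r + params.show_up_fee
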