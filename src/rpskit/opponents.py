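"""Synthetic opponent strategies standing in for human players.

Every other part of the engine is testable without human-subject data
because these generators emit reproducible move streams: given the same
(parameters, seed, observed history) a strategy always emits the same
move. Strategies see the full two-sided history (their own moves and the
AI's), which conditional responders such as win-stay-lose-shift need.

The set deliberately spans behaviours that different single orders are
blind to — e.g. a period-4 cycle defeats AI-1 but is transparent to
AI-4 — which is the ensemble's reason to exist. It is an engineering
choice, not a claim about what real players do.
"""

from __future__ import annotations

import random
from typing import Mapping, Sequence

from .game import Move, counter, parse_move

__all__ = [
    "OpponentStrategy",
    "Uniform",
    "BiasedIID",
    "Constant",
    "Cycle",
    "WinStayLoseShift",
    "CounterOwnLast",
    "MarkovGenerator",
    "Switching",
    "make_strategy",
    "generate_population",
    "default_population",
    "STRATEGY_CLASSES",
]


def _as_moves(seq) -> tuple[Move, ...]:
    if isinstance(seq, str):
        return tuple(parse_move(c) for c in seq)
    return tuple(Move(m) for m in seq)


class OpponentStrategy:
    """Base class: a named, parameterised, seeded move generator.

    Subclasses implement :meth:`_move`, receiving the strategy's own move
    history and the AI's move history (both oldest→newest, equal length).
    """

    name = "base"

    def __init__(self, seed: int = 0) -> None:
        self.seed = int(seed)
        self.rng = random.Random(2_147_483_629 * self.seed + 12345)

    # -- public API ---------------------------------------------------------
    def next_move(self, own_history: Sequence[Move], ai_history: Sequence[Move]) -> Move:
        if len(own_history) != len(ai_history):
            raise ValueError("own and AI histories must have equal length")
        return self._move(own_history, ai_history)

    def spawn(self, seed: int) -> "OpponentStrategy":
        """A fresh instance of the same strategy with a different stream."""
        return make_strategy(self.name, seed=seed, **self.params())

    def params(self) -> dict:
        """Strategy-specific parameters (serialisable; excludes the seed)."""
        return {}

    def spec(self) -> dict:
        return {"name": self.name, "seed": self.seed, **self.params()}

    def _move(self, own: Sequence[Move], ai: Sequence[Move]) -> Move:
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover
        inner = ", ".join(f"{k}={v!r}" for k, v in self.spec().items())
        return f"{type(self).__name__}({inner})"


class Uniform(OpponentStrategy):
    """Mixed-strategy Nash play: uniform 1/3 each, unexploitable in expectation."""

    name = "uniform"

    def _move(self, own, ai):
        return Move(self.rng.randrange(3))


class BiasedIID(OpponentStrategy):
    """Independent draws from a fixed non-uniform distribution (p_R, p_P, p_S)."""

    name = "biased"

    def __init__(self, probs: Sequence[float], seed: int = 0) -> None:
        super().__init__(seed)
        probs = tuple(float(p) for p in probs)
        if len(probs) != 3 or any(p < 0 for p in probs) or sum(probs) <= 0:
            raise ValueError(f"probs must be 3 non-negative weights, got {probs}")
        self.probs = probs

    def params(self):
        return {"probs": list(self.probs)}

    def _move(self, own, ai):
        return Move(self.rng.choices((0, 1, 2), weights=self.probs)[0])


class Constant(OpponentStrategy):
    """Always the same move."""

    name = "constant"

    def __init__(self, move: Move | str, seed: int = 0) -> None:
        super().__init__(seed)
        self.move = parse_move(move) if isinstance(move, str) else Move(move)

    def params(self):
        return {"move": self.move.char}

    def _move(self, own, ai):
        return self.move


class Cycle(OpponentStrategy):
    """Deterministic repetition of a fixed move sequence."""

    name = "cycle"

    def __init__(self, sequence: Sequence[Move] | str, seed: int = 0) -> None:
        super().__init__(seed)
        seq = _as_moves(sequence)
        if not seq:
            raise ValueError("cycle sequence must be nonempty")
        self.sequence = seq

    def params(self):
        return {"sequence": "".join(m.char for m in self.sequence)}

    def _move(self, own, ai):
        return self.sequence[len(own) % len(self.sequence)]


class WinStayLoseShift(OpponentStrategy):
    """Repeat the own move after a win or draw; after a loss, shift to the
    move that would have beaten the AI's last move. First move uniform."""

    name = "wsls"

    def _move(self, own, ai):
        if not own:
            return Move(self.rng.randrange(3))
        last_own, last_ai = own[-1], ai[-1]
        # player perspective: they lost iff the AI's move beat theirs
        lost = counter(last_own) == last_ai
        return counter(last_ai) if lost else last_own


class CounterOwnLast(OpponentStrategy):
    """Play the move that beats one's own previous move (a circular shifter)."""

    name = "counter_own"

    def _move(self, own, ai):
        if not own:
            return Move(self.rng.randrange(3))
        return counter(own[-1])


class MarkovGenerator(OpponentStrategy):
    """Generate from a known order-k Markov chain over the opponent's own moves.

    ``table`` maps each length-k context (a string such as ``"RP"``) to a
    3-vector of next-move weights (R, P, S); contexts absent from the
    table, and the first k rounds, are played uniformly. Useful as a
    ground-truth chain for parameter-recovery checks.
    """

    name = "markov_gen"

    def __init__(self, order: int, table: Mapping[str, Sequence[float]], seed: int = 0) -> None:
        super().__init__(seed)
        if order < 1:
            raise ValueError(f"order must be >= 1, got {order}")
        self.order = int(order)
        self.table: dict[tuple[Move, ...], tuple[float, ...]] = {}
        for ctx, weights in table.items():
            key = _as_moves(ctx)
            if len(key) != self.order:
                raise ValueError(f"context {ctx!r} does not have length {self.order}")
            w = tuple(float(x) for x in weights)
            if len(w) != 3 or any(x < 0 for x in w) or sum(w) <= 0:
                raise ValueError(f"weights for context {ctx!r} must be 3 non-negative values")
            self.table[key] = w

    def params(self):
        return {
            "order": self.order,
            "table": {
                "".join(m.char for m in k): list(v) for k, v in self.table.items()
            },
        }

    def _move(self, own, ai):
        if len(own) >= self.order:
            weights = self.table.get(tuple(own[-self.order :]))
            if weights is not None:
                return Move(self.rng.choices((0, 1, 2), weights=weights)[0])
        return Move(self.rng.randrange(3))


class Switching(OpponentStrategy):
    """Emulate a mid-match strategy change: a schedule of (sub-strategy, rounds).

    Each stage plays for its round budget, then hands over; the final
    stage plays forever. Sub-strategies see the full two-sided history.
    """

    name = "switching"

    def __init__(self, schedule: Sequence, seed: int = 0) -> None:
        super().__init__(seed)
        if not schedule:
            raise ValueError("switching schedule must be nonempty")
        self.stages: list[tuple[OpponentStrategy, int]] = []
        for i, (strat, n_rounds) in enumerate(schedule):
            if isinstance(strat, Mapping):
                strat = make_strategy(**{**strat, "seed": strat.get("seed", seed * 101 + i)})
            if n_rounds < 1:
                raise ValueError(f"stage round count must be >= 1, got {n_rounds}")
            self.stages.append((strat, int(n_rounds)))

    def params(self):
        return {
            "schedule": [[s.spec(), n] for s, n in self.stages],
        }

    def spawn(self, seed: int) -> "Switching":
        schedule = [
            ({**s.spec(), "seed": seed * 101 + i}, n)
            for i, (s, n) in enumerate(self.stages)
        ]
        return Switching(schedule, seed=seed)

    def _move(self, own, ai):
        t = len(own)  # 0-based index of the round being played
        for strat, n_rounds in self.stages:
            if t < n_rounds:
                return strat._move(own, ai)
            t -= n_rounds
        return self.stages[-1][0]._move(own, ai)


STRATEGY_CLASSES: dict[str, type[OpponentStrategy]] = {
    cls.name: cls
    for cls in (
        Uniform,
        BiasedIID,
        Constant,
        Cycle,
        WinStayLoseShift,
        CounterOwnLast,
        MarkovGenerator,
        Switching,
    )
}


def make_strategy(name: str, seed: int = 0, **params) -> OpponentStrategy:
    """Instantiate a strategy by name; malformed parameters fail here, not at play."""
    try:
        cls = STRATEGY_CLASSES[name]
    except KeyError:
        raise ValueError(
            f"unknown strategy {name!r}; available: {sorted(STRATEGY_CLASSES)}"
        ) from None
    return cls(seed=seed, **params)


def generate_population(entries: Sequence[Mapping]) -> list[OpponentStrategy]:
    """Build a reproducibly seeded population from a spec.

    Each entry is a mapping with ``name``, optional strategy parameters, a
    ``count`` (default 1) and a ``seed`` base; instance i of an entry gets
    seed ``seed + i``. Duplicate effective seeds across the population are
    rejected so no two opponents share a stream.
    """
    population: list[OpponentStrategy] = []
    seen_seeds: set[int] = set()
    for entry in entries:
        entry = dict(entry)
        name = entry.pop("name")
        count = int(entry.pop("count", 1))
        seed_base = int(entry.pop("seed", 0))
        if count < 1:
            raise ValueError(f"count must be positive for strategy {name!r}")
        for i in range(count):
            seed = seed_base + i
            if seed in seen_seeds:
                raise ValueError(f"duplicate opponent seed {seed} in population spec")
            seen_seeds.add(seed)
            population.append(make_strategy(name, seed=seed, **entry))
    return population


def default_population_spec(seed_base: int = 0) -> list[dict]:
    """Spec for the shipped 52-opponent synthetic population.

    A mix of patterned, hence exploitable, behaviours: constants, cycles
    of period 2–5, self-counter shifters, biased coins, strongly patterned
    first-order chains, win-stay-lose-shift players, and mid-match
    switchers. Seeds are offsets from ``seed_base`` so the whole
    population re-seeds coherently.
    """
    s = int(seed_base) * 1000
    entries: list[dict] = [
        {"name": "constant", "move": "R", "count": 1, "seed": s + 0},
        {"name": "constant", "move": "P", "count": 1, "seed": s + 1},
        {"name": "constant", "move": "S", "count": 1, "seed": s + 2},
        {"name": "cycle", "sequence": "RP", "count": 1, "seed": s + 10},
        {"name": "cycle", "sequence": "PS", "count": 1, "seed": s + 11},
        {"name": "cycle", "sequence": "RS", "count": 1, "seed": s + 12},
        {"name": "cycle", "sequence": "RPS", "count": 1, "seed": s + 13},
        {"name": "cycle", "sequence": "RSP", "count": 1, "seed": s + 14},
        {"name": "cycle", "sequence": "RRPS", "count": 1, "seed": s + 15},
        {"name": "cycle", "sequence": "RPPS", "count": 1, "seed": s + 16},
        {"name": "cycle", "sequence": "RPSSP", "count": 1, "seed": s + 17},
        {"name": "cycle", "sequence": "RRPPS", "count": 1, "seed": s + 18},
        {"name": "cycle", "sequence": "PPSR", "count": 1, "seed": s + 19},
        {"name": "cycle", "sequence": "SSRP", "count": 1, "seed": s + 80},
        {"name": "counter_own", "count": 3, "seed": s + 20},
        {"name": "biased", "probs": [0.6, 0.2, 0.2], "count": 2, "seed": s + 30},
        {"name": "biased", "probs": [0.2, 0.6, 0.2], "count": 2, "seed": s + 32},
        {"name": "biased", "probs": [0.2, 0.2, 0.6], "count": 2, "seed": s + 34},
        {"name": "biased", "probs": [0.7, 0.2, 0.1], "count": 2, "seed": s + 36},
        {"name": "biased", "probs": [0.1, 0.3, 0.6], "count": 2, "seed": s + 38},
        {"name": "biased", "probs": [0.5, 0.35, 0.15], "count": 2, "seed": s + 40},
        {"name": "biased", "probs": [0.15, 0.7, 0.15], "count": 2, "seed": s + 42},
        {
            "name": "markov_gen",
            "order": 1,
            "table": {"R": [0.1, 0.8, 0.1], "P": [0.1, 0.1, 0.8], "S": [0.8, 0.1, 0.1]},
            "count": 3,
            "seed": s + 50,
        },
        {
            "name": "markov_gen",
            "order": 1,
            "table": {"R": [0.8, 0.1, 0.1], "P": [0.1, 0.8, 0.1], "S": [0.1, 0.1, 0.8]},
            "count": 3,
            "seed": s + 53,
        },
        {
            "name": "markov_gen",
            "order": 1,
            "table": {"R": [0.1, 0.1, 0.8], "P": [0.8, 0.1, 0.1], "S": [0.1, 0.8, 0.1]},
            "count": 3,
            "seed": s + 56,
        },
        {"name": "wsls", "count": 6, "seed": s + 60},
        {
            "name": "switching",
            "schedule": [
                [{"name": "constant", "move": "R"}, 100],
                [{"name": "cycle", "sequence": "PS"}, 200],
            ],
            "count": 2,
            "seed": s + 70,
        },
        {
            "name": "switching",
            "schedule": [
                [{"name": "cycle", "sequence": "RPS"}, 150],
                [{"name": "cycle", "sequence": "SPR"}, 150],
            ],
            "count": 2,
            "seed": s + 72,
        },
        {
            "name": "switching",
            "schedule": [
                [{"name": "biased", "probs": [0.7, 0.15, 0.15]}, 150],
                [{"name": "biased", "probs": [0.15, 0.15, 0.7]}, 150],
            ],
            "count": 2,
            "seed": s + 74,
        },
    ]
    return entries


def default_population(seed_base: int = 0) -> list[OpponentStrategy]:
    """The shipped 52-opponent synthetic population (see spec above)."""
    population = generate_population(default_population_spec(seed_base))
    assert len(population) == 52
    return population
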