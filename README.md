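# rpskit

An engine for exploiting sequential dependence in iterated
Rock-Paper-Scissors (RPS). Human players — and many scripted agents —
do not play the uniform mixed-strategy Nash equilibrium: their next move
leaks information through their recent history. `rpskit` models an
opponent's move stream with a bank of fixed-memory Markov chains and
adaptively plays the best-performing one, for researchers in behavioural
game theory and for anyone building or evaluating sequence-exploiting
game agents.

## The model

**Single AI (AI-m).** An order-m Markov chain over the *opponent's* move
sequence. After each round the transition count
N(x<sub>t−m</sub> … x<sub>t−1</sub> → x<sub>t</sub>) is incremented, so
after n observed moves the table holds exactly max(0, n − m) counts. To
play, AI-m looks up the current length-m context, predicts the opponent's
next move as the argmax of the context column (ties uniform at random),
and plays its counter. With fewer than m moves observed, or an unseen
context, it predicts uniformly: Pr(R) = Pr(P) = Pr(S) = 1/3.

**Multi-AI.** A bank AI-1 … AI-M plays every round *hypothetically*; each
member is scored +1/0/−1 against the opponent's actual move whether or
not it played. Before round t, the member with the highest total
hypothetical score over the last F completed rounds — the **focus
length** window, rounds max(1, t−F) … t−1, ties to the lowest order —
becomes dominant and supplies the move. F controls the speed and
sensitivity of adaptation when the opponent changes strategy. The
presets `multi-5ai` (orders 1–5, F = 5) and `multi-10ai` (orders 1–10,
F = 10) are built in.

**Scoring and payoff.** The AI-side competitive score is wins − losses.
The opponent ("player") earns 2 virtual points per win and 1 per draw;
with payoff parameter a (= 2 for the neutral game) the session reward is
y = x·r + 5 RMB with exchange rate r = 0.45/(1 + a) = 0.15, so a
300-round session at the Nash expectation of (1 + a)/3 points per round
is worth exactly 50 RMB.

## Worked example

Simulate the multi-5AI against a deterministic period-3 cycler for 300
rounds:

```sh
rpskit simulate --preset multi-5ai --opponent cycle:RPS --rounds 300 --seed 7
```

```json
{
  "rounds": 300,
  "ai_wins": 298,
  "draws": 2,
  "ai_losses": 0,
  "ai_score": 298,
  "player_virtual_points": 2,
  "player_reward": 5.3,
  "preference_counts": {"R": 100, "P": 100, "S": 100}
}
```

After a two-round burn-in (round 1 is a uniform draw; round 2's context
is still unseen) the order-1 member has seen every transition of the
cycle and wins permanently: 298 wins, 2 draws, score +298. The cycler
earns only its 2 draw points, worth 2 × 0.15 + 5 = 5.30 RMB.

The same engine against the shipped 52-opponent synthetic population
(constants, cycles, biased coins, first-order generators,
win-stay-lose-shift players and mid-match switchers):

```sh
rpskit bench --preset multi-5ai --rounds 300 --seed 0
```

```json
{
  "matches": 52,
  "mean_score": 200.57692307692307,
  "stdev_score": 91.28974474840678,
  "fraction_won": 1.0
}
```

The multi-AI wins all 52 matches with a mean score of about +201 over
300 rounds (sample standard deviation ≈ 91 — patterned opponents differ
widely in how fast they are exploited).

From Python, the same run is:

```python
from rpskit import default_population, population_run

summary = population_run(default_population(0), orders=range(1, 6), focus=5,
                         rounds=300, master_seed=0)
print(summary.mean_score, summary.fraction_won)
```

Other entry points: `rpskit play` (interactive session against the
multi-AI, with a resumable log), `rpskit replay LOG` (re-feeds a logged
match through the engine and verifies every column), and
`standalone_model_scores(...)` for per-order score tables.

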