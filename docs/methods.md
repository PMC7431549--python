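# Methods

## Model

The engine treats an iterated RPS opponent as a stochastic process and
fits, online, one order-m Markov chain per memory length m. For the
chain of order m the predictive distribution of the opponent's next move
given context c = (x<sub>t−m</sub>, …, x<sub>t−1</sub>) is the
empirical conditional

    Pr(X_t = x | c) = N(c → x) / Σ_y N(c → y),

where N is the raw transition-count table accumulated over the match.
Counts are never smoothed: an unseen context (or a history shorter than
m) yields the uniform 1/3-1/3-1/3 prediction. This is deliberate — the
uniform fallback is the model's defined behaviour for missing data, and
Laplace-style pseudocounts would blur the early-match dynamics the focus
window reacts to. Counts conserve exactly: after n observed moves the
table total is max(0, n − m), which the suite checks exhaustively for
all histories up to length 8.

The chain models the *opponent's* moves only, not joint (own, opponent)
states: the context a member conditions on is the opponent's last m
plays.

Play is argmax-then-counter: predict the most frequent continuation of
the context (ties broken uniformly at random) and play the move that
beats it. Against a stationary opponent the argmax rule maximises the
expected per-round score. Sampling the prediction from the normalised
column instead is available via `policy="sample"` on `SingleAI` /
`MultiAI`; on a uniform column the two rules coincide.

## Ensemble selection

All M members play hypothetically every round and are scored against the
opponent's actual move (+1/0/−1). The dominant member for round t is the
argmax of the summed hypothetical scores over rounds
max(1, t−F) … t−1 — the window never includes the round being played,
and shrinks to "all rounds so far" early in the match, so round 1 is an
all-zero tie. Ties resolve to the lowest order, which is why the
lowest-order member opens the match with a uniform random move.
Re-selection happens every round with no hysteresis; the focus length F
alone sets how fast dominance can shift when the opponent changes
behaviour (small F adapts fast but is noisy; large F is stable but
slow).

Each member owns an independent deterministic random stream derived as
`Random(1_000_003 * master_seed + order)`. Consequences: (i) identical
(configuration, master seed, opponent) reproduce a match bit for bit;
(ii) changing F changes only which member's move is *played*, never any
member's hypothetical move sequence (asserted in the suite by sweeping F
against a history-independent opponent).

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `orders` | member memory lengths | 1–5 (`multi-5ai`); 1–10 (`multi-10ai`) | the two named bank presets |
| `focus` (F) | selection window, rounds | 5 (with orders 1–5), 10 (with 1–10) | paired with the presets |
| `rounds` | session length | 300 | the standard session |
| `a` | payoff parameter (win/draw incentive ratio) | 2 | the neutral game |
| `show_up_fee` | flat payment, RMB | 5 | session accounting |
| `r` | RMB per virtual point | 0.45/(1+a) = 0.15 | makes the Nash-expectation session worth exactly 50 RMB |
| `policy` | prediction rule | `argmax` | see above |

## Synthetic opponents

The `opponents` module generates every input the engine is tested on.
The shipped default population holds 52 opponents: 3 constants, 11
cycles of period 2–5, 3 self-counter shifters, 14 biased i.i.d. coins,
9 strongly patterned first-order Markov generators, 6
win-stay-lose-shift players and 6 mid-match switchers. Every class was
verified exploitable by brute-force simulation before being frozen
(e.g. win-stay-lose-shift: mean multi-5AI score ≈ +123/300, minimum +60
over 200 seeds); pure uniform (Nash) opponents are excluded from the
default because they are unexploitable by construction and belong in
neutrality tests instead.

What the generators emulate is *patterned, reactive play with occasional
strategy changes*; what they do not emulate is the richness of real
human behaviour — drift, fatigue, deliberate randomisation, responses
to the score display. A high win fraction against this population
demonstrates that the engine exploits the pattern classes it was built
for; it is not a measurement of performance against people.

## Numerical and design choices

* Competitive score fixed at +1/0/−1 (total = wins − losses): the only
  convention consistent with a 198-win/55-draw/47-loss match totalling
  151 and with small integer window scores.
* Outcomes are stored once, from the AI's perspective; player-side
  quantities (virtual points, player score) are derived by negation,
  never stored separately.
* Dominant selection uses the *stored* hypothetical moves of past
  rounds; moves are never resampled retroactively.
* Contexts are ordered oldest→newest and serialised as concatenated
  symbols ("PS" = Paper then Scissors); exported transition tables put
  next-moves on rows and the 3^m contexts on columns, lexicographic with
  R < P < S, as raw counts or as fractions of the whole-table total.
* Population statistics use the sample (n−1) standard deviation; a
  single-match population reports stdev 0.0 with an explicit
  `stdev_defined=False` flag rather than NaN.
* Standalone per-model score tables play each order in an *independent*
  match against a freshly re-seeded opponent instance, avoiding the
  selection coupling of reading hypothetical totals out of one ensemble
  match; the in-match reading is also exposed (`hypothetical_totals`)
  and labelled as coupled.
* Degenerate inputs: 0-round matches are valid (empty log, score 0);
  a one-member bank reduces exactly to the bare single model, asserted
  move-for-move.
* Match logs are tab-separated text with a commented provenance header
  (format version, full configuration JSON, config hash) sufficient to
  re-simulate the match bit for bit. Foreign tabular logs are adapted
  via an explicit column mapping, not format guessing; with only a
  human-move column, deterministic checks (count conservation,
  outcome arithmetic) still run and RNG-dependent columns are reported
  as not-applicable.

## Problem sizes in the suite

The suite plays 300-round matches (the standard session) for bounds and
population checks, 10<sup>4</sup>-round matches for neutrality and
parameter-recovery checks (mean absolute deviation of recovered
first-order transition probabilities < 0.05), and sweeps master seeds
0..99 where a bound is asserted seed-universally. The full population
check — 52 opponents × 300 rounds × 100 seeds — is the largest single
computation and runs in well under a minute.

## Known limitations

* Exploitation bounds are proven by simulation over a finite seed range,
  not analytically; the burn-in argument (a constant opponent is
  counter-played by AI-1 from round 3 on, hence score ≥ 296/300) is the
  one case simple enough to reason out exactly, and holds for the
  single-model configuration. The full ensemble can lose a few extra
  burn-in rounds while a higher-order member playing uniformly is
  transiently dominant, so its observed constant-opponent minimum is
  slightly lower (293/300 over seeds 0..99).
* Member selection is winner-take-all; weighted voting across members,
  pre-training phases and member pruning are out of scope.
* The focus length is a fixed hyperparameter; nothing learns it.
* Interactive play enforces no per-round time limit.
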