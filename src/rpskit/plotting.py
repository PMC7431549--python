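"""Optional figures: cumulative-score trajectories and population score bars."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless use; callers can switch backends first
import matplotlib.pyplot as plt

from .tournament import MatchSummary, PopulationSummary

__all__ = ["plot_trajectory", "plot_population_scores"]


def plot_trajectory(
    summaries: Sequence[MatchSummary] | MatchSummary,
    labels: Sequence[str] | None = None,
    ax: "plt.Axes | None" = None,
):
    """Cumulative AI score vs round, one line per match."""
    if isinstance(summaries, MatchSummary):
        summaries = [summaries]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for i, s in enumerate(summaries):
        label = labels[i] if labels else f"match {i + 1}"
        ax.plot(range(1, s.rounds + 1), s.score_trajectory, label=label)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("round")
    ax.set_ylabel("cumulative AI score (wins − losses)")
    ax.legend(fontsize="small")
    return ax


def plot_population_scores(summary: PopulationSummary, ax: "plt.Axes | None" = None):
    """Per-opponent total AI score bars for a population run."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    scores = [m.ai_score for m in summary.matches]
    ax.bar(range(1, len(scores) + 1), scores)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("opponent")
    ax.set_ylabel("total AI score")
    ax.set_title(
        f"mean {summary.mean_score:.1f}, "
        f"AI wins {100 * summary.fraction_won:.1f}% of matches"
    )
    return ax
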