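"""Match-log and summary-table file formats.

A match log is plain tab-separated text, one row per round, with a
commented provenance header (version, configuration, seed, config hash)
sufficient to reproduce the match bit-for-bit. Columns: round index,
human move, AI move, outcome (W/D/L, AI perspective), dominant order,
then per-member hypothetical move and score — a machine twin of the
engine's internal bookkeeping table. Moves are single R/P/S characters.

Foreign tabular logs (e.g. deposited experiment data with unknown layout)
are adapted with an explicit column mapping rather than guessed at.
"""

from __future__ import annotations

import hashlib
import io
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .ensemble import RoundRecord
from .game import Move, Outcome, parse_move, resolve
from .tournament import MatchHistory

__all__ = ["write_log", "read_log", "read_foreign_log", "LogParseError"]

FORMAT_NAME = "rpskit-match-log"
FORMAT_VERSION = 1

_OUTCOME_CHARS = {"W": Outcome.WIN, "D": Outcome.DRAW, "L": Outcome.LOSS}


class LogParseError(ValueError):
    """Raised with the offending line number when a log cannot be parsed."""

    def __init__(self, message: str, line: int | None = None) -> None:
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


def _config_dict(history: MatchHistory) -> dict:
    return {
        "orders": list(history.orders),
        "focus": history.focus,
        "seed": history.master_seed,
        "policy": history.policy,
        "opponent": history.opponent_spec,
    }


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def write_log(history: MatchHistory, path: str | Path) -> None:
    """Write a match log with its provenance header."""
    path = Path(path)
    config = _config_dict(history)
    lines = [
        f"# {FORMAT_NAME} v{FORMAT_VERSION}",
        f"# config: {json.dumps(config, sort_keys=True)}",
        f"# config_sha256: {_config_hash(config)}",
        f"# rounds: {history.rounds}",
    ]
    cols = ["t", "human", "ai", "outcome", "dominant"]
    cols += [f"hm{m}" for m in history.orders]
    cols += [f"hs{m}" for m in history.orders]
    lines.append("\t".join(cols))
    for r in history.records:
        row = [
            str(r.t),
            r.human_move.char,
            r.ai_move.char,
            r.outcome.char,
            str(r.dominant_order),
        ]
        row += [mv.char for mv in r.hypothetical_moves]
        row += [str(s) for s in r.hypothetical_scores]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_log(path: str | Path) -> MatchHistory:
    """Parse a match log back into a :class:`MatchHistory`."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as e:
        raise LogParseError(str(e)) from e
    config: dict = {}
    header_lines = 0
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.startswith("#"):
            break
        header_lines = i
        if line.startswith("# config:"):
            try:
                config = json.loads(line.partition("# config:")[2])
            except json.JSONDecodeError as e:
                raise LogParseError(f"malformed config header: {e}", line=i) from e
    if not config:
        raise LogParseError("missing '# config:' header line", line=header_lines or 1)
    orders = tuple(int(m) for m in config["orders"])
    try:
        frame = pd.read_csv(io.StringIO(text), sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError as e:
        raise LogParseError("no column header found", line=header_lines + 1) from e
    expected = (
        ["t", "human", "ai", "outcome", "dominant"]
        + [f"hm{m}" for m in orders]
        + [f"hs{m}" for m in orders]
    )
    if list(frame.columns) != expected:
        raise LogParseError(
            f"unexpected columns {list(frame.columns)} (expected {expected})",
            line=header_lines + 1,
        )
    records: list[RoundRecord] = []
    for pos, row in enumerate(frame.itertuples(index=False)):
        line_no = header_lines + 2 + pos
        try:
            rec = RoundRecord(
                t=int(row.t),
                human_move=parse_move(row.human),
                ai_move=parse_move(row.ai),
                outcome=_OUTCOME_CHARS[row.outcome.strip().upper()],
                dominant_order=int(row.dominant),
                hypothetical_moves=tuple(
                    parse_move(getattr(row, f"hm{m}")) for m in orders
                ),
                hypothetical_scores=tuple(
                    int(getattr(row, f"hs{m}")) for m in orders
                ),
            )
        except (ValueError, KeyError, AttributeError) as e:
            raise LogParseError(f"bad round row: {e}", line=line_no) from e
        if rec.t != pos + 1:
            raise LogParseError(
                f"round index {rec.t} out of sequence (expected {pos + 1})",
                line=line_no,
            )
        records.append(rec)
    return MatchHistory(
        records=records,
        orders=orders,
        focus=int(config["focus"]),
        master_seed=config.get("seed"),
        policy=config.get("policy", "argmax"),
        opponent_spec=config.get("opponent"),
    )


def read_foreign_log(
    path: str | Path,
    columns: Mapping[str, str],
    sep: str = "\t",
    orders: Sequence[int] = (),
    focus: int = 5,
) -> MatchHistory:
    """Adapt any tabular log with at least a human-move column.

    ``columns`` maps the roles ``human`` (required) and optionally ``ai``
    and ``t`` to the file's own column names. Rounds missing an AI move are
    filled with a placeholder pair carrying a draw outcome, usable for
    human-side analyses (counts, preferences, chain rebuilding) only.
    """
    if "human" not in columns:
        raise LogParseError("column mapping must include 'human'")
    frame = pd.read_csv(path, sep=sep, comment="#")
    for role, name in columns.items():
        if name not in frame.columns:
            raise LogParseError(f"mapped column {name!r} (role {role!r}) not in file")
    records: list[RoundRecord] = []
    orders = tuple(orders)
    n_members = len(orders)
    for pos in range(len(frame)):
        human = parse_move(str(frame[columns["human"]].iloc[pos]))
        ai = (
            parse_move(str(frame[columns["ai"]].iloc[pos]))
            if "ai" in columns
            else human  # placeholder: self-draw, human side still analysable
        )
        outcome = resolve(ai, human)
        records.append(
            RoundRecord(
                t=pos + 1,
                human_move=human,
                ai_move=ai,
                outcome=outcome,
                dominant_order=orders[0] if orders else 0,
                hypothetical_moves=(ai,) * n_members,
                hypothetical_scores=(int(outcome),) * n_members,
            )
        )
    return MatchHistory(records=records, orders=orders, focus=focus)
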