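"""Scoring detected events against ground truth.

Detections are matched one-to-one to truth events by onset proximity
(greedy, in time order, within a tolerance window); unmatched truth events
are misses and unmatched detections are false alarms.  From the matching
the standard report formats follow: a 3x3 predicted-by-actual confusion
matrix with miss/false-alarm margins, and per-label accuracy rows printed
as ``detected/actual  percent`` (one decimal, three on request).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import EVENT_LABELS, EventRecord

__all__ = [
    "MatchResult",
    "EvalReport",
    "match_events",
    "confusion_matrix",
    "accuracy_from_counts",
    "summarize_session",
]


@dataclass(frozen=True)
class MatchResult:
    """One-to-one event matching outcome."""

    pairs: tuple[tuple[EventRecord, EventRecord], ...]  # (truth, detected)
    misses: tuple[EventRecord, ...]
    false_alarms: tuple[EventRecord, ...]
    tolerance_s: float


@dataclass(frozen=True)
class EvalReport:
    """Confusion matrix plus per-label accuracy table."""

    confusion: pd.DataFrame  # rows: predicted labels (+missed), cols: actual (+false_alarm)
    per_label: pd.DataFrame  # index: label; columns: actual, detected, accuracy_pct


def _check_sorted(events: Sequence[EventRecord], name: str) -> None:
    onsets = [e.onset for e in events]
    if onsets != sorted(onsets):
        raise ValueError(f"{name} events must be sorted by onset")


def match_events(
    detected: Sequence[EventRecord],
    truth: Sequence[EventRecord],
    tolerance_s: float = 0.5,
) -> MatchResult:
    """Greedily pair each truth event with the nearest unmatched detection
    whose onset lies within ``tolerance_s``.

    Truth events are visited in time order, so when one detection could
    serve two truth events the earlier truth wins and the later one counts
    as a miss (the accounting used for merged events).
    """
    _check_sorted(detected, "detected")
    _check_sorted(truth, "truth")
    used = [False] * len(detected)
    pairs = []
    misses = []
    for t in truth:
        best, best_d = None, None
        for j, d in enumerate(detected):
            if used[j]:
                continue
            dist = abs(d.onset - t.onset)
            if dist <= tolerance_s and (best_d is None or dist < best_d):
                best, best_d = j, dist
        if best is None:
            misses.append(t)
        else:
            used[best] = True
            pairs.append((t, detected[best]))
    false_alarms = [d for j, d in enumerate(detected) if not used[j]]
    return MatchResult(
        pairs=tuple(pairs),
        misses=tuple(misses),
        false_alarms=tuple(false_alarms),
        tolerance_s=tolerance_s,
    )


def confusion_matrix(match: MatchResult) -> pd.DataFrame:
    """Predicted-by-actual counts over matched pairs, with margins.

    Rows are predicted labels plus a ``missed`` row (truth with no
    detection); columns are actual labels plus a ``false_alarm`` column
    (detections with no truth).  Row/column conservation: each actual
    column sums to that label's truth count.
    """
    labels = list(EVENT_LABELS)
    table = pd.DataFrame(
        0, index=labels + ["missed"], columns=labels + ["false_alarm"], dtype=int
    )
    for t, d in match.pairs:
        table.loc[d.label, t.label] += 1
    for t in match.misses:
        table.loc["missed", t.label] += 1
    for d in match.false_alarms:
        table.loc[d.label, "false_alarm"] += 1
    return table


def accuracy_from_counts(detected: int, actual: int, decimals: int = 1) -> float:
    """Detection accuracy as the printed percentage ``100 * detected/actual``."""
    if actual < 1:
        raise ValueError("actual count must be >= 1")
    if detected > actual:
        raise ValueError(f"detected ({detected}) cannot exceed actual ({actual})")
    return round(100.0 * detected / actual, decimals)


def summarize_session(
    detected: Sequence[EventRecord],
    truth: Sequence[EventRecord],
    tolerance_s: float = 0.5,
) -> EvalReport:
    """Match, then build the confusion matrix and per-label accuracy rows."""
    match = match_events(detected, truth, tolerance_s)
    confusion = confusion_matrix(match)
    rows = {}
    for label in EVENT_LABELS:
        actual = sum(1 for t in truth if t.label == label)
        correct = int(confusion.loc[label, label])
        rows[label] = {
            "actual": actual,
            "detected": correct,
            "accuracy_pct": accuracy_from_counts(correct, actual) if actual else np.nan,
        }
    per_label = pd.DataFrame.from_dict(rows, orient="index")
    return EvalReport(confusion=confusion, per_label=per_label)


def render_report(report: EvalReport) -> str:
    """Aligned text rendering; labels with no truth events print '-'."""
    lines = ["Per-label accuracy"]
    for label, row in report.per_label.iterrows():
        if row["actual"] == 0:
            lines.append(f"  {label:<12} -/-      -")
        else:
            lines.append(
                f"  {label:<12} {int(row['detected'])}/{int(row['actual']):<6} "
                f"{row['accuracy_pct']:.1f}"
            )
    lines.append("")
    lines.append("Confusion matrix (rows predicted, columns actual)")
    lines.append(report.confusion.to_string())
    return "\n".join(lines)


def report_to_csv(report: EvalReport, path: str | Path) -> None:
    """Write the per-label table and confusion matrix to one CSV file."""
    path = Path(path)
    with open(path, "w") as fh:
        report.per_label.to_csv(fh, index_label="label")
        fh.write("\n")
        report.confusion.to_csv(fh, index_label="predicted")
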