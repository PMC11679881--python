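"""Scoring ACTIVE/INACTIVE calls against ground truth.

"Correct" counts both true positives and true negatives among the
compounds included in the comparison; compounds EXCLUDED by a method
(too few detections, zero variance, or filtered fractions) are removed
from the denominator.  Percentages are reported to one decimal with
half-up rounding, the convention used in screening comparison tables.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd


def _pct(numerator: int, denominator: int) -> float:
    if denominator == 0:
        return float("nan")
    ratio = Decimal(100 * numerator) / Decimal(denominator)
    return float(ratio.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionReport:
    method: str
    n_included: int
    n_correct: int
    pct_correct: float
    n_active_included: int
    n_active_correct: int
    pct_active_correct: float
    n_false_positive: int
    n_false_negative: int

    def to_dict(self) -> dict:
        return asdict(self)


def score_predictions(calls: pd.Series, truth: dict, method: str = "") -> ConfusionReport:
    """Score classification calls against a compound -> is-active map.

    ``calls`` maps compound id to "ACTIVE"/"INACTIVE"/"EXCLUDED" (the
    string value or an enum with that ``.value``).  Every called compound
    must have a truth entry; EXCLUDED calls drop out of the comparison.
    """
    missing = [c for c in calls.index if c not in truth]
    if missing:
        raise KeyError(f"no ground truth for compounds: {missing}")
    tp = tn = fp = fn = n_active = 0
    n_included = 0
    for compound, call in calls.items():
        label = getattr(call, "value", call)
        if label == "EXCLUDED":
            continue
        n_included += 1
        is_active = bool(truth[compound])
        if is_active:
            n_active += 1
        if label == "ACTIVE" and is_active:
            tp += 1
        elif label == "ACTIVE" and not is_active:
            fp += 1
        elif label == "INACTIVE" and is_active:
            fn += 1
        elif label == "INACTIVE" and not is_active:
            tn += 1
        else:
            raise ValueError(f"unknown classification {label!r} for {compound}")
    n_correct = tp + tn
    return ConfusionReport(
        method=method,
        n_included=n_included,
        n_correct=n_correct,
        pct_correct=_pct(n_correct, n_included),
        n_active_included=n_active,
        n_active_correct=tp,
        pct_active_correct=_pct(tp, n_active),
        n_false_positive=fp,
        n_false_negative=fn,
    )


def compare_methods(
    reports: list[ConfusionReport],
    sort_by: tuple[str, ...] = ("n_false_positive", "pct_active_correct"),
) -> pd.DataFrame:
    """Side-by-side ranking table: false positives ascending, then
    correctly-predicted-actives percentage descending (by default)."""
    if len(reports) < 1:
        raise ValueError("no reports to compare")
    table = pd.DataFrame([r.to_dict() for r in reports]).set_index("method")
    ascending = [col == "n_false_positive" for col in sort_by]
    return table.sort_values(list(sort_by), ascending=ascending, kind="stable")
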