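"""Per-code precision / recall / F-measure and macro aggregation.

Precision = TP/(TP+FP), recall = TP/(TP+FN), F = 2PR/(P+R); ratios with a
zero denominator are set to 0 and flagged degenerate so aggregation can
optionally exclude them.  Reporting is restricted to the most-used codes
covering a configurable fraction (default 90%) of all code occurrences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .icd import ICDCode

__all__ = ["MetricsRecord", "prf", "select_codes", "macro_f", "evaluate"]


@dataclass
class MetricsRecord:
    code: ICDCode
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_measure: float
    degenerate: bool = False


def prf(
    preds: Sequence[set[ICDCode]], truths: Sequence[set[ICDCode]], code: ICDCode
) -> MetricsRecord:
    """Contingency counts and P/R/F for one code over aligned note lists."""
    if len(preds) != len(truths):
        raise ValueError(f"preds ({len(preds)}) and truths ({len(truths)}) differ in length")
    tp = sum(1 for p, t in zip(preds, truths) if code in p and code in t)
    fp = sum(1 for p, t in zip(preds, truths) if code in p and code not in t)
    fn = sum(1 for p, t in zip(preds, truths) if code not in p and code in t)
    degenerate = False
    if tp + fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = tp / (tp + fn)
    f = 0.0 if precision + recall == 0.0 else 2 * precision * recall / (precision + recall)
    return MetricsRecord(code, tp, fp, fn, precision, recall, f, degenerate)


def select_codes(
    truths: Sequence[set[ICDCode]], coverage: float = 0.90, mode: str = "occurrence"
) -> set[ICDCode]:
    """Most-used codes covering ``coverage`` of all code occurrences.

    Codes are ranked by occurrence count (ties lexicographic); the smallest
    prefix whose cumulative occurrences reach ``coverage`` of the total is
    returned.  ``mode="types"`` instead keeps the top ``coverage`` fraction
    of distinct codes.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    counts: dict[ICDCode, int] = {}
    for labels in truths:
        for c in labels:
            counts[c] = counts.get(c, 0) + 1
    if not counts:
        raise ValueError("empty dataset: no code occurrences")
    ranked = sorted(counts, key=lambda c: (-counts[c], c.code))
    if mode == "types":
        k = max(1, int(round(coverage * len(ranked))))
        return set(ranked[:k])
    total = sum(counts.values())
    included: set[ICDCode] = set()
    cum = 0
    for c in ranked:
        included.add(c)
        cum += counts[c]
        if cum >= coverage * total:
            break
    return included


def macro_f(
    records: Sequence[MetricsRecord], included: set[ICDCode]
) -> tuple[float, float, float]:
    """Unweighted mean precision, recall and F over the included codes."""
    by_code = {r.code: r for r in records}
    missing = included - set(by_code)
    if missing:
        raise ValueError(f"missing metrics records for {sorted(c.code for c in missing)}")
    rs = [by_code[c] for c in sorted(included)]
    n = len(rs)
    return (
        sum(r.precision for r in rs) / n,
        sum(r.recall for r in rs) / n,
        sum(r.f_measure for r in rs) / n,
    )


def evaluate(
    preds: Sequence[set[ICDCode]],
    truths: Sequence[set[ICDCode]],
    coverage: float = 0.90,
) -> pd.DataFrame:
    """Per-code metrics table for the coverage-included codes plus a MACRO row."""
    included = select_codes(truths, coverage)
    records = [prf(preds, truths, c) for c in sorted(included)]
    mp, mr, mf = macro_f(records, included)
    rows = [
        {
            "code": r.code.code,
            "tp": r.tp,
            "fp": r.fp,
            "fn": r.fn,
            "precision": r.precision,
            "recall": r.recall,
            "f_measure": r.f_measure,
            "degenerate": r.degenerate,
        }
        for r in records
    ]
    rows.append(
        {
            "code": "MACRO",
            "tp": sum(r.tp for r in records),
            "fp": sum(r.fp for r in records),
            "fn": sum(r.fn for r in records),
            "precision": mp,
            "recall": mr,
            "f_measure": mf,
            "degenerate": False,
        }
    )
    return pd.DataFrame(rows)
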