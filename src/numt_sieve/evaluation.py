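"""Benchmarking filter verdicts against ground-truth labels.

A removed pseudogene is a true positive; a retained gene is a true
negative. Sensitivity (true-positive rate) is the percentage of labelled
pseudogenes correctly removed; specificity (true-negative rate) is the
percentage of labelled genes correctly retained. Both are reported as
percentages to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DataError, UndefinedValueError

NUMT_LABELS = frozenset({"simulated_numt", "numt", "pseudogene"})


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int  # pseudogenes removed
    fn: int  # pseudogenes kept
    tn: int  # genes kept
    fp: int  # genes removed

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion(results, labels: dict) -> ConfusionMatrix:
    """Tally verdicts (``FilterResult``-like objects with ``record_id``
    and ``kept``) against a ``record_id -> label`` map, where pseudogene
    labels are any of ``simulated_numt``/``numt``/``pseudogene`` and
    everything else counts as ``gene``."""
    tp = fn = tn = fp = 0
    for res in results:
        if res.record_id not in labels:
            raise DataError(f"no label for record {res.record_id!r}")
        is_numt = labels[res.record_id] in NUMT_LABELS
        if is_numt:
            if res.kept:
                fn += 1
            else:
                tp += 1
        else:
            if res.kept:
                tn += 1
            else:
                fp += 1
    return ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp)


def sensitivity(cm: ConfusionMatrix) -> float:
    """100 * tp / (tp + fn)."""
    if cm.tp + cm.fn == 0:
        raise UndefinedValueError("no labelled pseudogenes; sensitivity undefined")
    return 100.0 * cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    """100 * tn / (tn + fp)."""
    if cm.tn + cm.fp == 0:
        raise UndefinedValueError("no labelled genes; specificity undefined")
    return 100.0 * cm.tn / (cm.tn + cm.fp)
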