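"""Pseudogene (nuMT) removal by outlier filtering.

Two methods, applied dataset-relative (fences are recomputed for every
input file, never fixed absolute thresholds):

``orf_only``
    Per record, keep the longest plus-strand ORF; records with no
    qualifying ORF are removed. Records whose longest-ORF length falls
    outside the Tukey fences ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]`` of the
    surviving lengths are removed as length outliers (short outliers are
    frame-broken pseudogene candidates; long outliers are suspect too).

``orf_hmm``
    ``orf_only`` followed by profile-HMM scoring of the surviving
    longest-ORF amino-acid sequences; records whose bit score falls below
    the *low* fence ``Q1 - 1.5*IQR`` of the surviving scores are removed.
    The score fence is one-sided: unusually high scores are unproblematic.

Quartiles use linear interpolation (R type-7, the numpy default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InsufficientDataError
from .genetic_codes import GeneticCode, INVERTEBRATE_MITO
from .orffinder import DEFAULT_MIN_LENGTH, find_orfs, longest_orf
from .profile_hmm import ProfileHmm, score_sequence
from .seqrecords import SequenceRecord

#: Verdict order is fixed: no_orf, then length, then score.
REASONS = ("ok", "no_orf", "length_low_outlier", "length_high_outlier", "score_low_outlier")


@dataclass(frozen=True)
class OutlierBounds:
    """Tukey fences at 1.5 * IQR around the quartiles."""

    q1: float
    q3: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lower(self) -> float:
        return self.q1 - 1.5 * self.iqr

    @property
    def upper(self) -> float:
        return self.q3 + 1.5 * self.iqr


@dataclass(frozen=True)
class FilterResult:
    """Per-record verdict with the measured diagnostics."""

    record_id: str
    kept: bool
    reason: str
    orf_length_nt: Optional[int] = None
    bit_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.reason not in REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")
        if self.kept != (self.reason == "ok"):
            raise ValueError("kept must be true exactly when reason is 'ok'")
        if self.reason == "no_orf" and self.orf_length_nt is not None:
            raise ValueError("no_orf results carry no ORF length")


def _quartiles(values) -> tuple:
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 4:
        raise InsufficientDataError(
            f"need at least 4 values for quartile fences, got {vals.size}"
        )
    q1, q3 = np.percentile(vals, [25, 75])  # linear interpolation = R type-7
    return float(q1), float(q3)


def length_outlier_bounds(lengths) -> OutlierBounds:
    """Two-sided Tukey fences on longest-ORF lengths (nt)."""
    q1, q3 = _quartiles(lengths)
    return OutlierBounds(q1=q1, q3=q3)


def score_lower_fence(scores) -> float:
    """One-sided low fence ``Q1 - 1.5*IQR`` on bit scores."""
    q1, q3 = _quartiles(scores)
    return q1 - 1.5 * (q3 - q1)


@dataclass
class FilterReport:
    """Results plus the dataset-level fences used to produce them."""

    results: list
    length_bounds: Optional[OutlierBounds]
    score_fence: Optional[float]


def filter_report(
    records,
    method: str = "orf_only",
    code: GeneticCode = INVERTEBRATE_MITO,
    hmm: Optional[ProfileHmm] = None,
    min_orf: int = DEFAULT_MIN_LENGTH,
) -> FilterReport:
    """Run the staged filter and also return the fences.

    Stage 1: longest ORF per record; none found -> removed (``no_orf``).
    Stage 2: length fences computed from the *surviving* ORF lengths;
    lengths strictly outside ``[lower, upper]`` -> removed.
    Stage 3 (``orf_hmm`` only): bit scores of the remaining longest-ORF
    amino-acid sequences; scores strictly below the low fence -> removed.
    """
    if method not in ("orf_only", "orf_hmm"):
        raise ValueError(f"unknown method {method!r}")
    if method == "orf_hmm" and hmm is None:
        raise ValueError("method 'orf_hmm' requires a profile HMM")

    best = {}
    order = []
    for rec in records:
        order.append(rec.id)
        best[rec.id] = longest_orf(find_orfs(rec, code, min_length=min_orf))

    survivors = [rid for rid in order if best[rid] is not None]
    bounds = length_outlier_bounds([best[rid].length_nt for rid in survivors])

    verdicts = {}
    for rid in order:
        orf = best[rid]
        if orf is None:
            verdicts[rid] = FilterResult(rid, False, "no_orf")
        elif orf.length_nt < bounds.lower:
            verdicts[rid] = FilterResult(rid, False, "length_low_outlier", orf.length_nt)
        elif orf.length_nt > bounds.upper:
            verdicts[rid] = FilterResult(rid, False, "length_high_outlier", orf.length_nt)

    fence = None
    if method == "orf_hmm":
        scored = [rid for rid in order if rid not in verdicts]
        scores = {}
        for rid in scored:
            orf = best[rid]
            aa_rec = SequenceRecord(rid, orf.aa_seq, alphabet="aa")
            scores[rid] = score_sequence(hmm, aa_rec).bit_score
        fence = score_lower_fence(list(scores.values()))
        for rid in scored:
            if scores[rid] < fence:
                verdicts[rid] = FilterResult(
                    rid, False, "score_low_outlier", best[rid].length_nt, scores[rid]
                )
            else:
                verdicts[rid] = FilterResult(
                    rid, True, "ok", best[rid].length_nt, scores[rid]
                )

    results = []
    for rid in order:
        if rid in verdicts:
            results.append(verdicts[rid])
        else:
            results.append(FilterResult(rid, True, "ok", best[rid].length_nt))
    return FilterReport(results=results, length_bounds=bounds, score_fence=fence)


def filter_pseudogenes(
    records,
    method: str = "orf_only",
    code: GeneticCode = INVERTEBRATE_MITO,
    hmm: Optional[ProfileHmm] = None,
    min_orf: int = DEFAULT_MIN_LENGTH,
) -> list:
    """Per-record keep/remove verdicts (see :func:`filter_report`)."""
    return filter_report(records, method=method, code=code, hmm=hmm, min_orf=min_orf).results
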