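"""Plus-strand open-reading-frame extraction.

An ORF here is a *maximal stop-free run of complete codons* in one of the
three plus-strand frames, bounded by a stop codon or the sequence end —
not an ATG-anchored gene call. The goal of downstream filtering is
reading-frame integrity of a marker amplicon, for which start-codon
annotation is irrelevant (a ``require_start`` switch exists for the
stricter convention). Codons containing ``N`` translate to ``X`` and
count as sense codons, which is conservative toward keeping genes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genetic_codes import GeneticCode, translate
from .seqrecords import SequenceRecord

#: Default minimum ORF length in nucleotides, stop codon excluded.
DEFAULT_MIN_LENGTH = 30


@dataclass(frozen=True)
class Orf:
    """A plus-strand ORF. ``start``/``end`` are 0-based, half-open
    nucleotide offsets on the source record; the stop codon is excluded,
    so ``end - start == length_nt`` is a multiple of 3 and ``aa_seq``
    contains no ``'*'``."""

    record_id: str
    frame: int
    start: int
    end: int
    nt_seq: str
    aa_seq: str

    @property
    def length_nt(self) -> int:
        return self.end - self.start


def find_orfs(
    record: SequenceRecord,
    code: GeneticCode,
    min_length: int = DEFAULT_MIN_LENGTH,
    ignore_nested: bool = True,
    require_start: bool = False,
) -> list:
    """Extract plus-strand ORFs from a nucleotide record.

    Parameters
    ----------
    min_length : int
        Minimum ORF length in nucleotides (stop codon excluded).
    ignore_nested : bool
        Drop a candidate whose span lies entirely within an
        already-retained candidate's span in any frame; for containment
        the span of a stop-terminated run includes its bounding stop
        codon (the ORF-finder convention). Longer candidates are retained
        first; ties broken by smaller start, then smaller frame.
    require_start : bool
        If true, trim each run to begin at its first Met codon (stricter,
        ORFfinder-like convention); runs without one are dropped.
    """
    if record.alphabet != "nt":
        raise ValueError("find_orfs expects a nucleotide record")
    seq = record.seq
    candidates: list[tuple] = []  # (Orf, stop-inclusive span end)
    for frame in (0, 1, 2):
        aa = translate(seq, code, frame)
        run_start = 0  # codon index
        for j in range(len(aa) + 1):
            if j == len(aa) or aa[j] == "*":
                s, e = run_start, j
                stop_terminated = j < len(aa)
                run_start = j + 1
                if require_start:
                    while s < e and aa[s] != "M":
                        s += 1
                if e - s == 0:
                    continue
                nt_start = frame + 3 * s
                nt_end = frame + 3 * e
                if nt_end - nt_start < min_length:
                    continue
                orf = Orf(
                    record_id=record.id,
                    frame=frame,
                    start=nt_start,
                    end=nt_end,
                    nt_seq=seq[nt_start:nt_end],
                    aa_seq=aa[s:e],
                )
                candidates.append((orf, nt_end + 3 if stop_terminated else nt_end))
    if not ignore_nested:
        return [o for o, _ in sorted(candidates, key=lambda c: (c[0].start, c[0].frame))]

    retained: list[tuple] = []
    for cand, span_end in sorted(candidates,
                                 key=lambda c: (-c[0].length_nt, c[0].start, c[0].frame)):
        if any(cand.start >= r.start and span_end <= r_span for r, r_span in retained):
            continue
        retained.append((cand, span_end))
    return [o for o, _ in sorted(retained, key=lambda c: (c[0].start, c[0].frame))]


def longest_orf(orfs: list) -> Orf | None:
    """The maximum-length ORF; ties broken by smaller start, then smaller
    frame. Empty input returns ``None``; mixed record ids are rejected."""
    if not orfs:
        return None
    if len({o.record_id for o in orfs}) != 1:
        raise ValueError("longest_orf requires ORFs from a single record")
    return min(orfs, key=lambda o: (-o.length_nt, o.start, o.frame))
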