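"""Sequence data model, FASTA/Stockholm I/O, and composition statistics.

Coordinate convention (used by every module in this package): 0-based,
half-open ``[start, end)`` intervals on the plus strand.

Alphabets are strict: nucleotide sequences may contain only ``ACGTN``
(``N`` being the single ambiguity code tolerated — inputs carrying other
IUPAC codes are rejected so that downstream translation and scoring never
see them), and amino-acid sequences the 20 standard residues plus ``X``
(unknown) and ``*`` (stop).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from Bio import AlignIO

from .errors import ParseError, UndefinedValueError

NT_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")
GAP = "-"


@dataclass
class SequenceRecord:
    """An identified nucleotide or amino-acid sequence.

    Parameters
    ----------
    id : str
        Unique identifier; must contain no whitespace.
    seq : str
        Uppercase sequence over the declared alphabet.
    alphabet : {"nt", "aa"}
        Which alphabet ``seq`` is validated against.
    description : str
        Free-text remainder of the FASTA header.
    """

    id: str
    seq: str
    alphabet: str = "nt"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ParseError(f"record id {self.id!r} is empty or contains whitespace")
        if self.alphabet not in ("nt", "aa"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        self.seq = self.seq.upper()
        if not self.seq:
            raise ParseError(f"record {self.id!r} has an empty sequence")
        allowed = NT_ALPHABET if self.alphabet == "nt" else AA_ALPHABET
        bad = set(self.seq) - allowed
        if bad:
            raise ParseError(
                f"record {self.id!r} contains characters {sorted(bad)} outside the "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Alignment:
    """A multiple alignment: equal-length rows that may contain ``-`` gaps."""

    records: list
    ncols: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ParseError("alignment has no rows")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            raise ParseError(f"alignment rows have ragged lengths {sorted(lengths)}")
        self.ncols = lengths.pop()

    def __len__(self) -> int:
        return len(self.records)


class _AlignedRow(SequenceRecord):
    """SequenceRecord whose seq may additionally contain '-' gaps."""

    def __post_init__(self) -> None:  # noqa: D105
        if not self.id or any(c.isspace() for c in self.id):
            raise ParseError(f"record id {self.id!r} is empty or contains whitespace")
        self.seq = self.seq.upper()
        if not self.seq:
            raise ParseError(f"record {self.id!r} has an empty sequence")
        allowed = (NT_ALPHABET if self.alphabet == "nt" else AA_ALPHABET) | {GAP, "."}
        bad = set(self.seq) - allowed
        if bad:
            raise ParseError(
                f"aligned record {self.id!r} contains illegal characters {sorted(bad)}"
            )
        self.seq = self.seq.replace(".", GAP)


def aligned_record(id: str, seq: str, alphabet: str = "aa", description: str = "") -> SequenceRecord:
    """Build a gap-tolerant :class:`SequenceRecord` for use in an :class:`Alignment`."""
    return _AlignedRow(id=id, seq=seq, alphabet=alphabet, description=description)


# ---------------------------------------------------------------------------
# FASTA I/O
#
# Hand line-tracked parser: the error contract (parse errors naming the
# offending line, strict alphabet validation on read) is part of this
# module's interface.
# ---------------------------------------------------------------------------

def read_fasta(path, alphabet: str = "nt", allow_gaps: bool = False) -> list:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved and sequences are uppercased. Raises
    :class:`ParseError` (naming the line) on malformed headers, empty
    sequences or characters outside the declared alphabet.
    """
    records: list = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}: entry at line {header_line} has an empty sequence")
        fields = header.split(maxsplit=1)
        rid = fields[0]
        desc = fields[1] if len(fields) > 1 else ""
        try:
            rec = (aligned_record(rid, seq, alphabet, desc) if allow_gaps
                   else SequenceRecord(rid, seq, alphabet, desc))
        except ParseError as exc:
            raise ParseError(f"{path}: entry at line {header_line}: {exc}") from None
        records.append(rec)

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
                if not header:
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
            else:
                if header is None:
                    raise ParseError(f"{path}: sequence data before any header at line {lineno}")
                chunks.append(line)
        flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path, wrap: int = 60) -> None:
    """Write records as multi-line FASTA; ``read_fasta`` round-trips ids and seqs."""
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i:i + wrap] + "\n")


def read_stockholm(path, alphabet: str = "aa") -> Alignment:
    """Read a (minimal, single-block) Stockholm 1.0 alignment."""
    try:
        msa = AlignIO.read(str(path), "stockholm")
    except ValueError as exc:
        raise ParseError(f"{path}: not a valid Stockholm alignment: {exc}") from None
    rows = [aligned_record(r.id, str(r.seq), alphabet, r.description or "") for r in msa]
    return Alignment(rows)


def write_stockholm(aln: Alignment, path) -> None:
    """Write an alignment as single-block Stockholm 1.0."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        width = max(len(r.id) for r in aln.records) + 2
        for r in aln.records:
            fh.write(f"{r.id:<{width}}{r.seq}\n")
        fh.write("//\n")


def read_alignment_fasta(path, alphabet: str = "aa") -> Alignment:
    """Read a gapped FASTA alignment (ragged rows are rejected)."""
    return Alignment(read_fasta(path, alphabet=alphabet, allow_gaps=True))


# ---------------------------------------------------------------------------
# Composition statistics
# ---------------------------------------------------------------------------

def gc_fraction(record: SequenceRecord) -> float:
    """GC content of a nucleotide record, on unambiguous bases only.

    ``N`` positions are excluded from both numerator and denominator.
    """
    if record.alphabet != "nt":
        raise ValueError("gc_fraction is defined for nucleotide records only")
    seq = record.seq
    gc = seq.count("G") + seq.count("C")
    total = gc + seq.count("A") + seq.count("T")
    if total == 0:
        raise UndefinedValueError(f"record {record.id!r} has no unambiguous bases")
    return gc / total
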