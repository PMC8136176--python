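"""Genetic-code tables and plus-strand translation.

Two codes ship: the standard code (NCBI table 1) and the invertebrate
mitochondrial code (NCBI table 5), the code under which animal COI
barcodes are read. Table 5 differs from table 1 exactly at AGA/AGG
(Arg→Ser), ATA (Ile→Met) and TGA (stop→Trp); its only stops are TAA and
TAG. Tables are built from Biopython's NCBI codon tables; the structure
is data-driven so further tables can be added.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Data import CodonTable

_BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


@dataclass(frozen=True)
class GeneticCode:
    """A total map from the 64 codons to an amino-acid letter or ``'*'``."""

    name: str
    table_id: int
    codon_map: dict

    def __post_init__(self) -> None:
        if set(self.codon_map) != set(ALL_CODONS):
            raise ValueError("codon_map must cover exactly the 64 codons")

    @property
    def stop_codons(self) -> frozenset:
        return frozenset(c for c, aa in self.codon_map.items() if aa == "*")

    def is_stop(self, codon: str) -> bool:
        return self.codon_map.get(codon) == "*"


@lru_cache(maxsize=None)
def _build(table_id: int, name: str) -> GeneticCode:
    ncbi = CodonTable.unambiguous_dna_by_id[table_id]
    codon_map = dict(ncbi.forward_table)
    for stop in ncbi.stop_codons:
        codon_map[stop] = "*"
    return GeneticCode(name=name, table_id=table_id, codon_map=codon_map)


STANDARD = _build(1, "standard")
INVERTEBRATE_MITO = _build(5, "invertebrate_mito")

CODES_BY_TABLE = {1: STANDARD, 5: INVERTEBRATE_MITO}


def get_code(table_id: int) -> GeneticCode:
    """Look up a shipped genetic code by NCBI table number."""
    try:
        return CODES_BY_TABLE[table_id]
    except KeyError:
        raise ValueError(
            f"genetic code table {table_id} not available (have {sorted(CODES_BY_TABLE)})"
        ) from None


def translate(seq: str, code: GeneticCode, frame: int = 0) -> str:
    """Translate consecutive complete codons starting at offset ``frame``.

    The trailing partial codon is dropped; any codon containing ``N``
    translates to ``'X'`` (ambiguity is propagated, not fatal); stop
    codons translate to ``'*'``.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame!r}")
    seq = seq.upper()
    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        if "N" in codon:
            out.append("X")
        else:
            out.append(code.codon_map[codon])
    return "".join(out)
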