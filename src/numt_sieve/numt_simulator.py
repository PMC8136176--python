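"""Synthetic COI-like communities and nuMT perturbations.

The generator emulates a taxonomically diverse barcode community: every
sequence is a mutated descendant of one random ancestor (so the set is
alignable), built from complete sense codons under the invertebrate
mitochondrial code with one leading pad base, hence a full-length open
reading frame in plus-strand frame 1 and no internal stops. Default
geometry matches the animal barcode region: 658 nt (= 1 pad + 219
codons), GC content near 40%.

Perturbations turn a labelled fraction of the community into simulated
nuclear pseudogene copies:

``gc_to_at``
    GC -> AT point substitutions (G->A, C->T) at ``round(edit_rate * L)``
    distinct G/C sites, lowering GC content by exactly ``edit_rate``
    percentage points on fixed-length input — drift toward the AT-rich
    background typical of nuclear pseudogene copies.
``frameshift``
    single-base insertions or deletions (probability 1/2 each) at
    ``round(edit_rate * L)`` distinct sites, breaking the reading frame
    and creating premature stop codons.

Fragment variants truncate *every* record (genes and nuMTs alike) to its
5' or 3' half after perturbation, emulating short metabarcode amplicons.

Defaults: 19% of the community becomes nuMTs and 2.5% of bases are
edited; the stressed variants double (38%) or halve (9.5%) the nuMT
proportion. All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SimulationError
from .genetic_codes import GeneticCode, INVERTEBRATE_MITO
from .seqrecords import SequenceRecord

#: Proportion of the community converted to simulated nuMTs.
DEFAULT_NUMT_FRACTION = 0.19
#: Proportion of bases edited in each simulated nuMT.
DEFAULT_EDIT_RATE = 0.025
#: Barcode-region length (nt): 1 pad base + 219 codons.
DEFAULT_LENGTH = 658
DEFAULT_GC = 0.40

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class Edit:
    """One recorded edit on *source* coordinates (0-based).

    ``op`` is ``sub`` (replace base at ``position``), ``ins`` (insert
    ``base`` before ``position``) or ``del`` (delete base at ``position``).
    """

    position: int
    op: str
    base: str

    def __post_init__(self) -> None:
        if self.op not in ("sub", "ins", "del"):
            raise ValueError(f"unknown edit op {self.op!r}")


@dataclass(frozen=True)
class PerturbationConfig:
    """Parameters of one perturbed-community dataset."""

    numt_fraction: float = DEFAULT_NUMT_FRACTION
    mode: str = "gc_to_at"
    edit_rate: float = DEFAULT_EDIT_RATE
    fragment: str = "full"
    seed: int = 0
    gc_relative: bool = False  # interpret edit_rate as a relative GC reduction
    uniform_at: bool = False   # G/C -> uniform A or T instead of G->A, C->T

    def __post_init__(self) -> None:
        if not 0 < self.numt_fraction < 1:
            raise ValueError("numt_fraction must be in (0, 1)")
        if not 0 < self.edit_rate < 1:
            raise ValueError("edit_rate must be in (0, 1)")
        if self.mode not in ("gc_to_at", "frameshift"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.fragment not in ("full", "half5", "half3", "both_halves"):
            raise ValueError(f"unknown fragment {self.fragment!r}")


@dataclass
class CommunityDataset:
    """A labelled community: records, per-record ``gene``/``simulated_numt``
    labels, and per-nuMT edit provenance (replayable on the source)."""

    records: list
    labels: dict
    edits: dict = field(default_factory=dict)
    fragment: str = "full"

    def __post_init__(self) -> None:
        ids = {r.id for r in self.records}
        if set(self.labels) != ids:
            raise ValueError("labels must cover exactly the record ids")
        bad = set(self.labels.values()) - {"gene", "simulated_numt"}
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")

    @property
    def n_numts(self) -> int:
        return sum(1 for v in self.labels.values() if v == "simulated_numt")


# ---------------------------------------------------------------------------
# Community generation
# ---------------------------------------------------------------------------

def _sample_codons(n_codons: int, gc: float, code: GeneticCode,
                   rng: np.random.Generator) -> np.ndarray:
    """Sample stop-free codons with per-base GC probability ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = _BASES[rng.choice(4, size=(n_codons, 3), p=p)]
    stops = {s.encode() for s in code.stop_codons}
    for _ in range(200):
        codes = np.array([b"".join(row) for row in arr])
        bad = np.array([c in stops for c in codes])
        if not bad.any():
            return arr
        arr[bad] = _BASES[rng.choice(4, size=(int(bad.sum()), 3), p=p)]
    raise SimulationError("could not sample stop-free codons")


def generate_synthetic_community(
    n: int,
    length: int = DEFAULT_LENGTH,
    gc_target: float = DEFAULT_GC,
    code: GeneticCode = INVERTEBRATE_MITO,
    seed: int = 0,
    divergence: float = 0.05,
    id_prefix: str = "seq",
) -> list:
    """Generate ``n`` alignable, codon-clean marker sequences.

    Each sequence is 1 pad base + ``(length - 1) // 3`` complete sense
    codons (so the realized length is ``length`` adjusted down to
    1 mod 3), carries no stop codon in frame 1, and sits within ±5 GC
    percentage points of ``gc_target``. Descendants differ from a single
    random ancestor by point substitutions at rate ``divergence`` per
    site; substitutions that would create an in-frame stop are reverted.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n == 0:
        return []
    if length < 60:
        raise ValueError("length must be >= 60")
    if not 0.05 <= gc_target <= 0.95:
        raise SimulationError(f"gc_target {gc_target} unattainable")
    rng = np.random.default_rng(seed)
    n_codons = (length - 1) // 3
    L = 1 + 3 * n_codons

    stops = {s.encode() for s in code.stop_codons}
    for _attempt in range(50):
        ancestor = _sample_codons(n_codons, gc_target, code, rng)
        anc_flat = ancestor.reshape(-1)
        gc = np.isin(anc_flat, _BASES[1:3]).mean()
        if abs(gc - gc_target) <= 0.03:
            break
    else:
        raise SimulationError(
            f"could not hit GC target {gc_target} after bounded retries"
        )
    pad = _BASES[rng.choice(4)]

    # descendants: vectorized point substitutions over the codon region
    p = np.array([(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2])

    def derive(k: int) -> np.ndarray:
        """k mutated copies of the ancestor, stop-creating edits reverted."""
        mat = np.tile(anc_flat, (k, 1))  # (k, 3 * n_codons)
        mutate = rng.random(mat.shape) < divergence
        proposals = _BASES[rng.choice(4, size=mat.shape, p=p)]
        mat[mutate] = proposals[mutate]
        codons = mat.reshape(k, n_codons, 3)
        if stops == {b"TAA", b"TAG"}:
            bad = ((codons[:, :, 0] == b"T") & (codons[:, :, 1] == b"A")
                   & ((codons[:, :, 2] == b"A") | (codons[:, :, 2] == b"G")))
        else:  # general fallback for other codes
            flat = codons.reshape(-1, 3)
            bad = np.array([b"".join(row) in stops for row in flat]).reshape(k, n_codons)
        codons[bad] = np.broadcast_to(ancestor[np.newaxis], codons.shape)[bad]
        return codons.reshape(k, -1)

    mat = derive(n)
    pad_gc = float(pad in _BASES[1:3])
    for _attempt in range(100):
        gc_rows = (np.isin(mat, _BASES[1:3]).sum(axis=1) + pad_gc) / L
        off_band = np.flatnonzero(np.abs(gc_rows - gc_target) > 0.05)
        if off_band.size == 0:
            break
        mat[off_band] = derive(off_band.size)  # redraw drifted rows
    else:
        raise SimulationError("could not keep descendants inside the GC band")

    width = max(4, len(str(n)))
    return [
        SequenceRecord(f"{id_prefix}_{i:0{width}d}",
                       (pad.tobytes() + mat[i].tobytes()).decode(),
                       alphabet="nt")
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

def apply_gc_to_at(seq: str, edit_rate: float, rng: np.random.Generator,
                   relative: bool = False, uniform_at: bool = False):
    """GC -> AT substitutions at ``k = round(edit_rate * L)`` distinct G/C
    sites (G->A, C->T). Length is preserved and the GC fraction drops by
    exactly ``k / L``. With ``relative=True``, ``k`` is instead
    ``round(edit_rate * #GC)`` (a relative GC reduction)."""
    L = len(seq)
    gc_positions = [i for i, b in enumerate(seq) if b in "GC"]
    k = int(round(edit_rate * (len(gc_positions) if relative else L)))
    if len(gc_positions) < k:
        raise SimulationError(
            f"sequence has only {len(gc_positions)} G/C sites; {k} edits requested"
        )
    chosen = rng.choice(len(gc_positions), size=k, replace=False)
    edits = []
    out = list(seq)
    for idx in sorted(int(i) for i in chosen):
        pos = gc_positions[idx]
        if uniform_at:
            new = "AT"[rng.integers(2)]
        else:
            new = "A" if seq[pos] == "G" else "T"
        out[pos] = new
        edits.append(Edit(pos, "sub", new))
    return "".join(out), edits


def apply_frameshifts(seq: str, edit_rate: float, rng: np.random.Generator):
    """``k = round(edit_rate * L)`` indel events at distinct source
    positions; each is independently an insertion of a uniform random base
    (placed before the position) or a deletion, with probability 1/2."""
    L = len(seq)
    if L < 40:
        raise SimulationError("sequence too short for frameshift perturbation")
    k = int(round(edit_rate * L))
    positions = sorted(int(p) for p in rng.choice(L, size=k, replace=False))
    edits = []
    for pos in positions:
        if rng.random() < 0.5:
            edits.append(Edit(pos, "ins", "ACGT"[rng.integers(4)]))
        else:
            edits.append(Edit(pos, "del", seq[pos]))
    return replay_edits(seq, edits), edits


def replay_edits(seq: str, edits) -> str:
    """Apply recorded edits (source coordinates, distinct positions,
    resolved left-to-right) to ``seq``; the provenance round-trip."""
    by_pos = {e.position: e for e in edits}
    if len(by_pos) != len(list(edits)):
        raise ValueError("edit positions must be distinct")
    out = []
    for i, base in enumerate(seq):
        e = by_pos.get(i)
        if e is None:
            out.append(base)
        elif e.op == "sub":
            out.append(e.base)
        elif e.op == "ins":
            out.append(e.base)
            out.append(base)
        elif e.op == "del":
            pass
    return "".join(out)


def split_half(seq: str):
    """(5' half, 3' half): first ``floor(L/2)`` bases and the remainder."""
    if len(seq) < 2:
        raise ValueError("sequence too short to split")
    mid = len(seq) // 2
    return seq[:mid], seq[mid:]


def perturb_community(records, config: PerturbationConfig):
    """Turn a clean community into a labelled perturbed dataset.

    ``round(numt_fraction * n)`` records are chosen uniformly without
    replacement (seeded) and perturbed per ``config.mode``; fragment
    variants then truncate every record. Returns a
    :class:`CommunityDataset`, or a ``(half5, half3)`` pair when
    ``fragment == "both_halves"``.
    """
    rng = np.random.default_rng(config.seed)
    n = len(records)
    k = int(round(config.numt_fraction * n))
    chosen = set(int(i) for i in rng.choice(n, size=k, replace=False)) if k else set()

    out_records = []
    labels = {}
    all_edits = {}
    for i, rec in enumerate(records):
        if i in chosen:
            if config.mode == "gc_to_at":
                seq, edits = apply_gc_to_at(
                    rec.seq, config.edit_rate, rng,
                    relative=config.gc_relative, uniform_at=config.uniform_at,
                )
            else:
                seq, edits = apply_frameshifts(rec.seq, config.edit_rate, rng)
            out_records.append(SequenceRecord(rec.id, seq, "nt", rec.description))
            labels[rec.id] = "simulated_numt"
            all_edits[rec.id] = edits
        else:
            out_records.append(rec)
            labels[rec.id] = "gene"

    def fragment_ds(which: str) -> CommunityDataset:
        if which == "full":
            recs = out_records
        else:
            part = 0 if which == "half5" else 1
            recs = [
                SequenceRecord(r.id, split_half(r.seq)[part], "nt", r.description)
                for r in out_records
            ]
        return CommunityDataset(records=recs, labels=dict(labels),
                                edits=dict(all_edits), fragment=which)

    if config.fragment == "both_halves":
        return fragment_ds("half5"), fragment_ds("half3")
    return fragment_ds(config.fragment)
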