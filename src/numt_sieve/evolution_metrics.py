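"""Pairwise evolutionary diagnostics: dN/dS (Nei–Gojobori 1986) and
Kimura 2-parameter nucleotide distances.

dN/dS contrasts substitution pressure at nonsynonymous versus synonymous
codon sites: functional protein-coding genes evolve under purifying
selection (ratio << 1) while pseudogenes drift neutrally (ratio ~ 1).
Counting follows NG86 — per-codon synonymous/nonsynonymous site fractions
(changes to stop codons excluded from the denominators), pairwise
differences classified by equal-weight enumeration of mutational
pathways (pathways through stop codons discarded), and a Jukes–Cantor
multiple-hit correction. Pairs whose synonymous divergence is too small
(< 0.01, sequences too similar for a reliable ratio) or too large (> 2,
near saturation) are excluded, as are pairs where the JC correction is
undefined.

The K2P distance separates transition (P) and transversion (Q)
frequencies: d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)); it is the
conventional distance of DNA barcoding. Sites with a gap or N in either
sequence are pairwise-deleted.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional

from .errors import DataError, UndefinedValueError
from .genetic_codes import GeneticCode, INVERTEBRATE_MITO
from .seqrecords import Alignment

KS_MIN = 0.01
KS_MAX = 2.0


@dataclass(frozen=True)
class KaKsResult:
    id_pair: tuple
    ka: Optional[float]
    ks: Optional[float]
    ratio: Optional[float]
    excluded: bool
    exclusion_reason: str  # none | ks_too_small | ks_too_large | undefined_correction


@dataclass(frozen=True)
class PairwiseDifferences:
    """Transition/transversion fractions over the compared sites."""

    p_transitions: float
    q_transversions: float
    sites: int


# ---------------------------------------------------------------------------
# Nei-Gojobori dN/dS
# ---------------------------------------------------------------------------

def _codon_sites(codon: str, code: GeneticCode) -> float:
    """Synonymous site count of one sense codon (0..3); changes to stop
    codons are excluded from the per-position denominators."""
    aa = code.codon_map[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            alt_aa = code.codon_map[alt]
            if alt_aa == "*":
                continue
            valid += 1
            if alt_aa == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s


def _pathway_counts(a: str, b: str, code: GeneticCode) -> tuple:
    """(synonymous, nonsynonymous) difference counts between two sense
    codons, averaged over equally weighted mutational pathways; pathways
    through stop codons are discarded when any stop-free pathway exists."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    valid_paths = []
    all_paths = []
    for order in itertools.permutations(diff):
        cur = a
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if code.codon_map[nxt] == "*":
                ok = False
            if code.codon_map[nxt] == code.codon_map[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        all_paths.append((sd, nd))
        if ok:
            valid_paths.append((sd, nd))
    paths = valid_paths or all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        raise UndefinedValueError("Jukes-Cantor correction undefined (p too large)")
    return -0.75 * math.log(arg)


def kaks_pair(codon_seq_a: str, codon_seq_b: str,
              code: GeneticCode = INVERTEBRATE_MITO,
              id_pair: tuple = ("a", "b")) -> KaKsResult:
    """NG86 Ka/Ks for one pair of in-frame codon sequences.

    Sequences must be equal-length multiples of 3; codons containing a
    gap, an N, or a stop in either sequence are pairwise-skipped.
    """
    if len(codon_seq_a) != len(codon_seq_b):
        raise ValueError("codon sequences must have equal length")
    if len(codon_seq_a) % 3:
        raise ValueError("codon sequence length must be a multiple of 3")
    a_up, b_up = codon_seq_a.upper(), codon_seq_b.upper()
    S = N = sd = nd = 0.0
    for i in range(0, len(a_up), 3):
        ca, cb = a_up[i:i + 3], b_up[i:i + 3]
        if set(ca + cb) - set("ACGT"):
            continue  # gapped or ambiguous codon: pairwise-deleted
        if code.codon_map[ca] == "*" or code.codon_map[cb] == "*":
            continue
        sa, sb = _codon_sites(ca, code), _codon_sites(cb, code)
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        psd, pnd = _pathway_counts(ca, cb, code)
        sd += psd
        nd += pnd
    if S <= 0 or N <= 0:
        raise UndefinedValueError("no comparable codons between the pair")

    def result(ka, ks, ratio, excluded, reason):
        return KaKsResult(id_pair=id_pair, ka=ka, ks=ks, ratio=ratio,
                          excluded=excluded, exclusion_reason=reason)

    try:
        ks = _jukes_cantor(sd / S)
        ka = _jukes_cantor(nd / N)
    except UndefinedValueError:
        return result(None, None, None, True, "undefined_correction")
    if ks < KS_MIN:
        return result(ka, ks, None, True, "ks_too_small")
    if ks > KS_MAX:
        return result(ka, ks, None, True, "ks_too_large")
    return result(ka, ks, ka / ks, False, "none")


def kaks_matrix(codon_alignment: Alignment,
                code: GeneticCode = INVERTEBRATE_MITO) -> list:
    """All unordered pairs of a codon alignment, in row order."""
    recs = codon_alignment.records
    out = []
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            try:
                out.append(kaks_pair(recs[i].seq, recs[j].seq, code,
                                     id_pair=(recs[i].id, recs[j].id)))
            except (ValueError, UndefinedValueError) as exc:
                raise type(exc)(f"pair ({recs[i].id}, {recs[j].id}): {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Kimura 2-parameter distance
# ---------------------------------------------------------------------------

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def pairwise_differences(seq_a: str, seq_b: str) -> PairwiseDifferences:
    """Transition/transversion fractions; gap/N sites pairwise-deleted."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    ts = tv = sites = 0
    for x, y in zip(seq_a.upper(), seq_b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        sites += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    if sites == 0:
        raise UndefinedValueError("no comparable ungapped sites")
    return PairwiseDifferences(ts / sites, tv / sites, sites)


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """K2P distance in substitutions per site."""
    d = pairwise_differences(seq_a, seq_b)
    p, q = d.p_transitions, d.q_transversions
    a1 = 1.0 - 2.0 * p - q
    a2 = 1.0 - 2.0 * q
    if a1 <= 0 or a2 <= 0:
        raise UndefinedValueError(
            f"K2P distance saturated (P={p:.4f}, Q={q:.4f})"
        )
    return -0.5 * math.log(a1 * math.sqrt(a2))


def k2p_matrix(alignment: Alignment):
    """Square symmetric K2P :class:`~numt_sieve.phylo.DistanceMatrix`."""
    from .phylo import DistanceMatrix  # deferred: phylo depends on this module

    import numpy as np

    recs = alignment.records
    ids = [r.id for r in recs]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate ids in alignment")
    n = len(recs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                mat[i, j] = mat[j, i] = k2p_distance(recs[i].seq, recs[j].seq)
            except UndefinedValueError as exc:
                raise UndefinedValueError(f"pair ({ids[i]}, {ids[j]}): {exc}") from exc
    return DistanceMatrix(ids=ids, d=mat)
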