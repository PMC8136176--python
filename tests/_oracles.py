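"""Independent reference implementations used only to check the package.

Each oracle is deliberately written in the most naive way possible —
explicit enumeration, O(L^2) scanning, recursion — and shares no code
with the implementation under test.
"""

from __future__ import annotations

import itertools

from Bio.Seq import Seq


# ---------------------------------------------------------------------------
# Profile-HMM forward probability by exhaustive path enumeration
# ---------------------------------------------------------------------------

def forward_by_enumeration(hmm, query: str, mode: str = "local") -> float:
    """Sum of P(path, query) over every admissible state path.

    State graph (mirrors the documented model): match states M_1..M_M,
    interior inserts I_k (no flanking inserts), deletes D_k; local mode
    enters any match state uniformly and exits freely after any match
    state; glocal mode enters through the begin node (M_1 or a leading
    delete chain) and exits from M_M or D_M. Every query residue is
    emitted; paths begin and end on a match state.
    """
    from numt_sieve.profile_hmm import AA_INDEX

    M = hmm.M
    x = [20 if c == "X" else AA_INDEX[c] for c in query]
    L = len(x)
    me = [list(row) + [1.0] for row in hmm.match_emit]    # X emits prob 1
    ie = [list(row) + [1.0] for row in hmm.insert_emit]
    t = hmm.trans
    total = [0.0]

    def exit_prob(state: str, node: int) -> float:
        if mode == "local":
            return 1.0 if state == "m" else 0.0
        if state == "m" and node == M:
            return t[M][0]
        if state == "d" and node == M:
            return t[M][5]
        return 0.0

    def walk(state: str, node: int, i: int, p: float) -> None:
        if p == 0.0:
            return
        if i == L:
            total[0] += p * exit_prob(state, node)
        if state == "m":
            if node < M and i < L:
                walk("m", node + 1, i + 1, p * t[node][0] * me[node][x[i]])
            if 1 <= node <= M and i < L:
                walk("i", node, i + 1, p * t[node][1] * ie[node][x[i]])
            if node < M:
                walk("d", node + 1, i, p * t[node][2])
        elif state == "i":
            if node < M and i < L:
                walk("m", node + 1, i + 1, p * t[node][3] * me[node][x[i]])
            if i < L:
                walk("i", node, i + 1, p * t[node][4] * ie[node][x[i]])
        elif state == "d":
            if node < M and i < L:
                walk("m", node + 1, i + 1, p * t[node][5] * me[node][x[i]])
            if node < M:
                walk("d", node + 1, i, p * t[node][6])

    if L == 0:
        return 0.0
    if mode == "local":
        for k in range(1, M + 1):
            walk("m", k, 1, (1.0 / M) * me[k - 1][x[0]])
    else:
        walk("m", 1, 1, t[0][0] * me[0][x[0]])
        walk("d", 1, 0, t[0][2])
    return total[0]


# ---------------------------------------------------------------------------
# Brute-force ORF scanner
# ---------------------------------------------------------------------------

_codon_cache: dict = {}


def _translate_codon(codon: str, table: int) -> str:
    key = (codon, table)
    if key not in _codon_cache:
        _codon_cache[key] = "X" if "N" in codon else str(Seq(codon).translate(table=table))
    return _codon_cache[key]


def orfs_by_window_scan(seq: str, table: int, min_length: int):
    """Every maximal stop-free in-frame window, as (frame, start, end).

    Tests each codon-aligned window for stop-freeness and keeps those
    that cannot be extended in either direction.
    """
    found = []
    L = len(seq)
    for frame in range(3):
        ncod = (L - frame) // 3
        stop = [_translate_codon(seq[frame + 3 * c: frame + 3 * c + 3], table) == "*"
                for c in range(ncod)]
        for s in range(ncod):
            for e in range(s + 1, ncod + 1):
                if any(stop[s:e]):
                    continue
                left_ext = s > 0 and not stop[s - 1]
                right_ext = e < ncod and not stop[e]
                if left_ext or right_ext:
                    continue  # not maximal
                if 3 * (e - s) < min_length:
                    continue
                found.append((frame, frame + 3 * s, frame + 3 * e))
    return sorted(found)


# ---------------------------------------------------------------------------
# Naive Nei-Gojobori counting
# ---------------------------------------------------------------------------

def _aa(codon: str, table: int) -> str:
    return str(Seq(codon).translate(table=table))


def ng86_by_enumeration(seq_a: str, seq_b: str, table: int):
    """(S, N, sd, nd): site and difference counts, recomputed naively."""
    S = N = sd = nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3].upper(), seq_b[i:i + 3].upper()
        if set(ca + cb) - set("ACGT"):
            continue
        if _aa(ca, table) == "*" or _aa(cb, table) == "*":
            continue
        for codon, weight in ((ca, 0.5), (cb, 0.5)):
            for pos in range(3):
                alts = [codon[:pos] + b + codon[pos + 1:]
                        for b in "ACGT" if b != codon[pos]]
                alts = [alt for alt in alts if _aa(alt, table) != "*"]
                if alts:
                    frac = sum(_aa(alt, table) == _aa(codon, table)
                               for alt in alts) / len(alts)
                    S += weight * frac
                    N += weight * (1 - frac)
                else:
                    N += weight  # position counts as nonsynonymous site
        diffs = [p for p in range(3) if ca[p] != cb[p]]
        if not diffs:
            continue
        paths = []
        stop_free_paths = []
        for order in itertools.permutations(diffs):
            cur, psd, pnd, through_stop = ca, 0, 0, False
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if _aa(nxt, table) == "*":
                    through_stop = True
                if _aa(nxt, table) == _aa(cur, table):
                    psd += 1
                else:
                    pnd += 1
                cur = nxt
            paths.append((psd, pnd))
            if not through_stop:
                stop_free_paths.append((psd, pnd))
        use = stop_free_paths or paths
        sd += sum(p[0] for p in use) / len(use)
        nd += sum(p[1] for p in use) / len(use)
    return S, N, sd, nd
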