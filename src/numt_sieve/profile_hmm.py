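"""Amino-acid profile hidden Markov model: build from an alignment, score
queries in bits against an i.i.d. null.

The model is the classic match/insert/delete profile architecture. A
reference multiple alignment is converted to a model whose match states
correspond to low-gap columns, with emission probabilities derived from
column residue frequencies and transition probabilities from the observed
state paths of the rows; Laplace (+1) pseudocounts keep every probability
strictly positive. Scoring uses the forward algorithm in log space and
reports

    bit_score = (ln P(query | model) - ln P(query | null)) / ln 2,

the log-odds of the query under the profile versus an i.i.d. background —
high for sequences that fit the conserved profile, low for degraded
copies (pseudogenes) whose residues drift toward the background.

Two alignment modes are available. The default, ``local``, enters the
model uniformly at any match state and may exit freely after any match
state, so truncated fragments of the modelled region score well. In
``glocal`` mode the full model must be traversed (entry through node 0,
exit from the final node), with delete states absorbing missing columns.
In both modes the *entire query* is emitted by the path (there are no
flanking states), and paths begin and end on a match state.

Exact parity with HMMER (Dirichlet mixture priors, null2 bias correction,
E-values) is deliberately out of scope: downstream filtering uses only the
rank order of full-sequence bit scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, UndefinedValueError
from .seqrecords import Alignment, SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
_NEG_INF = -np.inf

#: Order of the seven per-node transition types.
TRANSITIONS = ("mm", "mi", "md", "im", "ii", "dm", "dd")


@dataclass
class ProfileHmm:
    """A profile HMM over the 20 amino acids.

    Node ``k`` (1..M) carries match state ``M_k``; insert state ``I_k``
    sits between ``M_k`` and ``M_{k+1}``; delete state ``D_k`` shadows
    ``M_k``. Node 0 is the begin state (its ``mm``/``mi``/``md``
    probabilities are the glocal entry distribution); transitions out of
    node M lead to the end state.

    Arrays are indexed by node: ``match_emit[k-1]`` is the emission
    vector of ``M_k``; ``trans[k, t]`` is the probability of transition
    type ``TRANSITIONS[t]`` out of node ``k`` (k = 0..M).
    """

    M: int
    match_emit: np.ndarray      # (M, 20)
    insert_emit: np.ndarray     # (M + 1, 20), node 0 = N-terminal insert
    trans: np.ndarray           # (M + 1, 7)
    null_freqs: np.ndarray      # (20,)

    def __post_init__(self) -> None:
        self.match_emit = np.asarray(self.match_emit, dtype=float)
        self.insert_emit = np.asarray(self.insert_emit, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        self.null_freqs = np.asarray(self.null_freqs, dtype=float)
        if self.M < 1 or self.match_emit.shape != (self.M, 20):
            raise DataError("match_emit must have shape (M, 20) with M >= 1")
        for name, vec in (("match_emit", self.match_emit),
                          ("insert_emit", self.insert_emit),
                          ("null_freqs", self.null_freqs.reshape(1, -1))):
            if np.any(vec < 0):
                raise DataError(f"{name} must be nonnegative")
            if not np.allclose(vec.sum(axis=-1), 1.0, atol=1e-9):
                raise DataError(f"{name} rows must sum to 1 within 1e-9")
        # models estimated by build_profile_hmm are strictly positive after
        # pseudocounting; hand-specified models may carry structural zeros
        # outgoing-transition trios/duos must each sum to 1
        t = self.trans
        for sl, name in (((0, 3), "M"), ((3, 5), "I"), ((5, 7), "D")):
            sums = t[:, sl[0]:sl[1]].sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise DataError(f"outgoing transitions from {name} states must sum to 1")

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        """Write the model in a plain-text format that round-trips bit-exact."""
        def fmt(vec) -> str:
            # repr of a Python float round-trips bit-exact
            return "\t".join(repr(float(x)) for x in vec)

        with open(path, "w", encoding="utf-8") as fh:
            fh.write("PHMM\t1\n")
            fh.write(f"M\t{self.M}\n")
            fh.write("ALPHABET\t" + AA + "\n")
            fh.write("NULL\t" + fmt(self.null_freqs) + "\n")
            for k in range(self.M + 1):
                if k >= 1:
                    fh.write(f"MATCH\t{k}\t" + fmt(self.match_emit[k - 1]) + "\n")
                fh.write(f"INSERT\t{k}\t" + fmt(self.insert_emit[k]) + "\n")
                fh.write(f"TRANS\t{k}\t" + fmt(self.trans[k]) + "\n")

    @classmethod
    def load(cls, path) -> "ProfileHmm":
        fields: dict = {"MATCH": {}, "INSERT": {}, "TRANS": {}}
        M = None
        null = None
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                tag = parts[0]
                if tag == "M":
                    M = int(parts[1])
                elif tag == "NULL":
                    null = [float(x) for x in parts[1:]]
                elif tag in fields:
                    fields[tag][int(parts[1])] = [float(x) for x in parts[2:]]
        if M is None or null is None:
            raise DataError(f"{path}: not a PHMM model file")
        return cls(
            M=M,
            match_emit=np.array([fields["MATCH"][k] for k in range(1, M + 1)]),
            insert_emit=np.array([fields["INSERT"][k] for k in range(M + 1)]),
            trans=np.array([fields["TRANS"][k] for k in range(M + 1)]),
            null_freqs=np.array(null),
        )

    # -- sampling -----------------------------------------------------------

    def sample_sequence(self, rng: np.random.Generator) -> str:
        """Draw one sequence by a glocal walk through the model."""
        out: list[str] = []
        state, node = "m", 0  # begin state behaves like M_0
        while True:
            if state == "m":
                probs, moves = self.trans[node, 0:3], ("m", "i", "d")
            elif state == "i":
                probs, moves = self.trans[node, 3:5], ("m", "i")
            else:
                probs, moves = self.trans[node, 5:7], ("m", "d")
            nxt = moves[rng.choice(len(moves), p=probs / probs.sum())]
            if nxt == "i":
                out.append(AA[rng.choice(20, p=self.insert_emit[node])])
                state = "i"
                continue
            node += 1
            state = nxt
            if node > self.M:
                break
            if state == "m":
                out.append(AA[rng.choice(20, p=self.match_emit[node - 1])])
        return "".join(out)


@dataclass(frozen=True)
class HmmScore:
    """Per-query scoring result; ``bit_score`` is the base-2 log-odds of
    the natural-log forward and null likelihoods."""

    record_id: str
    bit_score: float
    log_fwd_model: float
    log_null: float


# ---------------------------------------------------------------------------
# Model building
# ---------------------------------------------------------------------------

def build_profile_hmm(
    aln: Alignment,
    match_rule: float = 0.5,
    pseudocount: float = 1.0,
) -> ProfileHmm:
    """Estimate a profile HMM from an amino-acid alignment.

    Columns whose gap fraction is <= ``match_rule`` become match states.
    Match emissions are column residue counts with a Laplace pseudocount:
    ``(count + pc) / (column total + 20 * pc)``; insert emissions equal the
    background; transitions are counted from each row's state path with a
    pseudocount of 1 per transition type. The background (null)
    distribution is the overall residue frequency of the alignment, also
    Laplace-smoothed. ``X``/``*`` residues occupy states on a path but
    contribute no emission counts.
    """
    nrow = len(aln.records)
    ncol = aln.ncols
    cols = np.array([list(r.seq) for r in aln.records])  # (nrow, ncol) of chars
    gap_frac = (cols == "-").sum(axis=0) / nrow
    is_match = gap_frac <= match_rule
    M = int(is_match.sum())
    if M == 0:
        raise DataError("alignment yields zero match columns; cannot build a model")

    # background frequencies over the whole alignment
    null_counts = np.full(20, pseudocount)
    for a, i in AA_INDEX.items():
        null_counts[i] += (cols == a).sum()
    null_freqs = null_counts / null_counts.sum()

    # match emissions
    match_emit = np.full((M, 20), pseudocount)
    match_cols = np.flatnonzero(is_match)
    for k, j in enumerate(match_cols):
        col = cols[:, j]
        for a, i in AA_INDEX.items():
            match_emit[k, i] += (col == a).sum()
    match_emit /= match_emit.sum(axis=1, keepdims=True)

    insert_emit = np.tile(null_freqs, (M + 1, 1))

    # transition counts from observed state paths
    tcounts = np.full((M + 1, 7), 1.0)  # Laplace per type per node
    tindex = {t: i for i, t in enumerate(TRANSITIONS)}
    node_of_col = np.cumsum(is_match)  # match node index reached at column j
    for r in range(nrow):
        row = cols[r]
        prev_state, prev_node = "m", 0  # begin
        for j in range(ncol):
            if is_match[j]:
                state = "d" if row[j] == "-" else "m"
                node = node_of_col[j]
            else:
                if row[j] == "-":
                    continue
                state, node = "i", prev_node
            tcounts[prev_node, tindex[prev_state + state]] += 1
            prev_state, prev_node = state, node
        tcounts[prev_node, tindex[prev_state + "m"]] += 1  # into end state
    # normalize trios/duos
    trans = tcounts.copy()
    trans[:, 0:3] /= trans[:, 0:3].sum(axis=1, keepdims=True)
    trans[:, 3:5] /= trans[:, 3:5].sum(axis=1, keepdims=True)
    trans[:, 5:7] /= trans[:, 5:7].sum(axis=1, keepdims=True)
    return ProfileHmm(M=M, match_emit=match_emit, insert_emit=insert_emit,
                      trans=trans, null_freqs=null_freqs)


# ---------------------------------------------------------------------------
# Scoring (forward algorithm, log space)
# ---------------------------------------------------------------------------

def _encode(seq: str) -> list:
    """Map residues to indices; X is index 20 (emits with probability 1
    under both model and null, i.e. score-neutral)."""
    idx = []
    for c in seq:
        if c == "*":
            raise UndefinedValueError("query contains a stop character '*'")
        if c == "X":
            idx.append(20)
        elif c in AA_INDEX:
            idx.append(AA_INDEX[c])
        else:
            raise DataError(f"illegal amino-acid character {c!r}")
    return idx


def _log_with_x(emit: np.ndarray) -> np.ndarray:
    """Append a column of log(1) = 0 for the score-neutral X residue."""
    with np.errstate(divide="ignore"):
        return np.hstack([np.log(emit), np.zeros((emit.shape[0], 1))])


def score_sequence(hmm: ProfileHmm, query: SequenceRecord, mode: str = "local") -> HmmScore:
    """Forward-score one amino-acid query against the model.

    ``local`` (default): uniform entry over match states, free exit after
    any match state. ``glocal``: entry through node 0, exit from node M.
    Returns the natural-log forward and null likelihoods and the bit score.
    """
    if mode not in ("local", "glocal"):
        raise ValueError(f"unknown mode {mode!r}")
    x = _encode(query.seq)
    if not x:
        raise UndefinedValueError(f"query {query.id!r} is empty")
    L, M = len(x), hmm.M

    lme = _log_with_x(hmm.match_emit)           # (M, 21)
    lie = _log_with_x(hmm.insert_emit)          # (M+1, 21)
    with np.errstate(divide="ignore"):
        lnull = np.log(np.append(hmm.null_freqs, 1.0))
        lt = np.log(hmm.trans)                  # (M+1, 7)

    # per-node transition vectors, index k = node (1..M-1 used for interior)
    t_mm, t_mi, t_md = lt[:, 0], lt[:, 1], lt[:, 2]
    t_im, t_ii = lt[:, 3], lt[:, 4]
    t_dm, t_dd = lt[:, 5], lt[:, 6]

    # DP rows over match nodes 1..M (0-based arrays of length M);
    # fI[k] is insert state I_{k+1} (interior only), fD[k] is D_{k+1}.
    def d_chain(fm_row: np.ndarray, extra_into_d1: float = _NEG_INF) -> np.ndarray:
        """Given the current-position match row, propagate delete chains.

        fD[t] (state D_{t+1}) = logsumexp over entry points j <= t of
        (fm_row[j-1] + t_md[j]) carried through D-to-D transitions, plus an
        optional direct begin->D_1 term (glocal entry).
        """
        # contribution entering D_{j+1} from M_j (j = 1..M-1)
        a = np.full(M, _NEG_INF)
        if M > 1:
            a[1:] = fm_row[:-1] + t_md[1:M]
        a[0] = extra_into_d1
        # chain weights: moving D_t -> D_{t+1} uses t_dd[t] (t = 1..M-1);
        # structural-zero links are clamped to log ~5e-324 so the prefix-sum
        # trick stays NaN-free while still zeroing any path across them
        dd = t_dd[1:M] if M > 1 else np.empty(0)
        dd = np.maximum(dd, -745.0)
        c = np.concatenate([[0.0], np.cumsum(dd)])       # c[t] = sum of first t dd's
        inner = a - c                                    # a[j] - c[j]
        acc = np.logaddexp.accumulate(inner)
        return c + acc                                   # fD over states D_1..D_M

    if mode == "local":
        entry = np.full(M, -math.log(M))
    else:
        # glocal entry: B -> M_1, or B -> D_1 ... D_k -> M_{k+1}
        entry = np.full(M, _NEG_INF)
        entry[0] = t_mm[0]

    # position 1
    fM = entry + lme[:, x[0]]
    if mode == "glocal":
        # entry through leading deletes: B->D_1 (t_md[0]) -> ... -> M_k
        d0 = d_chain(np.full(M, _NEG_INF), extra_into_d1=t_md[0])
        if M > 1:
            fM[1:] = np.logaddexp(fM[1:], d0[:-1] + t_dm[1:M] + lme[1:, x[0]])
    fI = np.full(M, _NEG_INF)
    fD = d_chain(fM)

    for i in range(1, L):
        e = lme[:, x[i]]
        new_fM = np.full(M, _NEG_INF)
        if M > 1:
            from_m = fM[:-1] + t_mm[1:M]
            from_i = fI[:-1] + t_im[1:M]
            from_d = fD[:-1] + t_dm[1:M]
            new_fM[1:] = e[1:] + np.logaddexp(np.logaddexp(from_m, from_i), from_d)
        new_fI = np.logaddexp(fM + t_mi[1:M + 1], fI + t_ii[1:M + 1]) + lie[1:M + 1, x[i]]
        fM, fI = new_fM, new_fI
        fD = d_chain(fM)

    if mode == "local":
        log_fwd = float(np.logaddexp.reduce(fM))  # free exit from any match
    else:
        # exit from M_M (t_mm[M]) or through trailing deletes D_k..D_M -> end
        ends = [fM[-1] + t_mm[M], fD[-1] + t_dm[M]]
        log_fwd = float(np.logaddexp.reduce(np.array(ends)))

    log_null = float(lnull[x].sum())
    if not np.isfinite(log_fwd):
        raise UndefinedValueError(
            f"query {query.id!r} has zero probability under the model in {mode} mode"
        )
    bit = (log_fwd - log_null) / math.log(2.0)
    return HmmScore(record_id=query.id, bit_score=bit,
                    log_fwd_model=log_fwd, log_null=log_null)


def score_batch(hmm: ProfileHmm, records, mode: str = "local") -> list:
    """Order-preserving map of :func:`score_sequence`; per-record errors
    are re-raised with the record id attached."""
    out = []
    for rec in records:
        try:
            out.append(score_sequence(hmm, rec, mode=mode))
        except Exception as exc:
            raise type(exc)(f"record {rec.id!r}: {exc}") from exc
    return out
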