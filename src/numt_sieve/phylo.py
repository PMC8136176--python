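"""Neighbor-joining phylogenetics: distance matrices, NJ trees,
nonparametric bootstrap with majority-rule consensus, midpoint rooting,
and Newick I/O.

Tree building and manipulation delegate to dendropy; this module fixes
the conventions: Saitou–Nei NJ with the standard Q-criterion, negative
branch-length estimates clamped to zero with a warning flag, bootstrap
supports as percentages of replicates containing each bipartition, and
plain >50% majority-rule consensus. Supports serialize as internal-node
labels in Newick.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import DataError, UndefinedValueError
from .seqrecords import Alignment, aligned_record

Tree = dendropy.Tree


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal over labelled taxa."""

    ids: list
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise DataError(f"matrix shape {self.d.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise DataError("duplicate taxon ids")
        if np.any(np.diag(self.d) != 0):
            raise DataError("diagonal must be exactly zero")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise DataError("matrix is not symmetric within 1e-12")
        if np.any(self.d < 0):
            raise DataError("distances must be nonnegative")

    def to_phylip(self) -> str:
        lines = [f"{len(self.ids)}"]
        for i, tid in enumerate(self.ids):
            lines.append(tid + "  " + "  ".join(f"{x:.10f}" for x in self.d[i]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_phylip(cls, text: str) -> "DistanceMatrix":
        rows = [ln.split() for ln in text.strip().splitlines() if ln.strip()]
        try:
            n = int(rows[0][0])
            ids = [r[0] for r in rows[1:n + 1]]
            d = np.array([[float(x) for x in r[1:n + 1]] for r in rows[1:n + 1]])
        except (IndexError, ValueError) as exc:
            raise DataError(f"malformed PHYLIP distance matrix: {exc}") from None
        return cls(ids=ids, d=d)


def _to_dendropy_pdm(dm: DistanceMatrix, tns: dendropy.TaxonNamespace):
    buf = io.StringIO()
    buf.write("." + "".join("," + t for t in dm.ids) + "\n")
    for i, tid in enumerate(dm.ids):
        buf.write(tid + "".join(f",{float(x)!r}" for x in dm.d[i]) + "\n")
    buf.seek(0)
    return dendropy.PhylogeneticDistanceMatrix.from_csv(
        buf, delimiter=",", taxon_namespace=tns
    )


def nj_tree(dm: DistanceMatrix, taxon_namespace=None) -> Tree:
    """Saitou–Nei neighbor joining. Negative branch-length estimates are
    clamped to 0 (each clamped edge is flagged ``clamped=True`` and a
    warning is emitted). The returned tree is unrooted; the basal
    bifurcation dendropy introduces is collapsed so the root placeholder
    has degree >= 3 where possible."""
    if len(dm.ids) < 2:
        raise DataError("need at least 2 taxa")
    tns = taxon_namespace or dendropy.TaxonNamespace(dm.ids)
    if len(dm.ids) == 2:
        half = float(dm.d[0, 1]) / 2.0
        tree = dendropy.Tree.get(
            data=f"({dm.ids[0]}:{half!r},{dm.ids[1]}:{half!r});",
            schema="newick", taxon_namespace=tns,
        )
        tree.is_rooted = False
        return tree
    pdm = _to_dendropy_pdm(dm, tns)
    tree = pdm.nj_tree()
    if len(dm.ids) >= 3:
        tree.collapse_basal_bifurcation()
    clamped = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            edge.clamped = True
            clamped += 1
    if clamped:
        warnings.warn(f"{clamped} negative NJ branch length(s) clamped to 0")
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bootstrap + consensus
# ---------------------------------------------------------------------------

def _resample_alignment(aln: Alignment, rng: np.random.Generator) -> Alignment:
    cols = rng.integers(0, aln.ncols, size=aln.ncols)
    rows = [
        aligned_record(r.id, "".join(r.seq[c] for c in cols), r.alphabet, r.description)
        for r in aln.records
    ]
    return Alignment(rows)


def bootstrap_trees(aln: Alignment, n_reps: int, distance=None,
                    seed: int = 0) -> tuple:
    """Column-resampled replicate NJ trees on a shared taxon namespace.

    Returns ``(trees, n_skipped)``; replicates whose distances saturate
    are skipped (with a warning), not failed.
    """
    if distance is None:
        from .evolution_metrics import k2p_matrix as distance
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace([r.id for r in aln.records])
    trees = dendropy.TreeList(taxon_namespace=tns)
    skipped = 0
    for _ in range(n_reps):
        rep = _resample_alignment(aln, rng)
        try:
            dm = distance(rep)
            trees.append(nj_tree(dm, taxon_namespace=tns))
        except UndefinedValueError:
            skipped += 1
    if skipped:
        warnings.warn(f"{skipped}/{n_reps} bootstrap replicates skipped (saturated distances)")
    return trees, skipped


def bipartition_supports(trees) -> dict:
    """Percentage of trees containing each non-trivial bipartition,
    keyed by frozenset of leaf labels on the smaller (tie: lexicographic
    first) side."""
    if not len(trees):
        raise DataError("no trees to summarize")
    all_labels = frozenset(t.label for t in trees.taxon_namespace)
    counts: dict = {}
    for tree in trees:
        seen = set()
        for edge in tree.preorder_internal_edge_iter():
            node = edge.head_node
            if node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            other = all_labels - side
            if len(side) < 2 or len(other) < 2:
                continue
            key = min((side, other), key=lambda s: (len(s), sorted(s)))
            seen.add(key)
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    return {k: 100.0 * v / len(trees) for k, v in counts.items()}


def bootstrap_consensus(aln: Alignment, n_reps: int = 1000, distance=None,
                        seed: int = 0) -> Tree:
    """Majority-rule (> 50%) consensus of NJ trees over column-resampled
    bootstrap replicates, with supports (percentages) attached to
    internal nodes as ``support_pct`` and as node labels."""
    if len(aln.records) < 4:
        raise DataError("bootstrap consensus needs at least 4 rows")
    trees, _ = bootstrap_trees(aln, n_reps, distance=distance, seed=seed)
    if not len(trees):
        raise UndefinedValueError("all bootstrap replicates were skipped")
    cons = trees.consensus(min_freq=0.5)
    cons.is_rooted = False
    supports = bipartition_supports(trees)
    all_labels = frozenset(t.label for t in cons.taxon_namespace)
    for node in cons.preorder_internal_node_iter():
        if node.parent_node is None:
            node.label = None
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_labels - side
        key = min((side, other), key=lambda s: (len(s), sorted(s)))
        pct = supports.get(key, round(100.0 * node.support, 10) if node.support else 0.0)
        node.support_pct = pct
        node.label = f"{pct:g}"
    return cons


def map_supports_to_tree(tree: Tree, replicate_trees) -> Tree:
    """Attach bootstrap supports to an existing tree's internal nodes
    (the alternative to reading them off the consensus topology)."""
    supports = bipartition_supports(replicate_trees)
    all_labels = frozenset(t.label for t in tree.taxon_namespace)
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_labels - side
        if len(side) < 2 or len(other) < 2:
            continue
        key = min((side, other), key=lambda s: (len(s), sorted(s)))
        pct = supports.get(key, 0.0)
        node.support_pct = pct
        node.label = f"{pct:g}"
    return tree


# ---------------------------------------------------------------------------
# Rooting and Newick I/O
# ---------------------------------------------------------------------------

def midpoint_root(tree: Tree) -> Tree:
    """Root at the midpoint of the longest leaf-to-leaf path. A tree with
    zero total path length gets a degenerate-root warning and is rooted
    at its first internal node."""
    tree = tree.clone(depth=1)
    leaves = list(tree.leaf_node_iter())
    if len(leaves) == 2:
        # the root already sits on the single edge; rebalance it
        total = sum(lf.edge.length or 0.0 for lf in leaves)
        for lf in leaves:
            lf.edge.length = total / 2.0
        tree.is_rooted = True
        return tree
    pdm = tree.phylogenetic_distance_matrix()
    maxlen = 0.0
    for t1 in tree.taxon_namespace:
        for t2 in tree.taxon_namespace:
            maxlen = max(maxlen, pdm.patristic_distance(t1, t2))
    if maxlen == 0.0:
        warnings.warn("zero-length tree; rooting at the first internal node")
        internal = next(tree.preorder_internal_node_iter())
        tree.reroot_at_node(internal)
        return tree
    tree.reroot_at_midpoint(update_bipartitions=True)
    return tree


def write_newick(tree: Tree, path) -> None:
    """Newick with branch lengths at 12 significant digits and supports
    as internal-node labels."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".12g",
        ))


def read_newick(path) -> Tree:
    """Read a Newick tree; numeric internal-node labels are interpreted
    as bootstrap supports (``support_pct``)."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:
        raise DataError(f"{path}: malformed Newick: {exc}") from None
    for node in tree.preorder_internal_node_iter():
        if node.label:
            try:
                node.support_pct = float(node.label)
            except ValueError:
                pass
    return tree
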