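"""Neighbor-joining trees from p-distance matrices.

The tree is descriptive — a visual summary of MOTU divergence annotated
with trap occupancy — not a phylogeny, so no support values are computed.
The agglomeration follows Saitou & Nei with the Studier-Keppler Q
criterion; ties are broken on the lexicographically smallest pair of node
keys (a node's key is its smallest descendant leaf id), which makes the
output deterministic and invariant to input leaf order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .clustering import DistanceMatrix, pairwise_distances
from .errors import DegenerateInputError
from .io import AlignedSeqSet, MotuPartition, SpecimenTable


@dataclass
class NJTree:
    """Unrooted NJ tree (root is the final trifurcation) plus leaf annotations."""

    tree: TreeNode
    leaf_annotations: dict[str, int] | None = None

    def leaf_names(self) -> set[str]:
        return {t.name for t in self.tree.tips()}

    def path_length_matrix(self) -> tuple[list[str], np.ndarray]:
        """Tip-to-tip path lengths, rows/cols ordered by leaf name."""
        dm = self.tree.tip_tip_distances()
        order = sorted(dm.ids)
        idx = [dm.ids.index(i) for i in order]
        return order, dm.data[np.ix_(idx, idx)]


def neighbor_joining(
    ids: Sequence[str],
    d: np.ndarray,
    clamp_negative: bool = False,
    annotations: Mapping[str, int] | None = None,
) -> NJTree:
    """Build an NJ tree from a symmetric distance matrix over ``ids``.

    Negative branch lengths (possible under raw NJ) are preserved with a
    warning unless ``clamp_negative`` is set.  Requires >= 3 leaves; with
    exactly 2 a single edge is returned with a warning.
    """
    ids = list(ids)
    d = np.asarray(d, dtype=float)
    if len(ids) < 2:
        raise DegenerateInputError("neighbor joining needs >= 2 leaves")
    if d.shape != (len(ids), len(ids)):
        raise DegenerateInputError("distance matrix shape does not match ids")
    if not np.all(np.isfinite(d)):
        raise DegenerateInputError("distances must be finite")

    if len(ids) == 2:
        warnings.warn("only 2 leaves: returning a single edge, not an NJ tree")
        root = TreeNode()
        half = float(d[0, 1]) / 2
        root.append(TreeNode(name=ids[0], length=half))
        root.append(TreeNode(name=ids[1], length=half))
        return NJTree(root, dict(annotations) if annotations else None)

    # active nodes: parallel lists of sort keys, TreeNodes, matrix indices
    keys = list(ids)
    nodes = [TreeNode(name=i) for i in ids]
    D = d.copy()
    negative_seen = False

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        i, j = min(
            (tuple(sorted((keys[a], keys[b]))), (min(a, b), max(a, b)))
            for a, b in cand
        )[1]
        li = D[i, j] / 2 + (R[i] - R[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        negative_seen |= li < 0 or lj < 0
        if clamp_negative:
            li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = float(li), float(lj)
        parent.append(ni)
        parent.append(nj)
        dnew = (D[i] + D[j] - D[i, j]) / 2
        keep = [k for k in range(r) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], dnew[keep]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]
        nodes = [nodes[k] for k in keep] + [parent]

    # final trifurcation: solve the 3-leaf star exactly
    (a, b, c) = range(3)
    la = (D[a, b] + D[a, c] - D[b, c]) / 2
    lb = D[a, b] - la
    lc = D[a, c] - la
    negative_seen |= min(la, lb, lc) < 0
    if clamp_negative:
        la, lb, lc = (max(v, 0.0) for v in (la, lb, lc))
    root = TreeNode()
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = float(length)
        root.append(node)

    if negative_seen and not clamp_negative:
        warnings.warn("NJ produced negative branch length(s); preserved as-is")
    return NJTree(root, dict(annotations) if annotations else None)


def motu_tree(
    seqs: AlignedSeqSet,
    partition: MotuPartition,
    specimens: SpecimenTable,
    clamp_negative: bool = False,
) -> NJTree:
    """NJ tree over one representative sequence per MOTU, p-distance based.

    The representative is the member with the lexicographically smallest
    specimen id (at the 1-bp threshold all members are identical, so the
    choice is immaterial there).  Leaves are annotated with the number of
    pitfall traps in which the MOTU occurred.
    """
    seqd = specimens.sequenced()
    seq_of = dict(zip(seqd["specimen_id"], seqd["sequence_id"]))
    trap_of = dict(zip(seqd["specimen_id"], seqd["trap_id"]))
    reps: dict[str, str] = {}  # motu -> sequence id of representative
    traps: dict[str, set[str]] = {}
    for motu, members in partition.members().items():
        reps[motu] = seq_of[members[0]]  # members sorted
        traps[motu] = {trap_of[s] for s in members}
    motus = sorted(reps)
    if len(motus) < 3:
        raise DegenerateInputError("need >= 3 MOTUs for an NJ tree")
    dm: DistanceMatrix = pairwise_distances(seqs.subset(reps[m] for m in motus))
    d = dm.p_dist
    annotations = {m: len(traps[m]) for m in motus}
    return neighbor_joining(motus, d, clamp_negative, annotations)


def to_newick(njtree: NJTree) -> str:
    """Newick string; leaves labelled ``motuID|ntraps`` when annotated."""
    tree = njtree.tree.copy()
    if njtree.leaf_annotations:
        for tip in tree.tips():
            if tip.name in njtree.leaf_annotations:
                tip.name = f"{tip.name}|{njtree.leaf_annotations[tip.name]}"
    return str(tree)


def write_newick(njtree: NJTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(njtree))


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
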