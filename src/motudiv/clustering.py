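"""Pairwise basepair differences, p-distances and threshold MOTU delimitation.

A MOTU (molecular operational taxonomic unit) is delimited by a basepair
threshold: a difference of ``k`` bp assigns a specimen to a different MOTU,
encoded as *merge iff bp_diff < k* under single linkage.  At the default
threshold of 1 bp a MOTU is therefore exactly a group of identical
sequences; at larger thresholds single-linkage chaining applies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ParameterError, UndefinedDistanceError
from .io import AlignedSeqSet, MotuPartition

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate("ACGTN-"):
    _CODE[ord(_ch)] = _i
_N = 4
_GAP = 5


def _encode(seqs: AlignedSeqSet) -> tuple[list[str], np.ndarray]:
    ids = list(seqs.records)
    mat = np.frombuffer(
        "".join(seqs.records[i] for i in ids).encode("ascii"), dtype=np.uint8
    ).reshape(len(ids), seqs.alignment_length)
    return ids, _CODE[mat]


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise bp differences and p-distances over an alignment.

    ``bp_diff[i, j]`` counts positions where sequences i and j differ under
    the gap/ambiguity policies; ``compared_sites[i, j]`` counts positions
    retained for the pair; ``p_dist = bp_diff / compared_sites``.
    """

    ids: tuple[str, ...]
    bp_diff: np.ndarray
    compared_sites: np.ndarray
    p_dist: np.ndarray

    def index(self, sid: str) -> int:
        return self.ids.index(sid)

    def subset(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in keep]
        return DistanceMatrix(
            ids=tuple(keep),
            bp_diff=self.bp_diff[np.ix_(idx, idx)],
            compared_sites=self.compared_sites[np.ix_(idx, idx)],
            p_dist=self.p_dist[np.ix_(idx, idx)],
        )


def pairwise_distances(
    seqs: AlignedSeqSet,
    ambiguity_policy: Literal["pairwise_deletion", "count"] = "pairwise_deletion",
    gap_policy: Literal["difference", "pairwise_deletion"] = "difference",
    collapse_gap_runs: bool = False,
) -> DistanceMatrix:
    """Count differing sites for every sequence pair of the alignment.

    Policies (defaults shown first):

    * ``ambiguity_policy='pairwise_deletion'``: positions where either
      residue is N are excluded from both ``bp_diff`` and
      ``compared_sites``; ``'count'`` treats N as an ordinary residue.
    * ``gap_policy='difference'``: a gap aligned to a base counts as one
      difference (gap-gap is identical); ``'pairwise_deletion'`` drops any
      position where either residue is a gap.
    * ``collapse_gap_runs``: with the default gap policy, count a maximal
      run of consecutive gap-vs-base positions (gap on the same side) as a
      single difference and a single compared site (one indel event).

    Raises :class:`UndefinedDistanceError` if a pair retains no sites.
    """
    ids, X = _encode(seqs)
    n = len(ids)
    is_n = X == _N
    is_gap = X == _GAP

    bp = np.zeros((n, n), dtype=np.int64)
    comp = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        diff = X[i] != X  # (n, L)
        valid = np.ones_like(diff, dtype=bool)
        if ambiguity_policy == "pairwise_deletion":
            valid &= ~(is_n[i] | is_n)
        if gap_policy == "pairwise_deletion":
            valid &= ~(is_gap[i] | is_gap)
        bp[i] = (diff & valid).sum(axis=1)
        comp[i] = valid.sum(axis=1)

    if collapse_gap_runs and gap_policy == "difference":
        _collapse_runs(X, is_n if ambiguity_policy == "pairwise_deletion" else None,
                       bp, comp)

    np.fill_diagonal(bp, 0)
    for i in range(n):
        for j in range(i + 1, n):
            if comp[i, j] == 0:
                raise UndefinedDistanceError(
                    f"no comparable sites between {ids[i]!r} and {ids[j]!r}"
                )
    with np.errstate(invalid="ignore"):
        p = bp / comp
    return DistanceMatrix(tuple(ids), bp, comp, p)


def _collapse_runs(X: np.ndarray, is_n: np.ndarray | None,
                   bp: np.ndarray, comp: np.ndarray) -> None:
    """Reduce each maximal same-side gap-vs-base run to one event, in place."""
    n = X.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            valid = np.ones(X.shape[1], dtype=bool)
            if is_n is not None:
                valid &= ~(is_n[i] | is_n[j])
            a, b = X[i], X[j]
            gap_i = valid & (a == _GAP) & (b != _GAP)
            gap_j = valid & (b == _GAP) & (a != _GAP)
            removed = 0
            for mask in (gap_i, gap_j):
                if not mask.any():
                    continue
                # count positions beyond the first of each maximal run
                padded = np.concatenate(([False], mask))
                starts = int((mask & ~padded[:-1]).sum())
                removed += int(mask.sum()) - starts
            bp[i, j] -= removed
            bp[j, i] = bp[i, j]
            comp[i, j] -= removed
            comp[j, i] = comp[i, j]


def cluster_motus(
    dm: DistanceMatrix,
    threshold_bp: int,
    id_map: Mapping[str, str] | None = None,
) -> MotuPartition:
    """Single-linkage MOTU delimitation: merge iff ``bp_diff < threshold_bp``.

    Two sequences share a MOTU iff they are connected by a chain of pairs
    each differing by fewer than ``threshold_bp`` basepairs.  MOTU ids are
    assigned deterministically, ordered by each cluster's smallest sequence
    id.  ``id_map`` optionally translates sequence ids to specimen ids in
    the returned assignment.
    """
    if threshold_bp < 1:
        raise ParameterError("threshold_bp must be >= 1")
    adj = csr_matrix(dm.bp_diff < threshold_bp)
    _, labels = connected_components(adj, directed=False)
    groups: dict[int, list[str]] = {}
    for sid, lab in zip(dm.ids, labels):
        groups.setdefault(int(lab), []).append(sid)
    ordered = sorted(groups.values(), key=lambda g: min(g))
    width = len(str(len(ordered)))
    assignment: dict[str, str] = {}
    for k, members in enumerate(ordered, start=1):
        motu = f"MOTU_{k:0{width}d}"
        for sid in members:
            key = id_map[sid] if id_map is not None else sid
            assignment[key] = motu
    return MotuPartition(threshold_bp=threshold_bp, assignment=assignment)


def motu_threshold_profile(
    dm: DistanceMatrix, thresholds: Iterable[int],
    id_map: Mapping[str, str] | None = None,
) -> dict[int, int]:
    """Number of MOTUs at each bp threshold (non-increasing in threshold)."""
    ts = list(thresholds)
    if not ts:
        raise ParameterError("thresholds must be non-empty")
    return {t: cluster_motus(dm, t, id_map).n_motus for t in sorted(ts)}
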