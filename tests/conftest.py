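"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from motudiv import AlignedSeqSet, SpecimenTable, SimConfig


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; no package internals)
# ---------------------------------------------------------------------------

def naive_bp_diff(a: str, b: str) -> tuple[int, int]:
    """Position-by-position recount under the default policies.

    Returns (bp_diff, compared_sites): N against anything is excluded,
    gap-vs-base is a difference, gap-gap is an identical compared site.
    """
    bp = comp = 0
    for x, y in zip(a, b):
        if x == "N" or y == "N":
            continue
        comp += 1
        if x != y:
            bp += 1
    return bp, comp


def naive_components(ids, bp, threshold):
    """Connected components of the graph with edges bp_diff < threshold,
    found by breadth-first traversal."""
    ids = list(ids)
    n = len(ids)
    remaining = set(range(n))
    comps = []
    while remaining:
        start = min(remaining)
        stack, seen = [start], {start}
        while stack:
            i = stack.pop()
            for j in range(n):
                if j not in seen and bp[i][j] < threshold:
                    seen.add(j)
                    stack.append(j)
        remaining -= seen
        comps.append(frozenset(ids[i] for i in seen))
    return set(comps)


def random_alignment(rng: np.random.Generator, n_seqs: int, length: int,
                     alphabet: str = "ACGT") -> AlignedSeqSet:
    letters = np.array(list(alphabet))
    return AlignedSeqSet({
        f"S{i:03d}": "".join(letters[rng.integers(0, len(letters), size=length)])
        for i in range(n_seqs)
    })


def random_clustered_alignment(rng: np.random.Generator, n_seqs: int,
                               length: int) -> AlignedSeqSet:
    """Sequences around a few centroids so thresholds 1-3 actually differ."""
    n_centroids = max(2, n_seqs // 4)
    bases = np.array(list("ACGT"))
    centroids = rng.integers(0, 4, size=(n_centroids, length))
    records = {}
    for i in range(n_seqs):
        seq = centroids[rng.integers(0, n_centroids)].copy()
        for _ in range(int(rng.integers(0, 4))):  # 0-3 substitutions
            p = rng.integers(0, length)
            seq[p] = (seq[p] + rng.integers(1, 4)) % 4
        records[f"S{i:03d}"] = "".join(bases[seq])
    return AlignedSeqSet(records)


def random_additive_matrix(rng: np.random.Generator, n_leaves: int):
    """Distance matrix from a random binary tree with positive branch lengths.

    Built by sequential leaf attachment; returns (ids, matrix, splits) where
    splits is the set of non-trivial bipartitions (frozenset of the smaller
    side by leaf name, canonicalised to exclude leaf 'L00').
    """
    ids = [f"L{i:02d}" for i in range(n_leaves)]
    # represent the tree as an adjacency map with branch lengths
    adj: dict[int, dict[int, float]] = {0: {}, 1: {}}
    next_node = [2]

    def blen():
        return float(rng.uniform(0.1, 2.0))

    adj[0][1] = adj.setdefault(1, {})[0] = blen()
    leaf_nodes = {0: ids[0], 1: ids[1]}
    edges = [(0, 1)]
    for k in range(2, n_leaves):
        # split a random edge with a new internal node, hang the new leaf
        ei = int(rng.integers(0, len(edges)))
        u, v = edges[ei]
        w = adj[u].pop(v); adj[v].pop(u)
        mid, leaf = next_node[0], next_node[0] + 1
        next_node[0] += 2
        adj[mid] = {}; adj[leaf] = {}
        a = float(rng.uniform(0.05, w - 0.05)) if w > 0.1 else w / 2
        adj[u][mid] = adj[mid][u] = a
        adj[mid][v] = adj[v][mid] = w - a
        adj[mid][leaf] = adj[leaf][mid] = blen()
        leaf_nodes[leaf] = ids[k]
        edges[ei] = (u, mid)
        edges.extend([(mid, v), (mid, leaf)])

    # all-pairs path lengths by BFS from each leaf
    import heapq
    node_ids = {n: leaf_nodes.get(n) for n in adj}
    d = np.zeros((n_leaves, n_leaves))
    name_to_idx = {name: i for i, name in enumerate(ids)}
    for src, src_name in leaf_nodes.items():
        dist = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            dd, u = heapq.heappop(heap)
            if dd > dist.get(u, np.inf):
                continue
            for v, w in adj[u].items():
                nd = dd + w
                if nd < dist.get(v, np.inf):
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
        for n, name in leaf_nodes.items():
            d[name_to_idx[src_name], name_to_idx[name]] = dist[n]

    # splits: for each internal edge, leaves on one side
    splits = set()
    leafset = set(leaf_nodes)
    for u in adj:
        for v in adj[u]:
            if u > v:
                continue
            # side of u without crossing v
            stack, seen = [u], {u, v}
            side = set()
            while stack:
                x = stack.pop()
                if x in leaf_nodes:
                    side.add(leaf_nodes[x])
                for y in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            if 2 <= len(side) <= n_leaves - 2:
                if ids[0] in side:
                    side = {leaf_nodes[n] for n in leafset} - side
                splits.add(frozenset(side))
    return ids, d, splits


def tree_splits(tree) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted skbio tree, canonicalised to
    the side not containing the lexicographically smallest leaf."""
    leaves = {t.name for t in tree.tips()}
    anchor = min(leaves)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(leaves) - 2:
            if anchor in side:
                side = frozenset(leaves - side)
            splits.add(side)
    return splits


def random_incidence(rng, m, s, p=0.35):
    """Random trap x taxon incidence matrix with no empty taxa."""
    from motudiv import CommunityMatrix
    inc = (rng.random((m, s)) < p).astype(int)
    inc[0, :] |= (inc.sum(axis=0) == 0)
    return CommunityMatrix(
        pd.DataFrame(inc, index=[f"u{i}" for i in range(m)],
                     columns=[f"t{j}" for j in range(s)]),
        mode="incidence",
    )


def random_dissim(rng, n):
    """Euclidean distances of random points, scaled into [0, 1]."""
    from motudiv import DissimilarityMatrix
    x = rng.random((n, 3))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    d /= d.max()
    return DissimilarityMatrix(tuple(f"u{i}" for i in range(n)), d, name="test")


def brute_force_mantel(dA, dB):
    """Full enumeration over all unit permutations of dB (independent oracle)."""
    import itertools
    n = dA.shape[0]
    iu = np.triu_indices(n, k=1)
    a = dA[iu]
    r_obs = np.corrcoef(a, dB[iu])[0, 1]
    count = total = 0
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        r = np.corrcoef(a, dB[np.ix_(p, p)][iu])[0, 1]
        count += r >= r_obs - 1e-12
        total += 1
    return r_obs, count / total


def reciprocal_averaging(N, tol=1e-13, max_iter=20000):
    """Fixed point of reciprocal averaging: first non-trivial CA axis.

    Iterates taxon scores = weighted means of site scores and back,
    re-standardising site scores to zero weighted mean / unit weighted
    variance.  Returns the standardised site scores and the CA eigenvalue
    (the shrink factor of one full site->taxon->site round at convergence).
    """
    N = np.asarray(N, dtype=float)
    r = N.sum(axis=1)
    c = N.sum(axis=0)
    w = r / r.sum()
    x = np.arange(N.shape[0], dtype=float)
    x -= (w * x).sum()
    x /= np.sqrt((w * x ** 2).sum())
    norm = 0.0
    for _ in range(max_iter):
        u = (N.T @ x) / c
        x_new = (N @ u) / r
        x_new -= (w * x_new).sum()
        norm = np.sqrt((w * x_new ** 2).sum())
        x_new /= norm
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    return x, norm


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_specimens(rows) -> SpecimenTable:
    return SpecimenTable(pd.DataFrame(
        rows,
        columns=["specimen_id", "trap_id", "transect_id", "habitat",
                 "morphospecies_id", "sequence_id"],
    ))


@pytest.fixture
def small_specimens() -> SpecimenTable:
    """Five specimens, two transects (one per habitat), hand-enumerable."""
    return make_specimens([
        ("I1", "T1a", "T1", "primary", "M1", "Q1"),
        ("I2", "T1a", "T1", "primary", "M1", "Q2"),
        ("I3", "T1b", "T1", "primary", "M2", "Q3"),
        ("I4", "T2a", "T2", "secondary", "M2", "Q4"),
        ("I5", "T2a", "T2", "secondary", "M3", "Q5"),
    ])


@pytest.fixture
def noiseless_cfg() -> SimConfig:
    """Noise-free study design with engineered splittings and lumpings."""
    return SimConfig(
        n_species=20, seed=7, n_cryptic_pairs=1, n_dimorphic_species=2,
        intraspecific_variant_rate=0.0, failure_rate=0.0,
        habitat_specialist_fraction=1.0,
    )
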