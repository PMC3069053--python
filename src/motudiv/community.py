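"""Community composition: Bray-Curtis dissimilarity, Mantel tests,
detrended correspondence analysis (DCA) and a permutation test of a
grouping factor (habitat) fitted to the first two ordination axes.

The Mantel test and the factor fit switch to exhaustive enumeration at
small unit counts (<= 7 units, or label multisets with few distinct
arrangements), so p-values are exact at the scale of a six-transect
design.  DCA implements detrending by segments only (no nonlinear
rescaling): axis 1 is plain correspondence analysis; axis-2 site scores
have the within-segment mean (over ``n_segments`` equal-width bins of
axis 1) subtracted and are re-centred.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import (
    ConsistencyError,
    DegenerateInputError,
    ParameterError,
    UndefinedDistanceError,
)
from .io import CommunityMatrix

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DissimilarityMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray
    name: str = "bray-curtis"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ConsistencyError("matrix shape does not match unit ids")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0.0):
            raise ConsistencyError("dissimilarity matrix must be symmetric, zero-diagonal")
        object.__setattr__(self, "matrix", m)

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def bray_curtis(cm: CommunityMatrix) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity d(x, y) = sum|x-y| / sum(x+y) among units."""
    X = cm.df.values.astype(float)
    if X.shape[0] < 2:
        raise ParameterError("need >= 2 units")
    zero_rows = np.where(X.sum(axis=1) == 0)[0]
    if len(zero_rows) >= 2:
        ids = [cm.units[i] for i in zero_rows]
        raise UndefinedDistanceError(
            f"Bray-Curtis undefined between all-zero units {ids}"
        )
    d = squareform(pdist(X, metric="braycurtis"))
    return DissimilarityMatrix(tuple(cm.units), d)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str  # "exhaustive" or "permutation"


def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel(
    dA: DissimilarityMatrix,
    dB: DissimilarityMatrix,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    exhaustive_max_units: int = 7,
) -> MantelResult:
    """One-sided (upper-tail) Mantel test of matrix correlation.

    ``r`` is the Pearson correlation of the upper-triangle vectors; the
    null distribution permutes rows and columns of ``dB`` simultaneously.
    With ``n <= exhaustive_max_units`` all n! permutations are enumerated
    and the p-value is exact; otherwise ``p = (1 + #{r* >= r}) / (1 + n_perm)``.
    """
    if dA.ids != dB.ids:
        raise ConsistencyError("Mantel requires identical unit sets in order")
    n = len(dA.ids)
    if n < 3:
        raise DegenerateInputError("Mantel needs >= 3 units")
    a = _upper(dA.matrix)
    B = dB.matrix
    if np.std(a) == 0 or np.std(_upper(B)) == 0:
        raise DegenerateInputError("constant distance matrix; r undefined")

    az = (a - a.mean()) / a.std()
    iu = np.triu_indices(n, k=1)

    def corr(perm: np.ndarray) -> float:
        b = B[np.ix_(perm, perm)][iu]
        return float(az @ ((b - b.mean()) / b.std()) / a.size)

    r_obs = corr(np.arange(n))
    if n <= exhaustive_max_units:
        rs = np.array(
            [corr(np.array(p)) for p in itertools.permutations(range(n))]
        )
        p_val = float((rs >= r_obs - _EPS).sum() / rs.size)
        return MantelResult(r_obs, p_val, rs.size, "exhaustive")
    if n_perm < 99:
        raise ParameterError("n_perm must be >= 99")
    rng = np.random.default_rng() if rng is None else rng
    count = sum(
        corr(rng.permutation(n)) >= r_obs - _EPS for _ in range(n_perm)
    )
    return MantelResult(r_obs, float((1 + count) / (1 + n_perm)), n_perm, "permutation")


# ---------------------------------------------------------------------------
# correspondence analysis + detrending by segments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DcaResult:
    site_scores: pd.DataFrame    # units x [axis1, axis2]
    taxon_scores: pd.DataFrame   # taxa x [axis1, axis2]
    eigenvalues: tuple[float, float]
    n_segments: int
    row_weights: pd.Series       # unit masses (for weighted means)


def _ca(N: np.ndarray):
    """Correspondence analysis via SVD of the chi-square standardised matrix."""
    total = N.sum()
    P = N / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    # principal coordinates for sites, standard coordinates for taxa
    site = (U / np.sqrt(r)[:, None]) * sv[None, :]
    taxon = Vt.T / np.sqrt(c)[:, None]
    return site, taxon, sv ** 2, r


def dca(cm: CommunityMatrix, n_segments: int = 26) -> DcaResult:
    """Detrended correspondence analysis (detrending by segments).

    Axis 1 equals plain CA axis 1 (site principal coordinates).  Axis-2
    site scores are detrended against axis 1: the axis-1 range is split
    into ``n_segments`` equal-width bins and the within-bin mean of the
    axis-2 scores is subtracted, then scores are re-centred.  All-zero
    rows/columns are dropped with a warning.
    """
    if n_segments < 1:
        raise ParameterError("n_segments must be >= 1")
    df = cm.df.astype(float)
    zero_r = df.index[(df.sum(axis=1) == 0)]
    zero_c = df.columns[(df.sum(axis=0) == 0)]
    if len(zero_r) or len(zero_c):
        warnings.warn(
            f"dropping all-zero rows {list(zero_r)} / columns {list(zero_c)}"
        )
        df = df.drop(index=zero_r, columns=zero_c)
    if df.shape[0] < 3:
        raise DegenerateInputError("DCA needs >= 3 non-empty units")

    site, taxon, eig, r = _ca(df.values)
    n_axes = min(2, site.shape[1])
    ax1 = site[:, 0]
    ax2 = site[:, 1].copy() if n_axes > 1 else np.zeros_like(ax1)
    eig2 = float(eig[1]) if n_axes > 1 else 0.0

    # detrend axis 2 against axis 1 by segments
    lo, hi = ax1.min(), ax1.max()
    if hi > lo:
        edges = np.linspace(lo, hi, n_segments + 1)
        bins = np.clip(np.digitize(ax1, edges[1:-1]), 0, n_segments - 1)
        for b in np.unique(bins):
            mask = bins == b
            ax2[mask] -= ax2[mask].mean()
    ax2 -= ax2.mean()

    sites = pd.DataFrame({"axis1": ax1, "axis2": ax2}, index=df.index)
    taxa = pd.DataFrame(
        {"axis1": taxon[:, 0],
         "axis2": taxon[:, 1] if n_axes > 1 else np.zeros(df.shape[1])},
        index=df.columns,
    )
    weights = pd.Series(r, index=df.index, name="weight")
    return DcaResult(sites, taxa, (float(eig[0]), eig2), n_segments, weights)


# ---------------------------------------------------------------------------
# factor fit on ordination scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorFitResult:
    r_squared: float
    p: float
    n_perm: int
    method: str  # "exhaustive" or "permutation"
    centroids: pd.DataFrame


def _r2(scores: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    centre = scores.mean(axis=0)
    ss_total = float(((scores - centre) ** 2).sum())
    if ss_total <= 0:
        raise DegenerateInputError("all ordination scores identical")
    ss_within = 0.0
    for g in range(n_groups):
        pts = scores[codes == g]
        ss_within += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return 1.0 - ss_within / ss_total


def fit_factor(
    scores: pd.DataFrame,
    groups,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    exhaustive_max_arrangements: int = 10000,
) -> FactorFitResult:
    """Fit a grouping factor to 2-D ordination scores; permutation test.

    ``r^2 = 1 - SS_within / SS_total`` over the (axis1, axis2) site scores.
    The null permutes group labels across units; all distinct label
    arrangements are enumerated when their number is small (exact p with
    floor 1/#arrangements), otherwise Monte-Carlo with the +1 correction.
    """
    X = np.asarray(scores, dtype=float)
    labels = pd.Series(list(groups))
    if len(labels) != X.shape[0]:
        raise ConsistencyError("groups length does not match score rows")
    cats = sorted(labels.unique())
    if len(cats) < 2:
        raise ParameterError("need >= 2 groups")
    codes = labels.map({c: i for i, c in enumerate(cats)}).to_numpy()

    r2_obs = _r2(X, codes, len(cats))
    counts = labels.value_counts()
    n_arr = math.factorial(len(labels))
    for c in counts:
        n_arr //= math.factorial(c)

    centroids = pd.DataFrame(
        [X[codes == i].mean(axis=0) for i in range(len(cats))],
        index=cats, columns=list(scores.columns) if hasattr(scores, "columns")
        else ["axis1", "axis2"],
    )

    if n_arr <= exhaustive_max_arrangements:
        arrangements = sorted(set(itertools.permutations(codes)))
        r2s = np.array([_r2(X, np.array(a), len(cats)) for a in arrangements])
        p = float((r2s >= r2_obs - _EPS).sum() / r2s.size)
        return FactorFitResult(r2_obs, p, r2s.size, "exhaustive", centroids)
    rng = np.random.default_rng() if rng is None else rng
    count = sum(
        _r2(X, rng.permutation(codes), len(cats)) >= r2_obs - _EPS
        for _ in range(n_perm)
    )
    p = float((1 + count) / (1 + n_perm))
    return FactorFitResult(r2_obs, p, n_perm, "permutation", centroids)
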