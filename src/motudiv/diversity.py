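"""Sample-based accumulation curves, first-order jackknife richness,
per-transect richness / per-trap density, and the t-test comparisons.

Samples are pitfall traps throughout.  The accumulation curve gives the
expected number of taxa found in the first ``h`` of ``m`` pooled traps,
either by Monte-Carlo permutation of trap order (with percentile confidence
intervals) or by the analytic hypergeometric formula (Mao tau)

    E[S_h] = S_obs - sum_i C(m - k_i, h) / C(m, h),

where ``k_i`` is the number of traps containing taxon ``i``.  The
first-order jackknife extrapolates total richness from the uniques
``f1`` (taxa found in exactly one trap): ``S_jack1 = S_obs + f1 (m-1)/m``,
with the Heltshe-Forrester variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ConsistencyError, ParameterError
from .io import CommunityMatrix


# ---------------------------------------------------------------------------
# accumulation curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AccumulationCurve:
    h: np.ndarray              # 1..m pooled samples
    mean_richness: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    method: Literal["permutation", "analytic"]
    mc_se: np.ndarray | None = None  # Monte-Carlo SE of the permutation mean

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "h": self.h,
                "mean_richness": self.mean_richness,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def accumulation_curve(
    cm: CommunityMatrix,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
    method: Literal["permutation", "analytic"] = "permutation",
) -> AccumulationCurve:
    """Expected richness vs number of pooled samples (rows of ``cm``).

    The permutation method averages cumulative richness over random sample
    orderings and takes 2.5/97.5 percentiles as a 95% band; the analytic
    method evaluates the exact hypergeometric expectation (no band).
    """
    inc = (cm.df.values > 0)
    m, _ = inc.shape
    if m < 1:
        raise ParameterError("need at least one sample")
    k = inc.sum(axis=0)          # per-taxon sample counts
    k = k[k > 0]
    s_obs = k.size
    h = np.arange(1, m + 1)

    if method == "analytic":
        # E[S_h] = S_obs - sum_i C(m-k_i, h)/C(m, h)
        miss = special.comb(m - k[:, None], h[None, :]) / special.comb(m, h)
        mean = s_obs - miss.sum(axis=0)
        return AccumulationCurve(h, mean, mean.copy(), mean.copy(), "analytic")

    if n_permutations < 2:
        raise ParameterError("permutation method needs n_permutations >= 2")
    rng = np.random.default_rng() if rng is None else rng
    present = inc[:, inc.any(axis=0)]
    rich = np.empty((n_permutations, m), dtype=np.int64)
    ranks = np.empty(m, dtype=np.int64)
    for p in range(n_permutations):
        order = rng.permutation(m)
        ranks[order] = np.arange(m)
        first = np.min(np.where(present, ranks[:, None], m), axis=0)
        rich[p] = np.cumsum(np.bincount(first, minlength=m + 1)[:m])
    mean = rich.mean(axis=0)
    lo = np.percentile(rich, 2.5, axis=0)
    hi = np.percentile(rich, 97.5, axis=0)
    mc_se = rich.std(axis=0, ddof=1) / np.sqrt(n_permutations)
    return AccumulationCurve(h, mean, lo, hi, "permutation", mc_se)


# ---------------------------------------------------------------------------
# first-order jackknife
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JackknifeEstimate:
    s_obs: int
    f1: int
    m: int
    estimate: float
    se: float


def jackknife1(cm: CommunityMatrix) -> JackknifeEstimate:
    """First-order jackknife richness estimate with Heltshe-Forrester SE.

    ``estimate = S_obs + f1 (m-1)/m``;
    ``var = ((m-1)/m) (sum_s r_s^2 - f1^2/m)`` where ``r_s`` is the number
    of uniques (taxa with k_i = 1) found in sample ``s``.
    """
    inc = cm.df.values > 0
    m = inc.shape[0]
    if m < 2:
        raise ParameterError("jackknife needs at least 2 samples")
    k = inc.sum(axis=0)
    s_obs = int((k > 0).sum())
    unique_taxa = k == 1
    f1 = int(unique_taxa.sum())
    estimate = s_obs + f1 * (m - 1) / m
    r_s = inc[:, unique_taxa].sum(axis=1)  # uniques per sample
    var = (m - 1) / m * (float((r_s ** 2).sum()) - f1 ** 2 / m)
    return JackknifeEstimate(s_obs, f1, m, float(estimate), float(np.sqrt(max(var, 0.0))))


# ---------------------------------------------------------------------------
# richness and density
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RichnessDensity:
    transect_richness: pd.Series   # taxa per transect
    trap_richness: pd.Series       # taxa per trap
    transect_density: pd.Series    # mean taxa per trap, by transect


def richness_and_density(
    cm_trap: CommunityMatrix,
    cm_transect: CommunityMatrix,
    trap_to_transect: Mapping[str, str],
) -> RichnessDensity:
    """Per-transect richness and per-trap density (mean taxa per trap).

    Traps present in ``trap_to_transect`` but absent from ``cm_trap``
    (empty traps) count as zero-taxon traps, not missing data.
    """
    transects = list(cm_transect.df.index)
    traps_of: dict[str, list[str]] = {t: [] for t in transects}
    for trap, tr in trap_to_transect.items():
        traps_of.setdefault(tr, []).append(trap)
    empty = [t for t in transects if not traps_of.get(t)]
    if empty:
        raise ConsistencyError(f"transect(s) with zero traps: {empty}")

    richness = (cm_transect.df > 0).sum(axis=1).astype(int)
    richness.name = "richness"
    trap_counts = (cm_trap.df > 0).sum(axis=1).astype(int)
    trap_counts = trap_counts.reindex(sorted(trap_to_transect), fill_value=0)
    trap_counts.name = "richness"
    density = pd.Series(
        {t: float(trap_counts.loc[traps_of[t]].mean()) for t in transects},
        name="density",
    )
    return RichnessDensity(richness, trap_counts, density)


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    kind: Literal["paired", "welch"]
    t: float
    df: float
    p: float
    mean_difference: float | None = None
    group_means: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        out = {"kind": self.kind, "t": self.t, "df": self.df, "p": self.p}
        if self.mean_difference is not None:
            out["mean_difference"] = self.mean_difference
        if self.group_means is not None:
            out["group_means"] = list(self.group_means)
        return out


def paired_t(x, y) -> TTestResult:
    """Two-sided paired t-test of per-unit values from two methods."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ParameterError("paired_t needs two equal-length vectors, n >= 2")
    diff = x - y
    md = float(diff.mean())
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.isclose(md, 0.0):
            return TTestResult("paired", 0.0, float(x.size - 1), 1.0, md)
        warnings.warn("zero variance of differences with nonzero mean; p = 0")
        return TTestResult(
            "paired", float(np.sign(md) * np.inf), float(x.size - 1), 0.0, md
        )
    res = stats.ttest_rel(x, y)
    return TTestResult(
        "paired", float(res.statistic), float(x.size - 1), float(res.pvalue), md
    )


def welch_t(a, b) -> TTestResult:
    """Two-sided Welch two-sample t-test (Welch-Satterthwaite df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("welch_t needs >= 2 values per group")
    gm = (float(a.mean()), float(b.mean()))
    if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
        df = float(a.size + b.size - 2)
        if np.isclose(gm[0], gm[1]):
            return TTestResult("welch", 0.0, df, 1.0, group_means=gm)
        warnings.warn("both groups have zero variance, unequal means; p = 0")
        return TTestResult(
            "welch", float(np.sign(gm[0] - gm[1]) * np.inf), df, 0.0, group_means=gm
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    df = float(res.df) if hasattr(res, "df") else float("nan")
    return TTestResult(
        "welch", float(res.statistic), df, float(res.pvalue), group_means=gm
    )
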