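"""Bray-Curtis, Mantel, correspondence analysis/DCA, habitat factor fit."""

import itertools

import numpy as np
import pandas as pd
import pytest

from motudiv import (
    CommunityMatrix,
    DissimilarityMatrix,
    bray_curtis,
    dca,
    fit_factor,
    mantel,
)
from motudiv.errors import (
    ConsistencyError,
    DegenerateInputError,
    ParameterError,
    UndefinedDistanceError,
)

from conftest import brute_force_mantel, random_dissim, reciprocal_averaging


def cm_from(rows, units=None, taxa=None, mode="abundance"):
    rows = np.asarray(rows)
    units = units or [f"u{i}" for i in range(rows.shape[0])]
    taxa = taxa or [f"t{j}" for j in range(rows.shape[1])]
    return CommunityMatrix(pd.DataFrame(rows, index=units, columns=taxa), mode=mode)


def random_cm(rng, m, s):
    X = rng.poisson(3.0, size=(m, s))
    X[:, X.sum(axis=0) == 0] += 1
    X[X.sum(axis=1) == 0, 0] += 1
    return cm_from(X)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis(cm_from([[1, 2, 3], [1, 2, 3]]))
        assert d.matrix[0, 1] == pytest.approx(0.0)

    def test_disjoint_rows_one(self):
        d = bray_curtis(cm_from([[3, 0, 1], [0, 2, 0]]))
        assert d.matrix[0, 1] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # x=(1,2,0), y=(0,2,2): (1+0+2)/(1+4+2) = 3/7
        d = bray_curtis(cm_from([[1, 2, 0], [0, 2, 2]]))
        assert d.matrix[0, 1] == pytest.approx(3 / 7)

    def test_column_order_invariance(self, rng):
        cm = random_cm(rng, 5, 12)
        shuffled = CommunityMatrix(cm.df.iloc[:, rng.permutation(12)])
        np.testing.assert_allclose(
            bray_curtis(cm).matrix, bray_curtis(shuffled).matrix
        )

    def test_bounds_symmetry_and_identity(self, rng):
        d = bray_curtis(random_cm(rng, 6, 10)).matrix
        assert np.all((d >= 0) & (d <= 1))
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0)

    def test_two_empty_units_rejected(self):
        with pytest.raises(UndefinedDistanceError):
            bray_curtis(cm_from([[0, 0], [0, 0], [1, 2]]))


class TestMantel:
    def test_identical_matrices_r1(self, rng):
        d = random_dissim(rng, 6)
        res = mantel(d, d)
        assert res.r == pytest.approx(1.0)
        assert res.method == "exhaustive"

    def test_exhaustive_n4_matches_brute_force(self, rng):
        for _ in range(5):
            dA, dB = random_dissim(rng, 4), random_dissim(rng, 4)
            res = mantel(dA, dB)
            r_ref, p_ref = brute_force_mantel(dA.matrix, dB.matrix)
            assert res.n_perm == 24
            assert res.r == pytest.approx(r_ref)
            assert res.p == pytest.approx(p_ref)

    def test_joint_relabeling_invariance(self, rng):
        dA, dB = random_dissim(rng, 6), random_dissim(rng, 6)
        perm = rng.permutation(6)
        ids = tuple(f"u{i}" for i in range(6))
        dA2 = DissimilarityMatrix(ids, dA.matrix[np.ix_(perm, perm)], "test")
        dB2 = DissimilarityMatrix(ids, dB.matrix[np.ix_(perm, perm)], "test")
        assert mantel(dA2, dB2).r == pytest.approx(mantel(dA, dB).r)

    def test_unit_mismatch_rejected(self, rng):
        dA = random_dissim(rng, 8)
        dB = DissimilarityMatrix(
            tuple(f"v{i}" for i in range(8)), dA.matrix, "test"
        )
        with pytest.raises(ConsistencyError):
            mantel(dA, dB)

    def test_null_p_values_roughly_uniform(self, rng):
        """Independent matrices: P(p <= a) ~ a (smaller replicate of the
        large calibration run in the acceptance suite)."""
        n_rep = 150
        ps = []
        for _ in range(n_rep):
            res = mantel(random_dissim(rng, 12), random_dissim(rng, 12),
                         n_perm=199, rng=rng)
            ps.append(res.p)
        ps = np.asarray(ps)
        for a in (0.1, 0.5):
            se = np.sqrt(a * (1 - a) / n_rep)
            assert abs((ps <= a).mean() - a) <= 4 * se


class TestCorrespondenceAnalysis:
    def test_axis1_matches_reciprocal_averaging(self, rng):
        cm = random_cm(rng, 6, 30)
        res = dca(cm)
        x_ra, ev = reciprocal_averaging(cm.df.values)
        ax1 = res.site_scores["axis1"].values
        w = res.row_weights.values
        x_ca = ax1 - (w * ax1).sum() / w.sum()
        x_ca = x_ca / np.sqrt((w / w.sum() * x_ca ** 2).sum())
        agreement = min(
            np.max(np.abs(x_ca - x_ra)), np.max(np.abs(x_ca + x_ra))
        )
        assert agreement < 1e-8
        # the two-step reciprocal-averaging operator shrinks by the CA
        # eigenvalue itself (sigma^2) per iteration
        assert res.eigenvalues[0] == pytest.approx(ev, abs=1e-9)

    def test_block_structure_gives_unit_eigenvalue(self):
        cm = cm_from([
            [3, 1, 2, 0, 0, 0],
            [1, 2, 2, 0, 0, 0],
            [2, 2, 1, 0, 0, 0],
            [0, 0, 0, 1, 3, 2],
            [0, 0, 0, 2, 1, 1],
        ])
        res = dca(cm)
        assert res.eigenvalues[0] == pytest.approx(1.0)
        ax1 = res.site_scores["axis1"].values
        assert len({np.sign(v) for v in ax1[:3]}) == 1
        assert np.sign(ax1[0]) != np.sign(ax1[3])

    def test_detrending_leaves_axis1_untouched(self, rng):
        cm = random_cm(rng, 8, 20)
        few = dca(cm, n_segments=2)
        many = dca(cm, n_segments=26)
        np.testing.assert_allclose(
            few.site_scores["axis1"], many.site_scores["axis1"]
        )
        assert not np.allclose(
            few.site_scores["axis2"], many.site_scores["axis2"]
        )

    def test_axis1_zero_weighted_mean(self, rng):
        res = dca(random_cm(rng, 7, 15))
        w = res.row_weights.values
        assert (w * res.site_scores["axis1"].values).sum() == pytest.approx(0, abs=1e-12)

    def test_zero_rows_dropped_with_warning(self):
        cm = cm_from([[1, 2, 0], [0, 0, 0], [2, 1, 0], [1, 1, 0], [3, 0, 0]])
        with pytest.warns(UserWarning, match="dropping"):
            res = dca(cm)
        assert "u1" not in res.site_scores.index
        assert "t2" not in res.taxon_scores.index

    def test_too_few_units_rejected(self):
        with pytest.raises(DegenerateInputError):
            dca(cm_from([[1, 2], [2, 1]]))


def brute_force_fit(scores, labels):
    """Exhaustive label-arrangement enumeration for the factor-fit p-value."""
    X = np.asarray(scores, dtype=float)

    def r2(lab):
        lab = np.asarray(lab)
        centre = X.mean(axis=0)
        sst = ((X - centre) ** 2).sum()
        ssw = sum(
            ((X[lab == g] - X[lab == g].mean(axis=0)) ** 2).sum()
            for g in set(lab.tolist())
        )
        return 1 - ssw / sst

    obs = r2(labels)
    arrangements = sorted(set(itertools.permutations(labels)))
    hits = sum(r2(np.array(a)) >= obs - 1e-12 for a in arrangements)
    return obs, hits / len(arrangements)


class TestFactorFit:
    def test_perfect_separation_r2_one(self):
        scores = pd.DataFrame(
            {"axis1": [0.0, 0.0, 5.0, 5.0], "axis2": [1.0, 1.0, -1.0, -1.0]},
            index=list("abcd"),
        )
        res = fit_factor(scores, ["g1", "g1", "g2", "g2"])
        assert res.r_squared == pytest.approx(1.0)

    def test_exhaustive_matches_brute_force(self, rng):
        scores = pd.DataFrame(
            rng.normal(size=(6, 2)), columns=["axis1", "axis2"],
            index=[f"u{i}" for i in range(6)],
        )
        labels = ["a", "a", "a", "b", "b", "b"]
        res = fit_factor(scores, labels)
        obs, p_ref = brute_force_fit(scores, labels)
        assert res.method == "exhaustive"
        assert res.n_perm == 20
        assert res.r_squared == pytest.approx(obs)
        assert res.p == pytest.approx(p_ref)

    def test_null_mean_r2_matches_expectation(self, rng):
        """Random labels: E[r^2] = (g-1)/(n-1) under the permutation null."""
        from motudiv.community import _r2

        scores = pd.DataFrame(
            rng.normal(size=(12, 2)), columns=["axis1", "axis2"]
        )
        vals = [
            _r2(scores.values, rng.permutation([0] * 6 + [1] * 6), 2)
            for _ in range(600)
        ]
        expect = (2 - 1) / (12 - 1)
        assert np.mean(vals) == pytest.approx(expect, abs=3 * np.std(vals) / np.sqrt(600))

    def test_single_group_rejected(self, rng):
        scores = pd.DataFrame(rng.normal(size=(4, 2)), columns=["axis1", "axis2"])
        with pytest.raises(ParameterError):
            fit_factor(scores, ["g"] * 4)

    def test_centroids_reported_per_group(self, rng):
        scores = pd.DataFrame(
            {"axis1": [0.0, 1.0, 10.0, 11.0], "axis2": [0.0] * 4}
        )
        res = fit_factor(scores, ["a", "a", "b", "b"])
        assert res.centroids.loc["a", "axis1"] == pytest.approx(0.5)
        assert res.centroids.loc["b", "axis1"] == pytest.approx(10.5)
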