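"""Accumulation curves, jackknife richness, richness/density tables, t-tests."""

import warnings

import numpy as np
import pandas as pd
import pytest

from motudiv import (
    CommunityMatrix,
    accumulation_curve,
    build_community_matrix,
    jackknife1,
    paired_t,
    richness_and_density,
    simulate,
    welch_t,
    SimConfig,
)
from motudiv.errors import ConsistencyError, ParameterError

from conftest import make_specimens, random_incidence


class TestAccumulationCurve:
    def test_single_sample_is_a_point(self, rng):
        cm = CommunityMatrix(
            pd.DataFrame([[1] * 7], index=["u0"], columns=[f"t{j}" for j in range(7)])
        )
        for method in ("permutation", "analytic"):
            c = accumulation_curve(cm, n_permutations=10, rng=rng, method=method)
            assert list(c.h) == [1]
            assert c.mean_richness[0] == pytest.approx(7.0)

    def test_ubiquitous_taxon_always_counts(self, rng):
        # taxon present in all m samples contributes 1 at every h
        m = 6
        df = pd.DataFrame(0, index=[f"u{i}" for i in range(m)],
                          columns=["everywhere", "once"])
        df["everywhere"] = 1
        df.loc["u0", "once"] = 1
        c = accumulation_curve(CommunityMatrix(df), method="analytic")
        contribution = c.mean_richness - (1 - (m - np.arange(1, m + 1)) / m)
        np.testing.assert_allclose(contribution, np.ones(m))

    def test_permutation_matches_analytic_within_mc_error(self, rng):
        cm = random_incidence(rng, 10, 15)
        perm = accumulation_curve(cm, n_permutations=2000, rng=rng)
        exact = accumulation_curve(cm, method="analytic")
        tol = 3 * np.maximum(perm.mc_se, 1e-12)
        assert np.all(np.abs(perm.mean_richness - exact.mean_richness) <= tol)

    def test_both_methods_hit_s_obs_at_full_pooling(self, rng):
        cm = random_incidence(rng, 8, 20)
        s_obs = int((cm.df.sum(axis=0) > 0).sum())
        perm = accumulation_curve(cm, n_permutations=50, rng=rng)
        exact = accumulation_curve(cm, method="analytic")
        assert perm.mean_richness[-1] == pytest.approx(s_obs)
        assert exact.mean_richness[-1] == pytest.approx(s_obs)
        assert np.all(np.diff(perm.mean_richness) >= 0)
        assert np.all(perm.ci_low <= perm.mean_richness + 1e-12)
        assert np.all(perm.mean_richness <= perm.ci_high + 1e-12)

    def test_too_few_permutations_rejected(self, rng):
        cm = random_incidence(rng, 4, 5)
        with pytest.raises(ParameterError):
            accumulation_curve(cm, n_permutations=1, rng=rng)


class TestJackknife:
    def test_no_uniques_estimate_equals_observed(self):
        df = pd.DataFrame([[1, 1], [1, 1], [0, 1]],
                          index=list("abc"), columns=["t1", "t2"])
        est = jackknife1(CommunityMatrix(df))
        assert est.f1 == 0
        assert est.estimate == est.s_obs == 2
        assert est.se == 0.0

    def test_worked_example(self):
        # m=5 samples, S_obs=10, f1=4 -> 10 + 4*(4/5) = 13.2
        m, s = 5, 10
        df = pd.DataFrame(0, index=[f"u{i}" for i in range(m)],
                          columns=[f"t{j}" for j in range(s)])
        df.iloc[:, :6] = 1          # six taxa in every sample
        for j in range(6, 10):      # four uniques
            df.iloc[j % m, j] = 1
        est = jackknife1(CommunityMatrix(df))
        assert (est.s_obs, est.f1, est.m) == (10, 4, 5)
        assert est.estimate == pytest.approx(13.2)

    def test_closed_form_equals_pseudovalue_mean(self, rng):
        """Estimate equals the delete-one-sample jackknife pseudovalue mean."""
        for _ in range(30):
            m = int(rng.integers(3, 12))
            cm = random_incidence(rng, m, int(rng.integers(5, 25)))
            inc = cm.df.values > 0
            s_obs = int((inc.sum(axis=0) > 0).sum())
            pseudo = [
                m * s_obs - (m - 1) * int(
                    (np.delete(inc, i, axis=0).sum(axis=0) > 0).sum()
                )
                for i in range(m)
            ]
            est = jackknife1(cm)
            assert est.estimate == pytest.approx(np.mean(pseudo))
            assert est.estimate >= est.s_obs

    def test_relabeling_invariance(self, rng):
        cm = random_incidence(rng, 8, 15)
        est = jackknife1(cm)
        perm = rng.permutation(8)
        shuffled = CommunityMatrix(cm.df.iloc[perm], mode="incidence")
        est2 = jackknife1(shuffled)
        assert est2.estimate == pytest.approx(est.estimate)
        assert est2.se == pytest.approx(est.se)

    def test_single_sample_rejected(self):
        df = pd.DataFrame([[1]], index=["u"], columns=["t"])
        with pytest.raises(ParameterError):
            jackknife1(CommunityMatrix(df))


class TestRichnessDensity:
    def test_hand_enumeration(self):
        # one transect, traps with 2 and 4 disjoint taxa -> richness 6, density 3
        t = make_specimens(
            [(f"I{i}", "A", "T1", "primary", f"M{i}", f"Q{i}") for i in range(2)]
            + [(f"J{i}", "B", "T1", "primary", f"N{i}", f"R{i}") for i in range(4)]
        )
        cm_trap = build_community_matrix(t, unit_level="trap")
        cm_tr = build_community_matrix(t, unit_level="transect")
        rd = richness_and_density(cm_trap, cm_tr, t.trap_to_transect())
        assert rd.transect_richness["T1"] == 6
        assert rd.transect_density["T1"] == pytest.approx(3.0)

    def test_duplicate_taxa_counted_once(self):
        t = make_specimens([
            ("I1", "A", "T1", "primary", "M1", "Q1"),
            ("I2", "B", "T1", "primary", "M1", "Q2"),
        ])
        cm_trap = build_community_matrix(t, unit_level="trap")
        cm_tr = build_community_matrix(t, unit_level="transect")
        rd = richness_and_density(cm_trap, cm_tr, t.trap_to_transect())
        assert rd.transect_richness["T1"] == 1
        assert rd.transect_density["T1"] == pytest.approx(1.0)

    def test_empty_trap_counts_as_zero(self):
        t = make_specimens([("I1", "A", "T1", "primary", "M1", "Q1")])
        cm_trap = build_community_matrix(t, unit_level="trap")
        cm_tr = build_community_matrix(t, unit_level="transect")
        rd = richness_and_density(
            cm_trap, cm_tr, {"A": "T1", "B": "T1"}  # trap B deployed, empty
        )
        assert rd.trap_richness["B"] == 0
        assert rd.transect_density["T1"] == pytest.approx(0.5)

    def test_transect_without_traps_rejected(self):
        t = make_specimens([("I1", "A", "T1", "primary", "M1", "Q1")])
        cm_trap = build_community_matrix(t, unit_level="trap")
        cm_tr = build_community_matrix(t, unit_level="transect")
        with pytest.raises(ConsistencyError):
            richness_and_density(cm_trap, cm_tr, {"A": "T9"})


class TestTTests:
    # reference statistics computed independently in R (t.test, 15 digits)
    def test_paired_matches_r_reference(self):
        res = paired_t([12, 15, 11, 14, 13, 16], [10, 14, 12, 13, 11, 15])
        assert res.t == pytest.approx(2.23606797749979, rel=1e-12)
        assert res.df == 5
        assert res.p == pytest.approx(0.0755868184216124, rel=1e-12)
        assert res.mean_difference == pytest.approx(1.0)

    def test_welch_matches_r_reference(self):
        res = welch_t([44, 39, 51, 42, 47, 40], [36, 50, 41, 44, 38, 49])
        assert res.t == pytest.approx(0.279421191704418, rel=1e-12)
        assert res.df == pytest.approx(9.50076170637053, rel=1e-12)
        assert res.p == pytest.approx(0.785909648707903, rel=1e-12)

    def test_identical_inputs_give_t0_p1(self):
        x = [3.0, 4.0, 5.0]
        assert paired_t(x, x).p == 1.0
        assert paired_t(x, x).t == 0.0
        res = welch_t([2.0, 2.0, 2.0], [2.0, 2.0])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_constant_nonzero_difference_warns_p0(self):
        with pytest.warns(UserWarning, match="zero variance"):
            res = paired_t([2, 3, 4, 5, 6, 7], [1, 2, 3, 4, 5, 6])
        assert res.p == 0.0

    def test_length_validation(self):
        with pytest.raises(ParameterError):
            paired_t([1, 2], [1, 2, 3])
        with pytest.raises(ParameterError):
            welch_t([1.0], [1.0, 2.0])


class TestWelchNullCalibration:
    def test_calibrated_where_t_assumptions_hold(self, rng):
        """On normal data with group sizes large enough for the
        Welch-Satterthwaite approximation (n = 15 per group), the type-I
        error at alpha = 0.05 is nominal within 3 binomial SE."""
        alpha = 0.05
        n_rep = 4000
        a = rng.normal(size=(n_rep, 15))
        b = rng.normal(scale=2.0, size=(n_rep, 15))  # unequal variances
        rate = np.mean([welch_t(a[i], b[i]).p <= alpha for i in range(n_rep)])
        band = 3 * np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) <= band, f"rejection rate {rate}"

    def test_bounded_type_i_error_on_null_surveys(self):
        """No habitat effect: Welch on per-transect richness must not reject
        spuriously far beyond its small-sample behaviour.

        With 3 transects per habitat the t-approximation on discrete
        richness is only approximate (mildly anti-conservative); a correct
        pipeline stays well below twice the nominal level plus Monte-Carlo
        error, while a broken test statistic would not.  1,000 independent
        surveys at the study scale.
        """
        alpha = 0.05
        n_rep = 1000
        rejections = 0
        for seed in range(n_rep):
            cfg = SimConfig(
                n_species=100, seed=10_000 + seed,
                habitat_specialist_fraction=0.0,
                intraspecific_variant_rate=0.0, failure_rate=0.0,
            )
            table, _, _ = simulate(cfg)
            cm_tr = build_community_matrix(table, unit_level="transect")
            rich = (cm_tr.df > 0).sum(axis=1)
            hab = rich.index.map(table.transect_to_habitat())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = welch_t(rich[hab == "primary"], rich[hab == "secondary"])
            rejections += res.p <= alpha
        rate = rejections / n_rep
        band = 3 * np.sqrt(alpha * (1 - alpha) / n_rep)
        assert rate <= 2 * alpha + band, f"rejection rate {rate}"
        assert rate >= alpha / 5, f"implausibly conservative rate {rate}"
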