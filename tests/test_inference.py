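"""Time-course statistics: FDR, clusters, permutation, Bayes factors, score models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pupilpca as pp
from pupilpca.inference import ScoreModel, jzs_bf10

from conftest import make_long_recording


# ---------------------------------------------------------------------------
# BH-FDR
# ---------------------------------------------------------------------------

class TestFdrAdjust:
    def test_closed_form_case(self):
        # m = 4: adjusted p_(i) = min_k>=i (m/k) p_(k), all equal 0.04 here
        out = pp.fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert pp.fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_equal_unchanged(self):
        out = pp.fdr_adjust([0.2, 0.2, 0.2])
        assert np.allclose(out, 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pp.fdr_adjust([0.5, 1.5])

    def test_nan_passthrough(self):
        out = pp.fdr_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], pp.fdr_adjust([0.01, 0.04]))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_never_below_raw_and_monotone(self, ps):
        p = np.asarray(ps)
        adj = pp.fdr_adjust(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

class TestFindClusters:
    def test_empty(self):
        assert pp.find_clusters([False, False], [0.0, 10.0]) == []

    def test_single_span_on_10ms_grid(self):
        times = np.arange(0.0, 4500.0, 10.0)
        flags = (times >= 440) & (times <= 4490)
        out = pp.find_clusters(flags, times)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (440.0, 4490.0)

    def test_two_runs_in_temporal_order(self):
        times = np.arange(6) * 10.0
        flags = [True, True, False, False, True, False]
        out = pp.find_clusters(flags, times)
        assert [(c.start, c.end) for c in out] == [(0.0, 10.0), (40.0, 40.0)]

    def test_mass_is_sum_of_abs_statistics(self):
        out = pp.find_clusters([True, True, False], [0.0, 10.0, 20.0],
                               statistics=[-2.0, 3.0, 9.0])
        assert out[0].mass == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# per-timepoint LMM
# ---------------------------------------------------------------------------

class TestTimecourseLMM:
    def test_detects_effect_and_builds_cluster(self):
        rng = np.random.default_rng(42)
        rec = make_long_recording(rng, n_subjects=10, trials=16, n_times=8,
                                  beta=0.25, effect_window=(20.0, 60.0))
        res = pp.TimecourseLMM(rec, "Luminance", adjust="fdr").fit()
        tab = res.table
        inside = tab[(tab.time >= 20) & (tab.time < 60)]
        outside = tab[(tab.time < 20) | (tab.time >= 60)]
        assert inside.flag.all()
        assert inside.p.max() < outside.p.min()
        assert any(c.start == 20.0 for c in res.clusters)

    def test_adjusted_p_not_below_raw(self):
        rng = np.random.default_rng(1)
        rec = make_long_recording(rng, n_times=6, beta=0.1)
        res = pp.TimecourseLMM(rec, "Luminance").fit()
        assert np.all(res.table.p_adj >= res.table.p - 1e-12)

    def test_constant_condition_rejected(self):
        rng = np.random.default_rng(2)
        rec = make_long_recording(rng, n_times=2, n_levels=1)
        with pytest.raises(ValueError):
            pp.TimecourseLMM(rec, "Luminance").fit()

    def test_effect_power_in_confined_window(self):
        """A simulated effect confined to a window is found by a cluster
        overlapping that window in nearly every replicate (scaled-down
        power check)."""
        rng = np.random.default_rng(3)
        hits = 0
        n_rep = 15
        for _ in range(n_rep):
            rec = make_long_recording(rng, n_subjects=10, trials=16, n_times=10,
                                      beta=0.22, effect_window=(30.0, 70.0))
            res = pp.TimecourseLMM(rec, "Luminance").fit()
            hits += any(c.start < 70.0 and c.end >= 30.0 for c in res.clusters)
        assert hits >= 0.9 * n_rep


# ---------------------------------------------------------------------------
# cluster permutation
# ---------------------------------------------------------------------------

class TestClusterPermutation:
    def test_add_one_minimum_p(self):
        rng = np.random.default_rng(5)
        rec = make_long_recording(rng, n_subjects=10, trials=16, n_times=6,
                                  beta=0.6, noise_sd=0.3)
        res = pp.ClusterPermutation(rec, "Luminance", n_perm=999, seed=1).fit()
        assert min(c.p for c in res.clusters) == pytest.approx(1.0 / 1000.0)

    def test_seed_reproducibility_bitwise(self):
        rng = np.random.default_rng(6)
        rec = make_long_recording(rng, n_subjects=8, trials=12, n_times=6, beta=0.2)
        r1 = pp.ClusterPermutation(rec, "Luminance", n_perm=300, seed=7).fit()
        r2 = pp.ClusterPermutation(rec, "Luminance", n_perm=300, seed=7).fit()
        assert [c.p for c in r1.clusters] == [c.p for c in r2.clusters]
        assert np.array_equal(r1.notes["null_max"], r2.notes["null_max"])

    def test_small_n_perm_warns(self):
        rng = np.random.default_rng(8)
        rec = make_long_recording(rng, n_times=2, beta=0.2)
        with pytest.warns(UserWarning, match="n_perm"):
            pp.ClusterPermutation(rec, "Luminance", n_perm=50, seed=0)

    def test_no_within_subject_variation_rejected(self):
        rng = np.random.default_rng(9)
        rec = make_long_recording(rng, n_times=2)
        df = rec.data.copy()
        df["Luminance"] = df["subject"].astype("category").cat.codes * 1.0
        rec2 = pp.Recording(df, conditions=["Luminance"])
        with pytest.raises(ValueError, match="permute"):
            pp.ClusterPermutation(rec2, "Luminance", n_perm=200, seed=0).fit()

    def test_power_for_confined_effect(self):
        rng = np.random.default_rng(10)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            rec = make_long_recording(rng, n_subjects=10, trials=16, n_times=10,
                                      beta=0.22, effect_window=(30.0, 70.0))
            res = pp.ClusterPermutation(rec, "Luminance", n_perm=500,
                                        seed=int(rng.integers(2**31))).fit()
            sig = [c for c in res.clusters if c.p is not None and c.p < 0.05]
            hits += any(c.start < 70.0 and c.end >= 30.0 for c in sig)
        assert hits >= 0.9 * n_rep


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------

def _dense_quadrature_bf(t, n_eff, df, r):
    """Independent oracle: trapezoid integration of the scale-mixture
    marginal on a dense log-grid."""
    u = np.linspace(-40.0, 40.0, 40001)
    g = np.exp(u)
    c = 1.0 + n_eff * g
    prior = np.sqrt(r**2 / (2 * np.pi)) * g**-1.5 * np.exp(-r**2 / (2 * g))
    like = c**-0.5 * (1 + t**2 / (c * df)) ** (-(df + 1) / 2)
    num = np.trapezoid(prior * like * g, u)
    den = (1 + t**2 / df) ** (-(df + 1) / 2)
    return num / den


class TestJzsBayesFactor:
    @pytest.mark.parametrize("t,n,df", [(0.0, 40, 38), (2.1, 40, 38),
                                        (3.7, 24, 22), (-2.5, 60, 57),
                                        (8.0, 100, 97)])
    def test_matches_dense_quadrature_oracle(self, t, n, df):
        r = pp.inference.DEFAULT_PRIOR_SCALE
        assert jzs_bf10(t, n, df, r) == pytest.approx(
            _dense_quadrature_bf(t, n, df, r), rel=0.01)

    def test_matches_pingouin_two_sample_convention(self):
        """For a balanced two-group design, the standardized-slope prior with
        scale r * sd(x) reproduces the canonical two-sample JZS Bayes factor
        (independent implementation in pingouin)."""
        pingouin = pytest.importorskip("pingouin")
        from scipy import stats as sps
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 24)
        y = rng.normal(0.5, 1, 24)
        t, _ = sps.ttest_ind(x, y)
        bf_ref = float(pingouin.bayesfactor_ttest(t, nx=24, ny=24, r=0.707))
        bf_me = jzs_bf10(t, n_eff=48, df=46, r=0.707 * 0.5)
        assert bf_me == pytest.approx(bf_ref, rel=1e-6)

    def test_large_n_null_favours_the_null(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 200)
        y = rng.normal(0, 1, 200)
        from scipy import stats as sps
        t, _ = sps.ttest_ind(x, y)
        bf = jzs_bf10(t, n_eff=400, df=398, r=pp.inference.DEFAULT_PRIOR_SCALE * 0.5)
        assert bf < 1.0

    def test_timecourse_flags_and_default_prior(self):
        rng = np.random.default_rng(12)
        rec = make_long_recording(rng, n_subjects=10, trials=16, n_times=6,
                                  beta=0.3, effect_window=(0.0, 30.0))
        res = pp.BayesFactorTimecourse(rec, "Luminance").fit()
        assert res.notes["prior_scale"] == pytest.approx(np.sqrt(2) / 2)
        tab = res.table
        assert tab[tab.time < 30].bf10.min() > 3.0
        assert (tab[tab.time >= 30].bf10 < tab[tab.time < 30].bf10.min()).all()

    def test_bf_evidence_is_subset_of_raw_significance(self):
        """Timepoints with BF10 > 3 also reach p < 0.05 unadjusted on the
        standard fixture battery."""
        rng = np.random.default_rng(13)
        for beta in (0.0, 0.1, 0.25):
            rec = make_long_recording(rng, n_subjects=10, trials=16, n_times=8,
                                      beta=beta)
            res = pp.BayesFactorTimecourse(rec, "Luminance").fit()
            tab = res.table
            assert ((tab.bf10 > 3) <= (tab.p < 0.05)).all()


# ---------------------------------------------------------------------------
# score-level models
# ---------------------------------------------------------------------------

class TestScoreModel:
    def _scores(self, rng, beta, S=15, trials=20):
        subj = np.repeat(np.arange(S), trials)
        x = rng.integers(1, 9, S * trials).astype(float)
        y = 0.3 + beta * x + rng.normal(0, 0.4, S)[subj] + rng.normal(0, 0.6, S * trials)
        return pd.DataFrame({"subject": subj, "trial": np.tile(np.arange(trials), S),
                             "Luminance": x, "score_1": y})

    def test_recovers_generating_slope(self):
        rng = np.random.default_rng(21)
        res = ScoreModel(self._scores(rng, beta=0.15), "Luminance").fit()
        row = res.effects().iloc[0]
        assert row["estimate"] == pytest.approx(0.15, abs=3 * row["se"])
        assert row["p"] < 0.001

    def test_summary_layout(self):
        rng = np.random.default_rng(22)
        df = self._scores(rng, beta=0.1)
        df["score_2"] = df["score_1"] * 0.5 + rng.normal(0, 0.3, len(df))
        res = ScoreModel(df, "Luminance").fit()
        assert set(res.table.component) == {"score_1", "score_2"}
        assert {"estimate", "se", "z", "p", "ci_low", "ci_high"} <= set(res.table.columns)

    def test_requires_subject_and_condition_columns(self):
        df = pd.DataFrame({"score_1": [1.0, 2.0], "Luminance": [1, 2]})
        with pytest.raises(KeyError):
            ScoreModel(df, "Luminance")

    def test_third_rotated_component_separates_luminance(self, default_rpca):
        """On the simulated luminance experiment, every rotated component —
        including the late sympathetic one — carries a detectable luminance
        effect in the score-level mixed model."""
        table = default_rpca.scores_table(add=["Luminance"])
        res = ScoreModel(table, "Luminance").fit()
        eff = res.effects().set_index("component")
        assert eff.loc["score_3", "p"] < 0.05
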