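"""Group statistics: Bonferroni, per-ROI GLMs, post-hocs, LMM, RSQ ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from drowsebold import stats
from drowsebold.io import default_atlas
from drowsebold.simulate import simulate_null_psd_table
from drowsebold.states import STATE_NAMES


class TestBonferroni:
    @pytest.mark.parametrize("m,expected", [
        (164, 0.05 / 164),   # prints as p < 0.0003
        (984, 0.05 / 984),   # prints as p < 0.00005
        (1, 0.05),
    ])
    def test_threshold_values(self, m, expected):
        assert stats.bonferroni_alpha(0.05, m) == pytest.approx(expected)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            stats.bonferroni_alpha(0.05, 0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(m1=st.integers(1, 500), m2=st.integers(1, 500))
    def test_multiplicativity(self, m1, m2):
        assert stats.bonferroni_alpha(0.05, m1 * m2) == pytest.approx(
            stats.bonferroni_alpha(stats.bonferroni_alpha(0.05, m1), m2))


class TestCohensD:
    def test_unit_difference_unit_sd(self, rng):
        a = rng.normal(1.0, 1.0, 100_000)
        b = rng.normal(0.0, 1.0, 100_000)
        assert stats.cohens_d(a, b) == pytest.approx(1.0, abs=0.02)

    def test_identical_samples_zero(self):
        x = np.arange(10.0)
        assert stats.cohens_d(x, x) == 0.0

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=(2, 40))
        assert stats.cohens_d(a, b) == pytest.approx(-stats.cohens_d(b, a))


def _table_from_matrix(values, states=STATE_NAMES, roi="roi-001"):
    """values: (n_participants, n_states) -> long psd table."""
    recs = []
    for p, row in enumerate(values):
        for s, v in zip(states, row):
            recs.append((f"sub-{p:03d}", roi, s, v))
    return pd.DataFrame(recs, columns=["participant", "roi", "state", "psd005"])


class TestRoiGlm:
    def test_matches_two_sample_t_test_on_balanced_data(self, rng):
        tab = _table_from_matrix(rng.normal(size=(30, 2)),
                                 states=("awake", "drowsy"))
        res = stats.roi_glm(tab, "roi-001")
        a = tab.loc[tab.state == "awake", "psd005"]
        b = tab.loc[tab.state == "drowsy", "psd005"]
        t, p = sps.ttest_ind(a, b)
        assert res.p_value == pytest.approx(p, abs=1e-12)
        assert res.wald_chi2 == pytest.approx(t**2, rel=1e-10)

    def test_state_invariant_response_gives_null_result(self, rng):
        base = rng.normal(size=20)
        tab = _table_from_matrix(np.tile(base[:, None], (1, 4)))
        res = stats.roi_glm(tab, "roi-001")
        assert res.wald_chi2 == pytest.approx(0.0, abs=1e-16)
        assert res.p_value > 0.99

    def test_single_state_rejected(self, rng):
        tab = _table_from_matrix(rng.normal(size=(10, 1)), states=("awake",))
        with pytest.raises(ValueError, match="2 states"):
            stats.roi_glm(tab, "roi-001")

    def test_zero_variance_rejected(self):
        tab = _table_from_matrix(np.ones((10, 4)))
        with pytest.raises(ValueError, match="zero-variance"):
            stats.roi_glm(tab, "roi-001")

    def test_gamma_family_runs(self, rng):
        tab = _table_from_matrix(rng.gamma(4.0, size=(25, 4)))
        res = stats.roi_glm(tab, "roi-001", family="gamma")
        assert res.df == 3 and 0 <= res.p_value <= 1

    def test_within_participant_variant_gains_power(self, rng):
        scale = np.exp(rng.normal(0, 0.8, size=(40, 1)))
        effect = np.array([0.0, 0.0, 0.6, 0.6])
        vals = scale * (1.0 + effect + rng.normal(0, 0.15, size=(40, 4)))
        tab = _table_from_matrix(vals)
        pooled = stats.roi_glm(tab, "roi-001")
        within = stats.roi_glm(tab, "roi-001", within_participant=True)
        assert within.p_value < pooled.p_value


class TestPairwisePosthoc:
    def test_full_scale_comparison_count(self, rng):
        atlas = default_atlas(164)
        recs = []
        for roi in atlas["roi_id"]:
            for p in range(10):
                for s in STATE_NAMES:
                    recs.append((f"sub-{p}", roi, s, rng.random()))
        tab = pd.DataFrame(recs, columns=["participant", "roi", "state",
                                          "psd005"])
        out = stats.pairwise_posthoc(tab)
        assert len(out) == 984
        assert out.attrs["m_tests"] == 984
        assert out.attrs["bonferroni_alpha"] == pytest.approx(0.05 / 984)

    def test_d_definition_means_one_apart(self, rng):
        a = rng.normal(0.0, 1.0, 5000)
        tab = _table_from_matrix(np.column_stack([a, a + 1.0]),
                                 states=("awake", "drowsy"))
        out = stats.pairwise_posthoc(tab)
        row = out.iloc[0]
        assert row["mean_diff"] == pytest.approx(1.0, abs=0.05)
        assert row["cohens_d"] == pytest.approx(1.0, abs=0.05)

    def test_identical_groups_give_zero_d(self):
        x = np.arange(12.0)
        tab = _table_from_matrix(np.column_stack([x, x]),
                                 states=("awake", "drowsy"))
        out = stats.pairwise_posthoc(tab)
        assert out.iloc[0]["cohens_d"] == 0.0

    def test_underpopulated_state_skipped_with_reason(self, rng):
        tab = _table_from_matrix(rng.normal(size=(10, 2)),
                                 states=("awake", "drowsy"))
        tab = pd.concat([tab, pd.DataFrame(
            [("sub-000", "roi-001", "microsleep", 1.0)],
            columns=tab.columns)], ignore_index=True)
        out = stats.pairwise_posthoc(tab)
        assert len(out) == 1
        assert any("microsleep" in (a, b)
                   for _, a, b, _ in out.attrs["skipped"])


class TestPerclosRegression:
    def test_exact_linear_relationship(self, rng):
        perc = {"a": rng.random(200)}
        psd = {"a": 2.0 * perc["a"]}
        res = stats.perclos_psd_regression(perc, psd)
        assert res["r2"] == pytest.approx(1.0)
        assert res["slope"] > 0

    def test_independent_noise_has_tiny_r2(self, rng):
        perc = {"a": rng.random(1000)}
        psd = {"a": rng.normal(size=1000)}
        assert stats.perclos_psd_regression(perc, psd)["r2"] < 0.01

    def test_constant_predictor_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            stats.perclos_psd_regression({"a": np.full(50, 0.1)},
                                         {"a": rng.normal(size=50)})


def _network_table(rng, n_participants=12, effect=0.0,
                   effect_networks=("visual",)):
    atlas = default_atlas(28)
    recs = []
    for p in range(n_participants):
        base = rng.normal(0, 0.5)
        for _, roi in atlas.iterrows():
            for j, s in enumerate(STATE_NAMES):
                v = base + rng.normal(0, 0.3)
                if roi["network"] in effect_networks and j >= 2:
                    v += effect
                recs.append((f"sub-{p:02d}", roi["roi_id"], roi["network"],
                             s, v))
    return pd.DataFrame(recs, columns=["participant", "roi", "network",
                                       "state", "psd005"])


class TestNetworkLmm:
    def test_posthoc_count_and_df_structure(self, rng):
        res = stats.network_lmm(_network_table(rng))
        assert len(res.posthoc) == 42
        dfs = dict(zip(res.anova["term"], res.anova["df_num"]))
        assert dfs["C(state)"] == 3
        assert dfs["C(network)"] == 6
        assert dfs["C(state):C(network)"] == 18
        assert (res.anova["df_den"] > 0).all()

    def test_single_participant_rejected(self, rng):
        tab = _network_table(rng, n_participants=1)
        with pytest.raises(ValueError, match="participant"):
            stats.network_lmm(tab)

    def test_interaction_detected_when_injected(self, rng):
        res = stats.network_lmm(_network_table(rng, n_participants=20,
                                               effect=0.6))
        row = res.anova.set_index("term").loc["C(state):C(network)"]
        assert row["p_value"] < 0.001
        sig = res.posthoc[res.posthoc["significant"]]
        assert set(sig["network"]) == {"visual"}


class TestRsqAnova:
    def _occupancy(self, rng, n=41, biased_frac=0.25, shift=0.0):
        labels, recs = {}, []
        for p in range(n):
            pid = f"sub-{p:02d}"
            biased = p < int(biased_frac * n)
            labels[pid] = "did_not_sleep" if biased else "slept"
            occ = rng.dirichlet(np.ones(4) * 20)
            if biased and shift:
                occ[0] += shift
                occ /= occ.sum()
            for s, v in zip(STATE_NAMES, occ):
                recs.append((pid, s, v))
        table = pd.DataFrame(recs, columns=["participant", "state",
                                            "occupancy"])
        return table, pd.Series(labels)

    def test_constructed_awake_bias_detected(self, rng):
        table, labels = self._occupancy(rng, shift=0.3)
        res = stats.rsq_anova(table, labels)
        assert not res.one_way
        assert res.df_num == 3
        assert res.interaction_p < 0.001

    def test_balanced_null_not_significant(self, rng):
        table, labels = self._occupancy(rng, shift=0.0)
        res = stats.rsq_anova(table, labels)
        assert res.interaction_p > 0.01

    def test_single_report_level_degrades_to_one_way(self, rng):
        table, labels = self._occupancy(rng, biased_frac=0.0)
        res = stats.rsq_anova(table, labels)
        assert res.one_way

    def test_missing_label_rejected(self, rng):
        table, labels = self._occupancy(rng)
        with pytest.raises(ValueError, match="without RSQ"):
            stats.rsq_anova(table, labels.iloc[:-1])


def test_roi_glm_table_attaches_bonferroni_flags(rng):
    tab = simulate_null_psd_table(12, 5, rng)
    out = stats.roi_glm_table(tab)
    assert len(out) == 5
    assert out.attrs["m_tests"] == 5
    assert out.attrs["bonferroni_alpha"] == pytest.approx(0.01)
    assert out["significant"].dtype == bool
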