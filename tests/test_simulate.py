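"""Synthetic cohort generator: covariance structure, motion, phenotypes."""

import numpy as np
import pandas as pd
import pytest

from sysseg_pain.atlas import PartitionAtlas, default_partition
from sysseg_pain.connectivity import framewise_displacement
from sysseg_pain.scores import PCS_KEYING, score_phenotypes
from sysseg_pain.simulate import (
    DEFAULT_BEHAVIORAL_BETAS,
    SimulationConfig,
    _split_sum,
    _split_sum_int,
    analytic_sys,
    assign_groups,
    make_block_covariance,
    simulate_cohort,
    simulate_motion,
    simulate_phenotypes,
    simulate_sys_profiles,
    simulate_timeseries,
)


@pytest.fixture
def atlas4(two_net_atlas):
    return two_net_atlas


def small_config(**kw):
    nets = ("A",) * 4 + ("B",) * 4
    atlas = PartitionAtlas(tuple(f"n{i}" for i in range(8)), nets)
    defaults = dict(
        n_subjects=10,
        partition=atlas,
        n_volumes=100,
        r_within={"A": 0.5, "B": 0.5},
        r_between=0.1,
        seed=1,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestBlockCovariance:
    def test_two_block_layout(self, atlas4):
        cov = make_block_covariance(atlas4, {"A": 0.5, "B": 0.5}, 0.1)
        expect = np.array(
            [
                [1.0, 0.5, 0.1, 0.1],
                [0.5, 1.0, 0.1, 0.1],
                [0.1, 0.1, 1.0, 0.5],
                [0.1, 0.1, 0.5, 1.0],
            ]
        )
        assert np.array_equal(cov, expect)

    def test_zero_correlations_give_identity(self, atlas4):
        cov = make_block_covariance(atlas4, 0.0, 0.0)
        assert np.array_equal(cov, np.eye(4))

    def test_full_partition_is_positive_definite(self):
        cov = make_block_covariance(default_partition(), 0.5, 0.1)
        assert np.linalg.eigvalsh(cov)[0] > 0

    def test_indefinite_combination_rejected(self, atlas4):
        with pytest.raises(ValueError, match="positive definite"):
            make_block_covariance(atlas4, 0.0, 0.9)

    def test_out_of_range_correlation_rejected(self, atlas4):
        with pytest.raises(ValueError, match="outside"):
            make_block_covariance(atlas4, 1.0, 0.1)


class TestSimulateTimeseries:
    def test_same_seed_identical_output(self):
        cfg = small_config()
        a = simulate_timeseries(cfg, 42)
        b = simulate_timeseries(cfg, 42)
        assert np.array_equal(a.values, b.values)

    def test_within_network_correlation_converges(self):
        cfg = small_config(n_volumes=50_000)
        ts = simulate_timeseries(cfg, 7)
        r = np.corrcoef(ts.values, rowvar=False)
        within = r[np.ix_(range(4), range(4))][np.triu_indices(4, 1)]
        assert np.all(np.abs(within - 0.5) < 0.01)

    def test_independent_networks_uncorrelated(self):
        cfg = small_config(r_between=0.0, n_volumes=4000)
        ts = simulate_timeseries(cfg, 3)
        r = np.corrcoef(ts.values, rowvar=False)
        cross = r[np.ix_(range(4), range(4, 8))]
        assert np.abs(cross).max() < 4 / np.sqrt(4000)

    def test_shape(self):
        ts = simulate_timeseries(small_config(), 0)
        assert ts.values.shape == (100, 8)


class TestSimulateMotion:
    def test_zero_sd_gives_zero_trace_and_fd(self):
        trace = simulate_motion(50, 0.0, seed=1)
        assert np.all(trace.as_matrix() == 0)
        assert framewise_displacement(trace).fd_mean == 0

    def test_fixed_seed_identical(self):
        a = simulate_motion(60, 0.05, seed=9, target_mean_fd=0.2)
        b = simulate_motion(60, 0.05, seed=9, target_mean_fd=0.2)
        assert np.array_equal(a.as_matrix(), b.as_matrix())

    def test_hits_group_level_fd_target(self):
        trace = simulate_motion(200, 0.05, seed=4, target_mean_fd=0.163)
        realized = framewise_displacement(trace).fd_mean
        assert realized == pytest.approx(0.163, rel=0.10)

    def test_needs_two_volumes(self):
        with pytest.raises(ValueError):
            simulate_motion(1, 0.05, seed=0)


class TestItemSplitting:
    def test_continuous_split_exact_sum_and_bounds(self, rng):
        for _ in range(200):
            total = rng.uniform(0, 40)
            w = _split_sum(total, 4, 10.0, rng)
            assert w.sum() == pytest.approx(total, abs=1e-9)
            assert np.all(w >= -1e-12) and np.all(w <= 10 + 1e-12)

    def test_integer_split_exact_sum_and_bounds(self, rng):
        for _ in range(200):
            total = int(rng.integers(0, 25))
            w = _split_sum_int(total, 6, 4, rng)
            assert w.sum() == total
            assert np.all((0 <= w) & (w <= 4))

    def test_infeasible_split_rejected(self, rng):
        with pytest.raises(ValueError, match="infeasible"):
            _split_sum(41.0, 4, 10.0, rng)


class TestSimulatePhenotypes:
    def phenotypes(self, rng, n=120, **cfg_kw):
        cfg = small_config(n_subjects=n, pain_prevalence=1.0, **cfg_kw)
        groups = assign_groups(n, 1.0, rng)
        _, true_sys = simulate_sys_profiles(cfg, rng)
        df, planted, clip = simulate_phenotypes(cfg, true_sys, groups, rng)
        return cfg, true_sys, df, planted, clip

    def test_items_consistent_with_planted_composites(self, rng):
        _, _, df, planted, _ = self.phenotypes(rng)
        scored = score_phenotypes(df)
        # the scored longitudinal change must equal the planted change wherever
        # the composite stayed inside the instrument bounds
        delta = scored["pain_experience_longitudinal"] - planted
        inside = (scored["pain_experience_t2"] > 0) & (scored["pain_experience_t2"] < 10)
        assert inside.mean() > 0.8
        assert delta[inside].abs().max() < 1e-8

    def test_noise_free_null_interaction_recovers_exactly(self, rng):
        betas = {
            "helplessness": 0.1, "sys_default": 0.05, "sys_dorsoattention": -0.05,
            "intensity_t1": -0.1, "affective_interference_t1": -0.1,
            "activity_interference_t1": 0.05, "interaction": 0.0,
        }
        nets = ("default",) * 4 + ("dorsoattention",) * 4
        atlas = PartitionAtlas(tuple(f"n{i}" for i in range(8)), nets)
        cfg = SimulationConfig(
            n_subjects=150, partition=atlas, n_volumes=100,
            r_within={"default": 0.5, "dorsoattention": 0.5}, r_between=0.1,
            behavioral_betas=betas, noise_sd=0.0, pain_prevalence=1.0, seed=5,
        )
        groups = ["pain"] * 150
        _, true_sys = simulate_sys_profiles(cfg, rng)
        df, planted, _ = simulate_phenotypes(cfg, true_sys, groups, rng)
        scored = score_phenotypes(df)

        def z(a):
            a = np.asarray(a, float)
            return (a - a.mean()) / a.std(ddof=1)

        X = np.column_stack([
            np.ones(150),
            z(scored["pcs_helplessness"]),
            z(true_sys["default"]),
            z(true_sys["dorsoattention"]),
            z(scored["intensity_t1"]),
            z(scored["affective_interference_t1"]),
            z(scored["activity_interference_t1"]),
        ])
        y = scored["pain_experience_longitudinal"].values
        beta_hat, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        expect = [0.0, 0.1, 0.05, -0.05, -0.1, -0.1, 0.05]
        assert np.allclose(beta_hat, expect, atol=1e-8)
        assert np.abs(y - X @ beta_hat).max() < 1e-8

    def test_pcs_items_match_subscale_targets(self, rng):
        _, _, df, _, _ = self.phenotypes(rng)
        items = df[[f"pcs_item_{k}" for k in range(1, 14)]].values
        assert np.all((items >= 0) & (items <= 4))
        assert np.all(items == np.rint(items))
        helpless_cols = np.asarray(PCS_KEYING["helplessness"]) - 1
        assert np.all(items[:, helpless_cols].sum(1) <= 24)

    def test_extreme_settings_warn_about_clipping(self, rng):
        betas = dict(DEFAULT_BEHAVIORAL_BETAS, helplessness=50.0, interaction=4.0)
        with pytest.warns(UserWarning, match="bounds"):
            self.phenotypes(rng, n=150, behavioral_betas=betas, noise_sd=0.0)

    def test_group_prevalence(self, rng):
        groups = assign_groups(4000, 133 / 347, rng)
        frac = np.mean([g == "pain" for g in groups])
        assert frac == pytest.approx(133 / 347, abs=0.03)


class TestCohortDeterminism:
    def test_identical_configs_reproduce_everything(self):
        cfg = small_config(n_subjects=6, n_volumes=60, pain_prevalence=1.0)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        sid = a.phenotypes["subject_id"].iloc[0]
        assert np.array_equal(a.timeseries[sid].values, b.timeseries[sid].values)
        assert np.array_equal(a.motion[sid].as_matrix(), b.motion[sid].as_matrix())
        assert a.ground_truth.to_json() == b.ground_truth.to_json()

    def test_different_seed_changes_data(self):
        a = simulate_cohort(small_config(n_subjects=6, n_volumes=60, seed=1,
                                         pain_prevalence=1.0))
        b = simulate_cohort(small_config(n_subjects=6, n_volumes=60, seed=2,
                                         pain_prevalence=1.0))
        sid = a.phenotypes["subject_id"].iloc[0]
        assert not np.array_equal(a.timeseries[sid].values, b.timeseries[sid].values)


class TestConfigValidation:
    def test_between_must_be_below_within(self):
        with pytest.raises(ValueError, match="segregated"):
            small_config(r_between=0.6)

    def test_short_series_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            small_config(n_volumes=10)

    def test_analytic_sys_value(self):
        assert analytic_sys(0.5, 0.1) == pytest.approx(
            (np.arctanh(0.5) - np.arctanh(0.1)) / np.arctanh(0.5)
        )
        assert analytic_sys(0.5, 0.0) == 1.0
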