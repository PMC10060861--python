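"""Motion QC, nuisance model, connectivity and segregation."""

import numpy as np
import pytest

from sysseg_pain.atlas import PartitionAtlas, default_partition
from sysseg_pain.connectivity import (
    ConnectivityMatrix,
    MotionTrace,
    RoiTimeSeries,
    compute_fc,
    compute_segregation,
    dct_drift_basis,
    exclude_high_motion,
    framewise_displacement,
    motion_regressors,
    nuisance_regress,
)

from conftest import random_fc


# ---------------------------------------------------------------------------
# framewise displacement
# ---------------------------------------------------------------------------

class TestFramewiseDisplacement:
    def test_zero_trace_gives_zero_fd(self):
        trace = MotionTrace(np.zeros((20, 3)), np.zeros((20, 3)))
        s = framewise_displacement(trace)
        assert np.all(s.fd_series == 0) and s.fd_mean == 0

    def test_hand_computed_single_step(self):
        # translations step (0.1, -0.2, 0.05) mm, rotations step (0.002, 0, -0.001) rad
        rot = np.array([[0, 0, 0], [0.002, 0.0, -0.001]])
        trans = np.array([[0, 0, 0], [0.1, -0.2, 0.05]])
        s = framewise_displacement(MotionTrace(rot, trans))
        assert s.fd_series[0] == pytest.approx(0.35 + 50 * 0.003, abs=1e-12)

    def test_pure_rotation_converts_on_50mm_sphere(self):
        rot = np.array([[0, 0, 0], [0.01, 0, 0]])
        s = framewise_displacement(MotionTrace(rot, np.zeros((2, 3))))
        assert s.fd_series[0] == pytest.approx(0.5, abs=1e-12)

    def test_needs_two_volumes(self):
        with pytest.raises(ValueError, match="at least 2"):
            framewise_displacement(MotionTrace(np.zeros((1, 3)), np.zeros((1, 3))))


class TestExclusionRule:
    @staticmethod
    def trace_with_fd(fd_values):
        """Build a trace whose FD series equals fd_values (x-translation steps)."""
        x = np.concatenate([[0.0], np.cumsum(fd_values)])
        trans = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
        return MotionTrace(np.zeros_like(trans), trans)

    def test_majority_above_threshold_excluded(self):
        fd = [0.6] * 6 + [0.1] * 4  # 60% above 0.5 mm
        s = framewise_displacement(self.trace_with_fd(fd))
        assert exclude_high_motion(s) is True

    def test_still_subject_retained(self):
        s = framewise_displacement(MotionTrace(np.zeros((30, 3)), np.zeros((30, 3))))
        assert exclude_high_motion(s) is False

    def test_exactly_half_excluded(self):
        # "at least 50%" reads as >=
        fd = [0.6] * 5 + [0.1] * 5
        s = framewise_displacement(self.trace_with_fd(fd))
        assert exclude_high_motion(s) is True

    def test_just_under_half_retained(self):
        fd = [0.6] * 4 + [0.1] * 6
        s = framewise_displacement(self.trace_with_fd(fd))
        assert exclude_high_motion(s) is False


# ---------------------------------------------------------------------------
# drift basis and nuisance regression
# ---------------------------------------------------------------------------

class TestDctBasis:
    def test_column_count_matches_cutoff(self):
        # 740 volumes at TR 0.8 s span 592 s; frequencies below 0.01 Hz
        basis = dct_drift_basis(740, 0.8, 0.01)
        assert basis.shape == (740, 11)

    def test_columns_orthogonal(self):
        basis = dct_drift_basis(300, 0.8, 0.05)
        gram = basis.T @ basis
        off = gram - np.diag(np.diagonal(gram))
        assert np.abs(off).max() < 1e-10

    def test_tiny_cutoff_gives_empty_basis(self):
        assert dct_drift_basis(100, 0.8, 1e-6).shape == (100, 0)

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            dct_drift_basis(100, 0.8, 0.0)


class TestNuisanceRegress:
    def test_intercept_only_mean_centers(self, rng):
        ts = RoiTimeSeries(rng.normal(5.0, 1.0, size=(50, 4)))
        out = nuisance_regress(ts, np.empty((50, 0)))
        assert np.allclose(out.values, ts.values - ts.values.mean(0), atol=1e-10)

    def test_series_equal_to_confound_vanishes(self, rng):
        conf = rng.standard_normal((60, 1))
        ts = RoiTimeSeries(np.hstack([conf, rng.standard_normal((60, 3))]))
        out = nuisance_regress(ts, conf)
        assert np.abs(out.values[:, 0]).max() < 1e-10

    def test_residuals_orthogonal_to_confounds(self, rng):
        ts = RoiTimeSeries(rng.standard_normal((200, 100)))
        conf = rng.standard_normal((200, 8))
        out = nuisance_regress(ts, conf)
        corr = np.corrcoef(np.hstack([out.values, conf]), rowvar=False)
        cross = corr[:100, 100:]
        assert np.abs(cross).max() < 1e-10

    def test_collinear_confounds_dropped_with_warning(self, rng):
        conf = rng.standard_normal((50, 2))
        conf = np.hstack([conf, conf[:, :1] * 2.0])
        ts = RoiTimeSeries(rng.standard_normal((50, 3)))
        with pytest.warns(UserWarning, match="collinear"):
            out = nuisance_regress(ts, conf)
        assert out.values.shape == (50, 3)

    def test_row_mismatch_rejected(self, rng):
        ts = RoiTimeSeries(rng.standard_normal((50, 3)))
        with pytest.raises(ValueError, match="rows"):
            nuisance_regress(ts, rng.standard_normal((49, 2)))


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

class TestComputeFc:
    def test_entries_are_fisher_z_of_pearson(self, rng):
        vals = rng.standard_normal((120, 5))
        fc = compute_fc(RoiTimeSeries(vals))
        r = np.corrcoef(vals, rowvar=False)
        expect = np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7))
        expect[expect < 0] = 0
        np.fill_diagonal(expect, 0)
        assert np.allclose(fc.z_values, expect, atol=1e-12)

    def test_anticorrelated_pair_truncated_to_zero(self, rng):
        x = rng.standard_normal(80)
        vals = np.column_stack([x, -x + 1e-6 * rng.standard_normal(80)])
        fc = compute_fc(RoiTimeSeries(vals))
        assert fc.z_values[0, 1] == 0.0

    def test_diagonal_zero(self, rng):
        fc = compute_fc(RoiTimeSeries(rng.standard_normal((60, 4))))
        assert np.all(np.diagonal(fc.z_values) == 0)

    def test_perfect_correlation_stays_finite(self, rng):
        x = rng.standard_normal(40)
        with np.errstate(all="raise"):
            fc = compute_fc(RoiTimeSeries(np.column_stack([x, 2 * x + 1])))
        assert np.isfinite(fc.z_values).all()

    def test_zero_variance_node_named_in_error(self, rng):
        vals = rng.standard_normal((40, 3))
        vals[:, 1] = 7.0
        with pytest.raises(ValueError, match="zero-variance.*node_b"):
            compute_fc(RoiTimeSeries(vals, node_labels=("node_a", "node_b", "node_c")))


class TestComputeSegregation:
    def test_hand_worked_example(self, two_net_atlas):
        z = np.zeros((4, 4))
        z[0, 1] = z[1, 0] = 0.6931
        z[2, 3] = z[3, 2] = 0.4
        cross = [(0, 2), (0, 3), (1, 2), (1, 3)]
        for i, j in cross:
            z[i, j] = z[j, i] = 0.2
        prof = compute_segregation(ConnectivityMatrix(z), two_net_atlas)
        assert prof.sys_of("A") == pytest.approx((0.6931 - 0.2) / 0.6931, abs=1e-10)
        assert prof.sys_of("B") == pytest.approx(0.5, abs=1e-12)

    def test_isolated_networks_reach_upper_bound(self, two_net_atlas):
        z = np.zeros((4, 4))
        z[0, 1] = z[1, 0] = 0.5
        z[2, 3] = z[3, 2] = 0.9
        prof = compute_segregation(ConnectivityMatrix(z), two_net_atlas)
        assert prof.sys_of("A") == 1.0 and prof.sys_of("B") == 1.0

    def test_equal_within_and_between_gives_zero(self, two_net_atlas):
        z = np.full((4, 4), 0.3)
        np.fill_diagonal(z, 0.0)
        prof = compute_segregation(ConnectivityMatrix(z), two_net_atlas)
        assert prof.sys_of("A") == pytest.approx(0.0, abs=1e-12)

    def test_zero_within_flagged_undefined(self, two_net_atlas):
        z = np.zeros((4, 4))
        z[0, 2] = z[2, 0] = 0.3  # only a cross edge
        prof = compute_segregation(ConnectivityMatrix(z), two_net_atlas)
        frame = prof.to_frame().set_index("network")
        assert frame.loc["A", "undefined"] and np.isnan(frame.loc["A", "sys"])

    def test_matches_brute_force_pair_loop(self, small_atlas, rng):
        for _ in range(100):
            z = random_fc(10, rng)
            prof = compute_segregation(ConnectivityMatrix(z), small_atlas).to_frame()
            for _, row in prof.iterrows():
                inside = set(small_atlas.nodes_of(row["network"]))
                w_vals = [z[i, j] for i in inside for j in inside if i < j]
                b_vals = [z[i, j] for i in inside for j in range(10) if j not in inside]
                w, b = np.mean(w_vals), np.mean(b_vals)
                assert abs(row["w_net"] - w) < 1e-10
                assert abs(row["b_net"] - b) < 1e-10
                assert abs(row["sys"] - (w - b) / w) < 1e-10

    def test_invariant_to_node_permutation(self, small_atlas, rng):
        z = random_fc(10, rng)
        base = compute_segregation(ConnectivityMatrix(z), small_atlas).to_frame()
        perm = rng.permutation(10)
        atlas_p = PartitionAtlas(
            tuple(small_atlas.node_labels[i] for i in perm),
            tuple(small_atlas.networks[i] for i in perm),
        )
        zp = z[np.ix_(perm, perm)]
        permuted = compute_segregation(ConnectivityMatrix(zp), atlas_p).to_frame()
        for net in ("A", "B", "C"):
            a = base.set_index("network").loc[net, "sys"]
            b = permuted.set_index("network").loc[net, "sys"]
            assert a == pytest.approx(b, abs=1e-12)

    def test_raising_between_edge_never_raises_sys(self, small_atlas, rng):
        z = random_fc(10, rng)
        base = compute_segregation(ConnectivityMatrix(z), small_atlas).to_frame()
        i, j = 0, 9  # nodes in networks A and C
        z2 = z.copy()
        z2[i, j] = z2[j, i] = z[i, j] + 0.5
        bumped = compute_segregation(ConnectivityMatrix(z2), small_atlas).to_frame()
        for net in ("A", "C"):
            assert (
                bumped.set_index("network").loc[net, "sys"]
                <= base.set_index("network").loc[net, "sys"]
            )

    def test_dimension_mismatch_rejected(self, two_net_atlas, rng):
        z = random_fc(6, rng)
        with pytest.raises(ValueError, match="partition"):
            compute_segregation(ConnectivityMatrix(z), two_net_atlas)


def test_motion_regressors_shape_and_padding(rng):
    trace = MotionTrace(rng.standard_normal((30, 3)), rng.standard_normal((30, 3)))
    reg = motion_regressors(trace)
    assert reg.shape == (30, 12)
    assert np.all(reg[0, 6:] == 0)
    assert np.allclose(reg[1:, 6:], np.diff(trace.as_matrix(), axis=0))


def test_default_partition_shape():
    atlas = default_partition()
    assert atlas.n_nodes == 100 and len(atlas.network_names) == 7
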