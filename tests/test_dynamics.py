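"""IQR, distance-variation matrices, DCCM, and mass-weighted PCA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flexconcord import dccm, dv_matrix, iqr, pc_animation, pca
from flexconcord.dynamics import DistanceVariationMatrix

from conftest import make_ca_ensemble, random_rotation


def iqr_oracle(samples):
    """Sort-based linear-interpolation quantiles, p(k) = (k-1)/(n-1)."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)

    def quantile(p):
        if n == 1:
            return x[0]
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    return quantile(0.75) - quantile(0.25)


class TestIQR:
    def test_constant_sample(self):
        assert iqr([1, 1, 1, 1]) == 0.0

    def test_four_point_interpolation(self):
        # Q1 = 1.75, Q3 = 3.25 under the linear-interpolation rule
        assert iqr([1, 2, 3, 4]) == pytest.approx(1.5, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            iqr([])

    def test_outlier_moves_iqr_less_than_range(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        spiked = np.append(base, 1e4)
        d_iqr = abs(iqr(spiked) - iqr(base))
        d_range = abs(np.ptp(spiked) - np.ptp(base))
        assert d_iqr < d_range

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=50
        )
    )
    def test_agrees_with_sort_based_oracle(self, samples):
        assert iqr(samples) == pytest.approx(iqr_oracle(samples), abs=1e-9)


class TestDVMatrix:
    def test_rigid_ensemble_gives_zero_matrix(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(8, 3)) * 6
        frames = np.stack(
            [base @ random_rotation(rng).T + rng.normal(size=3) * 20 for _ in range(10)]
        )
        dv = dv_matrix(make_ca_ensemble(frames))
        assert np.abs(dv.values).max() < 1e-8

    def test_two_frame_pair_distance(self):
        # two frames with CA-CA distances 3.8 and 4.2 A: IQR of two points
        # is half their gap (Q1 = 3.9, Q3 = 4.1)
        coords = np.zeros((2, 3, 3))
        coords[0, 1, 0] = 3.8
        coords[1, 1, 0] = 4.2
        coords[:, 2, 1] = 9.0
        dv = dv_matrix(make_ca_ensemble(coords))
        assert dv.values[0, 1] == pytest.approx(0.2, abs=1e-12)

    def test_invariant_under_per_frame_rigid_transforms(self, gaussian_system):
        ens, _ = gaussian_system
        coords = ens.coords[:40].copy()
        dv_ref = dv_matrix(make_ca_ensemble(coords))
        rng = np.random.default_rng(2)
        moved = np.stack(
            [
                frame @ random_rotation(rng).T + rng.normal(size=3) * 50
                for frame in coords
            ]
        )
        dv_moved = dv_matrix(make_ca_ensemble(moved))
        assert np.abs(dv_moved.values - dv_ref.values).max() < 1e-8

    def test_symmetry_and_zero_diagonal_exact(self, gaussian_system):
        ens, _ = gaussian_system
        dv = dv_matrix(make_ca_ensemble(ens.coords[:60]))
        np.testing.assert_array_equal(dv.values, dv.values.T)
        np.testing.assert_array_equal(np.diag(dv.values), 0.0)

    def test_blocking_does_not_change_values(self, gaussian_system):
        ens, _ = gaussian_system
        small = make_ca_ensemble(ens.coords[:30])
        np.testing.assert_allclose(
            dv_matrix(small, block_size=4).values,
            dv_matrix(small, block_size=1000).values,
            atol=1e-12,
        )

    def test_hinge_block_structure(self, hinge_system):
        ens, _, partition = hinge_system
        dv = dv_matrix(ens)
        assign = partition.assignment(ens.residue_count)
        intra = (assign[:, None] == assign[None, :]) & (assign[:, None] >= 0)
        inter = (
            (assign[:, None] != assign[None, :])
            & (assign[:, None] >= 0)
            & (assign[None, :] >= 0)
        )
        off = ~np.eye(ens.residue_count, dtype=bool)
        assert (
            np.median(dv.values[intra & off]) < np.median(dv.values[inter])
        )

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            dv_matrix(make_ca_ensemble(np.zeros((1, 4, 3))))


class TestDCCM:
    def test_opposite_motion_is_anticorrelated(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(6, 3)) * 8
        amp = rng.normal(size=40)
        coords = np.repeat(base[None], 40, axis=0)
        coords[:, 0, 0] += amp
        coords[:, 1, 0] -= amp
        with pytest.warns(UserWarning, match="zero positional variance"):
            mat = dccm(make_ca_ensemble(coords), superpose=False)
        assert mat.values[0, 1] == pytest.approx(-1.0, abs=1e-10)
        assert mat.values[0, 0] == 1.0

    def test_common_translation_removed_then_flagged(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(5, 3)) * 5
        shifts = rng.normal(size=(20, 1, 3)) * 4
        coords = base[None] + shifts  # pure collective translation
        raw = dccm(make_ca_ensemble(coords), superpose=False)
        off = ~np.eye(5, dtype=bool)
        assert raw.values[off].min() > 0.99  # looks fully correlated unfitted
        with pytest.warns(UserWarning, match="zero positional variance"):
            fitted = dccm(make_ca_ensemble(coords), superpose=True)
        np.testing.assert_array_equal(fitted.values, 0.0)

    def test_hinge_intra_positive_inter_negative(self, hinge_system):
        ens, _, partition = hinge_system
        mat = dccm(ens)
        assign = partition.assignment(ens.residue_count)
        off = ~np.eye(ens.residue_count, dtype=bool)
        intra = (assign[:, None] == assign[None, :]) & (assign[:, None] >= 0) & off
        inter = (
            (assign[:, None] != assign[None, :])
            & (assign[:, None] >= 0)
            & (assign[None, :] >= 0)
        )
        assert mat.values[intra].mean() > 0.0
        assert mat.values[inter].mean() < 0.0

    def test_entries_bounded(self, gaussian_system):
        ens, _ = gaussian_system
        mat = dccm(make_ca_ensemble(ens.coords[:100]))
        assert np.abs(mat.values).max() <= 1.0
        np.testing.assert_array_equal(np.diag(mat.values), 1.0)


class TestPCA:
    def test_two_mode_variance_ratio(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(10, 3)) * 10
        v1 = rng.normal(size=(10, 3))
        v1 /= np.linalg.norm(v1)
        v2 = rng.normal(size=(10, 3))
        v2 -= v1 * np.sum(v1 * v2)
        v2 /= np.linalg.norm(v2)
        a = rng.normal(size=5000) * 3.0
        b = rng.normal(size=5000) * 1.0
        coords = base[None] + a[:, None, None] * v1 + b[:, None, None] * v2
        res = pca(make_ca_ensemble(coords), superpose=False)
        ratio = res.eigenvalues[0] / res.eigenvalues[1]
        assert ratio == pytest.approx(9.0, rel=0.15)
        assert res.variance_fraction[:2].sum() > 0.999

    def test_rigid_ensemble_zero_spectrum(self):
        base = np.random.default_rng(6).normal(size=(6, 3)) * 5
        coords = np.repeat(base[None], 10, axis=0)
        res = pca(make_ca_ensemble(coords))
        assert res.eigenvalues.max() < 1e-10

    def test_eigenvalue_sum_equals_trace(self, gaussian_system):
        ens, _ = gaussian_system
        small = make_ca_ensemble(ens.coords[:300])
        res = pca(small, superpose=False)
        from flexconcord.superposition import _iterative_mean_fit  # noqa: F401

        flat = (small.coords * np.sqrt(small.masses)[None, :, None]).reshape(
            300, -1
        )
        cov_trace = np.sum(flat.var(axis=0, ddof=1))
        assert res.eigenvalues.sum() == pytest.approx(cov_trace, rel=1e-10)

    def test_modes_orthonormal(self, hinge_system):
        ens, _, _ = hinge_system
        res = pca(make_ca_ensemble(ens.coords[:200]))
        k = 10
        gram = res.modes[:, :k].T @ res.modes[:, :k]
        np.testing.assert_allclose(gram, np.eye(k), atol=1e-8)

    def test_hinge_is_single_mode(self, hinge_system):
        ens, _, _ = hinge_system
        res = pca(ens)
        assert res.variance_fraction[0] > 0.9


class TestPCAnimation:
    def test_frames_span_mode(self, hinge_system):
        ens, _, _ = hinge_system
        res = pca(ens)
        anim = pc_animation(res, ens, mode=0, n_steps=3, amplitude=2.0)
        assert anim.n_frames == 3
        np.testing.assert_allclose(anim.coords[1], res.mean_coords, atol=1e-10)
        step = anim.coords[2] - anim.coords[0]
        direction = res.modes[:, 0].reshape(-1, 3) / np.sqrt(res.masses)[:, None]
        np.testing.assert_allclose(step, 4.0 * direction, atol=1e-10)

    def test_round_trip_recovers_mode(self, hinge_system):
        ens, _, _ = hinge_system
        res = pca(ens)
        anim = pc_animation(res, ens, mode=0, n_steps=21, amplitude=5.0)
        res2 = pca(anim, superpose=False)
        cosine = abs(res.modes[:, 0] @ res2.modes[:, 0])
        assert cosine > 0.99

    def test_bad_amplitude(self, hinge_system):
        ens, _, _ = hinge_system
        res = pca(ens)
        with pytest.raises(ValueError):
            pc_animation(res, ens, amplitude=0.0)


def test_dv_matrix_type_validates_contract():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceVariationMatrix(values=np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        DistanceVariationMatrix(values=np.array([[1.0, 2.0], [2.0, 0.0]]))
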