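import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ctbrush import mart
from ctbrush.mart import (ConvergenceInfo, ReconState, full_view_report,
                          full_view_reconstruction, line_profile,
                          mart_update, process_new_ray, raysum, refine,
                          refine_to_convergence, relative_error, residual)
from ctbrush.raygeom import (DomainError, GridDims, StarConfig, make_star,
                             rasterize_ray, spaced_angles)


def oracle_update(estimate, pixel_set, target):
    """Independent per-pixel multiplicative update: every pixel under
    the ray's binary mask is rescaled by target / masked-sum; all other
    pixels are copied through.  Dense-mask arithmetic, no shortcuts."""
    H, W = estimate.shape
    mask = np.zeros((H, W))
    for r, c in pixel_set:
        mask[r, c] = 1.0
    s = float((mask * estimate).sum())
    out = np.empty_like(estimate)
    for r in range(H):
        for c in range(W):
            if mask[r, c] == 1.0:
                if target == 0.0:
                    out[r, c] = 0.0
                elif s > 0.0:
                    out[r, c] = estimate[r, c] * target / s
                else:
                    out[r, c] = estimate[r, c]
            else:
                out[r, c] = estimate[r, c]
    return out


@pytest.fixture
def grid8():
    return GridDims(8, 8)


class TestRaysum:
    def test_counts_pixels_on_uniform_image(self, grid8):
        ray = rasterize_ray((3, 0), 0, grid8)
        assert raysum(np.ones(grid8.shape), ray) == len(ray)

    def test_picks_single_hot_pixel(self, grid8):
        ray = rasterize_ray((3, 0), 0, grid8)
        img = np.zeros(grid8.shape)
        img[3, 5] = 5.0
        assert raysum(img, ray) == 5.0

    def test_zero_image_zero_sum(self, grid8):
        assert raysum(np.zeros(grid8.shape),
                      rasterize_ray((2, 2), 117.0, grid8)) == 0.0


class TestMartUpdate:
    def test_uniform_doubling(self, grid8):
        ray = rasterize_ray((3, 0), 0, grid8)
        est = np.ones(grid8.shape)
        out = mart_update(est, ray, 2 * len(ray))
        assert np.allclose(out[3], 2.0)
        assert np.allclose(np.delete(out, 3, axis=0), 1.0)

    def test_zero_target_zeroes_the_ray(self, grid8):
        ray = rasterize_ray((0, 0), 45, grid8)
        out = mart_update(np.ones(grid8.shape), ray, 0.0)
        assert all(out[r, c] == 0.0 for r, c in ray.pixels)

    def test_consistent_target_is_identity(self, grid8):
        ray = rasterize_ray((5, 2), 30, grid8)
        est = np.full(grid8.shape, 0.7)
        out = mart_update(est, ray, raysum(est, ray))
        assert np.allclose(out, est)

    def test_negative_target_rejected(self, grid8):
        with pytest.raises(DomainError):
            mart_update(np.ones(grid8.shape),
                        rasterize_ray((0, 0), 0, grid8), -1.0)

    @given(st.floats(0.0, 50.0), st.integers(0, 7),
           st.floats(0, 180, exclude_max=True))
    def test_constraint_satisfied_after_update(self, target, r, angle):
        d = GridDims(8, 8)
        ray = rasterize_ray((r, 3), angle, d)
        out = mart_update(np.full(d.shape, 0.5), ray, target)
        assert raysum(out, ray) == pytest.approx(target, rel=1e-9, abs=1e-9)

    @given(st.integers(0, 7), st.integers(0, 7),
           st.floats(0, 180, exclude_max=True), st.floats(0.0, 20.0))
    def test_matches_dense_mask_oracle(self, r, c, angle, target):
        d = GridDims(8, 8)
        ray = rasterize_ray((r, c), angle, d)
        est = np.linspace(0.1, 1.0, 64).reshape(8, 8)
        expected = oracle_update(est, ray.pixels, target)
        np.testing.assert_allclose(mart_update(est, ray, target), expected,
                                   rtol=1e-12, atol=1e-15)


class TestProcessNewRay:
    def test_duplicate_ray_adds_nothing(self, grid8, rng):
        hidden = rng.uniform(0.1, 1, grid8.shape)
        state = ReconState.initial(grid8)
        ray = rasterize_ray((4, 4), 30, grid8)
        _, new1 = process_new_ray(state, ray, hidden)
        est_after = state.estimate.copy()
        _, new2 = process_new_ray(state, rasterize_ray((4, 4), 30, grid8),
                                  hidden)
        assert (new1, new2) == (True, False)
        assert state.dose == 1
        assert np.array_equal(state.estimate, est_after)

    def test_first_ray_matches_hidden_raysum(self, grid8, rng):
        hidden = rng.uniform(0.1, 1, grid8.shape)
        state = ReconState.initial(grid8)
        ray = rasterize_ray((2, 5), 80, grid8)
        process_new_ray(state, ray, hidden)
        assert raysum(state.estimate, ray) \
            == pytest.approx(raysum(hidden, ray), rel=1e-12)

    def test_two_crossing_rays_sequential_semantics(self):
        """The second constraint holds exactly; the first may drift
        until a refine pass.  Cross-checked against the dense oracle."""
        d = GridDims(3, 3)
        hidden = np.array([[1., 2., 3.], [4., 5., 6.], [7., 8., 9.]])
        row = rasterize_ray((1, 0), 0, d)      # raysum 15
        col = rasterize_ray((0, 1), 90, d)     # raysum 15, crosses at (1,1)
        state = ReconState.initial(d)
        process_new_ray(state, row, hidden)
        process_new_ray(state, col, hidden)
        expected = oracle_update(np.ones((3, 3)), row.pixels, 15.0)
        expected = oracle_update(expected, col.pixels, 15.0)
        assert np.array_equal(state.estimate, expected)
        assert raysum(state.estimate, col) == pytest.approx(15.0, rel=1e-12)

    def test_dimension_mismatch_rejected(self, grid8):
        state = ReconState.initial(grid8)
        with pytest.raises(DomainError):
            process_new_ray(state, rasterize_ray((0, 0), 0, grid8),
                            np.ones((4, 4)))


def build_state(dims, hidden, centers, n_rays=6):
    state = ReconState.initial(dims)
    for ctr in centers:
        for ray in make_star(ctr, StarConfig(n_rays=n_rays), dims):
            process_new_ray(state, ray, hidden)
    return state


class TestRefine:
    def test_empty_registry_noop(self, grid8):
        state = ReconState.initial(grid8)
        refine(state)
        assert np.array_equal(state.estimate, np.ones(grid8.shape))
        assert state.refine_count == 1

    def test_single_ray_already_consistent(self, grid8, rng):
        hidden = rng.uniform(0.1, 1, grid8.shape)
        state = ReconState.initial(grid8)
        process_new_ray(state, rasterize_ray((3, 3), 58, grid8), hidden)
        before = state.estimate.copy()
        refine(state)
        assert np.allclose(state.estimate, before, rtol=1e-12)

    def test_residual_monotone_on_consistent_system(self, rng):
        dims = GridDims(16, 16)
        hidden = rng.uniform(0.1, 1, dims.shape)
        state = build_state(dims, hidden, [(3, 4), (8, 8), (12, 5), (6, 11)])
        res = [residual(state)]
        for _ in range(40):
            refine(state)
            res.append(residual(state))
        assert all(b <= a + 1e-12 for a, b in zip(res, res[1:]))
        assert res[-1] < res[0]

    def test_refine_never_changes_dose(self, rng):
        dims = GridDims(16, 16)
        hidden = rng.uniform(0.1, 1, dims.shape)
        state = build_state(dims, hidden, [(8, 8), (3, 12)])
        dose = state.dose
        for _ in range(10):
            refine(state)
        assert state.dose == dose

    def test_untouched_pixels_keep_initial_value(self, rng):
        dims = GridDims(16, 16)
        hidden = rng.uniform(0.1, 1, dims.shape)
        state = build_state(dims, hidden, [(8, 8)], n_rays=2)
        refine(state)
        touched = np.zeros(dims.shape, dtype=bool)
        for ray, _ in state.registry.items():
            touched[ray.rows, ray.cols] = True
        assert np.array_equal(state.estimate[~touched],
                              np.ones(dims.shape)[~touched])

    def test_estimates_stay_nonnegative(self, rng):
        dims = GridDims(16, 16)
        hidden = rng.uniform(0, 1, dims.shape)
        hidden[hidden < 0.3] = 0.0
        state = build_state(dims, hidden,
                            [(int(r), int(c))
                             for r, c in rng.integers(0, 16, (6, 2))])
        for _ in range(5):
            refine(state)
        assert (state.estimate >= 0).all()

    def test_zero_conservation(self, rng):
        dims = GridDims(16, 16)
        hidden = rng.uniform(0.1, 1, dims.shape)
        hidden[5] = 0.0  # an all-zero row: its 0-degree ray has raysum 0
        state = build_state(dims, hidden, [(5, 8), (7, 7)])
        zeroed = state.estimate == 0.0
        assert zeroed.any()
        for _ in range(10):
            refine(state)
        assert (state.estimate[zeroed] == 0.0).all()


class TestConvergence:
    def test_already_converged_returns_immediately(self, grid8, rng):
        hidden = rng.uniform(0.1, 1, grid8.shape)
        state = ReconState.initial(grid8)
        process_new_ray(state, rasterize_ray((4, 1), 0, grid8), hidden)
        info = refine_to_convergence(state, tol=1e-6)
        assert info.converged and info.passes == 0

    def test_consistent_system_converges(self, rng):
        dims = GridDims(64, 64)
        hidden = rng.uniform(0.1, 1, dims.shape)
        centers = [(int(r), int(c)) for r, c in rng.integers(0, 64, (8, 2))]
        state = build_state(dims, hidden, centers, n_rays=8)
        info = refine_to_convergence(state, tol=1e-6, max_passes=200)
        assert info.converged
        assert info.residual < 1e-6

    def test_inconsistent_system_hits_pass_limit(self, grid8):
        state = ReconState.initial(grid8)
        r1 = rasterize_ray((3, 0), 0, grid8)
        r2 = rasterize_ray((0, 4), 90, grid8)
        # contradictory targets on crossing rays
        state.registry.add(r1, 1.0)
        state.registry.add(r2, 50.0)
        refine(state)
        info = refine_to_convergence(state, tol=1e-12, max_passes=5)
        assert not info.converged
        assert info.passes == 5
        assert info.reason == "max_passes"
        assert info.residual > 0


class TestFullView:
    def test_uniform_hidden_reconstructs_uniformly(self):
        img = full_view_reconstruction(np.full((16, 16), 0.37), 4, tol=1e-8)
        assert np.allclose(img, 0.37, atol=1e-6)

    def test_zero_rows_reconstruct_to_exact_zero(self, rng):
        hidden = rng.uniform(0.1, 1, (16, 16))
        hidden[:4] = 0.0  # all-zero rows; their 0-degree raysums are 0
        img = full_view_reconstruction(hidden, 6, tol=1e-6, max_passes=50)
        assert (img[:4] == 0.0).all()

    def test_constraints_match_object_level_star_placement(self, rng):
        """The compiled path iterates exactly the staircases (and raysum
        targets) that placing a star at every pixel produces."""
        dims = GridDims(8, 8)
        hidden = rng.uniform(0.1, 1, dims.shape)
        n_views = 3
        expected = {}
        for r in range(8):
            for c in range(8):
                for angle in spaced_angles(n_views):
                    ray = rasterize_ray((r, c), angle, dims)
                    expected[ray.pixel_key] = raysum(hidden, ray)
        indices, indptr, _ = mart._build_system(spaced_angles(n_views), 8, 8)
        got = {}
        flat = hidden.ravel()
        for j in range(indptr.size - 1):
            px = indices[indptr[j]:indptr[j + 1]]
            key = frozenset((int(i) // 8, int(i) % 8) for i in px)
            got[key] = float(flat[px].sum())
        assert got.keys() == expected.keys()
        for k in got:
            assert got[k] == pytest.approx(expected[k], rel=1e-12)

    def test_dose_counts_match_closed_form_at_irrational_angles(self):
        # 5 views at 36-degree spacing: only the 0-degree view collapses
        res = full_view_report(np.ones((16, 16)), 5, max_passes=1)
        assert res.n_unique_rays == 5 * 256 - 16 * 15

    def test_more_views_do_not_increase_error(self, rng):
        from ctbrush.phantom import random_phantom
        from ctbrush.raygeom import GridDims as GD
        ph = random_phantom(GD(64, 64), rng)
        errs = [relative_error(
            full_view_reconstruction(ph.image, R, tol=1e-5, max_passes=60),
            ph.image) for R in (6, 18)]
        assert errs[1] <= errs[0]


class TestLineProfile:
    def test_uniform_profile(self):
        assert np.array_equal(line_profile(np.full((4, 7), 0.5), 2),
                              np.full(7, 0.5))

    def test_length_is_width(self, rng):
        img = rng.uniform(0, 1, (5, 9))
        assert line_profile(img, 4).shape == (9,)

    def test_profile_plateaus_at_gray_tone(self, small_phantom):
        prof = line_profile(small_phantom.image, 10)  # through the circle
        assert (prof[7:13] == 0.5).all()

    def test_row_out_of_range(self):
        with pytest.raises(DomainError):
            line_profile(np.ones((4, 4)), 4)
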