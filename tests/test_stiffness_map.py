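"""Stiffness interpolation, area metrics, soft-area regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import woundfield as wf


def samples_df(x, y, z):
    return pd.DataFrame({"x_mm": x, "y_mm": y, "stiffness_kPa": z})


def dense_grid_samples(fn, lo=-2.0, hi=2.0, n=41):
    xs = np.linspace(lo, hi, n)
    X, Y = np.meshgrid(xs, xs)
    return samples_df(X.ravel(), Y.ravel(), fn(X, Y).ravel())


class TestInterpolation:
    def test_constant_field(self):
        s = dense_grid_samples(lambda X, Y: np.full_like(X, 10.0), n=7)
        grid = wf.interpolate_grid(s, pixel_size=0.1)
        assert np.allclose(grid.values[grid.valid_mask], 10.0)

    def test_affine_exactness(self):
        s = dense_grid_samples(lambda X, Y: 2 * X + 3.0 + 0 * Y, lo=0, hi=2, n=6)
        grid = wf.interpolate_grid(s, pixel_size=0.05)
        X, _ = np.meshgrid(grid.x_coords, grid.y_coords)
        expect = 2 * X + 3.0
        assert np.allclose(grid.values[grid.valid_mask],
                           expect[grid.valid_mask], atol=1e-9)

    def test_reproduces_sample_values(self, rng):
        from scipy.interpolate import LinearNDInterpolator

        x = rng.uniform(-3, 3, 40)
        y = rng.uniform(-3, 3, 40)
        z = rng.uniform(5, 30, 40)
        # interpolant property: exact at the sample locations themselves
        interp = LinearNDInterpolator(np.column_stack([x, y]), z)
        np.testing.assert_allclose(interp(x, y), z, rtol=1e-9)
        # nearest grid pixel agrees within the local variation over one pixel
        grid = wf.interpolate_grid(samples_df(x, y, z), pixel_size=0.01)
        ny, nx = grid.values.shape
        for xi, yi, zi in zip(x, y, z):
            j = min(int(round((xi - grid.origin[0]) / grid.pixel_size)), nx - 1)
            i = min(int(round((yi - grid.origin[1]) / grid.pixel_size)), ny - 1)
            if not grid.valid_mask[i, j]:
                continue
            patch = grid.values[max(i - 1, 0):i + 2, max(j - 1, 0):j + 2]
            tol = np.nanmax(patch) - np.nanmin(patch) + 1e-9
            assert grid.values[i, j] == pytest.approx(zi, abs=tol)

    def test_too_few_or_collinear_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            wf.interpolate_grid(samples_df([0, 1], [0, 0], [1, 1]))
        with pytest.raises(ValueError, match="collinear"):
            wf.interpolate_grid(samples_df([0, 1, 2], [0, 0, 0], [1, 1, 1]))

    def test_conflicting_duplicates_named(self):
        s = samples_df([0, 1, 0, 0], [0, 0, 1, 0], [1, 1, 1, 2])
        with pytest.raises(ValueError, match=r"\(0, 0\)"):
            wf.interpolate_grid(s)


class TestAreas:
    def make_uniform(self, value=10.0, extent=2.0, px=0.05):
        s = dense_grid_samples(lambda X, Y: np.full_like(X, value),
                               lo=0.0, hi=extent, n=11)
        return wf.interpolate_grid(s, pixel_size=px)

    def test_uniform_grid_full_area(self):
        grid = self.make_uniform(10.0, extent=2.0, px=0.05)
        # hull covers the full 2 x 2 mm square
        assert wf.area_below(grid, 15.0) == pytest.approx(grid.valid_area)
        assert grid.valid_area == pytest.approx(4.0, rel=0.06)

    def test_threshold_below_minimum_gives_zero(self):
        grid = self.make_uniform(10.0)
        assert wf.area_below(grid, 5.0) == 0.0

    def test_bad_threshold_rejected(self):
        grid = self.make_uniform()
        with pytest.raises(ValueError, match="threshold"):
            wf.area_below(grid, 0.0)

    def test_radial_cone_disk_area(self):
        s = dense_grid_samples(lambda X, Y: 10.0 * np.hypot(X, Y) + 1e-9,
                               lo=-2, hi=2, n=81)
        grid = wf.interpolate_grid(s, pixel_size=0.02)
        area = wf.area_below(grid, 15.0)
        assert area == pytest.approx(np.pi * 1.5 ** 2, rel=0.02)

    def test_monotone_in_threshold_and_partition(self, rng):
        x, y = rng.uniform(-2, 2, (2, 60))
        z = rng.uniform(1, 30, 60)
        grid = wf.interpolate_grid(samples_df(x, y, z), pixel_size=0.05)
        areas = [wf.area_below(grid, t) for t in (2, 5, 10, 15, 25, 40)]
        assert all(a <= b + 1e-12 for a, b in zip(areas, areas[1:]))
        assert areas[-1] == pytest.approx(grid.valid_area)
        # exact partition: below-low + in-band + above-high = valid
        band = wf.BandSpec(5.0, 15.0)
        _, band_area = wf.competence_band_area(grid, band)
        below = wf.area_below(grid, band.low)
        strictly_above = grid.valid_mask & (grid.values > band.high)
        above = strictly_above.sum() * grid.pixel_size ** 2
        assert below + band_area + above == pytest.approx(grid.valid_area,
                                                          abs=1e-12)

    def test_band_masks_uniform_cases(self):
        grid10 = self.make_uniform(10.0)
        mask, area = wf.competence_band_area(grid10, wf.BandSpec())
        assert np.array_equal(mask, grid10.valid_mask)
        assert area == pytest.approx(grid10.valid_area)
        grid3 = self.make_uniform(3.0)
        _, area3 = wf.competence_band_area(grid3, wf.BandSpec())
        assert area3 == 0.0

    def test_lab_landscape_band_topology(self):
        """Band mask is a central disk: wound center in band, margin not."""
        cfg = wf.LandscapeConfig.preset("lab_pwd14")
        field, samples = wf.gen_stiffness_landscape(cfg)
        grid = wf.interpolate_grid(samples, pixel_size=0.1)
        mask, _ = wf.competence_band_area(grid, wf.BandSpec())
        X, Y = np.meshgrid(grid.x_coords, grid.y_coords)
        r = np.hypot(X, Y)
        center = grid.valid_mask & (r < 0.3 * cfg.wound_halfwidth)
        margin = grid.valid_mask & (r > 1.2 * cfg.wound_halfwidth)
        assert mask[center].all()
        assert not mask[margin].any()
        # topology: the band is one simply-connected central region, as in
        # the continuous field where K crosses 15 kPa at a single radius
        from scipy import ndimage
        _, n_comp = ndimage.label(mask)
        assert n_comp == 1
        cont = (field(X, Y) >= 5) & (field(X, Y) <= 15) & grid.valid_mask
        _, n_cont = ndimage.label(cont)
        assert n_cont == 1
        # overlap: a 4-arm transect renders the circular 15 kPa contour as a
        # polygon whose diagonal apothem is cos(45) of the arm radius, so the
        # recovered disk covers at least ~2/pi of the continuous one
        overlap = (mask & cont).sum() / max(cont.sum(), 1)
        assert overlap > 0.55

    def test_refinement_convergence(self):
        s = dense_grid_samples(lambda X, Y: 10.0 * np.hypot(X, Y) + 1e-9,
                               lo=-2, hi=2, n=41)
        coarse = wf.interpolate_grid(s, pixel_size=0.04)
        fine = wf.interpolate_grid(s, pixel_size=0.02)
        a1 = wf.area_below(coarse, 15.0)
        a2 = wf.area_below(fine, 15.0)
        assert abs(a1 - a2) < 2 * np.pi * 1.5 * 0.04 * 2  # perimeter bound


class TestRegression:
    def test_exact_line(self):
        table = pd.DataFrame({"area_mm2": [1.0, 2.0, 3.0, 4.0],
                              "follicles": 12.812 * np.array([1.0, 2, 3, 4])})
        reg = wf.regress_area_count(table)
        assert reg.slope == pytest.approx(12.812, abs=1e-12)
        assert reg.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_counts(self):
        table = pd.DataFrame({"area_mm2": [1.0, 2.0, 3.0],
                              "follicles": [7.0, 7.0, 7.0]})
        reg = wf.regress_area_count(table)
        assert reg.slope == 0.0
        assert reg.r_squared == 0.0

    def test_generator_truth_in_ci(self):
        cfg = wf.FollicleModelConfig(slope=2.0, intercept=0.0, noise_sd=1.0,
                                     n_wounds=50, area_range=(0.5, 4.0), seed=11)
        reg = wf.regress_area_count(wf.gen_follicle_dataset(cfg))
        lo, hi = reg.slope_ci95()
        assert lo <= 2.0 <= hi

    def test_degenerate_and_small_inputs_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            wf.regress_area_count([[1, 2], [2, 4]])
        with pytest.raises(ValueError, match="degenerate"):
            wf.regress_area_count([[1, 2], [1, 4], [1, 6]])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 50), b=st.floats(-20, 20),
           c=st.floats(0.1, 50), d=st.floats(-20, 20))
    def test_r_squared_affine_invariant(self, a, b, c, d):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 5, 30)
        y = 3 * x + rng.normal(0, 1, 30)
        r1 = wf.regress_area_count(np.column_stack([x, y])).r_squared
        r2 = wf.regress_area_count(np.column_stack([a * x + b,
                                                    c * y + d])).r_squared
        assert r2 == pytest.approx(r1, rel=1e-9)
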