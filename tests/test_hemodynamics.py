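"""Oscillatory shear index, quartic WSS normalization, CHP, peak patch."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from twascore import (
    SacExtremes,
    SacMask,
    ScalarField,
    Weighting,
    chp,
    compute_osi,
    osi_norm,
    peak_region,
    sac_extremes,
    wss_from_gradient,
    wss_magnitude_at,
    wss_norm,
)
from twascore.hemodynamics import default_diastolic_index

from conftest import full_reversal_series, single_face_series


class TestWssFromGradient:
    @pytest.mark.parametrize(
        "mu,rate,expected",
        [(0.004, 0.0, 0.0), (0.004, 250.0, 1.0), (1.0, 1.0, 1.0)],
    )
    def test_product(self, mu, rate, expected):
        assert wss_from_gradient(mu, rate) == pytest.approx(expected)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            wss_from_gradient(-0.004, 1.0)
        with pytest.raises(ValueError):
            wss_from_gradient(0.004, -1.0)


class TestWssMagnitude:
    @pytest.mark.parametrize(
        "vec,expected",
        [((3.0, 4.0, 0.0), 5.0), ((0.0, 0.0, 0.0), 0.0), ((1.0, 1.0, 1.0), np.sqrt(3))],
    )
    def test_norm(self, vec, expected):
        series = single_face_series([vec, vec, vec])
        assert wss_magnitude_at(series, 1).values[0] == pytest.approx(expected)

    def test_index_out_of_range(self):
        series = single_face_series([(1, 0, 0)] * 3)
        with pytest.raises(IndexError):
            wss_magnitude_at(series, 3)


class TestOsi:
    def test_constant_direction_is_zero(self):
        # varying magnitude, fixed direction: no oscillation
        series = single_face_series([(2, 0, 0), (5, 0, 0), (1, 0, 0), (3, 0, 0)])
        assert compute_osi(series).values[0] == pytest.approx(0.0, abs=1e-15)

    def test_full_reversal_is_half_exactly(self):
        assert compute_osi(full_reversal_series()).values[0] == 0.5

    def test_engineered_integral_ratio(self):
        # trapezoid on [0, .5, 1]: integral = (f0 + 2 f1 + f2)/4
        # x-components (1.2, 1.0, -0.8): net 0.6, magnitude 1.0 -> OSI 0.2
        series = single_face_series([(1.2, 0, 0), (1.0, 0, 0), (-0.8, 0, 0)])
        assert compute_osi(series).values[0] == pytest.approx(0.2, abs=1e-12)

    def test_matches_hand_trapezoid_on_random_series(self):
        rng = np.random.default_rng(42)
        vecs = rng.normal(size=(5, 3))
        times = np.array([0.0, 0.2, 0.45, 0.7, 1.0])
        series = single_face_series(vecs, times=times)
        num = np.linalg.norm(np.trapezoid(vecs, x=times, axis=0))
        den = np.trapezoid(np.linalg.norm(vecs, axis=1), x=times)
        assert compute_osi(series).values[0] == pytest.approx(
            0.5 * (1 - num / den), abs=1e-12
        )

    def test_periodic_closure_uses_wrap_interval(self):
        # samples stop short of the period; the wrap back to the first sample
        # must enter the quadrature
        vecs = [(1.0, 0, 0), (1.0, 0, 0), (-1.0, 0, 0), (-1.0, 0, 0)]
        times = np.array([0.0, 0.25, 0.5, 0.75])
        series = single_face_series(vecs, times=times, period=1.0)
        assert compute_osi(series).values[0] == 0.5

    @pytest.mark.parametrize("scale", [0.3, 2.0, 117.0])
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(3)
        vecs = rng.normal(size=(9, 3))
        base = compute_osi(single_face_series(vecs)).values[0]
        scaled = compute_osi(single_face_series(scale * vecs)).values[0]
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_zero_flow_face_gets_zero(self):
        series = single_face_series([(0, 0, 0)] * 4)
        assert compute_osi(series).values[0] == 0.0

    def test_rejects_non_monotonic_times(self):
        with pytest.raises(ValueError):
            single_face_series([(1, 0, 0)] * 3, times=[0.0, 0.5, 0.4])

    def test_range_on_random_fields(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            vals = compute_osi(single_face_series(rng.normal(size=(7, 3)))).values
            assert 0.0 <= vals[0] <= 0.5


class TestSacExtremes:
    def _field(self, vals):
        return ScalarField(np.asarray(vals, dtype=float), "wss_magnitude")

    def test_extremes_over_sac(self):
        mask = SacMask(np.array([True, True, True]))
        ext = sac_extremes(self._field([0.2, 1.0, 3.0]), mask)
        assert (ext.wss_min, ext.wss_max) == (0.2, 3.0)

    def test_non_sac_faces_ignored(self):
        mask = SacMask(np.array([True, True, False]))
        ext = sac_extremes(self._field([0.2, 1.0, 99.0]), mask)
        assert ext.wss_max == 1.0

    def test_degenerate_range_errors(self):
        mask = SacMask(np.array([True, True]))
        with pytest.raises(ValueError, match="degenerate"):
            sac_extremes(self._field([1.0, 1.0]), mask)


class TestWssNorm:
    EXT = SacExtremes(wss_min=0.1, wss_max=2.0)

    def _norm(self, wss):
        field = ScalarField(np.atleast_1d(np.asarray(wss, float)), "wss_magnitude")
        return wss_norm(field, self.EXT).values

    def test_boundaries(self):
        assert self._norm(self.EXT.wss_max)[0] == 0.0
        assert self._norm(self.EXT.wss_min)[0] == 1.0

    def test_midpoint_root(self):
        mid = 0.5 * (self.EXT.wss_min + self.EXT.wss_max)
        expected = 1.0 - (15.0 / 16.0) ** 0.25  # quartic root at u = -1/2
        assert self._norm(mid)[0] == pytest.approx(expected, abs=1e-12)

    def test_quartic_residual_on_dense_grid(self):
        wss = np.linspace(self.EXT.wss_min, self.EXT.wss_max, 2001)
        x = self._norm(wss)
        u = (wss - self.EXT.wss_max) / self.EXT.span
        residual = (x - 1.0) ** 4 + u**4
        assert np.abs(residual - 1.0).max() <= 1e-9

    def test_monotone_non_increasing(self):
        wss = np.linspace(self.EXT.wss_min, self.EXT.wss_max, 2001)
        x = self._norm(wss)
        assert (np.diff(x) <= 1e-15).all()

    def test_out_of_range_values_clamped(self):
        x = self._norm([0.0, 5.0])
        assert x[0] == 1.0 and x[1] == 0.0


class TestOsiNormAndChp:
    def test_doubling(self):
        osi = ScalarField(np.array([0.0, 0.5, 0.073]), "osi")
        assert osi_norm(osi).values == pytest.approx([0.0, 1.0, 0.146])

    def test_rejects_out_of_range_osi(self):
        with pytest.raises(ValueError):
            ScalarField(np.array([0.6]), "osi")

    def test_midpoint_weighting(self):
        w = Weighting(0.5, 0.5)
        out = chp(
            ScalarField(np.array([0.8]), "wss_norm"),
            ScalarField(np.array([0.2]), "osi_norm"),
            w,
        )
        assert out.values[0] == pytest.approx(0.5)

    def test_w1_one_is_wssnorm(self):
        rng = np.random.default_rng(5)
        wssn = ScalarField(rng.uniform(size=30), "wss_norm")
        osin = ScalarField(rng.uniform(size=30), "osi_norm")
        assert chp(wssn, osin, Weighting(1.0, 0.0)).values == pytest.approx(wssn.values)
        assert chp(wssn, osin, Weighting(0.0, 1.0)).values == pytest.approx(osin.values)

    def test_mean_linear_in_w1(self):
        rng = np.random.default_rng(6)
        wssn = ScalarField(rng.uniform(size=50), "wss_norm")
        osin = ScalarField(rng.uniform(size=50), "osi_norm")
        means = {
            w1: chp(wssn, osin, Weighting.from_w1(w1)).values.mean()
            for w1 in (0.0, 0.5, 1.0)
        }
        assert means[0.5] == pytest.approx(
            0.5 * (means[0.0] + means[1.0]), abs=1e-12
        )

    def test_mismatched_faces_error(self):
        with pytest.raises(ValueError):
            chp(
                ScalarField(np.zeros(3), "wss_norm"),
                ScalarField(np.zeros(4), "osi_norm"),
                Weighting(0.5, 0.5),
            )

    def test_weights_validated(self):
        with pytest.raises(ValueError):
            Weighting(0.7, 0.7)
        with pytest.raises(ValueError):
            Weighting(-0.1, 1.1)


class TestPeakRegion:
    def test_radius_zero_is_extreme_face(self, default_case):
        from twascore.hemodynamics import wss_magnitude_at

        case = default_case
        field = wss_magnitude_at(case.series, 0)
        peak = peak_region(field, case.sac_mask, case.series.mesh, 0.0, mode="min")
        sac_vals = np.where(case.sac_mask.member, field.values, np.inf)
        assert peak.seed_face == int(np.argmin(sac_vals))
        assert peak.patch_faces.tolist() == [peak.seed_face]

    def test_uniform_field_tie_breaks_to_lowest_sac_face(self, default_case):
        case = default_case
        m = case.series.mesh.n_faces
        field = ScalarField(np.full(m, 0.3), "chp")
        peak = peak_region(field, case.sac_mask, case.series.mesh, 0.5)
        assert peak.seed_face == int(case.sac_mask.indices[0])

    def test_patch_mean_is_area_weighted(self, default_case):
        case = default_case
        mesh = case.series.mesh
        rng = np.random.default_rng(1)
        field = ScalarField(rng.uniform(size=mesh.n_faces), "chp")
        peak = peak_region(field, case.sac_mask, mesh, 0.7)
        expected = np.average(
            field.values[peak.patch_faces], weights=mesh.face_areas[peak.patch_faces]
        )
        assert peak.patch_mean == pytest.approx(expected, abs=1e-12)

    def test_planted_low_wss_patch_recovered(self, default_case):
        from twascore import RunConfig
        from twascore.pipeline import score_surface

        case = default_case
        _, _, peak, _ = score_surface(case.series, case.sac_mask, RunConfig(w1=1.0))
        assert case.ground_truth.twa_face_mask[peak.seed_face]

    def test_empty_mask_unconstructible(self):
        with pytest.raises(ValueError):
            SacMask(np.zeros(5, dtype=bool))


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    data=st_.lists(
        st_.tuples(
            st_.floats(-10, 10), st_.floats(-10, 10), st_.floats(-10, 10)
        ),
        min_size=3,
        max_size=12,
    ),
    scale=st_.floats(0.01, 100.0),
)
def test_osi_bounds_and_scale_invariance_property(data, scale):
    vecs = np.asarray(data)
    osi = compute_osi(single_face_series(vecs)).values[0]
    assert 0.0 <= osi <= 0.5
    rescaled = compute_osi(single_face_series(scale * vecs)).values[0]
    assert rescaled == pytest.approx(osi, abs=1e-9)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    lo=st_.floats(0.0, 5.0),
    span=st_.floats(0.01, 20.0),
    frac=st_.floats(0.0, 1.0),
)
def test_quartic_residual_property(lo, span, frac):
    ext = SacExtremes(wss_min=lo, wss_max=lo + span)
    wss = lo + frac * span
    x = wss_norm(ScalarField(np.array([wss]), "wss_magnitude"), ext).values[0]
    u = (wss - ext.wss_max) / ext.span
    assert 0.0 <= x <= 1.0
    assert (x - 1.0) ** 4 + u**4 == pytest.approx(1.0, abs=1e-9)


def test_default_diastolic_index_minimizes_sac_wss(default_case):
    case = default_case
    idx = default_diastolic_index(case.series, case.sac_mask)
    w = case.series.mesh.face_areas[case.sac_mask.member]
    mags = np.linalg.norm(
        case.series.wss_vectors[:, case.sac_mask.member, :], axis=2
    )
    assert idx == int(np.argmin(mags @ w))
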