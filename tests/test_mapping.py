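"""Invariant, cubic-phase fraction, map assembly and layering."""

import numpy as np
import pytest

from conftest import process
from mesomap.containers import RasterScan, ScatteringCurve
from mesomap.lineshapes import pseudo_voigt
from mesomap.mapping import (Layer, assemble_map, cubic_fraction,
                             fd3m_ladder_factor, invariant, radial_profile,
                             segment_layers)
from mesomap.phases import get_phase
from mesomap.synthetic import (DEFAULT_Q_GRID, generate_curve,
                               generate_raster, make_depot_scenario,
                               scenario_one_day)


class TestInvariant:
    def test_closed_form_constant_intensity(self):
        # I = 2 on q in [0, 0.3]: Q = 2 * 0.3^3 / 3 = 0.018
        q = np.linspace(0.0, 0.3, 2001)
        curve = ScatteringCurve(q, np.full(q.size, 2.0))
        assert invariant(curve) == pytest.approx(0.018, rel=1e-5)

    def test_zero_intensity_gives_zero(self):
        q = DEFAULT_Q_GRID
        assert invariant(ScatteringCurve(q, np.zeros(q.size))) == 0.0

    def test_matches_generator_components(self, fd3m_curve):
        """Q agrees with brute-force integration of the analytic
        background plus each pseudo-Voigt component."""
        q = fd3m_curve.q
        meta = fd3m_curve.metadata
        b, p, c = meta["background"]
        expected = b * q ** (-p) + c
        for center, area in zip(meta["peak_centers"], meta["peak_areas"]):
            expected = expected + pseudo_voigt(q, center, meta["peak_fwhm"],
                                               meta["peak_eta"], area)
        assert invariant(fd3m_curve) == pytest.approx(
            float(np.trapezoid(q ** 2 * expected, q)), rel=5e-3)

    def test_doubling_intensity_doubles_q(self, fd3m_curve):
        doubled = fd3m_curve.with_intensity(2 * fd3m_curve.intensity)
        assert invariant(doubled) == pytest.approx(2 * invariant(fd3m_curve),
                                                   rel=1e-12)

    def test_rejects_single_point(self):
        with pytest.raises(ValueError):
            invariant(ScatteringCurve(np.array([0.1]), np.array([1.0])))


class TestCubicFraction:
    def test_pure_fd3m_reads_one(self, fd3m_curve):
        sub, _ = process(fd3m_curve)
        assert cubic_fraction(sub) == pytest.approx(1.0, abs=0.05)

    def test_lone_111_peak_reads_one(self):
        q = DEFAULT_Q_GRID
        y = pseudo_voigt(q, 0.0633, 0.0025, eta=0.2, area=1.0)
        assert cubic_fraction(ScatteringCurve(q, y)) == 1.0

    def test_peak_free_curve_reads_zero(self):
        q = DEFAULT_Q_GRID
        assert cubic_fraction(ScatteringCurve(q, np.zeros(q.size))) == 0.0

    def test_non_cubic_phase_reads_zero(self):
        curve = generate_curve([("H2", 52.0, 1.0)])
        sub, _ = process(curve)
        assert cubic_fraction(sub) == 0.0

    def test_thirty_percent_cubic_mixture(self):
        """A two-phase curve built so the cubic ladder carries 30 % of
        the total peak invariant reads 0.30; the expected share comes
        from brute-force integration of the generator components."""

        def ladder_invariant(name, a, w):
            pat = get_phase(name)
            pos = pat.peak_positions(a)
            k = np.arange(pos.size)
            areas = w * 0.5 ** k / np.sum(0.5 ** k)
            keep = (pos >= 0.016) & (pos <= 0.85)
            q = DEFAULT_Q_GRID
            total = 0.0
            for c, ar in zip(pos[keep], areas[keep]):
                total += np.trapezoid(
                    q ** 2 * pseudo_voigt(q, c, 0.0025, 0.2, ar), q)
            return total

        # solve the Fd3m weight giving a 30 % invariant share vs H2
        qf1 = ladder_invariant("Fd3m", 160.0, 1.0)
        qh1 = ladder_invariant("H2", 52.0, 1.0)
        w_f = 0.30 * qh1 / (0.70 * qf1)  # share = wf*qf1/(wf*qf1+qh1)
        share = w_f * qf1 / (w_f * qf1 + qh1)
        assert share == pytest.approx(0.30, rel=1e-6)

        curve = generate_curve([("Fd3m", 160.0, w_f), ("H2", 52.0, 1.0)])
        sub, _ = process(curve)
        assert cubic_fraction(sub) == pytest.approx(0.30, abs=0.02)

    def test_invariant_under_global_scaling(self, fd3m_curve):
        sub, _ = process(fd3m_curve)
        scaled = sub.with_intensity(3.7 * sub.intensity)
        if scaled.sigma is not None:
            scaled.sigma = scaled.sigma * 3.7
        assert cubic_fraction(scaled) == pytest.approx(cubic_fraction(sub),
                                                       rel=1e-6)

    def test_monotone_in_fd3m_weight(self):
        fractions = []
        for w in (0.2, 0.5, 1.0, 2.0):
            curve = generate_curve([("Fd3m", 160.0, w), ("H2", 52.0, 1.0)])
            sub, _ = process(curve)
            fractions.append(cubic_fraction(sub))
        assert np.all(np.diff(fractions) > 0)

    def test_ladder_factor_value(self):
        # sum over N/3 * 0.5^k for N = 3,8,11,12,16,19,24,27
        assert fd3m_ladder_factor() == pytest.approx(4.4766, abs=1e-4)


class TestAssembleMap:
    def test_one_day_fraction_zero_in_rim_and_core(self, one_day_map):
        pmap = one_day_map
        yy, xx = np.meshgrid(pmap.y_mm, pmap.x_mm, indexing="ij")
        r = np.hypot(xx, yy)
        core = pmap.mask & (r < 1.0)
        annulus = pmap.mask & (r > 2.6) & (r < 3.2)
        rim = pmap.mask & (r > 3.6)
        assert np.nanmean(pmap.fraction[core]) < 0.05
        assert np.nanmean(pmap.fraction[annulus]) > 0.8
        assert np.nanmean(pmap.fraction[rim]) < 0.05

    def test_four_week_center_dominated_by_cubic(self, four_week_map):
        pmap = four_week_map
        yy, xx = np.meshgrid(pmap.y_mm, pmap.x_mm, indexing="ij")
        r = np.hypot(xx, yy)
        center = pmap.mask & (r < 1.5)
        assert np.nanmean(pmap.fraction[center]) > 0.9

    def test_mask_covers_depot_not_buffer(self, one_day_map):
        pmap = one_day_map
        yy, xx = np.meshgrid(pmap.y_mm, pmap.x_mm, indexing="ij")
        r = np.hypot(xx, yy)
        assert pmap.mask[r < 3.9].all()
        assert not pmap.mask[r > 4.1].any()

    def test_all_buffer_raster_has_empty_mask(self):
        scen = scenario_one_day()
        scan = generate_raster(scen, pixel_pitch=1.0)
        buffer_only = RasterScan(
            scan.q,
            np.tile(scan.intensities[0], (9, 1)),  # corner pixel = buffer
            np.repeat(np.arange(3.0), 3), np.tile(np.arange(3.0), 3), 1.0)
        assert not scan.truth["in_depot"][0]
        pmap = assemble_map(buffer_only)
        assert not pmap.mask.any()

    def test_duplicate_pixels_rejected(self):
        q = DEFAULT_Q_GRID
        scan = RasterScan(q, np.ones((2, q.size)), np.zeros(2), np.zeros(2),
                          0.05)
        with pytest.raises(ValueError, match="duplicate"):
            assemble_map(scan)

    def test_map_determinism(self):
        scan = generate_raster(scenario_one_day(), pixel_pitch=1.0)
        m1, m2 = assemble_map(scan), assemble_map(scan)
        assert np.array_equal(m1.fraction, m2.fraction)
        assert np.array_equal(m1.lattice, m2.lattice, equal_nan=True)


class TestRadialProfile:
    def test_constant_map_gives_constant_profile(self, one_day_map):
        pmap = one_day_map
        import copy
        flat = copy.copy(pmap)
        flat.fraction = np.where(np.isnan(pmap.fraction), np.nan, 0.6)
        prof = radial_profile(flat)
        vals = prof.mean_fraction[prof.counts > 0]
        assert np.allclose(vals, 0.6)

    def test_matches_generator_radial_truth(self, one_day_profile):
        scen = scenario_one_day()
        prof = one_day_profile
        for r, f, n in zip(prof.radius_mm, prof.mean_fraction, prof.counts):
            if n == 0 or r > scen.depot_radius_mm - 0.3:
                continue
            layer = scen.layer_at(r)
            expected = 1.0 if layer.phase == "Fd3m" else 0.0
            # annuli straddling a layer boundary may blend
            near_boundary = any(
                abs(r - ly.outer_radius_mm) < 0.45 for ly in scen.layers)
            if not near_boundary:
                assert f == pytest.approx(expected, abs=0.1)

    def test_lattice_profile_increases_with_radius(self, four_week_profile):
        prof = four_week_profile
        sel = np.isfinite(prof.mean_lattice)
        a = prof.mean_lattice[sel]
        assert a[0] < 160.0
        assert np.all(np.diff(a) > -0.5)
        assert a.max() > 168.0

    def test_center_outside_mask_rejected(self, one_day_map):
        with pytest.raises(ValueError, match="outside"):
            radial_profile(one_day_map, center=(10.0, 10.0))


class TestSegmentLayers:
    def test_one_day_has_three_layers(self, one_day_profile):
        layers = segment_layers(one_day_profile, 0.25)
        assert [ly.kind for ly in layers] == ["non-cubic", "cubic",
                                              "non-cubic"]

    def test_four_week_has_two_layers(self, four_week_profile):
        layers = segment_layers(four_week_profile, 0.25)
        assert [ly.kind for ly in layers] == ["cubic", "non-cubic"]

    def test_uniform_cubic_profile_is_one_layer(self, one_day_profile):
        import copy
        prof = copy.copy(one_day_profile)
        prof.mean_fraction = np.where(prof.counts > 0, 0.9, np.nan)
        assert len(segment_layers(prof, 0.25)) == 1

    def test_threshold_validation_and_empty_profile(self, one_day_profile):
        with pytest.raises(ValueError):
            segment_layers(one_day_profile, 1.5)
        import copy
        empty = copy.copy(one_day_profile)
        empty.counts = np.zeros_like(empty.counts)
        with pytest.raises(ValueError, match="no populated"):
            segment_layers(empty, 0.25)


def test_higher_spc_scenario_has_thicker_cubic_free_rim():
    """A 56:44 SPC/GDO depot shows a thicker cubic-free outer layer
    than the 50:50 depot at the same age."""

    def rim_thickness(spc):
        scen = make_depot_scenario(7.0, spc_fraction=spc)
        scan = generate_raster(scen, pixel_pitch=0.2)
        layers = segment_layers(radial_profile(assemble_map(scan)), 0.25)
        assert layers[-1].kind == "non-cubic"
        return layers[-1].r_outer - layers[-1].r_inner

    assert rim_thickness(0.56) > rim_thickness(0.50)
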