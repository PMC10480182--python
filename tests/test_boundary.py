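"""Inlet construction: intensity relations, profile extraction and mapping."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from stenoflow import (
    InletSpec,
    ValidationError,
    build_geometry,
    build_uniform_ti_inlet,
    eps_from_mixing_length,
    extract_plane_profile,
    generate_mesh,
    intensity_from_reynolds,
    k_from_intensity,
    map_profile_to_inlet,
    ti_inlet_from_profile,
)
from stenoflow.boundary import C_MU, PlaneProfile


class TestIntensityRelations:
    @pytest.mark.parametrize(
        "U,I,expected",
        [
            (0.66, 0.05, 0.0016335),  # reference inlet: 0.66 m/s at 5%
            (3.0, 0.0, 0.0),
            (1.0, 1.0, 1.5),
        ],
    )
    def test_k_from_intensity(self, U, I, expected):
        assert k_from_intensity(U, I) == pytest.approx(expected, rel=1e-12)

    def test_k_negative_rejected(self):
        with pytest.raises(ValidationError):
            k_from_intensity(-1.0, 0.05)
        with pytest.raises(ValidationError):
            k_from_intensity(1.0, -0.05)

    @given(
        u=st.floats(0.01, 100.0), i=st.floats(0.001, 1.0),
        a=st.floats(0.1, 10.0),
    )
    @hyp_settings(max_examples=50, derandomize=True)
    def test_k_homogeneous_degree_two(self, u, i, a):
        assert k_from_intensity(a * u, i) == pytest.approx(
            a**2 * k_from_intensity(u, i), rel=1e-9
        )
        assert k_from_intensity(u, a * i) == pytest.approx(
            a**2 * k_from_intensity(u, i), rel=1e-9
        )

    def test_intensity_from_reynolds_values(self):
        # fully developed duct-core intensity at the study Reynolds number
        assert intensity_from_reynolds(4000.0) == pytest.approx(0.0567, abs=5e-4)
        assert intensity_from_reynolds(1.0) == pytest.approx(0.16)

    @given(st.floats(10.0, 1e8), st.floats(1.001, 100.0))
    @hyp_settings(max_examples=50, derandomize=True)
    def test_intensity_monotone_decreasing(self, re, factor):
        assert intensity_from_reynolds(re * factor) < intensity_from_reynolds(re)

    def test_intensity_invalid(self):
        with pytest.raises(ValidationError):
            intensity_from_reynolds(0.0)

    def test_eps_from_mixing_length_oracle(self):
        k, l = 0.0016335, 0.0014
        expected = C_MU**0.75 * k**1.5 / l
        assert eps_from_mixing_length(k, l) == pytest.approx(expected, rel=1e-12)
        assert eps_from_mixing_length(0.0, l) == 0.0

    def test_eps_halves_when_length_doubles(self):
        k = 0.01
        assert eps_from_mixing_length(k, 0.002) == pytest.approx(
            0.5 * eps_from_mixing_length(k, 0.001), rel=1e-12
        )
        with pytest.raises(ValidationError):
            eps_from_mixing_length(k, 0.0)


def _profile(positions, u, k, v=None, areas=None):
    positions = np.asarray(positions, float)
    u = np.asarray(u, float)
    n = len(positions)
    if areas is None:
        areas = np.full(n, (positions[-1] - positions[0]) / max(n - 1, 1))
    return PlaneProfile(
        station_label="apex",
        positions=positions,
        u_normal=u,
        u_transverse=np.zeros(n) if v is None else np.asarray(v, float),
        k=np.asarray(k, float),
        face_areas=np.asarray(areas, float),
        mass_flux=float(np.sum(u * areas)),
        lumen_halfwidth=float(0.5 * (positions[-1] - positions[0])),
    )


class TestExtractionAndMapping:
    @pytest.fixture(scope="class")
    def duct_flow(self):
        """Converged uniform-ish duct flow for extraction checks."""
        from stenoflow import SolverSettings, solve_steady_rans
        from .conftest import BLOOD, make_uniform_inlet

        g = build_geometry(0.02, 0.0, inlet_run=2, stenosis_length=2, outlet_run=4)
        m = generate_mesh(g, 48, 16, 1.15, "planar")
        inlet = build_uniform_ti_inlet(0.66, 0.05, 0.0014, m)
        flow, rep = solve_steady_rans(m, inlet, BLOOD, SolverSettings())
        assert rep.converged
        return g, m, flow

    def test_profile_mass_flux_matches_station(self, duct_flow):
        from stenoflow import CutPlane

        g, m, flow = duct_flow
        cp = CutPlane("mid", 0.08)
        prof = extract_plane_profile(flow, m, cp)
        icol = int(np.argmin(np.abs(m.axial_nodes - 0.08)))
        assert prof.mass_flux == pytest.approx(float(flow.Fx[icol].sum()), rel=1e-12)
        # conservation: equals the inlet mass flux of the full model
        assert prof.mass_flux == pytest.approx(float(flow.Fx[0].sum()), rel=1e-8)

    def test_node_coincident_mapping_is_exact(self, duct_flow):
        from stenoflow import CutPlane, extract_submodel_mesh

        g, m, flow = duct_flow
        cp = CutPlane("mid", 0.08)
        sub = extract_submodel_mesh(m, cp)
        prof = extract_plane_profile(flow, m, cp)
        spec = map_profile_to_inlet(prof, sub, 0.000375)
        assert spec.mode == "mapped_profile"
        assert np.array_equal(spec.u, prof.u_normal)
        assert np.array_equal(spec.k, prof.k)
        assert np.allclose(
            spec.eps, eps_from_mixing_length(prof.k, 0.000375), rtol=1e-14
        )

    def test_linear_interpolation_between_samples(self):
        """A profile sampled at 2x resolution maps by exact linear interp."""
        g = build_geometry(0.02, 0.0, inlet_run=1, stenosis_length=1, outlet_run=2)
        sub = generate_mesh(g, 32, 8, 1.0, "planar")
        targets = sub.fmid_x[0, :, 1]
        fine = np.linspace(-0.011, 0.011, 45)
        u = 1.0 + 30.0 * fine  # linear in position
        k = 0.01 + np.abs(fine)
        prof = _profile(fine, u, k)
        spec = map_profile_to_inlet(prof, sub, 0.001)
        expect_k = np.interp(targets, fine, k)
        assert np.allclose(spec.k, expect_k, rtol=1e-12)
        # velocity rescaled by one global flux factor: still linear in y
        ratio = spec.u / np.interp(targets, fine, u)
        assert np.allclose(ratio, ratio[0], rtol=1e-9)

    def test_constant_profile_maps_constant(self):
        g = build_geometry(0.02, 0.0, inlet_run=1, stenosis_length=1, outlet_run=2)
        sub = generate_mesh(g, 32, 10, 1.3, "planar")
        pos = np.linspace(-0.0099, 0.0099, 21)
        prof = _profile(pos, np.full(21, 0.7), np.full(21, 0.004))
        spec = map_profile_to_inlet(prof, sub, 0.001)
        assert np.allclose(spec.k, 0.004, rtol=1e-12)
        assert np.allclose(spec.u, spec.u[0], rtol=1e-12)

    def test_narrow_profile_rejected(self):
        g = build_geometry(0.02, 0.0, inlet_run=1, stenosis_length=1, outlet_run=2)
        sub = generate_mesh(g, 32, 8, 1.0, "planar")
        pos = np.linspace(-0.002, 0.002, 9)  # much narrower than the inlet
        prof = _profile(pos, np.ones(9), np.full(9, 0.01))
        with pytest.raises(ValidationError):
            map_profile_to_inlet(prof, sub, 0.001)


class TestTIInlets:
    def test_uniform_ti_inlet_constant_k(self):
        g = build_geometry(0.02, 0.0, inlet_run=1, stenosis_length=1, outlet_run=2)
        m = generate_mesh(g, 32, 8, 1.0, "planar")
        spec = build_uniform_ti_inlet(0.66, 0.05, 0.000375, m)
        assert spec.mode == "uniform_TI"
        assert np.allclose(spec.k, 0.0016335, rtol=1e-12)
        assert np.allclose(spec.u, 0.66)
        # zero intensity: laminar-like inlet
        spec0 = build_uniform_ti_inlet(0.66, 0.0, 0.000375, m)
        assert np.all(spec0.k == 0.0)

    def test_ti_inlet_determinism(self):
        g = build_geometry(0.02, 0.0, inlet_run=1, stenosis_length=1, outlet_run=2)
        m = generate_mesh(g, 32, 8, 1.0, "planar")
        a = build_uniform_ti_inlet(0.66, 0.10, 0.000375, m)
        b = build_uniform_ti_inlet(0.66, 0.10, 0.000375, m)
        assert np.array_equal(a.k, b.k) and np.array_equal(a.u, b.u)

    def test_local_ti_uses_local_velocity(self):
        g = build_geometry(0.02, 0.0, inlet_run=1, stenosis_length=1, outlet_run=2)
        sub = generate_mesh(g, 32, 8, 1.0, "planar")
        targets = sub.fmid_x[0, :, 1]
        pos = np.linspace(-0.011, 0.011, 23)
        u = 2.0 - 100.0 * np.abs(pos)  # peaked profile
        prof = _profile(pos, u, np.full(23, 0.01))
        spec = ti_inlet_from_profile(prof, 0.10, 0.000375, sub)
        assert spec.mode == "local_TI"
        expected = 1.5 * (np.hypot(spec.u, spec.v) * 0.10) ** 2
        assert np.allclose(spec.k, expected, rtol=1e-12)

    def test_invalid_inlet_values_rejected(self):
        with pytest.raises(ValidationError):
            InletSpec("uniform_TI", np.array([np.nan]), np.zeros(1),
                      np.zeros(1), np.zeros(1), 1.0)
        with pytest.raises(ValidationError):
            InletSpec("uniform_TI", np.ones(1), np.zeros(1),
                      -np.ones(1), np.zeros(1), 1.0)
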