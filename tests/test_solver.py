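import numpy as np
import pytest

from vesselrom import (
    MeshResolution,
    ReferenceVessel,
    RheologyParams,
    SolverConfig,
    build_mesh,
    get_solver,
    kinematic_viscosity,
    solve_flow,
    wall_shear_rate,
)

RES = MeshResolution(101, 8, 2)


def tube(radius_profile, length=30.0):
    n = RES.n_axial
    s = np.linspace(0.0, length, n)
    r = np.broadcast_to(radius_profile, (n,)).astype(float).copy() \
        if np.isscalar(radius_profile) else np.asarray(radius_profile, float)
    ref = ReferenceVessel(id="tube", length=length, stations=s, radius=r)
    return build_mesh(r, ref, RES)


class TestCarreauYasuda:
    def test_zero_shear_limit_is_nu0(self):
        assert kinematic_viscosity(0.0) == pytest.approx(56e-6, rel=1e-12)

    def test_infinite_shear_limit_is_nu_inf(self):
        assert kinematic_viscosity(1e12) == pytest.approx(3.45e-6, rel=1e-4)

    def test_value_at_reciprocal_relaxation_time(self):
        # direct evaluation of the formula at gamma = 1/tau:
        # nu_inf + (nu0 - nu_inf) * 2^((n-1)/alpha)
        p = RheologyParams()
        expected = p.nu_inf + (p.nu_0 - p.nu_inf) * 2.0 ** ((p.n - 1.0) / p.alpha)
        assert expected == pytest.approx(45.5e-6, rel=1e-2)  # ~45.5e-6 m^2/s
        assert kinematic_viscosity(1.0 / p.tau) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing_and_bounded(self):
        gammas = np.logspace(-3, 6, 200)
        nus = kinematic_viscosity(gammas)
        assert np.all(np.diff(nus) < 0)
        assert np.all(nus > 3.45e-6) and np.all(nus <= 56e-6)

    def test_negative_shear_rejected(self):
        with pytest.raises(ValueError):
            kinematic_viscosity(-1.0)

    def test_invalid_coefficients_rejected(self):
        with pytest.raises(ValueError):
            RheologyParams(nu_inf=5e-6, nu_0=4e-6)
        with pytest.raises(ValueError):
            RheologyParams(n=1.2)


class TestWallShearRate:
    def test_unit_case(self):
        assert wall_shear_rate(np.pi / 4, 1.0) == pytest.approx(1.0)

    def test_inverse_cube_scaling(self):
        g1 = wall_shear_rate(1e-6, 2e-3)
        g2 = wall_shear_rate(1e-6, 1e-3)
        assert g2 == pytest.approx(8.0 * g1)

    def test_poiseuille_mean_velocity_identity(self):
        # gamma_w = 4Q/(pi r^3) must equal 4U/r when Q = U pi r^2
        u, r = 1.0, 1.5e-3
        q = u * np.pi * r**2
        assert wall_shear_rate(q, r) == pytest.approx(4 * u / r, rel=1e-12)
        assert wall_shear_rate(q, r) == pytest.approx(2.667e3, rel=1e-3)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            wall_shear_rate(0.0, 1.0)
        with pytest.raises(ValueError):
            wall_shear_rate(1.0, -1.0)


class TestSolveFlow:
    def test_newtonian_limit_matches_poiseuille(self):
        # uniform tube with nu0 = nu_inf: analytic dp = 8 rho nu L Q / (pi r^4)
        nu = 3.45e-6
        rheo = RheologyParams(nu_inf=nu, nu_0=nu * (1 + 1e-12))
        cfg = SolverConfig()
        geom = tube(1.5)
        sol = solve_flow(geom, cfg, rheo)
        r, length = 1.5e-3, 30e-3
        q = 1.0 * np.pi * r**2
        dp_exact = 8 * cfg.density * nu * length * q / (np.pi * r**4)
        assert sol.station_pressure[0] == pytest.approx(dp_exact, rel=1e-3)
        # linear pressure profile, constant WSS
        assert np.allclose(np.diff(sol.station_pressure, 2), 0.0, atol=1e-9 * dp_exact)
        assert np.ptp(sol.station_wss) < 1e-12 * sol.station_wss[0]

    def test_outlet_pressure_zero(self, small_sols, small_geoms):
        for g, sol in zip(small_geoms[:5], small_sols[:5]):
            outlet = g.volume_station_index == g.resolution.n_axial - 1
            assert np.all(sol.pressure[outlet] == 0.0)

    def test_pressure_monotone_and_wss_positive(self, small_sols):
        for sol in small_sols:
            assert np.all(np.diff(sol.station_pressure) <= 0)
            assert np.all(sol.wss > 0)

    def test_constriction_raises_local_wss(self):
        # 10% mid-vessel constriction: throat WSS strictly above inlet WSS,
        # matching the 1/r^3 dependence evaluated on the profile directly
        n = RES.n_axial
        s = np.linspace(0, 30.0, n)
        r = 1.5 * (1 - 0.10 * np.exp(-(((s - 15.0) / 3.0) ** 2)))
        sol = solve_flow(tube(r))
        throat = np.argmin(r)
        assert np.argmax(sol.station_wss) == throat
        assert sol.station_wss[throat] > sol.station_wss[0]

    def test_station_values_broadcast_to_nodes(self, small_geoms, small_sols):
        g, sol = small_geoms[0], small_sols[0]
        assert np.array_equal(sol.wss, sol.station_wss[g.surface_station_index])
        assert np.array_equal(sol.pressure, sol.station_pressure[g.volume_station_index])

    def test_viscosity_evaluations_within_bounds(self, small_geoms):
        rheo = RheologyParams()
        for g in small_geoms[:5]:
            q = 1.0 * np.pi * (g.radius[0] * 1e-3) ** 2
            gam = wall_shear_rate(q, g.radius * 1e-3)
            nu = kinematic_viscosity(gam, rheo)
            assert np.all((nu > rheo.nu_inf) & (nu <= rheo.nu_0))

    def test_registry_roundtrip(self):
        assert get_solver("quasi1d") is solve_flow
        with pytest.raises(KeyError):
            get_solver("no-such-backend")
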