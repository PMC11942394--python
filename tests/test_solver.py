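import numpy as np
import pytest
from scipy.integrate import solve_ivp

from gelfront.errors import ContractError, SolverError
from gelfront.kinetics import ModelParameters
from gelfront.scenarios import Scenario, make_disc_scenario
from gelfront.solver import (
    BoundaryCondition,
    FieldState,
    Grid1D,
    SolverOptions,
    analytic_slab_diffusion,
    integrate,
    spatial_operator,
)


class _RawScenario:
    """Minimal scenario-like object for oracle tests that need initial
    conditions Scenario deliberately forbids (e.g. uniform interior barium)."""

    def __init__(self, grid, initial_state, bath_ba, horizon, cadence):
        self.grid = grid
        self.initial_state = initial_state
        self.bath_ba = bath_ba
        self.horizon = horizon
        self._cadence = cadence
        self.label = "raw"

    def output_times(self):
        return np.arange(0.0, self.horizon + 1e-9, self._cadence)


def _near_zero_reaction_params():
    # strictly positive (type invariant) but dynamically negligible
    return ModelParameters(
        D0_poly=6.78e-6, D0_ba=6.78e-3,
        K_poly=1e-30, K_ba=1e-30,
        C_poly=1e-30, C_ba=1e-30, C_kba=1e-30, C_k=1e-30,
    )


class TestGrid1D:
    def test_basic_properties(self):
        g = Grid1D.uniform(2.0, 101, 1)
        assert g.n == 101
        assert g.R == 2.0
        assert g.geometry == "disc"

    @pytest.mark.parametrize("bad", [
        [0.0, 0.5, 0.5, 1.0],          # not strictly increasing
        [0.1, 0.5, 1.0],               # does not start at 0
    ])
    def test_invalid_radii(self, bad):
        with pytest.raises(ContractError):
            Grid1D(bad, 1)

    def test_invalid_symmetry(self):
        with pytest.raises(ContractError):
            Grid1D([0.0, 0.5, 1.0], 3)

    def test_graded_refines_rim(self):
        g = Grid1D.graded(2.0, 201, 1, rim_fraction=0.2, refinement=2.0)
        dr = np.diff(g.r)
        core_mean = dr[g.r[:-1] < 1.5].mean()
        rim_mean = dr[g.r[:-1] > 1.6].mean()
        assert rim_mean < core_mean / 1.5
        assert g.r[0] == 0.0
        assert g.R == 2.0


class TestSpatialOperator:
    @pytest.mark.parametrize("m", [0, 1, 2])
    @pytest.mark.parametrize("bc", [
        BoundaryCondition.zero_flux(), BoundaryCondition.dirichlet(3.0),
    ])
    def test_constant_field_is_annihilated(self, m, bc):
        g = Grid1D.uniform(1.0, 80, m)
        D = np.full(g.n, 0.7)
        out = spatial_operator(g, D, np.full(g.n, 3.0), bc)
        assert np.allclose(out, 0.0, atol=1e-14)

    @pytest.mark.parametrize("m,expected", [(0, 2.0), (1, 4.0), (2, 6.0)])
    def test_quadratic_closed_form(self, m, expected):
        # (1/r^m)(r^m D (r^2)')' = 2 D (m+1); the midpoint-face FV scheme
        # reproduces this exactly at interior nodes
        g = Grid1D.uniform(1.0, 100, m)
        D = np.full(g.n, 0.5)
        out = spatial_operator(g, D, g.r**2, "zero_flux")
        assert np.allclose(out[:-1], expected * 0.5, rtol=1e-10)

    @pytest.mark.parametrize("m", [0, 1, 2])
    def test_quartic_second_order_convergence(self, m):
        # r^4 has closed form 4 D (m+3) r^2 and a nonzero truncation error
        D0 = 0.5
        errs = []
        for n in (51, 101, 201):
            g = Grid1D.uniform(1.0, n, m)
            out = spatial_operator(g, np.full(g.n, D0), g.r**4, "zero_flux")
            exact = 4.0 * D0 * (m + 3) * g.r**2
            interior = slice(1, -1)
            errs.append(np.max(np.abs(out[interior] - exact[interior])))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.25)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.25)

    def test_unknown_boundary_rejected(self):
        g = Grid1D.uniform(1.0, 10, 0)
        with pytest.raises(ContractError, match="boundary"):
            spatial_operator(g, np.ones(g.n), np.ones(g.n), "reflecting")

    def test_nonpositive_diffusivity_rejected(self):
        g = Grid1D.uniform(1.0, 10, 0)
        D = np.ones(g.n)
        D[3] = 0.0
        with pytest.raises(ContractError, match="D_nodes"):
            spatial_operator(g, D, np.ones(g.n), "zero_flux")


class TestAnalyticSlabDiffusion:
    def test_boundary_value(self):
        assert analytic_slab_diffusion(0.0, 5.0, 1.0, 2.5) == pytest.approx(2.5)

    def test_far_field_vanishes(self):
        assert analytic_slab_diffusion(1e3, 1.0, 1.0, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_half_similarity_point(self):
        # x such that x / (2 sqrt(D t)) = 0.5 -> erfc(0.5) = 0.4795
        D, t = 0.3, 7.0
        x = 0.5 * 2.0 * np.sqrt(D * t)
        assert analytic_slab_diffusion(x, t, D, 1.0) == pytest.approx(0.4795, abs=1e-4)

    def test_invalid_time(self):
        with pytest.raises(ContractError):
            analytic_slab_diffusion(0.1, 0.0, 1.0, 1.0)


class TestIntegrateBasics:
    def test_frozen_dynamics_fields_constant(self):
        p = _near_zero_reaction_params()
        g = Grid1D.uniform(1.0, 60, 0)
        n = g.n
        rho_ba = np.zeros(n)
        rho_ba[-1] = 1e-12  # effectively-zero Dirichlet value
        s0 = FieldState(0.0, np.full(n, 1.0), rho_ba, np.zeros(n), np.zeros(n))
        sc = _RawScenario(g, s0, 1e-12, horizon=100.0, cadence=25.0)
        res = integrate(sc, p)
        assert np.allclose(res.rho_poly, 1.0, atol=1e-8)
        assert np.allclose(res.rho_cross, 0.0, atol=1e-10)
        assert np.allclose(res.kappa, 0.0, atol=1e-10)
        assert np.all(res.rho_ba <= 2e-12)

    def test_erfc_diffusion_limit(self):
        # pure diffusion into a slab deep enough to look semi-infinite
        p = _near_zero_reaction_params()
        L, c0, t_end = 6.0, 1.0, 200.0
        g = Grid1D.uniform(L, 481, 0)
        n = g.n
        rho_ba = np.zeros(n)
        rho_ba[-1] = c0
        s0 = FieldState(0.0, np.full(n, 1.0), rho_ba, np.zeros(n), np.zeros(n))
        sc = _RawScenario(g, s0, c0, horizon=t_end, cadence=t_end / 4)
        res = integrate(sc, p, SolverOptions(rtol=1e-8, atol=1e-12))
        depth = L - g.r
        exact = analytic_slab_diffusion(depth, t_end, p.D0_ba, c0)
        probe = exact >= 0.01 * c0
        rel = np.abs(res.rho_ba[-1][probe] - exact[probe]) / exact[probe]
        assert rel.max() < 0.01

    def test_reaction_only_matches_independent_ode(self):
        # transport switched off (vanishing diffusivities); compare the full
        # MOL path against an independently written ODE reference
        p = ModelParameters.default().with_updates(D0_poly=1e-22, D0_ba=2e-21)
        g = Grid1D.uniform(1.0, 3, 0)
        n = g.n
        y0_local = (1.0, 2.0, 0.0, 0.0)
        s0 = FieldState(
            0.0,
            np.full(n, y0_local[0]),
            np.full(n, y0_local[1]),
            np.full(n, y0_local[2]),
            np.full(n, y0_local[3]),
        )
        sc = _RawScenario(g, s0, y0_local[1], horizon=60.0, cadence=10.0)
        res = integrate(sc, p, SolverOptions(rtol=1e-9, atol=1e-14))

        def reference_rhs(t, y):
            rp, rb, rc, k = y
            primary = rp * rb
            secondary = rb * (1.0 - k) * rc
            return [
                -p.C_poly * primary,
                -p.C_ba * primary - p.C_kba * secondary,
                (p.C_poly + p.C_ba) * primary + p.C_kba * secondary,
                p.C_k * secondary,
            ]

        ref = solve_ivp(
            reference_rhs, (0.0, 60.0), list(y0_local), method="Radau",
            t_eval=res.times, rtol=1e-12, atol=1e-16,
        )
        node = 0  # interior node, no boundary influence without transport
        for got, want in (
            (res.rho_poly[:, node], ref.y[0]),
            (res.rho_ba[:, node], ref.y[1]),
            (res.rho_cross[:, node], ref.y[2]),
            (res.kappa[:, node], ref.y[3]),
        ):
            # relative to the field's own scale: the free-polymer tail decays
            # below any sensible atol, where pointwise ratios are meaningless
            scale = max(np.abs(want).max(), 1e-12)
            rel = np.abs(got - want) / np.maximum(np.abs(want), 1e-3 * scale)
            assert rel.max() < 1e-6

    def test_bad_tolerances_rejected(self):
        with pytest.raises(ContractError):
            SolverOptions(rtol=-1.0)


class TestIntegrateProductionRuns:
    def test_output_times_and_state_validity(self, disc_runs):
        for mM, (scenario, result, _) in disc_runs.items():
            assert np.allclose(result.times, scenario.output_times())
            for i in (0, len(result) // 2, len(result) - 1):
                result.state(i).validate()

    def test_pointwise_monotonicity(self, disc_runs):
        # tolerance covers dense-output interpolation noise (~rtol * scale)
        for mM, (_, result, _) in disc_runs.items():
            assert np.all(np.diff(result.rho_cross, axis=0) >= -1e-6)
            assert np.all(np.diff(result.kappa, axis=0) >= -1e-6)
            assert result.kappa.min() >= 0.0
            assert result.kappa.max() <= 1.0

    def test_polymer_mass_conserved_without_barium_uptake(self, params):
        # with the barium-uptake channels switched off the cross-linked phase
        # gains polymer mass only, so polymer + cross is exactly conserved
        # under the zero-flux polymer boundary
        p2 = params.with_updates(C_ba=1e-30, C_kba=1e-30)
        sc = make_disc_scenario(40, p2, n_nodes=250, horizon_s=6e4,
                                output_cadence_s=300.0)
        res = integrate(sc, p2)
        r = res.grid.r
        w = r ** res.grid.m
        total = np.trapezoid((res.rho_poly + res.rho_cross) * w, r, axis=1)
        drift = np.abs(total - total[0]) / total[0]
        assert drift.max() < 1e-3

    def test_total_mass_balanced_by_boundary_influx(self, disc_runs, params):
        # the three reaction terms cancel pointwise, so the total constituent
        # mass changes only through barium entering at the rim; checked on a
        # window that excludes the under-resolved initial influx spike
        from gelfront.kinetics import effective_diffusivity

        _, res, _ = disc_runs[40]
        g = res.grid
        w = g.r ** g.m
        total = np.trapezoid(
            (res.rho_poly + res.rho_ba + res.rho_cross) * w, g.r, axis=1
        )
        face_area = (0.5 * (g.r[-1] + g.r[-2])) ** g.m
        influx = np.empty(len(res))
        for i in range(len(res)):
            Db = effective_diffusivity(res.rho_cross[i], params.D0_ba, params.K_ba)
            Dface = 2.0 * Db[-1] * Db[-2] / (Db[-1] + Db[-2])
            influx[i] = face_area * Dface * (
                (res.rho_ba[i, -1] - res.rho_ba[i, -2]) / (g.r[-1] - g.r[-2])
            )
        i0, i1 = 20, len(res) - 1
        lhs = total[i1] - total[i0]
        rhs = np.trapezoid(influx[i0 : i1 + 1], res.times[i0 : i1 + 1])
        assert lhs == pytest.approx(rhs, rel=1e-3)

    def test_barium_bookkeeping_short_horizon(self, params):
        # change of interior barium content == time-integrated boundary
        # influx minus reaction sink, away from the t~0 influx singularity
        sc = make_disc_scenario(40, params, n_nodes=200, horizon_s=400.0,
                                output_cadence_s=5.0)
        res = integrate(sc, params, SolverOptions(rtol=1e-8, atol=1e-12))
        g = res.grid
        from gelfront.kinetics import _raw_rates, effective_diffusivity

        w = g.r ** g.m
        # interior = everything but the Dirichlet boundary node
        content = np.trapezoid(res.rho_ba[:, :-1] * w[:-1], g.r[:-1], axis=1)
        influx = np.empty(len(res))
        sink = np.empty(len(res))
        face_area = (0.5 * (g.r[-1] + g.r[-2])) ** g.m
        for i in range(len(res)):
            Db = effective_diffusivity(res.rho_cross[i], params.D0_ba, params.K_ba)
            Dface = 2.0 * Db[-1] * Db[-2] / (Db[-1] + Db[-2])
            influx[i] = face_area * Dface * (
                (res.rho_ba[i, -1] - res.rho_ba[i, -2]) / (g.r[-1] - g.r[-2])
            )
            rb_rate = _raw_rates(
                res.rho_poly[i], res.rho_ba[i], res.rho_cross[i],
                res.kappa[i], params,
            )[1]
            sink[i] = np.trapezoid(-rb_rate[:-1] * w[:-1], g.r[:-1])
        t = res.times
        i0 = 20
        lhs = content[-1] - content[i0]
        rhs = np.trapezoid(influx[i0:] - sink[i0:], t[i0:])
        assert lhs == pytest.approx(rhs, rel=0.02)

    def test_dose_response_gelation_speed(self, disc_runs):
        # higher bath concentration -> faster overall gelation
        tg = {mM: traj.gelation_time for mM, (_, _, traj) in disc_runs.items()}
        assert all(v is not None for v in tg.values())
        assert tg[10] > tg[20] > tg[40]
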