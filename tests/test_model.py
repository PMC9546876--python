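import numpy as np
import pytest

from notchisland import (
    ModelParams,
    Scenario,
    force_free_fields,
    generate_lattice,
    initial_conditions,
    rhs,
    simulate,
)
from notchisland.model import SPECIES, Trajectory


@pytest.fixture(scope="module")
def isolated():
    """Single-cell lattice: no neighbors, so all trans terms vanish."""
    return generate_lattice(1, seed=0)


class TestInitialConditions:
    def test_nicd_and_nt_start_at_zero(self, lat20, params):
        s = initial_conditions(lat20, params, seed=7)
        assert np.all(s[SPECIES.index("NICD")] == 0)
        assert np.all(s[SPECIES.index("NT")] == 0)
        assert np.all(s[SPECIES.index("N_R")] == params.betaN)

    def test_zero_noise_zero_ligands(self, lat20, params):
        s = initial_conditions(lat20, params, seed=7, noise_amp=0.0)
        assert np.all(s[SPECIES.index("D")] == 0)
        assert np.all(s[SPECIES.index("J")] == 0)

    def test_seed_determinism(self, lat20, params):
        a = initial_conditions(lat20, params, seed=42)
        b = initial_conditions(lat20, params, seed=42)
        assert np.array_equal(a, b)
        c = initial_conditions(lat20, params, seed=43)
        assert not np.array_equal(a, c)


class TestRhs:
    def test_isolated_cell_hand_arithmetic(self, isolated):
        # betaN=betaD=betaJ=betaNICD=1, h=2, k_cD=22, k_tD=0.3, k_tJ=10;
        # state (N_R=1, NICD=0, D=0.1, J=0.1, NT=0). With no neighbors the
        # trans terms vanish:
        #   dN_R = 0 - 0 - 22*1*0.1 - 0 - 1      = -3.2
        #   dD   = 1 - 0 - 22*1*0.1 - 0.1        = -1.3
        #   dJ   = 1 - 0 - 0.1                   =  0.9
        #   dNICD = dNT = 0
        p = ModelParams(betaN=1, betaD=1, betaJ=1, betaNICD=1, h=2)
        state = np.array([[1.0], [0.0], [0.1], [0.1], [0.0]])
        d = rhs(state, isolated, force_free_fields(isolated), p)
        expected = {"N_R": -3.2, "NICD": 0.0, "D": -1.3, "J": 0.9, "NT": 0.0}
        for sp, val in expected.items():
            assert np.isclose(d[SPECIES.index(sp)][0], val, atol=1e-12), sp

    def test_jag_production_fixed_point(self, isolated, params):
        # isolated cell at J = betaJ has dJ = 0
        state = np.zeros((5, 1))
        state[SPECIES.index("J")] = params.betaJ
        d = rhs(state, isolated, force_free_fields(isolated), params)
        assert np.isclose(d[SPECIES.index("J")][0], 0.0)

    def test_nt_tracks_nicd(self, lat20, params):
        state = np.abs(np.random.default_rng(0).normal(size=(5, 20)))
        state[SPECIES.index("NT")] = state[SPECIES.index("NICD")]
        d = rhs(state, lat20, force_free_fields(lat20), params)
        assert np.allclose(d[SPECIES.index("NT")], 0.0)

    def test_nonfinite_state_reports_cell(self, lat20, params):
        state = np.zeros((5, 20))
        state[0, 13] = np.nan
        with pytest.raises(FloatingPointError, match="13"):
            rhs(state, lat20, force_free_fields(lat20), params)

    def test_printed_denominator_variant_differs(self, lat20, params):
        rng = np.random.default_rng(1)
        state = np.abs(rng.normal(0.5, 0.2, size=(5, 20)))
        ff = force_free_fields(lat20)
        d_sym = rhs(state, lat20, ff, params)
        d_lit = rhs(state, lat20, ff, params.with_overrides(eq2_printed_denominator=True))
        k = SPECIES.index("NICD")
        assert not np.allclose(d_sym[k], d_lit[k])
        others = [i for i in range(5) if i != k]
        assert np.allclose(d_sym[others], d_lit[others])


class TestSimulate:
    def test_absorbing_zero_state(self, lat20):
        p = ModelParams(betaN=0, betaD=0, betaJ=0, betaNICD=0, noise_amp=0.0)
        traj = simulate(lat20, force_free_fields(lat20), p, t_end=50, seed=0)
        assert np.allclose(traj.final, 0.0, atol=1e-8)
        assert traj.converged

    def test_homogeneous_limit_closed_form(self, lat20):
        # with all interaction constants zero the species decouple:
        # N_R(t) = betaN e^-t (NT stays 0), D(t) = betaD + (D0-betaD)e^-t,
        # J(t) = betaJ + (J0-betaJ)e^-t, NICD = NT = 0
        p = ModelParams(betaN=2, betaD=3, betaJ=0.5, betaNICD=4,
                        k_tD=0, k_cD=0, k_tJ=0, noise_amp=0.2)
        t_end = 5.0
        traj = simulate(lat20, force_free_fields(lat20), p, t_end=t_end,
                        seed=3, n_out=6)
        y0 = initial_conditions(lat20, p, seed=3)
        e = np.exp(-t_end)
        expect = {
            "N_R": p.betaN * e,
            "D": p.betaD + (y0[SPECIES.index("D")] - p.betaD) * e,
            "J": p.betaJ + (y0[SPECIES.index("J")] - p.betaJ) * e,
            "NICD": 0.0,
            "NT": 0.0,
        }
        for sp, val in expect.items():
            assert np.allclose(traj.final[SPECIES.index(sp)], val, atol=1e-6), sp

    def test_forward_euler_cross_integrator(self):
        lat = generate_lattice(10, seed=4)
        p = ModelParams()
        ff = force_free_fields(lat)
        t_end = 20.0
        traj = simulate(lat, ff, p, t_end=t_end, seed=4, n_out=3)
        # independent explicit integrator
        y = initial_conditions(lat, p, seed=4)
        dt = 1e-3
        for _ in range(int(t_end / dt)):
            y = y + dt * rhs(y, lat, ff, p)
        k = SPECIES.index("NT")
        scale = np.max(np.abs(y[k])) + 1e-9
        assert np.max(np.abs(traj.final[k] - y[k])) / scale < 1e-3

    def test_nonnegativity_and_boundedness(self, lat20, params):
        traj = simulate(lat20, force_free_fields(lat20), params, t_end=200,
                        seed=0, n_out=21)
        assert np.all(traj.states >= -1e-9)
        cap = 10 * max(params.betaN, params.betaD, params.betaJ, params.betaNICD)
        assert np.all(traj.states <= cap)

    def test_permutation_equivariance(self):
        from notchisland.lattice import Lattice

        lat = generate_lattice(12, seed=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(12)
        inv = np.argsort(perm)
        plat = Lattice(
            n_cells=12,
            polygons=[lat.polygons[i] for i in perm],
            centroids=lat.centroids[perm],
            areas=lat.areas[perm],
            adjacency=[frozenset(int(inv[j]) for j in lat.adjacency[i]) for i in perm],
            radius=lat.radius[perm],
            on_rim=lat.on_rim[perm],
            seed=lat.seed,
        )
        p = ModelParams(noise_amp=0.0)  # identical ICs so relabeling is exact
        ff = force_free_fields(lat)
        state = np.tile(np.array([1.0, 0.2, 0.4, 0.1, 0.3])[:, None], (1, 12))
        state = state * (1 + 0.1 * np.sin(np.arange(12)))  # cell-dependent
        d = rhs(state, lat, ff, p)
        d_perm = rhs(state[:, perm], plat, force_free_fields(plat), p)
        assert np.allclose(d[:, perm], d_perm)

    def test_invalid_t_end(self, lat20, params):
        with pytest.raises(ValueError):
            simulate(lat20, force_free_fields(lat20), params, t_end=0)

    def test_trajectory_export(self, lat20, params, tmp_path):
        import pandas as pd

        traj = simulate(lat20, force_free_fields(lat20), params, t_end=5,
                        seed=0, n_out=3)
        assert isinstance(traj, Trajectory)
        assert np.all(np.diff(traj.times) > 0)
        assert np.array_equal(traj.final, traj.states[-1])
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        df = pd.read_csv(path)
        assert set(df.columns) == {"cell_id", "time", *SPECIES}
        assert len(df) == 3 * 20


class TestScenarioTermsInRhs:
    def test_egf_term_raises_receptor_production(self, lat20, params):
        state = np.full((5, 20), 0.5)
        ff = force_free_fields(lat20)
        base = rhs(state, lat20, ff, params)
        egf = rhs(state, lat20, ff, params, Scenario(egf_on=True))
        k = SPECIES.index("N_R")
        assert np.all(egf[k] > base[k])

    def test_tgf_terms_raise_ligands_and_targets(self, lat20, params):
        state = np.full((5, 20), 0.5)
        ff = force_free_fields(lat20)
        base = rhs(state, lat20, ff, params)
        tgf = rhs(state, lat20, ff, params, Scenario(tgf_on=True))
        for sp in ("D", "J", "NT"):
            k = SPECIES.index(sp)
            assert np.all(tgf[k] >= base[k]), sp
        assert np.any(tgf[SPECIES.index("NT")] > base[SPECIES.index("NT")])
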