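import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from notchisland import (
    FieldParams,
    MechanicalFields,
    analytic_fields,
    compute_C_neighbor,
    compute_S,
    fields_from_traction_csv,
    force_free_fields,
    normalize_traction,
)
from notchisland.mechanics import traction_profile


class TestAnalyticProfiles:
    def test_rim_and_center_values(self):
        fp = FieldParams(t_interior=0.2, lam_t=0.05, c_max=1.0)
        assert np.isclose(traction_profile(1.0, fp), 1.0)
        assert np.isclose(traction_profile(0.0, fp), 0.2 + 0.8 * np.exp(-20))

    def test_cellcell_is_inverse_of_traction(self, lat400):
        mf = analytic_fields(lat400, FieldParams(c_max=1.0))
        assert np.allclose(mf.cellcell, 1.0 - mf.traction)
        rim = np.argmax(lat400.radius)
        assert mf.cellcell[rim] < 0.05

    def test_monotone_in_radius(self, lat400):
        mf = analytic_fields(lat400)
        order = np.argsort(lat400.radius)
        assert np.all(np.diff(mf.traction[order]) >= -1e-12)
        assert np.all(np.diff(mf.cellcell[order]) <= 1e-12)
        assert np.all(mf.traction >= 0) and np.all(mf.ecad >= 0)
        assert np.isclose(mf.traction.max(), 1.0, atol=1e-6)

    def test_field_params_validation(self):
        with pytest.raises(ValueError):
            FieldParams(t_interior=-0.1)
        with pytest.raises(ValueError):
            FieldParams(lam_t=0.5)


class TestNormalizeTraction:
    def test_replicate_mean_max_rule(self):
        # maxima 2.0 and 4.0 -> mean max 3.0; value 3.0 normalizes to 1.0
        out = normalize_traction([np.array([1.0, 2.0]), np.array([3.0, 4.0])])
        assert np.isclose(out[1][0], 1.0)

    def test_single_replicate_max_is_one(self):
        out = normalize_traction([np.array([0.5, 2.5])])
        assert np.isclose(out[0].max(), 1.0)

    def test_all_zero_passthrough(self):
        out = normalize_traction([np.zeros(4)])
        assert np.allclose(out[0], 0.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            normalize_traction([])
        with pytest.raises(ValueError):
            normalize_traction([np.array([])])

    @settings(deadline=None, max_examples=25)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_equivariance(self, k):
        groups = [np.array([1.0, 5.0, 2.0]), np.array([4.0, 0.5])]
        base = normalize_traction(groups)
        scaled = normalize_traction([g * k for g in groups])
        for a, b in zip(base, scaled):
            assert np.allclose(a, b, rtol=1e-9)


class TestCouplingTerms:
    def test_S_is_elementwise_product(self, lat20):
        mf = analytic_fields(lat20)
        oracle = np.array(
            [mf.ecad[i] * mf.traction[i] for i in range(lat20.n_cells)]
        )
        assert np.allclose(compute_S(mf), oracle)
        assert np.isclose(compute_S(mf, 3), oracle[3])

    def test_S_degenerate_values(self, lat20):
        n = lat20.n_cells
        mf = MechanicalFields(
            traction=np.zeros(n), cellcell=np.zeros(n), ecad=np.ones(n)
        )
        assert np.allclose(compute_S(mf), 0.0)
        mf2 = MechanicalFields(
            traction=np.full(n, 0.5), cellcell=np.zeros(n), ecad=np.full(n, 2.0)
        )
        assert np.allclose(compute_S(mf2), 1.0)

    def test_C_matches_brute_force_sum(self, lat20):
        mf = analytic_fields(lat20)
        for i in range(lat20.n_cells):
            oracle = sum(
                mf.ecad[j] * mf.cellcell[j] for j in lat20.adjacency[i]
            )
            assert np.isclose(compute_C_neighbor(lat20, mf, i), oracle)

    def test_C_no_neighbors_is_zero(self):
        from notchisland import generate_lattice

        lat = generate_lattice(1, seed=0)
        mf = MechanicalFields(
            traction=np.ones(1), cellcell=np.ones(1), ecad=np.ones(1)
        )
        assert compute_C_neighbor(lat, mf, 0) == 0.0

    def test_S_peaks_at_rim_C_peaks_interior(self, lat400, fields400):
        s = compute_S(fields400)
        c = compute_C_neighbor(lat400, fields400)
        assert lat400.radius[np.argmax(s)] > 0.9
        assert lat400.radius[np.argmax(c)] < 0.5

    def test_negative_field_rejected(self):
        with pytest.raises(ValueError):
            MechanicalFields(
                traction=np.array([-0.1]), cellcell=np.zeros(1), ecad=np.zeros(1)
            )


class TestTractionCsv:
    def test_binned_interpolation(self, lat20, tmp_path):
        import pandas as pd

        rng = np.random.default_rng(0)
        rows = []
        for rep in (0, 1):
            r = rng.uniform(0, 1, 200)
            stress = 100.0 * (0.2 + 0.8 * np.exp((r - 1) / 0.05))
            rows.append(
                pd.DataFrame(
                    {"replicate_id": rep, "radius": r, "stress_pa": stress}
                )
            )
        path = tmp_path / "traction.csv"
        pd.concat(rows).to_csv(path, index=False)
        mf = fields_from_traction_csv(lat20, path)
        assert mf.provenance == "csv"
        # recovered profile rises toward the rim and is near the analytic one
        order = np.argsort(lat20.radius)
        assert mf.traction[order][-1] > mf.traction[order][0]
        expected = traction_profile(lat20.radius, FieldParams())
        assert np.corrcoef(mf.traction, expected)[0, 1] > 0.95

    def test_missing_columns_rejected(self, lat20, tmp_path):
        import pandas as pd

        path = tmp_path / "bad.csv"
        pd.DataFrame({"radius": [0.5], "stress_pa": [1.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError):
            fields_from_traction_csv(lat20, path)


def test_force_free_fields_are_neutral(lat20):
    mf = force_free_fields(lat20)
    assert mf.neutral
    assert np.allclose(mf.ecad, 0.0)
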