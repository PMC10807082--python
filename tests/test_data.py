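import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latentconn.data import (
    EdgeScaler,
    ParcelScheme,
    devectorize,
    load_connectivity,
    residualize_confounds,
    split_hemispheres,
    vectorize,
)
from latentconn.synthetic import SyntheticConfig, cohort_edge_tables, generate_cohort


class TestParcelScheme:
    def test_default_scheme_balanced(self):
        scheme = ParcelScheme.default(200)
        assert scheme.n_parcels == 200
        assert len(scheme.hemisphere_parcels("L")) == 100
        assert len(scheme.hemisphere_parcels("R")) == 100
        # every parcel has exactly one hemisphere and one network
        assert scheme.table["network"].notna().all()

    def test_odd_parcel_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            ParcelScheme.default(201)

    def test_unknown_network_rejected(self):
        tab = ParcelScheme.default(14).table.copy()
        tab.loc[0, "network"] = "cerebellar"
        with pytest.raises(ValueError, match="network"):
            ParcelScheme(tab)

    def test_tsv_round_trip(self, tmp_path):
        scheme = ParcelScheme.default(28)
        scheme.to_tsv(tmp_path / "scheme.tsv")
        back = ParcelScheme.from_tsv(tmp_path / "scheme.tsv")
        pd.testing.assert_frame_equal(scheme.table, back.table)


class TestVectorize:
    def test_edge_count_100_parcels(self):
        m = np.zeros((100, 100))
        assert vectorize(m).shape == (4950,)

    def test_3x3_order(self):
        m = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        assert vectorize(m).tolist() == [1.0, 2.0, 3.0]

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="does not match"):
            devectorize(np.zeros(10), 6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=12), st.integers(0, 2**31 - 1))
    def test_round_trip_exact(self, p, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(size=(p, p))
        m = m + m.T
        np.fill_diagonal(m, 0.0)
        assert np.array_equal(devectorize(vectorize(m), p), m)


class TestLoadConnectivity:
    def _write(self, tmp_path, values, name="sub01"):
        path = tmp_path / f"{name}.tsv"
        np.savetxt(path, values, delimiter="\t")
        return path

    def test_valid_file(self, tmp_path):
        scheme = ParcelScheme.default(14)
        m = np.abs(np.random.default_rng(0).normal(size=(14, 14)))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        path = self._write(tmp_path, m)
        (loaded,) = load_connectivity([path], scheme)
        assert loaded.subject_id == "sub01"
        assert loaded.values.shape == (14, 14)

    def test_wrong_dimension_names_file(self, tmp_path):
        scheme = ParcelScheme.default(14)
        path = self._write(tmp_path, np.zeros((13, 14)))
        with pytest.raises(ValueError, match="sub01"):
            load_connectivity([path], scheme)

    def test_nan_cell_reported(self, tmp_path):
        scheme = ParcelScheme.default(14)
        m = np.zeros((14, 14))
        m[2, 3] = np.nan
        path = self._write(tmp_path, m)
        with pytest.raises(ValueError, match=r"\(2, 3\)"):
            load_connectivity([path], scheme)

    def test_asymmetric_symmetrized(self, tmp_path, caplog):
        scheme = ParcelScheme.default(14)
        m = np.zeros((14, 14))
        m[0, 1] = 2.0  # asymmetric on purpose
        path = self._write(tmp_path, m)
        (loaded,) = load_connectivity([path], scheme)
        assert loaded.values[0, 1] == loaded.values[1, 0] == 1.0


class TestSplitHemispheres:
    def test_200_parcels_gives_two_100(self):
        scheme = ParcelScheme.default(200)
        m = np.random.default_rng(0).normal(size=(200, 200))
        m = m + m.T
        left, right = split_hemispheres(m, scheme)
        assert left.shape == (100, 100)
        assert right.shape == (100, 100)
        assert np.allclose(left, left.T) and np.allclose(right, right.T)

    def test_block_structure_respected(self):
        scheme = ParcelScheme.default(28)
        m = np.ones((28, 28))
        left_ids = scheme.hemisphere_parcels("L")
        m[np.ix_(left_ids, left_ids)] = 0.0
        left, right = split_hemispheres(m, scheme)
        assert (left == 0).all()
        assert (right == 1).all()


@pytest.fixture(scope="module")
def cohort():
    config = SyntheticConfig(n_autism=60, n_control=60, n_parcels=28, seed=3)
    phenotype, matrices, truth = generate_cohort(config)
    left, right, combined = cohort_edge_tables(matrices, ParcelScheme.default(28))
    return phenotype, left


class TestResidualize:

    def test_residuals_orthogonal_to_design(self, cohort):
        phenotype, left = cohort
        resid = residualize_confounds(left, phenotype)
        age = phenotype["age"].to_numpy()
        age_c = age - age.mean()
        assert np.abs(resid.values.mean(axis=0)).max() < 1e-10
        assert np.abs(age_c @ resid.values).max() / len(age) < 1e-8

    def test_zero_betas_residuals_are_centered_originals(self):
        config = SyntheticConfig(
            n_autism=40,
            n_control=40,
            n_parcels=28,
            confound_betas={"age": 0.0, "sex": 0.0, "site": 0.0},
            noise_sd=0.05,
            seed=4,
        )
        phenotype, matrices, _ = generate_cohort(config)
        scheme = ParcelScheme.default(28)
        left, _, _ = cohort_edge_tables(matrices, scheme)
        resid = residualize_confounds(left, phenotype)
        centered = left.values - left.values.mean(axis=0)
        # no confound signal: OLS fits only ~k/n worth of noise variance
        assert (resid.values - centered).std() < 0.3 * centered.std()
        corr = np.corrcoef(resid.values.ravel(), centered.ravel())[0, 1]
        assert corr > 0.95

    def test_planted_group_difference_survives(self):
        config = SyntheticConfig(
            n_autism=150,
            n_control=150,
            n_parcels=28,
            effect_blocks=[("visual", "visual", 0.4)],
            confound_betas={"age": 0.05, "sex": 0.2, "site": 0.2},
            seed=5,
        )
        phenotype, matrices, truth = generate_cohort(config)
        scheme = ParcelScheme.default(28)
        left, right, _ = cohort_edge_tables(matrices, scheme)
        resid_l = residualize_confounds(left, phenotype)
        resid_r = residualize_confounds(right, phenotype)
        resid = np.hstack([resid_l.values, resid_r.values])
        g = phenotype["group"].to_numpy()
        diff = resid[g == "autism"].mean(0) - resid[g == "control"].mean(0)
        assert abs(diff[truth.effect_mask].mean() - 0.4) < 0.05

    def test_single_site_design_stays_full_rank(self, cohort):
        phenotype, left = cohort
        pheno = phenotype.copy()
        pheno["site"] = "NYU"  # dummies vanish; design shrinks but stays valid
        resid = residualize_confounds(left, pheno)
        assert np.isfinite(resid.values).all()
        assert np.abs(resid.values.mean(axis=0)).max() < 1e-10

    def test_collinear_confound_dropped_with_warning(self, cohort):
        phenotype, left = cohort
        pheno = phenotype.copy()
        pheno["sex"] = 1  # constant column, collinear with the intercept
        with pytest.warns(UserWarning, match="collinear"):
            resid = residualize_confounds(left, pheno)
        assert np.isfinite(resid.values).all()


class TestEdgeScaler:
    def test_training_range_maps_to_unit_interval(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 11))
        scaled = EdgeScaler().fit_transform(X)
        assert np.allclose(scaled.min(axis=0), -1)
        assert np.allclose(scaled.max(axis=0), 1)

    def test_constant_edge_maps_to_zero(self):
        X = np.ones((10, 3))
        X[:, 1] = np.arange(10)
        scaled = EdgeScaler().fit_transform(X)
        assert (scaled[:, 0] == 0).all()
        assert (scaled[:, 2] == 0).all()
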