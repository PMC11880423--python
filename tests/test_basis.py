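"""Design blocks: B-spline bases, difference penalties, tensors, formulas."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anemap.basis import (TermSpec, bspline_basis, build_design,
                          difference_penalty, parse_formula,
                          tensor_spatial_basis)


def cox_de_boor(x, knots, degree):
    """Independent textbook Cox-de Boor recursion (dense, slow)."""
    n_basis = len(knots) - degree - 1
    B = np.zeros((len(x), len(knots) - 1))
    for j in range(len(knots) - 1):
        B[:, j] = (knots[j] <= x) & (x < knots[j + 1])
    # make the last basis right-closed so max(x) is covered
    B[x == knots[-1], len(knots) - 2] = 1.0
    for d in range(1, degree + 1):
        Bn = np.zeros((len(x), len(knots) - d - 1))
        for j in range(len(knots) - d - 1):
            left_den = knots[j + d] - knots[j]
            right_den = knots[j + d + 1] - knots[j + 1]
            left = ((x - knots[j]) / left_den * B[:, j]) if left_den > 0 else 0
            right = ((knots[j + d + 1] - x) / right_den * B[:, j + 1]) \
                if right_den > 0 else 0
            Bn[:, j] = left + right
        B = Bn
    return B[:, :n_basis]


class TestBsplineBasis:
    def test_partition_of_unity(self, rng):
        x = rng.uniform(3.0, 9.0, 200)
        B, _ = bspline_basis(x, n_basis=12, degree=3)
        assert np.allclose(B.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(B >= 0)

    def test_degree_zero_is_one_hot(self, rng):
        x = rng.uniform(0.0, 1.0, 100)
        B, _ = bspline_basis(x, n_basis=5, degree=0)
        assert np.allclose(B.sum(axis=1), 1.0)
        assert np.all((B == 0) | (B == 1))

    def test_matches_cox_de_boor_recursion(self):
        x = np.linspace(0.0, 10.0, 101)
        B, knots = bspline_basis(x, n_basis=10, degree=3)
        expected = cox_de_boor(x, knots, 3)
        assert np.allclose(B, expected, atol=1e-12)

    def test_nbasis_must_exceed_degree(self):
        with pytest.raises(ValueError):
            bspline_basis(np.array([0.0, 1.0]), n_basis=3, degree=3)


class TestDifferencePenalty:
    def test_first_order_two_basis(self):
        assert np.array_equal(difference_penalty(2, 1),
                              np.array([[1.0, -1.0], [-1.0, 1.0]]))

    @pytest.mark.parametrize("n,order", [(5, 1), (8, 2), (12, 3)])
    def test_annihilates_low_degree_polynomials(self, n, order):
        K = difference_penalty(n, order)
        for deg in range(order):
            v = np.arange(n, dtype=float) ** deg
            assert np.allclose(K @ v, 0.0, atol=1e-9)

    def test_rank_and_psd(self):
        K = difference_penalty(5, 2)
        evals = np.linalg.eigvalsh(K)
        assert np.all(evals >= -1e-10)
        assert np.sum(evals > 1e-10) == 3  # rank n - order

    def test_order_bound(self):
        with pytest.raises(ValueError):
            difference_penalty(3, 3)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(n=st.integers(3, 25), order=st.integers(1, 2))
    def test_penalty_always_psd(self, n, order):
        K = difference_penalty(n, order)
        assert np.allclose(K, K.T)
        assert np.min(np.linalg.eigvalsh(K)) >= -1e-10


class TestTensorBasis:
    def test_rows_sum_to_one_and_dimensions(self, rng):
        lon = rng.uniform(30, 40, 150)
        lat = rng.uniform(-10, 0, 150)
        B, K, _ = tensor_spatial_basis(lon, lat, n_basis_per_margin=6, degree=3)
        assert B.shape == (150, 36)
        assert K.shape == (36, 36)
        assert np.allclose(B.sum(axis=1), 1.0, atol=1e-10)

    def test_constant_surface_in_penalty_null_space(self):
        lon = np.linspace(0, 1, 10)
        _, K, _ = tensor_spatial_basis(lon, lon, n_basis_per_margin=5)
        assert np.allclose(K @ np.ones(25), 0.0, atol=1e-10)

    def test_penalty_psd(self):
        lon = np.linspace(0, 1, 10)
        _, K, _ = tensor_spatial_basis(lon, lon, n_basis_per_margin=5)
        assert np.min(np.linalg.eigvalsh(K)) >= -1e-10

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            tensor_spatial_basis(np.zeros(3), np.zeros(4))


class TestBuildDesign:
    @pytest.fixture()
    def data(self, rng):
        return pd.DataFrame({
            "age_months": rng.uniform(6, 59, 80),
            "wealth_index": rng.standard_normal(80),
            "lon": rng.uniform(30, 40, 80),
            "lat": rng.uniform(-10, 0, 80),
            "cluster_id": [f"c{i % 8}" for i in range(80)],
        })

    def test_empty_terms_gives_intercept_only(self, data):
        design = build_design(data, [])
        assert [b.term.name for b in design["mu"]] == ["intercept"]
        assert [b.term.name for b in design["sigma"]] == ["intercept"]
        assert np.all(design["mu"][0].X == 1.0)

    def test_linear_term_is_standardized_covariate(self, data):
        terms = parse_formula("mu ~ linear(wealth_index)")
        block = build_design(data, terms)["mu"][1]
        x = data["wealth_index"].to_numpy()
        assert np.allclose(block.X[:, 0], (x - x.mean()) / x.std())

    def test_column_bookkeeping(self, data):
        terms = parse_formula("mu ~ s(age_months) + linear(wealth_index)")
        blocks = build_design(data, terms)["mu"]
        # intercept + 20 spline columns + 1 linear column
        assert [b.n_basis for b in blocks] == [1, 20, 1]
        assert blocks[1].column_names[0] == "mu:s(age_months)[0]"

    def test_unknown_covariate_error_names_it(self, data):
        terms = [TermSpec("linear(bmi)", "linear", ("bmi",))]
        with pytest.raises(KeyError, match="bmi"):
            build_design(data, terms)

    def test_training_evaluation_reproduces_basis(self, data):
        terms = parse_formula("mu ~ s(age_months) + te(lon,lat)")
        for block in build_design(data, terms)["mu"][1:]:
            assert np.allclose(block.evaluate(data), block.X, atol=1e-14)

    def test_out_of_range_prediction_clamps(self, data):
        terms = parse_formula("mu ~ s(age_months)")
        block = build_design(data, terms)["mu"][1]
        hi = data["age_months"].max()
        outside = pd.DataFrame({"age_months": [hi + 100.0]})
        boundary = pd.DataFrame({"age_months": [hi]})
        assert np.allclose(block.evaluate(outside), block.evaluate(boundary))

    def test_random_intercept_block(self, data):
        terms = [TermSpec("re(cluster_id)", "random_intercept", ("cluster_id",))]
        block = build_design(data, terms)["mu"][1]
        assert block.X.shape[1] == data["cluster_id"].nunique()
        assert np.allclose(block.X.sum(axis=1), 1.0)
        assert np.array_equal(block.K, np.eye(block.X.shape[1]))


class TestFormulaParsing:
    def test_full_formula(self):
        specs = parse_formula(
            "mu ~ 1 + linear(wealth_index) + s(age_months) + te(lon,lat)")
        assert [s.kind for s in specs] == ["intercept", "linear", "pspline",
                                           "spatial_tensor"]
        assert specs[3].covariates == ("lon", "lat")
        assert specs[3].n_basis == 10  # per-margin default for spatial smooth

    def test_sigma_side(self):
        (spec,) = parse_formula("sigma ~ linear(elevation)")
        assert spec.parameter == "sigma"

    def test_round_trip_through_to_string(self):
        specs = parse_formula("mu ~ s(age_months) + linear(wealth_index)")
        rebuilt = parse_formula("mu ~ " + " + ".join(s.to_string()
                                                     for s in specs))
        assert [(s.name, s.kind) for s in rebuilt] == \
            [(s.name, s.kind) for s in specs]

    @pytest.mark.parametrize("bad", ["mu + s(age)", "theta ~ s(age)",
                                     "mu ~ spline(age)", "mu ~ te(lon)"])
    def test_malformed_formulas_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)
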