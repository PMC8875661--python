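"""pp-LFER fitting, validation statistics and applicability domain."""

import numpy as np
import pandas as pd
import pytest

from nanosorb import lfer as L
from nanosorb.fixtures import reference_models
from nanosorb.lfer import (
    CollinearityError,
    CollinearityWarning,
    MissingDescriptorError,
    fit_pplfer,
    predict,
    split_train_validation,
    validate,
    williams_domain,
)


def _loo_refit_q2(train, endpoint, descriptor_set):
    """Independent brute-force leave-one-out oracle: n explicit refits."""
    X = np.column_stack(
        [np.ones(len(train))] + [train[d].to_numpy() for d in descriptor_set]
    )
    y = train[endpoint].to_numpy(dtype=float)
    press = 0.0
    for i in range(len(train)):
        mask = np.ones(len(train), dtype=bool)
        mask[i] = False
        beta, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
        press += (y[i] - X[i] @ beta) ** 2
    return 1.0 - press / np.sum((y - y.mean()) ** 2)


class TestSplit:
    def test_41_compounds_split_33_8(self, synthetic_dataset):
        train, valid = split_train_validation(synthetic_dataset.table, seed=0)
        assert (len(train), len(valid)) == (33, 8)

    def test_deterministic_and_disjoint(self, synthetic_dataset):
        t1, v1 = split_train_validation(synthetic_dataset.table, seed=42)
        t2, v2 = split_train_validation(synthetic_dataset.table, seed=42)
        assert list(t1.index) == list(t2.index)
        assert list(v1.index) == list(v2.index)
        assert set(t1.index).isdisjoint(v1.index)
        assert set(t1.index) | set(v1.index) == set(synthetic_dataset.table.index)

    def test_different_seeds_differ(self, synthetic_dataset):
        t1, _ = split_train_validation(synthetic_dataset.table, seed=1)
        t2, _ = split_train_validation(synthetic_dataset.table, seed=2)
        assert list(t1.index) != list(t2.index)
        assert len(t1) == len(t2)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            split_train_validation(pd.DataFrame({"E": range(5)}), seed=0)


class TestFit:
    def test_noiseless_recovery_of_generating_coefficients(self, synthetic_dataset):
        table = synthetic_dataset.table.copy()
        truth = reference_models()["logK_gaseous"]
        table["y_gaseous"] = predict(truth, table)
        model = fit_pplfer(table, "y_gaseous", descriptor_set=truth.descriptor_set)
        assert model.intercept == pytest.approx(truth.intercept, rel=1e-7, abs=1e-9)
        for d in truth.descriptor_set:
            assert model.coefficients[d] == pytest.approx(
                truth.coefficients[d], rel=1e-7, abs=1e-9
            )

    def test_constant_endpoint(self, synthetic_dataset):
        table = synthetic_dataset.table.copy()
        table["y_aqueous"] = 3.0
        model = fit_pplfer(table, "y_aqueous")
        assert model.intercept == pytest.approx(3.0, abs=1e-9)
        for c in model.coefficients.values():
            assert c == pytest.approx(0.0, abs=1e-9)

    def test_duplicated_descriptor_collinearity(self, synthetic_dataset):
        table = synthetic_dataset.table.copy()
        table["V"] = table["E"]  # duplicate column content
        with pytest.raises(CollinearityError):
            fit_pplfer(table, "logK_aqueous")

    def test_vif_warning_on_near_collinear(self, synthetic_dataset):
        rng = np.random.default_rng(0)
        table = synthetic_dataset.table.copy()
        table["V"] = table["E"] + rng.normal(0, 1e-3, len(table))
        with pytest.warns(CollinearityWarning):
            fit_pplfer(table, "logK_aqueous")

    def test_oracle_normal_equations(self, small_table):
        model = fit_pplfer(small_table, "logK_aqueous")
        X = np.column_stack(
            [np.ones(len(small_table))]
            + [small_table[d].to_numpy() for d in model.descriptor_set]
        )
        y = small_table["logK_aqueous"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert model.intercept == pytest.approx(beta[0], rel=1e-8)
        for j, d in enumerate(model.descriptor_set, start=1):
            assert model.coefficients[d] == pytest.approx(beta[j], rel=1e-8)


class TestPredict:
    def test_reference_intercepts_at_zero_descriptors(self):
        models = reference_models()
        zero = {d: 0.0 for d in "ESABVL"}
        assert predict(models["logK_aqueous"], zero) == pytest.approx(-1.7)
        assert predict(models["logK_gaseous"], zero) == pytest.approx(0.2)

    def test_aqueous_model_all_ones(self):
        model = reference_models()["logK_aqueous"]
        ones = {d: 1.0 for d in "ESABV"}
        # −1.7 + 0.65 + 0.75 + 0.048 − 0.095 + 4.0
        assert predict(model, ones) == pytest.approx(3.653, abs=1e-9)

    def test_missing_descriptor_named(self):
        model = reference_models()["logK_aqueous"]
        with pytest.raises(MissingDescriptorError, match="V"):
            predict(model, {"E": 1.0, "S": 1.0, "A": 0.0, "B": 0.0})

    def test_table_prediction_matches_rowwise(self, small_table):
        model = reference_models()["absEad_aqueous"]
        vec = predict(model, small_table)
        for i, (_, row) in enumerate(small_table.iterrows()):
            assert vec[i] == pytest.approx(predict(model, row), rel=1e-12)


class TestValidate:
    def test_perfect_model_statistics(self, synthetic_dataset):
        table = synthetic_dataset.table.copy()
        truth = reference_models()["logK_aqueous"]
        table["y_aqueous"] = predict(truth, table)
        train, valid = split_train_validation(table, seed=0)
        rep = validate(train, valid, "y_aqueous", repetitions=20, seed=0)
        assert rep.r2_adj == pytest.approx(1.0, abs=1e-9)
        assert rep.q2_loo == pytest.approx(1.0, abs=1e-9)
        assert rep.q2_ext == pytest.approx(1.0, abs=1e-9)
        assert rep.rmse_train == pytest.approx(0.0, abs=1e-9)
        assert rep.rmse_ext == pytest.approx(0.0, abs=1e-9)

    def test_q2_loo_equals_explicit_refit_loop(self, small_table):
        train = small_table
        rep = validate(train, train.iloc[:0], "logK_aqueous", repetitions=1, seed=0)
        oracle = _loo_refit_q2(train, "logK_aqueous", L.AQUEOUS_DESCRIPTORS)
        assert rep.q2_loo == pytest.approx(oracle, abs=1e-10)

    def test_empty_validation_reports_absent(self, small_table):
        rep = validate(small_table, small_table.iloc[:0], "logK_aqueous",
                       repetitions=5, seed=0)
        assert rep.q2_ext is None
        assert rep.rmse_ext is None
        assert rep.n_ext == 0

    def test_kfold_mean_stabilizes_with_repetitions(self, synthetic_dataset):
        train, valid = split_train_validation(synthetic_dataset.table, seed=3)
        fast = validate(train, valid, "logK_aqueous", repetitions=50, seed=10)
        slow = validate(train, valid, "logK_aqueous", repetitions=2000, seed=11)
        se = fast.q2_kfold_sd / np.sqrt(fast.repetitions)
        assert abs(fast.q2_kfold - slow.q2_kfold) < 3 * se

    def test_overlapping_sets_rejected(self, small_table):
        with pytest.raises(ValueError, match="overlap"):
            validate(small_table, small_table.iloc[:2], "logK_aqueous",
                     repetitions=1, seed=0)

    def test_permutation_sanity_y_scrambling(self, synthetic_dataset):
        """Shuffled endpoints carry no signal: Q²_LOO ≤ ~0 on average."""
        rng = np.random.default_rng(0)
        q2s = []
        for _ in range(30):
            table = synthetic_dataset.table.copy()
            table["logK_aqueous"] = rng.permutation(table["logK_aqueous"].to_numpy())
            rep = validate(table, table.iloc[:0], "logK_aqueous",
                           repetitions=1, seed=0)
            q2s.append(rep.q2_loo)
        assert np.mean(q2s) < 0.05

    def test_noise_monotonically_degrades_q2(self, synthetic_dataset):
        """More endpoint noise never raises expected Q²_LOO."""
        truth = reference_models()["logK_aqueous"]
        base = predict(truth, synthetic_dataset.table)
        rng = np.random.default_rng(1)
        means = []
        for sd in (0.2, 1.0, 3.0):
            vals = []
            for _ in range(25):
                table = synthetic_dataset.table.copy()
                table["y_aqueous"] = base + rng.normal(0, sd, len(table))
                rep = validate(table, table.iloc[:0], "y_aqueous",
                               repetitions=1, seed=0)
                vals.append(rep.q2_loo)
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestWilliams:
    def test_leverages_sum_to_p_plus_one(self, synthetic_dataset):
        train, valid = split_train_validation(synthetic_dataset.table, seed=0)
        model = fit_pplfer(train, "logK_aqueous")
        ad = williams_domain(model, train, valid)
        assert ad.train["leverage"].sum() == pytest.approx(6.0, abs=1e-8)
        assert ((ad.train["leverage"] > 0) & (ad.train["leverage"] <= 1)).all()

    def test_threshold_formula(self, synthetic_dataset):
        train, _ = split_train_validation(synthetic_dataset.table, seed=0)
        model = fit_pplfer(train, "logK_aqueous")
        ad = williams_domain(model, train)
        assert ad.leverage_threshold == pytest.approx(18.0 / 33.0)

    def test_well_fitted_data_has_no_flags(self, synthetic_dataset):
        train, valid = split_train_validation(synthetic_dataset.table, seed=0)
        model = fit_pplfer(train, "logK_aqueous")
        ad = williams_domain(model, train, valid)
        assert ad.train["in_domain"].all()

    def test_outlier_is_flagged(self, synthetic_dataset):
        train, _ = split_train_validation(synthetic_dataset.table, seed=0)
        spiked = train.copy()
        spiked.loc[spiked.index[0], "logK_aqueous"] += 25.0
        model = fit_pplfer(spiked, "logK_aqueous")
        ad = williams_domain(model, spiked)
        assert ad.train["outlier"].loc[spiked.index[0]]


class TestCoefficientCoverage:
    def test_confidence_intervals_cover_truth_at_nominal_rate(self):
        """95 % CIs from repeated noisy simulations cover the generating
        coefficients at roughly the nominal rate."""
        from nanosorb.synthetic import GeneratorConfig, generate_descriptor_table

        truth = reference_models()["logK_aqueous"]
        config = GeneratorConfig(n_compounds=33)
        rng = np.random.default_rng(2024)
        hits = total = 0
        for rep in range(40):
            table = generate_descriptor_table(config, seed=1000 + rep)
            mu = predict(truth, table)
            table = table.copy()
            table["y_aqueous"] = mu + rng.normal(0, 0.6, len(table))
            model = fit_pplfer(table, "y_aqueous")
            ci = model.conf_int(0.05)
            lo, hi = ci["intercept"]
            hits += lo <= truth.intercept <= hi
            total += 1
            for d in truth.descriptor_set:
                lo, hi = ci[d]
                hits += lo <= truth.coefficients[d] <= hi
                total += 1
        coverage = hits / total
        assert 0.89 <= coverage <= 0.99
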