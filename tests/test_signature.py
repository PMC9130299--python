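"""Stage-1 SPI model: preprocessing, nested CV, calibration, application."""

import numpy as np
import pandas as pd
import pytest

from gliosurv.signature import (
    RiskLabelConfig,
    SigmoidCalibration,
    apply_signature,
    compute_spi,
    fit_sigmoid_calibration,
    mad_filter,
    nested_cv_train,
    roc_auc_with_ci,
    train_signature,
    zscore_fit_apply,
)
from gliosurv.simulate import SyntheticConfig, generate_replication_split
from conftest import REPLICATE_CONFIG


class TestMadFilter:
    def test_constant_column_always_removed(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        kept, dropped = mad_filter(df, epsilon=0.0)
        assert dropped == ["b"] and list(kept.columns) == ["a"]

    def test_mad_arithmetic(self):
        # MAD of [1..5] = (2+1+0+1+2)/5 = 1.2 > 1.0 → kept
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0]})
        kept, dropped = mad_filter(df, epsilon=1.0)
        assert list(kept.columns) == ["a"] and dropped == []

    def test_epsilon_zero_removes_exactly_constants(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"x": rng.normal(size=10), "c1": 2.0, "y": rng.normal(size=10),
             "c2": -1.0}
        )
        kept, dropped = mad_filter(df, epsilon=0.0)
        assert dropped == ["c1", "c2"]
        assert list(kept.columns) == ["x", "y"]  # order preserved

    def test_all_removed_errors(self):
        with pytest.raises(ValueError):
            mad_filter(pd.DataFrame({"c": [1.0, 1.0]}), epsilon=0.0)


class TestZScore:
    def test_self_transform_standardizes(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(3, 2, size=(50, 4)),
                          columns=list("abcd"))
        z = zscore_fit_apply(df, df)
        assert np.allclose(z.mean(), 0, atol=1e-12)
        assert np.allclose(z.std(ddof=0), 1, atol=1e-12)

    def test_mean_row_maps_to_zero(self):
        rng = np.random.default_rng(2)
        train = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        mean_row = train.mean().to_frame().T
        z = zscore_fit_apply(train, mean_row)
        assert np.allclose(z.to_numpy(), 0, atol=1e-12)

    def test_discovery_statistics_differ_from_self_scoring(self):
        rng = np.random.default_rng(3)
        disc = pd.DataFrame(rng.normal(0, 1, size=(40, 3)), columns=list("abc"))
        rep = pd.DataFrame(rng.normal(1, 2, size=(20, 3)), columns=list("abc"))
        with_disc = zscore_fit_apply(disc, rep)
        with_self = zscore_fit_apply(rep, rep)
        assert not np.allclose(with_disc.to_numpy(), with_self.to_numpy())

    def test_zero_sd_column_named_in_error(self):
        df = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            zscore_fit_apply(df, df)


class TestNestedCv:
    def _separable(self, seed=0, n=80, p=12):
        rng = np.random.default_rng(seed)
        y = np.arange(n) % 2 == 0
        X = pd.DataFrame(
            rng.normal(size=(n, p)),
            columns=[f"f{i:02d}" for i in range(p)],
        )
        X["f00"] = np.where(y, 2.0, -2.0) + rng.normal(0, 0.05, n)
        return X, y

    def test_perfect_feature_is_selected_with_perfect_accuracy(self):
        X, y = self._separable()
        clf, oof = nested_cv_train(X, y, "high_risk", c_grid=[1.0], seed=0,
                                   min_features=4)
        assert "f00" in clf.selected_features
        best = max(d["validation_accuracy"] for d in clf.fold_diagnostics)
        assert best == 1.0

    def test_out_of_fold_partition_covers_each_patient_once(self):
        X, y = self._separable(seed=1)
        _, oof = nested_cv_train(X, y, "high_risk", c_grid=[1.0], seed=1,
                                 min_features=4)
        assert sorted(oof.index) == sorted(X.index)
        # stratified folds: class proportions preserved within ±1 patient
        for _, fold in oof.groupby("fold"):
            expected = y.mean() * len(fold)
            assert abs(fold["label"].sum() - expected) <= 1.0 + 1e-9

    def test_permuted_labels_give_chance_level_auc(self):
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(
                rng.normal(size=(80, 10)),
                columns=[f"f{i}" for i in range(10)],
            )
            y = rng.permutation(np.arange(80) % 2 == 0)
            _, oof = nested_cv_train(X, y, "high_risk", c_grid=[1.0],
                                     seed=seed, min_features=4)
            clf_aucs = []
            for _, fold in oof.groupby("fold"):
                from sklearn.metrics import roc_auc_score
                clf_aucs.append(roc_auc_score(fold["label"], fold["decision"]))
            aucs.append(np.mean(clf_aucs))
        assert 0.4 <= float(np.mean(aucs)) <= 0.6

    def test_minority_class_floor_enforced(self):
        X, y = self._separable()
        y = np.zeros(len(y), dtype=bool)
        y[:5] = True
        with pytest.raises(ValueError, match="10"):
            nested_cv_train(X, y, "high_risk", c_grid=[1.0], seed=0)

    def test_rfe_weights_nonzero_and_match_importance_order(self):
        X, y = self._separable(seed=2)
        clf, _ = nested_cv_train(X, y, "high_risk", c_grid=[1.0], seed=2,
                                 min_features=4)
        assert np.all(clf.weights != 0)
        imp = clf.feature_importance
        assert imp.iloc[0] == np.abs(clf.weights).max()


class TestSigmoidCalibration:
    def test_recovers_known_parameters(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0, 1.5, 5000)
        p = 1.0 / (1.0 + np.exp(-2.0 * d + 0.5))
        y = rng.uniform(size=5000) < p
        cal = fit_sigmoid_calibration(d, y)
        assert cal.A == pytest.approx(-2.0, abs=0.1)
        assert cal.B == pytest.approx(0.5, abs=0.1)

    def test_symmetric_data_centres_at_half(self):
        rng = np.random.default_rng(8)
        d = np.concatenate([rng.normal(1, 0.5, 500), rng.normal(-1, 0.5, 500)])
        y = np.concatenate([np.ones(500, bool), np.zeros(500, bool)])
        cal = fit_sigmoid_calibration(d, y)
        assert cal.predict([0.0])[0] == pytest.approx(0.5, abs=0.02)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            fit_sigmoid_calibration([1.0, 2.0], [True, True])

    def test_perfect_separation_stays_finite(self):
        d = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        y = d > 0
        cal = fit_sigmoid_calibration(d, y)
        assert np.isfinite(cal.A) and np.isfinite(cal.B)

    def test_monotone_mapping(self):
        cal = SigmoidCalibration(A=-2.0, B=0.3)
        p = cal.predict(np.linspace(-3, 3, 50))
        assert np.all(np.diff(p) > 0)


class TestSpi:
    @pytest.mark.parametrize(
        "p1, p2, expected", [(1, 1, 1.0), (0, 0, 0.0), (0.6, 0.2, 0.4)]
    )
    def test_average(self, p1, p2, expected):
        assert compute_spi(p1, p2) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_spi(1.2, 0.5)

    def test_strictly_increasing_in_each_argument(self):
        assert compute_spi(0.5, 0.5) < compute_spi(0.6, 0.5)
        assert compute_spi(0.5, 0.5) < compute_spi(0.5, 0.6)


@pytest.fixture(scope="module")
def trained_setup():
    cfg = SyntheticConfig(seed=3, **REPLICATE_CONFIG)
    disc, rep, truth = generate_replication_split(cfg)
    model = train_signature(disc, c_grid=[1.0], seed=0)
    return disc, rep, truth, model


class TestSignatureModel:
    def test_spi_bounded_and_deterministic(self, trained_setup):
        disc, rep, _, model = trained_setup
        spi = apply_signature(model, rep)
        assert ((spi >= 0) & (spi <= 1)).all()
        assert spi.equals(apply_signature(model, rep))

    def test_planted_signal_recovered_on_replication(self, trained_setup):
        from scipy.stats import kendalltau
        _, rep, _, model = trained_setup
        spi = apply_signature(model, rep)
        tau, p = kendalltau(spi, rep.os_months)
        assert tau > 0 and p < 0.01

    def test_spi_group_medians_ordered(self, trained_setup):
        _, rep, _, model = trained_setup
        spi = apply_signature(model, rep)
        os_m = rep.os_months
        labels = RiskLabelConfig()
        lo = spi[os_m >= labels.low_risk_threshold].median()
        mid = spi[(os_m >= labels.high_risk_threshold)
                  & (os_m < labels.low_risk_threshold)].median()
        hi = spi[os_m < labels.high_risk_threshold].median()
        assert lo > mid > hi

    def test_json_round_trip_preserves_predictions(self, trained_setup):
        from gliosurv.signature import SignatureModel
        _, rep, _, model = trained_setup
        clone = SignatureModel.from_json(model.to_json())
        pd.testing.assert_series_equal(
            apply_signature(clone, rep), apply_signature(model, rep)
        )

    def test_replication_survival_never_touches_training(self, trained_setup):
        # stage-1 training consumes the discovery cohort only; a second
        # train with identical inputs is bit-identical regardless of what
        # happens to replication labels
        disc, rep, _, model = trained_setup
        shuffled = rep.survival.copy()
        shuffled["os_months"] = shuffled["os_months"].sample(
            frac=1, random_state=0
        ).to_numpy()
        assert not shuffled["os_months"].equals(rep.survival["os_months"])
        model2 = train_signature(disc, c_grid=[1.0], seed=0)
        assert model2.to_json() == model.to_json()

    def test_monotone_recalibration_preserves_ranking(self, trained_setup):
        _, rep, _, model = trained_setup
        Z = model.preprocess(rep.features)
        p_high = model.calibration_high.predict(
            model.high_risk.decision_function(Z))
        p_low = model.calibration_low.predict(
            model.low_risk.decision_function(Z))
        spi = compute_spi(1 - p_high, p_low)
        # a shared increasing affine recalibration of both pseudo-probabilities
        # preserves the patient ranking by SPI exactly
        warped = compute_spi(
            0.5 * (1 - p_high) + 0.2, 0.5 * p_low + 0.2
        )
        pd.testing.assert_series_equal(
            pd.Series(spi).rank(), pd.Series(warped).rank()
        )

    def test_missing_feature_column_reported(self, trained_setup):
        _, rep, _, model = trained_setup
        needed = model.high_risk.selected_features[0]
        with pytest.raises(ValueError, match=needed):
            model.spi(rep.features.drop(columns=[needed]))


class TestRocAuc:
    def test_perfect_ranking(self):
        auc, _ = roc_auc_with_ci([1, 2, 3, 4], [0, 0, 1, 1], n_boot=100, seed=0)
        assert auc == 1.0

    def test_all_tied_scores(self):
        auc, _ = roc_auc_with_ci([1, 1, 1, 1], [0, 1, 0, 1], n_boot=100, seed=0)
        assert auc == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(4)
        scores = np.round(rng.normal(size=20), 1)
        y = rng.uniform(size=20) < 0.5
        auc, _ = roc_auc_with_ci(scores, y, n_boot=100, seed=0)
        num = den = 0.0
        for i in np.flatnonzero(y):
            for j in np.flatnonzero(~y):
                den += 1
                num += 1.0 if scores[i] > scores[j] else (
                    0.5 if scores[i] == scores[j] else 0.0)
        assert auc == pytest.approx(num / den, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc_with_ci([1, 2], [1, 1], n_boot=100, seed=0)
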