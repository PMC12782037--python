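"""Model contracts: OLS allometric recovery, transforms, training, transfer, freezing."""

import numpy as np
import pandas as pd
import pytest

from megamorph.biomod import (
    FrameStore,
    InvalidFoldError,
    LinearModelSpec,
    SingularFitError,
    TrainConfig,
    TrainedModel,
    apply_transform,
    fine_tune_regressor,
    fit_linear,
    invert_transform,
    predict_frames,
    predict_linear,
    train_classifier,
)
from megamorph.nnet import ConvNet


def _frame_table(n=60, seed=0, c=np.exp(0.7), b=1.5, noise=0.0):
    rng = np.random.default_rng(seed)
    area = rng.uniform(1.0, 30.0, n)
    mass = c * area**b * np.exp(rng.normal(0, noise, n))
    return pd.DataFrame({
        "specimen_id": [f"S{i:04d}" for i in range(n)],
        "camera_id": 0,
        "frame_index": 0,
        "area_mm2": area,
        "mfd_mm": rng.uniform(1, 10, n),
        "perimeter_mm": rng.uniform(3, 40, n),
        "mass_mg": mass,
    })


class TestLinear:
    def test_noiseless_log_recovery_exact(self):
        df = _frame_table()
        fit = fit_linear(df, LinearModelSpec(("A",), "log"))
        assert fit.coef[0] == pytest.approx(0.7, abs=1e-9)
        assert fit.coef[1] == pytest.approx(1.5, abs=1e-9)

    def test_log1p_constructed_inverse_recovery(self):
        df = _frame_table()
        df["mass_mg"] = np.exp(0.3 + 1.2 * np.log(df["area_mm2"])) - 1.0
        fit = fit_linear(df, LinearModelSpec(("A",), "log1p"))
        assert fit.coef[0] == pytest.approx(0.3, abs=1e-9)
        assert fit.coef[1] == pytest.approx(1.2, abs=1e-9)

    def test_noisy_slope_within_three_standard_errors(self):
        import statsmodels.api as sm

        df = _frame_table(n=2000, noise=0.3)
        fit = fit_linear(df, LinearModelSpec(("A",), "log"))
        X = sm.add_constant(np.log(df["area_mm2"]))
        se = sm.OLS(np.log(df["mass_mg"]), X).fit().bse.iloc[1]
        assert abs(fit.coef[1] - 1.5) < 3 * se

    def test_roundtrip_predictions_on_training_frames(self):
        df = _frame_table()
        fit = fit_linear(df, LinearModelSpec(("A",), "log"))
        pred = predict_linear(fit, df)
        assert np.allclose(pred["pred_mass_mg"], df["mass_mg"], rtol=1e-6)

    def test_duplicated_predictor_is_singular(self):
        df = _frame_table()
        df["mfd_mm"] = df["area_mm2"]
        with pytest.raises(SingularFitError):
            fit_linear(df, LinearModelSpec(("A", "MFD"), "log"))

    def test_empty_predictor_subset_rejected(self):
        with pytest.raises(ValueError):
            LinearModelSpec((), "log")

    def test_nonpositive_feature_names_frame(self):
        df = _frame_table(n=10)
        df.loc[3, "area_mm2"] = 0.0
        with pytest.raises(ValueError, match="S0003"):
            fit_linear(df, LinearModelSpec(("A",), "log"))

    def test_negative_identity_predictions_clipped_to_zero(self):
        df = _frame_table(n=30)
        df["mass_mg"] = -5.0 + 0.1 * np.log(df["area_mm2"])
        fit = fit_linear(df, LinearModelSpec(("A",), "identity"))
        assert (predict_linear(fit, df)["pred_mass_mg"] >= 0).all()


class TestTransforms:
    @pytest.mark.parametrize("t", ["identity", "log", "log1p"])
    def test_inverse_identity_on_study_mass_range(self, t):
        m = np.array([0.02, 1.0, 211.63])
        assert np.allclose(invert_transform(apply_transform(m, t), t), m, atol=1e-12)

    def test_unknown_transform_rejected(self):
        with pytest.raises(ValueError):
            apply_transform(np.ones(2), "sqrt")


def _toy_store(n_specimens=16, frames_per=4, size=32, seed=0):
    """Two visually distinct classes: small vs large centered squares.

    Mass is a deterministic monotone function of the square's side, so both
    the classification and the regression signal are learnable by design.
    """
    rng = np.random.default_rng(seed)
    X, sids = [], []
    labels, masses = {}, {}
    for i in range(n_specimens):
        sid = f"S{i:04d}"
        cls = i % 2
        side = (6 if cls == 0 else 14) + int(rng.integers(0, 3))
        labels[sid] = "small" if cls == 0 else "large"
        masses[sid] = 0.05 * side**2
        for _ in range(frames_per):
            img = np.zeros((size, size), np.float32)
            oy, ox = rng.integers(2, size - side - 2, 2)
            img[oy : oy + side, ox : ox + side] = 0.9
            X.append(img)
            sids.append(sid)
    return (
        FrameStore(
            X=np.stack(X)[:, None],
            specimen_id=np.array(sids),
            camera_id=np.zeros(len(sids), int),
            frame_index=np.arange(len(sids)),
        ),
        labels,
        masses,
    )


SPLIT = dict(
    train=[f"S{i:04d}" for i in range(10)],
    val=[f"S{i:04d}" for i in range(10, 12)],
    test=[f"S{i:04d}" for i in range(12, 16)],
)
TINY = dict(input_size=32, channels=(4, 8), batch_size=16)


class TestClassifier:
    def test_separable_classes_reach_high_f1(self):
        store, labels, _ = _toy_store()
        cfg = TrainConfig(task="classify", epochs=15, lr=5e-3, seed=0, **TINY)
        model = train_classifier(store, labels, SPLIT["train"], SPLIT["val"], cfg)
        pred = predict_frames(model, store, SPLIT["test"], 0, labels)
        assert (pred.pred_label == pred.true_label).mean() >= 0.95

    def test_checkpoint_is_argmin_of_validation_curve(self):
        store, labels, _ = _toy_store()
        cfg = TrainConfig(task="classify", epochs=6, lr=5e-3, seed=1, **TINY)
        model = train_classifier(store, labels, SPLIT["train"], SPLIT["val"], cfg)
        vals = [v for _, v in model.loss_curve]
        assert model.checkpoint_epoch == int(np.argmin(vals))

    def test_same_seed_identical_predictions(self):
        store, labels, _ = _toy_store()
        cfg = TrainConfig(task="classify", epochs=3, lr=5e-3, seed=4, **TINY)
        a = train_classifier(store, labels, SPLIT["train"], SPLIT["val"], cfg)
        b = train_classifier(store, labels, SPLIT["train"], SPLIT["val"], cfg)
        pa = predict_frames(a, store, SPLIT["test"], 0, labels)
        pb = predict_frames(b, store, SPLIT["test"], 0, labels)
        assert pa.equals(pb)

    def test_class_missing_from_train_raises(self):
        store, labels, _ = _toy_store()
        only_small = [s for s in SPLIT["train"] if labels[s] == "small"]
        cfg = TrainConfig(task="classify", epochs=2, **TINY)
        with pytest.raises(InvalidFoldError, match="large"):
            train_classifier(store, labels, only_small, SPLIT["val"], cfg)


class TestRegressor:
    def test_learnable_monotone_signal(self):
        store, _, masses = _toy_store(n_specimens=24, frames_per=6)
        train = [f"S{i:04d}" for i in range(16)]
        val = [f"S{i:04d}" for i in range(16, 20)]
        test = [f"S{i:04d}" for i in range(20, 24)]
        cfg = TrainConfig(task="regress", epochs=25, lr=5e-3, seed=0, **TINY)
        model = fine_tune_regressor(None, store, masses, train, val, cfg)
        pred = predict_frames(model, store, test, 0, masses)
        y, p = pred.true_mass_mg.to_numpy(), pred.pred_mass_mg.to_numpy()
        r2 = 1 - ((p - y) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert r2 >= 0.8

    def test_frozen_base_is_bit_identical(self):
        store, labels, masses = _toy_store()
        ccfg = TrainConfig(task="classify", epochs=2, **TINY)
        base = train_classifier(store, labels, SPLIT["train"], SPLIT["val"], ccfg)
        before = {k: v.copy() for k, v in base.net.params.items() if k.startswith("conv")}
        rcfg = TrainConfig(task="regress", frozen_base=True, epochs=3, **TINY)
        reg = fine_tune_regressor(base, store, masses, SPLIT["train"], SPLIT["val"], rcfg)
        for k, v in before.items():
            assert v.tobytes() == reg.net.params[k].tobytes()

    def test_unfrozen_base_changes(self):
        store, labels, masses = _toy_store()
        ccfg = TrainConfig(task="classify", epochs=2, **TINY)
        base = train_classifier(store, labels, SPLIT["train"], SPLIT["val"], ccfg)
        before = {k: v.copy() for k, v in base.net.params.items() if k.startswith("conv")}
        rcfg = TrainConfig(task="regress", frozen_base=False, epochs=3, **TINY)
        reg = fine_tune_regressor(base, store, masses, SPLIT["train"], SPLIT["val"], rcfg)
        assert any(not np.array_equal(before[k], reg.net.params[k]) for k in before)

    def test_frozen_without_base_rejected(self):
        store, _, masses = _toy_store()
        cfg = TrainConfig(task="regress", frozen_base=True, epochs=1, **TINY)
        with pytest.raises(ValueError, match="frozen_base"):
            fine_tune_regressor(None, store, masses, SPLIT["train"], SPLIT["val"], cfg)

    @pytest.mark.parametrize("t", ["identity", "log", "log1p"])
    def test_oracle_constant_head_back_transforms_exactly(self, t):
        store, _, masses = _toy_store()
        net = ConvNet.init(32, 1, (4, 8), seed=0)
        net.params["head_W"][:] = 0.0
        net.params["head_b"][:] = apply_transform(np.array([5.0]), t).astype(np.float32)
        model = TrainedModel(task="regress", net=net, loss_curve=[], checkpoint_epoch=0,
                             target_transform=t)
        pred = predict_frames(model, store, SPLIT["test"], 0, masses)
        assert np.allclose(pred.pred_mass_mg, 5.0, atol=1e-4)

    def test_prediction_bookkeeping_and_determinism(self):
        store, _, masses = _toy_store()
        net = ConvNet.init(32, 1, (4, 8), seed=0)
        model = TrainedModel(task="regress", net=net, loss_curve=[], checkpoint_epoch=0,
                             target_transform="log1p")
        a = predict_frames(model, store, SPLIT["test"], 2, masses)
        b = predict_frames(model, store, SPLIT["test"], 2, masses)
        assert a.equals(b)
        assert set(a.specimen_id) == set(SPLIT["test"])
        assert (a.fold == 2).all()
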