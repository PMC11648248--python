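import numpy as np
import pandas as pd
import pytest

import paddyopt as po
from paddyopt.ensemble import BenefitResponseModel, OptimizerError
from paddyopt.synthetic import SyntheticConfig


def _inputs_frame(n=240, seed=0, method="MT"):
    rng = np.random.default_rng(seed)
    means = po.method_mean_inputs()[method]
    df = pd.DataFrame({inp: rng.normal(means[inp], 0.15 * means[inp], n)
                       for inp in po.INPUT_COLUMNS}).abs()
    df.insert(0, "method", method)
    return df


@pytest.fixture(scope="module")
def linear_signal_fit():
    df = _inputs_frame(seed=1)
    df["yield"] = 2.0 * df["n_rate"]  # noise-free planted signal
    model = BenefitResponseModel(df, "MT")
    return model.fit(seed=0, benefits=("yield",))


def test_planted_linear_signal_recovered(linear_signal_fit):
    r2 = max(linear_signal_fit.metrics("yield", "rf").r2,
             linear_signal_fit.metrics("yield", "gbm").r2)
    assert r2 >= 0.99


def test_permuted_labels_have_no_signal():
    df = _inputs_frame(seed=2)
    rng = np.random.default_rng(3)
    df["yield"] = rng.permutation(2.0 * df["n_rate"].to_numpy())
    res = BenefitResponseModel(df, "MT").fit(seed=0, benefits=("yield",))
    assert res.metrics("yield", "rf").r2 <= 0.1
    assert res.metrics("yield", "gbm").r2 <= 0.1


def test_fit_is_deterministic():
    df = _inputs_frame(seed=4)
    df["yield"] = 2.0 * df["n_rate"] + 0.5 * df["k_rate"]
    r1 = BenefitResponseModel(df, "MT").fit(seed=9, benefits=("yield",))
    r2 = BenefitResponseModel(df, "MT").fit(seed=9, benefits=("yield",))
    assert np.array_equal(r1.heldout["yield"]["pred_rf"], r2.heldout["yield"]["pred_rf"])
    assert np.array_equal(r1.heldout["yield"]["pred_gbm"], r2.heldout["yield"]["pred_gbm"])


def test_importance_ranks_planted_signal_first(linear_signal_fit):
    imp = linear_signal_fit.importance(n_repeats=5)
    for which in ("rf", "gbm"):
        sub = imp[(imp["benefit"] == "yield") & (imp["model"] == which)]
        assert sub["importance"].sum() == pytest.approx(1.0, abs=1e-9)
        top = sub.sort_values("importance", ascending=False).iloc[0]
        assert top["input"] == "n_rate"
        assert top["importance"] >= 0.8


def test_null_input_ranked_last():
    df = _inputs_frame(seed=5)
    rng = np.random.default_rng(6)
    df["yield"] = (1.5 * df["n_rate"] + 0.8 * df["k_rate"] + 10 * df["seed_rate"]
                   + rng.normal(0, 5, len(df)))  # p_rate absent by construction
    res = BenefitResponseModel(df, "MT").fit(seed=0, benefits=("yield",))
    imp = res.importance(n_repeats=5)
    for which in ("rf", "gbm"):
        sub = imp[(imp["benefit"] == "yield") & (imp["model"] == which)]
        worst = sub.sort_values("importance").iloc[0]
        assert worst["input"] == "p_rate"


def test_partial_dependence_contract(linear_signal_fit):
    curve = linear_signal_fit.partial_dependence("yield", "n_rate", grid_size=15)
    assert len(curve.grid) == 15 and len(curve.values) == 15
    assert np.all(np.diff(curve.grid) > 0)
    lo, hi = linear_signal_fit.input_box()["n_rate"]
    assert curve.grid[0] == pytest.approx(lo) and curve.grid[-1] == pytest.approx(hi)
    assert np.all(np.isfinite(curve.values))
    # monotone planted signal -> curve increases overall
    assert curve.values[-1] > curve.values[0]


def test_unknown_input_rejected(linear_signal_fit):
    with pytest.raises(OptimizerError):
        linear_signal_fit.partial_dependence("yield", "rainfall")


def test_planted_concave_optimum_recovered_smoke():
    """Single-method, single-seed version of the deeper recovery suite."""
    cfg = po.validation_config(7)
    cfg.sizes = {"MT": 302}
    cfg = po.calibrate_mean_yields(cfg, targets={"MT": 10033.2})
    cohort = po.generate_cohort(cfg)
    coeffs = po.load_coefficients()
    bdf = po.benefit_table(cohort, coeffs)
    joined = cohort.data[list(po.INPUT_COLUMNS) + ["method"]].join(
        bdf[list(po.BENEFIT_COLUMNS)])
    res = po.fit_benefit_models(joined, seed=7, benefits=("yield",),
                                test_frac=0.1)["MT"]
    surface = cfg.surface("MT")
    box = res.input_box()
    rec = res.recommend(objective="yield", grid_size=9)
    for inp in po.INPUT_COLUMNS:
        lo, hi = box[inp]
        step = (hi - lo) / 8
        opt = float(np.clip(surface.optimum[inp], lo, hi))
        curve = res.partial_dependence("yield", inp, grid_size=21)
        assert abs(curve.peak(window=5) - opt) <= step
        assert abs(rec.recommended[inp] - opt) <= step


def test_pinned_constraints_return_baseline(linear_signal_fit):
    baseline = {inp: float(linear_signal_fit.model.data[inp].mean())
                for inp in po.INPUT_COLUMNS}
    constraints = {inp: (baseline[inp], baseline[inp]) for inp in po.INPUT_COLUMNS}
    rec = linear_signal_fit.recommend(objective="yield", baseline=baseline,
                                      constraints=constraints)
    for inp in po.INPUT_COLUMNS:
        assert rec.recommended[inp] == pytest.approx(baseline[inp])
        assert rec.pct_change[inp] == pytest.approx(0.0)
    assert all(abs(d) < 1e-9 for d in rec.benefit_deltas.values())


def test_ghg_objective_reduces_nitrogen(calibrated_cohort, calibrated_benefits):
    _, cohort = calibrated_cohort
    joined = cohort.data[list(po.INPUT_COLUMNS) + ["method"]].join(
        calibrated_benefits[list(po.BENEFIT_COLUMNS)])
    res = po.fit_benefit_models(joined, seed=0, benefits=("ghg",),
                                methods=("MT",))["MT"]
    rec = res.recommend(objective="ghg")  # minimized by default
    assert rec.recommended["n_rate"] <= rec.baseline["n_rate"]
    assert rec.benefit_deltas["ghg"] < 0


def test_empty_feasible_box_rejected(linear_signal_fit):
    with pytest.raises(OptimizerError):
        linear_signal_fit.recommend(objective="yield",
                                    constraints={"n_rate": (200.0, 100.0)})


# -- mixed-effects cross-check ------------------------------------------------

def _mixed_frame(seed, effect=2.0, noise=0.5):
    """Four-method frame with a planted effect on the pooled z-scale of N,
    plus a per-method intercept (the random effect the model absorbs)."""
    rng = np.random.default_rng(seed + 999_331)  # stream distinct from inputs
    frames = []
    for i, (method, shift) in enumerate(zip(po.METHODS, (0.0, 1.0, -1.0, 0.5))):
        # identical input distributions across groups, so the group intercepts
        # are orthogonal to the inputs and the planted slope is identifiable
        df = _inputs_frame(n=150, seed=seed * 10 + i, method="MT")
        df["method"] = method
        df["_shift"] = shift
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    # equalize group means exactly so the planted intercepts cannot leak into
    # the slope through finite-sample group imbalance
    for inp in po.INPUT_COLUMNS:
        out[inp] = out[inp] - out.groupby("method")[inp].transform("mean") + out[inp].mean()
    z = (out["n_rate"] - out["n_rate"].mean()) / out["n_rate"].std(ddof=0)
    out["eb"] = effect * z + out.pop("_shift") + rng.normal(0, noise, len(out))
    return out


def test_mixed_effects_recovers_planted_coefficient():
    df = _mixed_frame(seed=0)
    report = po.mixed_effects_check(df, "eb")
    lo, hi = report.conf_int.loc["n_rate", 0], report.conf_int.loc["n_rate", 1]
    assert lo <= 2.0 <= hi
    assert report.estimates["n_rate"] == pytest.approx(2.0, abs=0.2)


def test_mixed_effects_null_calibration():
    """With a pure-noise response, the 95% intervals of the four input
    effects cover zero at close to their nominal rate (seeded, so exact)."""
    covered = total = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        df = _mixed_frame(seed=seed, effect=0.0, noise=1.0)
        df["eb"] = rng.normal(0, 1.0, len(df))
        report = po.mixed_effects_check(df, "eb")
        for inp in po.INPUT_COLUMNS:
            total += 1
            covered += report.conf_int.loc[inp, 0] <= 0 <= report.conf_int.loc[inp, 1]
    assert total == 40
    assert covered >= 36  # ~nominal 95% coverage over 40 intervals


def test_mixed_effects_standardization_invariance():
    df = _mixed_frame(seed=3)
    r1 = po.mixed_effects_check(df, "eb")
    df2 = df.copy()
    df2["k_rate"] = df2["k_rate"] * 1000.0
    r2 = po.mixed_effects_check(df2, "eb")
    for inp in po.INPUT_COLUMNS:
        assert r1.estimates[inp] == pytest.approx(r2.estimates[inp], abs=1e-8)


def test_mixed_effects_needs_two_methods():
    df = _inputs_frame(seed=8)
    df["eb"] = 1.0
    with pytest.raises(OptimizerError):
        po.mixed_effects_check(df, "eb")
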