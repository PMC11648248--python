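"""Input -> benefit surrogate models and the input-recommendation search.

Per planting method and per benefit indicator, two tree-ensemble regressors —
a random forest and a gradient boosting machine — map the four optimizable
inputs (N, P2O5, K2O, seed, kg/ha) to the benefit.  On top of the fitted
surrogates the module provides permutation variable importance, partial
dependence curves, a constrained coordinate search that proposes input
adjustments maximizing either one benefit or a composite TOPSIS closeness,
and a mixed-effects (random intercept per method) regression cross-check of
the input effects.

Model-selection choices are deliberately small and fixed: the forest uses a
cross-validated choice of variables per split (mtry in {2, 3}) at a fixed
tree count, and the boosting machine picks its iteration count by
early stopping on an internal validation fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import GridSearchCV

from .io import BENEFIT_COLUMNS, INPUT_COLUMNS
from .metrics import MetricReport, compute_metrics
from .scoring import DEFAULT_COST_FLAGS

MIN_RECORDS = 30


class OptimizerError(ValueError):
    pass


@dataclass
class DependenceCurve:
    """Partial dependence of one benefit on one input."""

    input_name: str
    benefit: str
    grid: np.ndarray
    values: np.ndarray

    @property
    def argmax(self) -> float:
        return float(self.grid[int(np.argmax(self.values))])

    @property
    def argmin(self) -> float:
        return float(self.grid[int(np.argmin(self.values))])

    def peak(self, window: int = 3) -> float:
        """Sub-grid estimate of the curve's maximizer.

        Applies a centered moving average of the given window, then refines
        the discrete argmax by the vertex of the parabola through it and its
        two neighbors (when interior and concave).  This is the standard way
        to read a smooth peak off a sampled noisy curve.
        """
        vals = np.convolve(self.values, np.ones(window) / window, mode="valid")
        k = (window - 1) // 2
        grid = self.grid[k:len(self.grid) - k] if k else self.grid
        step = grid[1] - grid[0] if len(grid) > 1 else 0.0
        i = int(np.argmax(vals))
        arg = float(grid[i])
        if 0 < i < len(grid) - 1:
            denom = vals[i - 1] - 2 * vals[i] + vals[i + 1]
            if denom < 0:
                delta = 0.5 * (vals[i - 1] - vals[i + 1]) / denom
                if abs(delta) <= 1:
                    arg = float(grid[i] + delta * step)
        return arg

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.input_name: self.grid, self.benefit: self.values})


@dataclass
class Recommendation:
    """Proposed input adjustment for one method."""

    method: str
    objective: str
    baseline: dict[str, float]
    recommended: dict[str, float]
    predicted_before: dict[str, float]
    predicted_after: dict[str, float]
    code_before: str | None = None
    code_after: str | None = None

    @property
    def pct_change(self) -> dict[str, float]:
        return {
            k: 100.0 * (self.recommended[k] - self.baseline[k]) / self.baseline[k]
            if self.baseline[k] != 0 else float("nan")
            for k in self.baseline
        }

    @property
    def benefit_deltas(self) -> dict[str, float]:
        return {k: self.predicted_after[k] - self.predicted_before[k]
                for k in self.predicted_before}

    def summary(self) -> str:
        lines = [f"Recommendation for {self.method} (objective: {self.objective})"]
        for k in self.baseline:
            lines.append(
                f"  {k}: {self.baseline[k]:.1f} -> {self.recommended[k]:.1f} kg/ha "
                f"({self.pct_change[k]:+.1f}%)"
            )
        for b, d in self.benefit_deltas.items():
            lines.append(f"  predicted {b}: {self.predicted_before[b]:.2f} -> "
                         f"{self.predicted_after[b]:.2f} ({d:+.2f})")
        if self.code_before is not None:
            lines.append(f"  benefit code: {self.code_before} -> {self.code_after}")
        return "\n".join(lines)


class BenefitResponseModel:
    """Surrogate input->benefit models for one planting method.

    Parameters
    ----------
    data : DataFrame holding the four input columns and the benefit columns
        for the records of one method.
    method : the planting method code.
    mean_matrix : optional 4 x 5 method-mean benefit matrix of the whole
        cohort; required for the composite-TOPSIS recommendation objective.
    """

    def __init__(self, data: pd.DataFrame, method: str,
                 mean_matrix: pd.DataFrame | None = None):
        if len(data) < MIN_RECORDS:
            raise OptimizerError(
                f"need >= {MIN_RECORDS} records per method, got {len(data)} for {method}"
            )
        self.data = data.reset_index(drop=True)
        self.method = method
        self.mean_matrix = mean_matrix

    def fit(self, seed: int = 0, benefits: tuple[str, ...] = BENEFIT_COLUMNS,
            n_trees: int = 200, mtry_grid: tuple[int, ...] = (2, 3),
            cv_folds: int = 3, gbm_max_iter: int = 400,
            test_frac: float = 0.25) -> "BenefitResponseResults":
        """Fit forest + boosting per benefit on a 3:1 train/test split."""
        rng = np.random.default_rng(seed)
        n = len(self.data)
        perm = rng.permutation(n)
        n_test = max(int(round(test_frac * n)), 1)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        X = self.data[list(INPUT_COLUMNS)]
        models: dict[str, dict] = {}
        heldout: dict[str, dict] = {}
        for benefit in benefits:
            y = self.data[benefit]
            keep_tr = train_idx[~y.iloc[train_idx].isna().to_numpy()]
            keep_te = test_idx[~y.iloc[test_idx].isna().to_numpy()]
            if y.iloc[keep_tr].nunique() <= 1:
                warnings.warn(f"constant benefit {benefit!r} for {self.method}; skipped")
                continue
            Xtr, ytr = X.iloc[keep_tr], y.iloc[keep_tr]
            rf_seed = int(rng.integers(2**31))
            search = GridSearchCV(
                RandomForestRegressor(n_estimators=n_trees, min_samples_leaf=5,
                                      random_state=rf_seed),
                {"max_features": list(mtry_grid)}, cv=cv_folds,
                scoring="neg_mean_squared_error",
            )
            search.fit(Xtr, ytr)
            rf = search.best_estimator_
            gbm = GradientBoostingRegressor(
                n_estimators=gbm_max_iter, learning_rate=0.05, subsample=0.8,
                validation_fraction=0.2, n_iter_no_change=15,
                random_state=int(rng.integers(2**31)),
            )
            gbm.fit(Xtr, ytr)
            models[benefit] = {"rf": rf, "gbm": gbm,
                               "mtry": search.best_params_["max_features"],
                               "gbm_iters": gbm.n_estimators_}
            Xte, yte = X.iloc[keep_te], y.iloc[keep_te]
            heldout[benefit] = {
                "X": Xte, "y": yte.to_numpy(),
                "pred_rf": rf.predict(Xte) if len(Xte) else np.array([]),
                "pred_gbm": gbm.predict(Xte) if len(Xte) else np.array([]),
            }
        return BenefitResponseResults(model=self, models=models, heldout=heldout,
                                      seed=seed)


@dataclass
class BenefitResponseResults:
    """Fitted surrogates, held-out predictions, and the analysis surface."""

    model: BenefitResponseModel
    models: dict[str, dict]
    heldout: dict[str, dict]
    seed: int
    _perm_cache: dict = field(default_factory=dict, repr=False)

    # -- evaluation ---------------------------------------------------------
    def metrics(self, benefit: str, which: str = "rf") -> MetricReport:
        h = self.heldout[benefit]
        return compute_metrics(h["y"], h[f"pred_{which}"])

    def metrics_table(self) -> pd.DataFrame:
        rows = []
        for benefit in self.models:
            for which in ("rf", "gbm"):
                m = self.metrics(benefit, which).as_dict()
                m.update({"benefit": benefit, "model": which})
                rows.append(m)
        return pd.DataFrame(rows).set_index(["benefit", "model"])

    def summary(self) -> str:
        lines = [f"BenefitResponseModel[{self.model.method}] "
                 f"(n={len(self.model.data)}, seed={self.seed})"]
        lines.append(self.metrics_table().round(4).to_string())
        return "\n".join(lines)

    # -- importance ---------------------------------------------------------
    def importance(self, n_repeats: int = 10) -> pd.DataFrame:
        """Held-out permutation importance fractions per benefit and model.

        Fractions are clipped at zero and normalized to sum to 1 per
        (benefit, model).
        """
        rows = []
        rng = np.random.default_rng(self.seed + 1)
        for benefit, ms in self.models.items():
            h = self.heldout[benefit]
            for which in ("rf", "gbm"):
                imp = permutation_importance(
                    ms[which], h["X"], h["y"], n_repeats=n_repeats,
                    random_state=int(rng.integers(2**31)),
                ).importances_mean
                imp = np.clip(imp, 0.0, None)
                total = imp.sum()
                frac = imp / total if total > 0 else np.full(len(imp), 1.0 / len(imp))
                for inp, f in zip(INPUT_COLUMNS, frac):
                    rows.append({"benefit": benefit, "model": which,
                                 "input": inp, "importance": f})
        return pd.DataFrame(rows)

    # -- partial dependence --------------------------------------------------
    def input_box(self, lo_pct: float = 5.0, hi_pct: float = 95.0) -> dict[str, tuple[float, float]]:
        """Observed percentile box per input (default 5th-95th)."""
        box = {}
        for inp in INPUT_COLUMNS:
            vals = self.model.data[inp].to_numpy()
            box[inp] = (float(np.percentile(vals, lo_pct)),
                        float(np.percentile(vals, hi_pct)))
        return box

    def partial_dependence(self, benefit: str, input_name: str,
                           grid_size: int = 20, which: str = "rf") -> DependenceCurve:
        """Average prediction as one input varies over its 5th-95th percentile
        range, the other inputs held at their observed data values."""
        if input_name not in INPUT_COLUMNS:
            raise OptimizerError(f"unknown input {input_name!r}")
        lo, hi = self.input_box()[input_name]
        grid = np.linspace(lo, hi, grid_size)
        est = self.models[benefit][which]
        X = self.model.data[list(INPUT_COLUMNS)].reset_index(drop=True)
        n = len(X)
        Xrep = pd.concat([X] * grid_size, ignore_index=True)
        Xrep[input_name] = np.repeat(grid, n)
        values = est.predict(Xrep).reshape(grid_size, n).mean(axis=1)
        return DependenceCurve(input_name=input_name, benefit=benefit,
                               grid=grid, values=values)

    # -- recommendation search ----------------------------------------------
    def _predict_vector(self, x: dict[str, float], which: str,
                        smooth: np.ndarray | None = None) -> dict[str, float]:
        """Predicted benefit vector at x; with ``smooth`` (a points x inputs
        offset matrix), the locally averaged prediction around x instead of
        the raw point prediction, which is far less noisy for tree models.
        ``which`` is ``"rf"``, ``"gbm"`` or ``"avg"`` (mean of both)."""
        base = np.array([x[i] for i in INPUT_COLUMNS], dtype=float)
        pts = base[None, :] if smooth is None else base[None, :] + smooth
        frame = pd.DataFrame(pts, columns=list(INPUT_COLUMNS))
        out = {}
        for b, ms in self.models.items():
            if which == "avg":
                out[b] = float((ms["rf"].predict(frame) + ms["gbm"].predict(frame)).mean() / 2)
            else:
                out[b] = float(ms[which].predict(frame).mean())
        return out

    def _composite_closeness(self, vec: dict[str, float]) -> float:
        """TOPSIS closeness of a predicted benefit vector in the fixed space
        anchored at the cohort's method-mean matrix (GHG as cost)."""
        if self.mean_matrix is None:
            raise OptimizerError("composite objective needs the cohort mean matrix")
        M = self.mean_matrix[list(BENEFIT_COLUMNS)].to_numpy(dtype=float)
        cost = np.array([DEFAULT_COST_FLAGS[c] for c in BENEFIT_COLUMNS])
        norms = np.sqrt((M**2).sum(axis=0))
        w = np.full(M.shape[1], 1.0 / M.shape[1])
        V = M / norms * w
        ideal = np.where(cost, V.min(axis=0), V.max(axis=0))
        anti = np.where(cost, V.max(axis=0), V.min(axis=0))
        v = np.array([vec[c] for c in BENEFIT_COLUMNS]) / norms * w
        dp = float(np.sqrt(((v - ideal) ** 2).sum()))
        dm = float(np.sqrt(((v - anti) ** 2).sum()))
        return dm / (dp + dm) if dp + dm > 0 else 0.5

    @property
    def mean_matrix(self) -> pd.DataFrame | None:
        return self.model.mean_matrix

    def recommend(self, objective: str = "composite",
                  baseline: dict[str, float] | None = None,
                  constraints: dict[str, tuple[float, float]] | None = None,
                  grid_size: int = 9, which: str = "avg",
                  minimize: bool | None = None,
                  max_sweeps: int = 10,
                  bands=None) -> Recommendation:
        """Constrained coordinate-descent grid search over the input box.

        ``objective`` is ``"composite"`` (TOPSIS closeness of the predicted
        benefit vector, GHG as cost) or one of the five benefit names; GHG is
        minimized by default, everything else maximized.  The search box
        defaults to the observed 5th-95th percentile per input, which forbids
        extrapolating beyond training support.

        Candidates are scored on a locally averaged ("kernel smoothed")
        prediction — a fixed set of Gaussian offsets with scale one grid step
        per coordinate — because raw point predictions of tree ensembles are
        too noisy to rank neighboring grid points reliably.  After the
        coordinate sweeps converge, each coordinate is refined to the vertex
        of the parabola through its best grid point and neighbors, giving
        sub-grid resolution on smooth objectives.
        """
        box = dict(self.input_box())
        if constraints:
            box.update(constraints)
        for inp, (lo, hi) in box.items():
            if lo > hi:
                raise OptimizerError(f"empty feasible box for {inp}: ({lo}, {hi})")
        if baseline is None:
            baseline = {inp: float(self.model.data[inp].mean()) for inp in INPUT_COLUMNS}
        if minimize is None:
            minimize = objective == "ghg"
        sign = -1.0 if minimize else 1.0
        grids = {inp: np.linspace(box[inp][0], box[inp][1], grid_size)
                 for inp in INPUT_COLUMNS}
        steps = np.array([(box[inp][1] - box[inp][0]) / max(grid_size - 1, 1)
                          for inp in INPUT_COLUMNS])
        offsets = np.random.default_rng(171717).normal(size=(64, len(INPUT_COLUMNS)))
        smooth = offsets * steps

        def score(x: dict[str, float]) -> float:
            vec = self._predict_vector(x, which, smooth=smooth)
            if objective == "composite":
                return self._composite_closeness(vec)
            if objective not in vec:
                raise OptimizerError(f"unknown objective {objective!r}")
            return sign * vec[objective]

        current = {inp: float(np.clip(baseline[inp], *box[inp])) for inp in INPUT_COLUMNS}
        best_val = score(current)
        for _ in range(max_sweeps):
            moved = False
            for inp in INPUT_COLUMNS:
                cand_best, cand_val = current[inp], best_val
                for g in grids[inp]:
                    trial = dict(current)
                    trial[inp] = float(g)
                    val = score(trial)
                    if val > cand_val + 1e-12:
                        cand_best, cand_val = float(g), val
                if cand_best != current[inp]:
                    current[inp] = cand_best
                    best_val = cand_val
                    moved = True
            if not moved:
                break
        # parabolic sub-grid refinement per coordinate
        for k, inp in enumerate(INPUT_COLUMNS):
            g = grids[inp]
            if len(g) < 3 or g[1] == g[0]:
                continue
            i = int(np.argmin(np.abs(g - current[inp])))
            if i == 0 or i == len(g) - 1:
                continue
            vals = []
            for gg in (g[i - 1], g[i], g[i + 1]):
                trial = dict(current)
                trial[inp] = float(gg)
                vals.append(score(trial))
            denom = vals[0] - 2 * vals[1] + vals[2]
            if denom < 0:
                delta = 0.5 * (vals[0] - vals[2]) / denom
                if abs(delta) <= 1:
                    current[inp] = float(np.clip(g[i] + delta * steps[k], *box[inp]))
        before = self._predict_vector(baseline, which)
        after = self._predict_vector(current, which)
        code_before = code_after = None
        if bands is not None:
            from .classification import classify

            code_before = classify(before, bands)
            code_after = classify(after, bands)
        return Recommendation(method=self.model.method, objective=objective,
                              baseline=dict(baseline), recommended=current,
                              predicted_before=before, predicted_after=after,
                              code_before=code_before, code_after=code_after)


def fit_benefit_models(cohort_benefits: pd.DataFrame, seed: int = 0,
                       benefits: tuple[str, ...] = BENEFIT_COLUMNS,
                       methods: tuple[str, ...] | None = None,
                       **fit_kwargs) -> dict[str, BenefitResponseResults]:
    """Fit per-method surrogate models from a joined inputs+benefits table.

    ``cohort_benefits`` must hold ``method``, the four input columns and the
    benefit columns (as produced by joining the cohort with its benefit
    table).
    """
    mean_matrix = cohort_benefits.groupby("method", sort=False)[list(BENEFIT_COLUMNS)].mean()
    out = {}
    for method, grp in cohort_benefits.groupby("method", sort=False):
        if methods is not None and method not in methods:
            continue
        model = BenefitResponseModel(grp, method, mean_matrix=mean_matrix)
        out[method] = model.fit(seed=seed, benefits=benefits, **fit_kwargs)
    return out


# -- mixed-effects cross-check ----------------------------------------------

@dataclass
class MixedEffectsReport:
    """Standardized fixed-effect estimates with intervals, per input."""

    benefit: str
    estimates: pd.Series
    conf_int: pd.DataFrame
    random_intercept_var: float
    singular: bool = False

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"estimate": self.estimates})
        out["ci_low"] = self.conf_int[0]
        out["ci_high"] = self.conf_int[1]
        return out


def mixed_effects_check(cohort_benefits: pd.DataFrame, benefit: str) -> MixedEffectsReport:
    """Random-intercept model: benefit ~ z(N) + z(P2O5) + z(K2O) + z(seed),
    grouping on planting method.

    Inputs are z-standardized; the response is left on its own scale.  A
    singular random-effects fit falls back to plain OLS with the flag set.
    """
    import statsmodels.api as sm

    df = cohort_benefits.dropna(subset=[benefit]).copy()
    if df["method"].nunique() < 2:
        raise OptimizerError("need >= 2 methods for the mixed-effects check")
    Z = pd.DataFrame({inp: (df[inp] - df[inp].mean()) / df[inp].std(ddof=0)
                      for inp in INPUT_COLUMNS}, index=df.index)
    X = sm.add_constant(Z)
    singular = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(df[benefit], X, groups=df["method"]).fit(reml=True)
        re_var = float(res.cov_re.iloc[0, 0])
        if not np.isfinite(re_var):
            raise np.linalg.LinAlgError("non-finite random-effect variance")
        params = res.params[list(INPUT_COLUMNS)]
        ci = res.conf_int().loc[list(INPUT_COLUMNS)]
        if not np.isfinite(ci.to_numpy()).all():
            raise np.linalg.LinAlgError("non-finite fixed-effect intervals")
    except (np.linalg.LinAlgError, ValueError):
        warnings.warn(f"singular mixed-effects fit for {benefit}; "
                      "falling back to no-random-intercept OLS")
        singular = True
        res = sm.OLS(df[benefit], X).fit()
        re_var = 0.0
        params = res.params[list(INPUT_COLUMNS)]
        ci = res.conf_int().loc[list(INPUT_COLUMNS)]
    ci.columns = [0, 1]
    return MixedEffectsReport(benefit=benefit, estimates=params, conf_int=ci,
                              random_intercept_var=re_var, singular=singular)
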