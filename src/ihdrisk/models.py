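"""Risk models: penalized logistic fits, gradient-boosted EMR models,
fusion by feature concatenation or risk stacking, and config-driven
published baseline scores.

All cross-validated fits use stratified tenfold selection on the
training split with explicit seeds; stacking fits an L2 logistic
meta-model on component models' predicted risks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
import yaml
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .metrics import auroc

DEFAULT_PENALTY_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)


class NotFittedError(RuntimeError):
    pass


def _as_2d(features) -> np.ndarray:
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def _cv_folds(labels: np.ndarray, k: int, seed: int):
    """Stratified folds; shrink k (with a warning) when a class is scarce."""
    min_class = int(np.bincount(labels).min())
    k_eff = min(k, min_class)
    if k_eff < 2:
        warnings.warn("too few minority samples for cross-validation", stacklevel=3)
        return None
    if k_eff < k:
        warnings.warn(f"reduced CV folds from {k} to {k_eff} (scarce class)", stacklevel=3)
    return StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)


@dataclass
class L2LogisticModel:
    """L2-penalized logistic regression with CV-selected penalty weight.

    The penalty grid is in penalty-weight (λ) units; ties in mean
    validation AUROC break toward the smaller penalty.  Features are
    standardized inside the model.
    """

    penalty_grid: Sequence[float] = DEFAULT_PENALTY_GRID
    k: int = 10
    seed: int = 0
    chosen_penalty: float | None = None
    cv_scores: dict[float, float] = field(default_factory=dict)
    _scaler: StandardScaler | None = None
    _clf: LogisticRegression | None = None

    def _make_clf(self, penalty: float) -> LogisticRegression:
        # default penalty is L2; C is the inverse penalty weight
        return LogisticRegression(C=1.0 / penalty, solver="lbfgs", max_iter=2000)

    def fit(self, features, labels) -> "L2LogisticModel":
        x = _as_2d(features)
        y = np.asarray(labels).astype(int)
        folds = _cv_folds(y, self.k, self.seed)
        grid = sorted(self.penalty_grid)
        if folds is None:
            self.chosen_penalty = grid[0]
        else:
            for lam in grid:
                scores = []
                for tr, va in folds.split(x, y):
                    scaler = StandardScaler().fit(x[tr])
                    clf = self._make_clf(lam).fit(scaler.transform(x[tr]), y[tr])
                    pred = clf.predict_proba(scaler.transform(x[va]))[:, 1]
                    if len(np.unique(y[va])) < 2:
                        continue
                    scores.append(auroc(pred, y[va]))
                self.cv_scores[lam] = float(np.mean(scores)) if scores else float("nan")
            # max mean AUROC; ascending grid order means ties keep the smaller λ
            self.chosen_penalty = max(grid, key=lambda l: (self.cv_scores[l], -l))
        self._scaler = StandardScaler().fit(x)
        self._clf = self._make_clf(self.chosen_penalty).fit(self._scaler.transform(x), y)
        return self

    def predict_risk(self, features) -> np.ndarray:
        if self._clf is None:
            raise NotFittedError("model not fitted")
        return self._clf.predict_proba(self._scaler.transform(_as_2d(features)))[:, 1]

    @property
    def coefficients(self) -> np.ndarray:
        if self._clf is None:
            raise NotFittedError("model not fitted")
        return self._clf.coef_.ravel()


def fit_l2_logistic_cv(
    features,
    labels,
    penalty_grid: Sequence[float] = DEFAULT_PENALTY_GRID,
    k: int = 10,
    seed: int = 0,
) -> L2LogisticModel:
    """Fit an L2 logistic model with tenfold CV penalty selection."""
    return L2LogisticModel(penalty_grid=penalty_grid, k=k, seed=seed).fit(features, labels)


def segmentation_only_model(muscle_hu, vat_sat, labels, seed: int = 0) -> L2LogisticModel:
    """Bivariate logistic risk model on mean muscle HU and the VAT/SAT ratio."""
    x = np.column_stack([np.asarray(muscle_hu, float), np.asarray(vat_sat, float)])
    return fit_l2_logistic_cv(x, labels, seed=seed)


#: Default hyperparameter search space.  EMR designs are wide relative to
#: the number of events, with many weakly informative code-count columns:
#: L1-regularized depth-1 stumps fit sparse additive risk surfaces with
#: little variance, while deeper unregularized trees are available when CV
#: finds interaction structure.
DEFAULT_GBM_GRID = (
    {"max_depth": 1, "n_estimators": 1000, "learning_rate": 0.05, "reg_alpha": 10.0},
    {"max_depth": 1, "n_estimators": 500, "learning_rate": 0.1},
    {"max_depth": 3, "n_estimators": 200, "learning_rate": 0.1},
)


@dataclass
class GradientBoostedModel:
    """XGBoost classifier with native missing-value handling.

    Hyperparameters are selected by stratified tenfold CV over a small
    documented grid; NaN features pass straight through to the trees.
    """

    search_space: Sequence[dict] = DEFAULT_GBM_GRID
    k: int = 10
    seed: int = 0
    chosen_params: dict | None = None
    feature_names: list[str] | None = None
    _clf: xgb.XGBClassifier | None = None

    def _make_clf(self, params: dict) -> xgb.XGBClassifier:
        return xgb.XGBClassifier(
            **params,
            objective="binary:logistic",
            tree_method="hist",
            n_jobs=1,
            random_state=self.seed,
            eval_metric="logloss",
        )

    def fit(self, features, labels) -> "GradientBoostedModel":
        if isinstance(features, pd.DataFrame):
            self.feature_names = list(features.columns)
        x = _as_2d(features)
        y = np.asarray(labels).astype(int)
        folds = _cv_folds(y, self.k, self.seed)
        if folds is None or len(self.search_space) == 1:
            self.chosen_params = dict(self.search_space[0])
        else:
            best = None
            for params in self.search_space:
                scores = []
                for tr, va in folds.split(x, y):
                    clf = self._make_clf(params).fit(x[tr], y[tr])
                    pred = clf.predict_proba(x[va])[:, 1]
                    if len(np.unique(y[va])) < 2:
                        continue
                    scores.append(auroc(pred, y[va]))
                mean_score = float(np.mean(scores)) if scores else float("nan")
                if best is None or mean_score > best[0]:
                    best = (mean_score, dict(params))
            self.chosen_params = best[1]
        self._clf = self._make_clf(self.chosen_params).fit(x, y)
        return self

    def predict_risk(self, features) -> np.ndarray:
        if self._clf is None:
            raise NotFittedError("model not fitted")
        return self._clf.predict_proba(_as_2d(features))[:, 1]


def clinical_gbm(
    features, labels, search_space: Sequence[dict] = DEFAULT_GBM_GRID, k: int = 10, seed: int = 0
) -> GradientBoostedModel:
    """Gradient-boosted EMR risk model (missing values handled natively)."""
    return GradientBoostedModel(search_space=search_space, k=k, seed=seed).fit(features, labels)


def stack_models(risk_outputs: Sequence[np.ndarray], labels, seed: int = 0) -> L2LogisticModel:
    """L2-logistic stacking of component models' predicted risks.

    ``risk_outputs`` are the component risks on the training split (2 or 3
    columns).  At prediction time pass the component risks on new data in
    the same column order.
    """
    x = np.column_stack([np.asarray(r, float) for r in risk_outputs])
    return fit_l2_logistic_cv(x, labels, seed=seed)


def concat_fusion(
    pce_covariates: pd.DataFrame, muscle_hu, vat_sat, labels, seed: int = 0
) -> GradientBoostedModel:
    """Gradient-boosted fusion of baseline-score covariates with the two
    body-composition features (feature-level concatenation)."""
    design = pce_covariates.copy()
    design["mean_muscle_hu"] = np.asarray(muscle_hu, float)
    design["vat_sat_ratio"] = np.asarray(vat_sat, float)
    return clinical_gbm(design, labels, seed=seed)


# --- published baseline scores ------------------------------------------------


@dataclass
class BaselineScoreSpec:
    """A published Cox-form risk score loaded from a coefficient config.

    Risk = 1 - S0^exp(lp - mean_lp) per covariate group; term variables
    ``ln_<name>`` take the natural log of covariate ``<name>``.
    """

    name: str
    covariates: list[str]
    groups: dict
    worked_examples: list[dict]

    @classmethod
    def from_yaml(cls, path_or_name) -> "BaselineScoreSpec":
        candidate = str(path_or_name)
        if "/" not in candidate:
            ref = resources.files("ihdrisk.config") / candidate
            if ref.is_file():
                candidate = str(ref)
        with open(candidate) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            name=raw["name"],
            covariates=list(raw["covariates"]),
            groups=raw["groups"],
            worked_examples=raw.get("worked_examples", []),
        )

    def _var(self, row: dict, name: str) -> float:
        if name.startswith("ln_"):
            base = row[name[3:]]
            if base <= 0:
                raise ValueError(f"cannot take log of non-positive covariate {name[3:]}")
            return float(np.log(base))
        return float(row[name])

    def _risk_row(self, row: dict) -> float:
        missing = [c for c in self.covariates if c not in row or pd.isna(row[c])]
        if missing:
            raise ValueError(
                f"unresolvable covariates for {self.name}: {missing}; impute before scoring"
            )
        for group in self.groups.values():
            if all(row[k] == v for k, v in (group.get("select") or {}).items()):
                lp = 0.0
                for term in group["terms"]:
                    cond = term.get("if")
                    if cond and not all(row[k] == v for k, v in cond.items()):
                        continue
                    val = term["coef"]
                    for v in term["vars"]:
                        val *= self._var(row, v)
                    lp += val
                return float(
                    1.0
                    - group["baseline_survival"]
                    ** np.exp(lp - group["mean_linear_predictor"])
                )
        raise ValueError(f"no coefficient group matches covariate row for {self.name}")

    def risk(self, features) -> np.ndarray | float:
        """Evaluate the score for a covariate row (dict/Series) or table."""
        if isinstance(features, pd.DataFrame):
            return np.array([self._risk_row(dict(r)) for _, r in features.iterrows()])
        if isinstance(features, pd.Series):
            return self._risk_row(dict(features))
        return self._risk_row(dict(features))


def baseline_risk(spec: BaselineScoreSpec, features) -> np.ndarray | float:
    """Deterministic evaluation of a published baseline score."""
    return spec.risk(features)


def shap_summary(model: GradientBoostedModel, features) -> pd.DataFrame:
    """Per-feature SHAP attribution table, ranked by mean |value|.

    Delegates to the TreeSHAP implementation built into XGBoost
    (``pred_contribs``); only gradient-boosted models are supported.
    Returns columns feature, mean_abs_shap, mean_shap, ordered by
    descending mean_abs_shap.  Attribution rows satisfy additivity:
    contributions plus the base value equal the model margin.
    """
    if not isinstance(model, GradientBoostedModel) or model._clf is None:
        raise TypeError("shap_summary supports fitted GradientBoostedModel only")
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        x = features.to_numpy(dtype=float)
    else:
        x = _as_2d(features)
        names = model.feature_names or [f"f{i}" for i in range(x.shape[1])]
    booster = model._clf.get_booster()
    contribs = booster.predict(xgb.DMatrix(x, feature_names=names), pred_contribs=True)
    shap_vals = contribs[:, :-1]  # last column is the base value
    out = pd.DataFrame(
        {
            "feature": names,
            "mean_abs_shap": np.abs(shap_vals).mean(axis=0),
            "mean_shap": shap_vals.mean(axis=0),
        }
    )
    return out.sort_values("mean_abs_shap", ascending=False, ignore_index=True)


def shap_additivity_error(model: GradientBoostedModel, features, n_sample: int = 10) -> float:
    """Max |sum(contribs) + base - margin| over sampled rows (delegate check)."""
    if not isinstance(model, GradientBoostedModel) or model._clf is None:
        raise TypeError("requires a fitted GradientBoostedModel")
    x = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else _as_2d(features)
    x = x[:n_sample]
    booster = model._clf.get_booster()
    dm = xgb.DMatrix(x)
    contribs = booster.predict(dm, pred_contribs=True)
    margin = booster.predict(dm, output_margin=True)
    return float(np.abs(contribs.sum(axis=1) - margin).max())
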