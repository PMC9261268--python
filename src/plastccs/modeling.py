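"""Adduct-specific CCS regression: tuning, training, evaluation.

Two regressors are supported, each trained per adduct (protonated and
sodiated ions behave differently enough that a pooled model is worse):

* epsilon-SVR with an RBF kernel.  The cost grid is expressed as eight
  base values {0.001 ... 0.5} divided by the number of retained
  descriptors N_MD, crossed with nine gamma values 2^0 ... 2^8 — 72
  combinations in total.
* gradient-boosted trees (XGBoost) over a 576-combination grid of
  eta x max_depth x min_child_weight x subsample x colsample_bytree,
  with the boosting-round count chosen per combination by
  cross-validated RMSE with early stopping.

Model selection minimizes RMSECV under 10-fold cross-validation on the
training partition; reporting uses the held-out test partition only:
R^2_p, RMSEP, the median absolute relative error (MRE) and the share of
compounds predicted within 2 / 3 / 5 % of the measured CCS.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .descriptors import DescriptorMatrix, ScalingParams, autoscale_apply

MODEL_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test split specification (70/30 by default)."""

    train_fraction: float = 0.7
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")


def split_train_test(keys: list[str], spec: SplitSpec) -> tuple[list[str], list[str]]:
    """Randomly partition keys into train and test sets.

    The train size is round-half-up of ``train_fraction * n``; the split
    is deterministic given the seed and invariant to key order apart
    from membership.
    """
    keys = list(keys)
    n = len(keys)
    if n < 10:
        raise ValueError("need at least 10 keys for a 10-fold-CV-compatible split")
    n_train = int(math.floor(spec.train_fraction * n + 0.5))
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    train = [keys[i] for i in sorted(perm[:n_train])]
    test = [keys[i] for i in sorted(perm[n_train:])]
    return train, test


# ---------------------------------------------------------------------------
# Hyperparameter grids
# ---------------------------------------------------------------------------


@dataclass
class SVMGrid:
    """RBF-SVR grid: C = c_base / N_MD crossed with gamma = 2^0 ... 2^8."""

    c_base: tuple = (0.001, 0.005, 0.01, 0.025, 0.05, 0.1, 0.25, 0.5)
    gamma: tuple = tuple(float(2**k) for k in range(9))
    epsilon: float = 0.1

    def combinations(self, n_descriptors: int) -> list[dict]:
        if n_descriptors < 1:
            raise ValueError("n_descriptors must be positive")
        return [
            {"C": cb / n_descriptors, "gamma": g, "c_base": cb}
            for cb in self.c_base
            for g in self.gamma
        ]


@dataclass
class XGBGrid:
    """Gradient-boosting grid over five parameters (4*3*3*4*4 = 576)."""

    eta: tuple = (0.01, 0.05, 0.1, 0.3)
    max_depth: tuple = (3, 5, 7)
    min_child_weight: tuple = (1, 3, 5)
    subsample: tuple = (0.6, 0.7, 0.8, 0.9)
    colsample_bytree: tuple = (0.6, 0.7, 0.8, 0.9)
    max_rounds: int = 500
    early_stopping_rounds: int = 20

    def combinations(self) -> list[dict]:
        return [
            dict(
                zip(
                    ("eta", "max_depth", "min_child_weight", "subsample", "colsample_bytree"),
                    combo,
                )
            )
            for combo in itertools.product(
                self.eta, self.max_depth, self.min_child_weight,
                self.subsample, self.colsample_bytree,
            )
        ]


# ---------------------------------------------------------------------------
# Cross-validated tuning
# ---------------------------------------------------------------------------


class ScaledTargetSVR:
    """RBF epsilon-SVR that standardizes the target internally.

    The cost grid is expressed on a unit-variance target scale (the
    convention of the R SVM implementation the grids come from, which
    z-scores y before fitting); predictions are mapped back to A^2.
    """

    def __init__(self, C: float, gamma: float, epsilon: float = 0.1) -> None:
        self.C = C
        self.gamma = gamma
        self.epsilon = epsilon
        self._svr: SVR | None = None
        self._y_mean = 0.0
        self._y_sd = 1.0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ScaledTargetSVR":
        y = np.asarray(y, dtype=float)
        self._y_mean = float(y.mean())
        self._y_sd = float(y.std(ddof=1)) or 1.0
        self._svr = SVR(kernel="rbf", C=self.C, gamma=self.gamma,
                        epsilon=self.epsilon)
        self._svr.fit(X, (y - self._y_mean) / self._y_sd)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._svr is None:
            raise RuntimeError("model not fitted")
        return self._svr.predict(X) * self._y_sd + self._y_mean


def _cv_folds(n: int, k: int, seed: int) -> KFold:
    if k > n:
        raise ValueError(f"cannot run {k}-fold CV on {n} rows")
    return KFold(n_splits=k, shuffle=True, random_state=seed)


def _pooled_rmsecv(y: np.ndarray, residuals: np.ndarray) -> float:
    return float(np.sqrt(np.mean(residuals**2)))


def tune_svm(
    train_matrix: DescriptorMatrix,
    y: np.ndarray,
    grid: SVMGrid | None = None,
    k: int = 10,
    seed: int = 1,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive RMSECV grid search for the RBF-SVR.

    Every (C, gamma) combination is evaluated with the same k-fold
    partition; RMSECV is pooled over folds (square root of the grand
    mean squared out-of-fold residual).  The argmin is returned, ties
    broken by listed grid order (smaller C first, then smaller gamma).
    """
    grid = grid or SVMGrid()
    y = np.asarray(y, dtype=float)
    X = train_matrix.values
    folds = list(_cv_folds(len(y), k, seed).split(X))
    rows = []
    for params in grid.combinations(train_matrix.shape[1]):
        resid = np.empty(len(y))
        for tr_idx, va_idx in folds:
            model = ScaledTargetSVR(C=params["C"], gamma=params["gamma"],
                                    epsilon=grid.epsilon)
            model.fit(X[tr_idx], y[tr_idx])
            resid[va_idx] = model.predict(X[va_idx]) - y[va_idx]
        rows.append({**params, "rmsecv": _pooled_rmsecv(y, resid)})
    table = pd.DataFrame(rows)
    best = table.iloc[int(np.argmin(table["rmsecv"].to_numpy()))].to_dict()
    best_params = {"C": best["C"], "gamma": best["gamma"], "c_base": best["c_base"],
                   "epsilon": grid.epsilon}
    return best_params, table


def tune_xgb(
    train_matrix: DescriptorMatrix,
    y: np.ndarray,
    grid: XGBGrid | None = None,
    k: int = 10,
    seed: int = 1,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive RMSECV grid search for the gradient-boosted model.

    For each combination, ``xgboost.cv`` with early stopping returns the
    boosting-round count minimizing the cross-validated RMSE; that
    minimum is the combination's RMSECV.
    """
    import xgboost as xgb

    grid = grid or XGBGrid()
    y = np.asarray(y, dtype=float)
    if k > len(y):
        raise ValueError(f"cannot run {k}-fold CV on {len(y)} rows")
    dtrain = xgb.DMatrix(train_matrix.values, label=y)
    rows = []
    for params in grid.combinations():
        cv = xgb.cv(
            {**params, "objective": "reg:squarederror", "seed": seed, "nthread": 1},
            dtrain,
            num_boost_round=grid.max_rounds,
            nfold=k,
            early_stopping_rounds=grid.early_stopping_rounds,
            seed=seed,
            verbose_eval=False,
        )
        best_iter = int(cv["test-rmse-mean"].idxmin())
        rows.append(
            {**params, "nrounds": best_iter + 1,
             "rmsecv": float(cv["test-rmse-mean"].iloc[best_iter])}
        )
    table = pd.DataFrame(rows)
    best = table.iloc[int(np.argmin(table["rmsecv"].to_numpy()))].to_dict()
    best_params = {key: best[key] for key in
                   ("eta", "max_depth", "min_child_weight", "subsample",
                    "colsample_bytree", "nrounds")}
    best_params["max_depth"] = int(best_params["max_depth"])
    best_params["min_child_weight"] = int(best_params["min_child_weight"])
    best_params["nrounds"] = int(best_params["nrounds"])
    return best_params, table


# ---------------------------------------------------------------------------
# Final model
# ---------------------------------------------------------------------------


@dataclass
class TrainedCCSModel:
    """Fitted adduct-specific CCS regressor with its preprocessing state."""

    adduct: str
    algorithm: str  # "svm" | "xgb"
    params: dict
    descriptor_names: list[str]
    scaling: ScalingParams
    regressor: object
    rmsecv: float | None = None
    seed: int = 1
    backend_tag: str = ""

    def predict(self, matrix: DescriptorMatrix) -> np.ndarray:
        return predict_ccs(self, matrix)

    def save(self, path) -> None:
        payload = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "adduct": self.adduct,
            "algorithm": self.algorithm,
            "params": self.params,
            "descriptor_names": self.descriptor_names,
            "scaling_mean": self.scaling.mean.to_dict(),
            "scaling_sd": self.scaling.sd.to_dict(),
            "rmsecv": self.rmsecv,
            "seed": self.seed,
            "backend_tag": self.backend_tag,
            "regressor": self.regressor,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path) -> "TrainedCCSModel":
        payload = joblib.load(path)
        version = payload.get("schema_version")
        if version != MODEL_SCHEMA_VERSION:
            raise ValueError(
                f"model schema version {version!r} incompatible with "
                f"{MODEL_SCHEMA_VERSION}"
            )
        names = payload["descriptor_names"]
        scaling = ScalingParams(
            mean=pd.Series(payload["scaling_mean"])[names],
            sd=pd.Series(payload["scaling_sd"])[names],
        )
        return cls(
            adduct=payload["adduct"],
            algorithm=payload["algorithm"],
            params=payload["params"],
            descriptor_names=names,
            scaling=scaling,
            regressor=payload["regressor"],
            rmsecv=payload["rmsecv"],
            seed=payload["seed"],
            backend_tag=payload["backend_tag"],
        )


def train_final(
    train_matrix: DescriptorMatrix,
    y: np.ndarray,
    params: dict,
    algorithm: str,
    adduct: str = "[M+H]+",
    scaling: ScalingParams | None = None,
    seed: int = 1,
    rmsecv: float | None = None,
) -> TrainedCCSModel:
    """Fit the final regressor on the full training partition.

    ``train_matrix`` must already be auto-scaled; ``scaling`` carries the
    parameters needed to transform future (unscaled) prediction inputs.
    """
    y = np.asarray(y, dtype=float)
    if algorithm == "svm":
        reg = ScaledTargetSVR(C=params["C"], gamma=params["gamma"],
                              epsilon=params.get("epsilon", 0.1))
        reg.fit(train_matrix.values, y)
    elif algorithm == "xgb":
        from xgboost import XGBRegressor

        reg = XGBRegressor(
            n_estimators=int(params["nrounds"]),
            learning_rate=params["eta"],
            max_depth=int(params["max_depth"]),
            min_child_weight=params["min_child_weight"],
            subsample=params["subsample"],
            colsample_bytree=params["colsample_bytree"],
            random_state=seed,
            n_jobs=1,
        )
        reg.fit(train_matrix.values, y)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if scaling is None:
        scaling = ScalingParams(
            mean=pd.Series(0.0, index=train_matrix.col_names),
            sd=pd.Series(1.0, index=train_matrix.col_names),
        )
    missing = [c for c in train_matrix.col_names if c not in scaling.mean.index]
    if missing:
        raise ValueError(f"scaling params lack columns {missing}")
    return TrainedCCSModel(
        adduct=adduct,
        algorithm=algorithm,
        params=params,
        descriptor_names=train_matrix.col_names,
        scaling=ScalingParams(
            mean=scaling.mean[train_matrix.col_names],
            sd=scaling.sd[train_matrix.col_names],
        ),
        regressor=reg,
        rmsecv=rmsecv,
        seed=seed,
        backend_tag=train_matrix.backend_tag,
    )


def predict_ccs(model: TrainedCCSModel, matrix: DescriptorMatrix) -> np.ndarray:
    """Predict CCS (A^2) for an unscaled descriptor matrix.

    The matrix may carry extra columns; the model's retained descriptors
    are selected and z-scored with the stored training parameters.
    """
    missing = [c for c in model.descriptor_names if c not in matrix.col_names]
    if missing:
        raise KeyError(f"matrix lacks descriptor columns {missing}")
    sub = matrix.select_columns(model.descriptor_names)
    scaled = autoscale_apply(sub, model.scaling)
    return np.asarray(model.regressor.predict(scaled.values), dtype=float)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def relative_error(pred, exp):
    """Signed relative deviation (pred - exp) / exp * 100, in percent."""
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if np.any(exp <= 0):
        raise ValueError("experimental CCS must be positive")
    out = (pred - exp) / exp * 100.0
    return float(out) if out.ndim == 0 else out


@dataclass
class EvalReport:
    """Held-out-set performance summary."""

    r2p: float
    rmsep: float
    mre_pct: float
    pct_within_2: float
    pct_within_3: float
    pct_within_5: float
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "r2p": self.r2p,
            "rmsep": self.rmsep,
            "mre_pct": self.mre_pct,
            "pct_within_2": self.pct_within_2,
            "pct_within_3": self.pct_within_3,
            "pct_within_5": self.pct_within_5,
            "n": self.n,
        }


def evaluate(pred, exp) -> EvalReport:
    """Compute R^2_p, RMSEP, median |relative error| and error-band shares."""
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if pred.shape != exp.shape:
        raise ValueError("prediction and experimental vectors differ in length")
    if pred.size == 0:
        raise ValueError("cannot evaluate an empty vector pair")
    resid = pred - exp
    sstot = float(((exp - exp.mean()) ** 2).sum())
    r2p = 1.0 - float((resid**2).sum()) / sstot if sstot > 0 else float("nan")
    abs_rel = np.abs(relative_error(pred, exp))
    return EvalReport(
        r2p=r2p,
        rmsep=float(np.sqrt(np.mean(resid**2))),
        mre_pct=float(np.median(abs_rel)),
        pct_within_2=float(100.0 * np.mean(abs_rel < 2.0)),
        pct_within_3=float(100.0 * np.mean(abs_rel < 3.0)),
        pct_within_5=float(100.0 * np.mean(abs_rel < 5.0)),
        n=int(pred.size),
    )


def ablate_subset(
    train_matrix: DescriptorMatrix,
    y_train: np.ndarray,
    test_matrix: DescriptorMatrix,
    y_test: np.ndarray,
    predicate,
    params: dict,
    algorithm: str = "svm",
    seed: int = 1,
) -> dict:
    """Measure how excluding a training subset changes test performance.

    ``predicate(key) -> bool`` marks the class to remove from training
    (e.g. halogenated compounds).  Two models are trained with identical
    hyperparameters — on the full training set and on the filtered one —
    and both are evaluated on the fixed test partition, stratified by
    the predicate on the test rows.  Returns EvalReports keyed by
    (training variant, test stratum).
    """
    y_train = np.asarray(y_train, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    keep_keys = [k for k in train_matrix.row_keys if not predicate(k)]
    if len(keep_keys) < 10:
        raise ValueError("filtered training set too small to cross-validate")
    keep_idx = [i for i, k in enumerate(train_matrix.row_keys) if not predicate(k)]

    full_model = train_final(train_matrix, y_train, params, algorithm, seed=seed)
    filt_matrix = train_matrix.select_rows(keep_keys)
    filt_model = train_final(filt_matrix, y_train[keep_idx], params, algorithm, seed=seed)

    test_flags = np.array([predicate(k) for k in test_matrix.row_keys])
    out = {}
    for label, model in (("full", full_model), ("filtered", filt_model)):
        # test matrix arrives already scaled like the training matrix
        pred = np.asarray(model.regressor.predict(
            autoscale_apply(test_matrix.select_columns(model.descriptor_names),
                            model.scaling).values))
        for stratum, mask in (("in_class", test_flags), ("out_class", ~test_flags),
                              ("all", np.ones_like(test_flags, dtype=bool))):
            if mask.sum() == 0:
                continue
            out[(label, stratum)] = evaluate(pred[mask], y_test[mask])
    return out


def eval_report_json(report: EvalReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2)
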