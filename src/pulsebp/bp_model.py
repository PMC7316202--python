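"""Log-linear blood-pressure regression, feature selection and grading.

The estimator models the natural log of SBP or DBP as a linear
combination of interval features (semi-log / log-linear form), the shape
suggested by the inverse-exponential relation between pulse transit time
and pressure: ``BP = exp(beta0 + sum beta_j x_j)``, always positive.

Accuracy is summarised by the mean error, mean absolute error and the
standard deviation of errors, plus Bland-Altman pairs, the British
Hypertension Society cumulative-error grade and the AAMI mean-error /
SD criterion.

Feature screening keeps features whose univariate R^2 against ln(BP)
exceeds a threshold; the wrapper stage then greedily grows a subset by
cross-validated MAE (a seeded random-subset mode is available as an
alternative).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold

__all__ = [
    "LogLinearRegression",
    "EvalReport",
    "fit_log_linear",
    "predict",
    "evaluate",
    "screen_features_r2",
    "wrapper_select",
    "default_feature_sets",
    "bhs_grade",
    "aami_check",
    "BHS_GRADE_TABLE",
    "AAMI_MAX_ABS_ME",
    "AAMI_MAX_SD",
]

#: Standard BHS protocol: grade -> minimum cumulative % within 5/10/15 mmHg.
BHS_GRADE_TABLE: dict[str, tuple[float, float, float]] = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}

AAMI_MAX_ABS_ME = 5.0  # mmHg
AAMI_MAX_SD = 8.0  # mmHg

#: Published default feature sets (9 for SBP; DBP adds 5 PPG intervals).
_SBP_FEATURES = (
    "T_PN1", "T_PB", "T_RN1", "T_RB", "Tpr", "Tqrs", "Tst", "Tpt", "Trr",
)
_DBP_EXTRA = ("Tn1b", "Tn2n1", "Tn2a", "Tn2b", "Tbb")


def default_feature_sets() -> tuple[list[str], list[str]]:
    """The published default feature subsets: 9 for SBP, 14 for DBP
    (the SBP set plus five PPG-only intervals)."""
    sbp = list(_SBP_FEATURES)
    return sbp, sbp + list(_DBP_EXTRA)


def _as_frame(X, feature_names: Optional[Sequence[str]]) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"x{j}" for j in range(X.shape[1])]
    )
    return pd.DataFrame(X, columns=names)


class LogLinearRegression(RegressorMixin, BaseEstimator):
    """Ordinary least squares of ``ln(y)`` on features, with intercept.

    Parameters
    ----------
    target : str
        Which pressure the model estimates, ``"sbp"`` or ``"dbp"``
        (label only; the fit is identical).
    features : sequence of str, optional
        Column subset used when ``X`` is a DataFrame; ``None`` uses all
        columns.

    Attributes
    ----------
    intercept_ : float
        ``beta0`` on the log scale.
    coef_ : ndarray
        Per-feature coefficients (1/seconds scale for interval inputs).
    feature_names_in_ : list of str
        Fitted feature order.
    diagnostics_ : dict
        Residual summary of the log-scale fit (r2, residual SD, n).
    """

    def __init__(self, target: str = "sbp", features: Optional[Sequence[str]] = None):
        self.target = target
        self.features = features

    def fit(self, X, y):
        if self.target not in ("sbp", "dbp"):
            raise ValueError(f"target must be 'sbp' or 'dbp', got {self.target!r}")
        frame = _as_frame(X, None)
        if self.features is not None:
            missing = [f for f in self.features if f not in frame.columns]
            if missing:
                raise ValueError(f"X lacks required feature(s): {missing}")
            frame = frame[list(self.features)]
        y = np.asarray(y, dtype=float)
        if y.ndim != 1 or y.size != len(frame):
            raise ValueError("y must be 1-D with one value per row of X")
        if np.any(~np.isfinite(y)) or np.any(y <= 0):
            raise ValueError("y must be finite and strictly positive (mmHg)")
        mask = frame.notna().all(axis=1).to_numpy()
        frame = frame.loc[mask]
        y = y[mask]
        n, p = frame.shape
        if n < p + 1:
            raise ValueError(f"need at least {p + 1} complete rows, have {n}")
        design = sm.add_constant(frame.to_numpy(), has_constant="add")
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            self._raise_collinear(frame)
        res = sm.OLS(np.log(y), design).fit()
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.feature_names_in_ = list(frame.columns)
        self.n_features_in_ = p
        with np.errstate(divide="ignore", invalid="ignore"):
            # constant y has zero total variance; report r2 = 0 then
            r2 = float(res.rsquared) if p > 0 else 0.0
        self.diagnostics_ = {
            "r2": r2 if np.isfinite(r2) else 0.0,
            "resid_sd": float(np.std(res.resid, ddof=1)) if n > 1 else 0.0,
            "n": int(n),
        }
        return self

    @staticmethod
    def _raise_collinear(frame: pd.DataFrame) -> None:
        from scipy.linalg import qr

        design = sm.add_constant(frame.to_numpy(), has_constant="add")
        _, r, piv = qr(design, pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        bad = piv[np.flatnonzero(diag < tol)]
        names = ["intercept"] + list(frame.columns)
        culprits = [names[j] for j in sorted(bad)]
        raise ValueError(f"design matrix is rank deficient; collinear: {culprits}")

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        if isinstance(X, pd.Series):
            X = X.to_frame().T
        if isinstance(X, dict):
            X = pd.DataFrame([X])
        frame = _as_frame(X, self.feature_names_in_)
        missing = [f for f in self.feature_names_in_ if f not in frame.columns]
        if missing:
            raise ValueError(f"prediction input lacks feature(s): {missing}")
        vals = frame[self.feature_names_in_].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            rows, cols = np.nonzero(~np.isfinite(vals))
            bad = sorted({self.feature_names_in_[c] for c in cols})
            raise ValueError(f"prediction input has null feature(s): {bad}")
        return np.exp(self.intercept_ + vals @ self.coef_)

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise ValueError("model is not fitted")

    # --- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "target": self.target,
            "feature_names": self.feature_names_in_,
            "beta0": self.intercept_,
            "betas": self.coef_.tolist(),
            "diagnostics": self.diagnostics_,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "LogLinearRegression":
        model = cls(target=d["target"], features=d["feature_names"])
        model.intercept_ = float(d["beta0"])
        model.coef_ = np.asarray(d["betas"], dtype=float)
        model.feature_names_in_ = list(d["feature_names"])
        model.n_features_in_ = len(model.feature_names_in_)
        model.diagnostics_ = d.get("diagnostics", {})
        return model

    @classmethod
    def from_json(cls, path: str) -> "LogLinearRegression":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_log_linear(
    X, y, target: str = "sbp", features: Optional[Sequence[str]] = None
) -> LogLinearRegression:
    """Fit a log-linear BP model; thin wrapper over
    :class:`LogLinearRegression`."""
    return LogLinearRegression(target=target, features=features).fit(X, y)


def predict(model: LogLinearRegression, x) -> float | np.ndarray:
    """Predict BP (mmHg) for a feature vector, row dict/Series or table."""
    if hasattr(x, "as_series"):  # FeatureVector
        x = x.as_series()
    out = model.predict(x)
    return float(out[0]) if np.size(out) == 1 else out


@dataclass
class EvalReport:
    """Agreement summary between estimated and reference BP (mmHg).

    ``me``/``mae``/``sd`` are the mean error, mean absolute error and
    the (n-1) standard deviation of errors; ``ba_pairs`` holds the
    Bland-Altman (mean, difference) pairs; ``bhs`` the cumulative
    percentages within 5/10/15 mmHg and the resulting grade;
    ``aami_pass`` the |ME| <= 5 and SD <= 8 mmHg criterion.
    """

    me: float
    mae: float
    sd: float
    n: int
    ba_pairs: np.ndarray
    bhs: dict
    aami_pass: bool

    def to_dict(self) -> dict:
        return {
            "me": self.me,
            "mae": self.mae,
            "sd": self.sd,
            "n": self.n,
            "bhs": self.bhs,
            "aami_pass": bool(self.aami_pass),
            "ba_pairs": np.asarray(self.ba_pairs).tolist(),
        }


def bhs_grade(
    within5: float, within10: float, within15: float,
    table: dict[str, tuple[float, float, float]] = BHS_GRADE_TABLE,
) -> str:
    """BHS letter grade from cumulative percentages within 5/10/15 mmHg."""
    for grade in ("A", "B", "C"):
        t5, t10, t15 = table[grade]
        if within5 >= t5 and within10 >= t10 and within15 >= t15:
            return grade
    return "D"


def aami_check(me: float, sd: float) -> bool:
    """AAMI criterion: |mean error| <= 5 mmHg and SD <= 8 mmHg."""
    return abs(me) <= AAMI_MAX_ABS_ME and sd <= AAMI_MAX_SD


def evaluate(p, y) -> EvalReport:
    """Error statistics of estimates ``p`` against references ``y``.

    ME = sum(p - y)/n, MAE = sum|p - y|/n,
    SD = sqrt(sum((p - y - ME)^2) / (n - 1)).
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("p and y must be 1-D arrays of equal length")
    n = p.size
    if n < 2:
        raise ValueError("need at least 2 values")
    err = p - y
    me = float(err.mean())
    mae = float(np.abs(err).mean())
    sd = float(np.sqrt(np.sum((err - me) ** 2) / (n - 1)))
    ba_pairs = np.column_stack(((p + y) / 2.0, err))
    abs_err = np.abs(err)
    within = {
        thr: float(100.0 * np.mean(abs_err <= thr)) for thr in (5, 10, 15)
    }
    bhs = {
        "within5": within[5],
        "within10": within[10],
        "within15": within[15],
        "grade": bhs_grade(within[5], within[10], within[15]),
    }
    return EvalReport(
        me=me, mae=mae, sd=sd, n=n, ba_pairs=ba_pairs, bhs=bhs,
        aami_pass=aami_check(me, sd),
    )


def screen_features_r2(X, y, threshold: float = 0.3) -> list[str]:
    """Keep features whose univariate R^2 against ln(y) exceeds ``threshold``.

    Each feature is regressed alone (with intercept) on the log of the
    reference BP; columns with fewer than 3 complete values are skipped.
    """
    frame = _as_frame(X, None)
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("y must be strictly positive")
    logy = np.log(y)
    kept: list[str] = []
    for name in frame.columns:
        col = frame[name].to_numpy(dtype=float)
        mask = np.isfinite(col)
        if mask.sum() < 3 or np.std(col[mask]) == 0:
            continue
        r = np.corrcoef(col[mask], logy[mask])[0, 1]
        if r**2 > threshold:
            kept.append(name)
    return kept


def _cv_mae(
    frame: pd.DataFrame, y: np.ndarray, features: list[str],
    cv_folds: int, seed: int,
) -> float:
    """Cross-validated MAE (mmHg) of a log-linear fit on ``features``;
    an empty list scores the intercept-only model."""
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    errs: list[float] = []
    for train, test in kf.split(frame):
        ytr, yte = y[train], y[test]
        if features:
            try:
                model = LogLinearRegression(features=features).fit(
                    frame.iloc[train], ytr
                )
            except ValueError:
                return float("inf")  # e.g. collinear candidate set
            pred = model.predict(frame.iloc[test])
        else:
            pred = np.full(yte.size, np.exp(np.mean(np.log(ytr))))
        errs.append(float(np.mean(np.abs(pred - yte))))
    return float(np.mean(errs))


def wrapper_select(
    X,
    y,
    candidates: Sequence[str],
    cv_folds: int = 5,
    seed: int = 0,
    mode: str = "forward",
    n_random: int = 50,
    min_improve: float = 0.05,
) -> tuple[list[str], float]:
    """Wrapper feature selection by cross-validated MAE.

    ``mode="forward"`` (default) grows the subset greedily, adding the
    candidate that most lowers the CV MAE, with first-index preference
    on ties, and stops when the best candidate improves the current
    score by less than ``min_improve`` (relative; chance-level gains
    from irrelevant features do not grow the subset).  The intercept-only
    model is the starting baseline.  ``mode="random"`` scores
    ``n_random`` seeded random subsets instead.  Returns the selected
    feature list and its CV MAE (mmHg).
    """
    if not len(candidates):
        raise ValueError("candidates must be nonempty")
    frame = _as_frame(X, None)
    missing = [c for c in candidates if c not in frame.columns]
    if missing:
        raise ValueError(f"X lacks candidate feature(s): {missing}")
    y = np.asarray(y, dtype=float)
    mask = frame[list(candidates)].notna().all(axis=1).to_numpy()
    frame = frame.loc[mask].reset_index(drop=True)
    y = y[mask]

    if mode == "random":
        rng = np.random.default_rng(seed)
        best: list[str] = []
        best_score = _cv_mae(frame, y, [], cv_folds, seed)
        for _ in range(n_random):
            k = int(rng.integers(1, len(candidates) + 1))
            subset = sorted(
                rng.choice(len(candidates), size=k, replace=False).tolist()
            )
            feats = [candidates[j] for j in subset]
            score = _cv_mae(frame, y, feats, cv_folds, seed)
            if score < best_score - 1e-12:
                best, best_score = feats, score
        return best, best_score
    if mode != "forward":
        raise ValueError(f"mode must be 'forward' or 'random', got {mode!r}")

    selected: list[str] = []
    best_score = _cv_mae(frame, y, [], cv_folds, seed)
    remaining = list(candidates)
    while remaining:
        scores = [
            _cv_mae(frame, y, selected + [c], cv_folds, seed) for c in remaining
        ]
        j = int(np.argmin(scores))  # first index wins ties
        if scores[j] >= best_score * (1.0 - min_improve):
            break
        best_score = scores[j]
        selected.append(remaining.pop(j))
    return selected, best_score
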