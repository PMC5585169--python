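"""Age modelling: marker–age regressions, sex ANCOVA, SVR age predictor.

The two methylation scores carry complementary age information: ELOVL2
rises with ln(age) and EDARADD falls linearly with age.  The final
predictor is an epsilon-SVR with RBF kernel (C = 1.1, gamma = 0.1,
epsilon = 0.1) on the standardized score pair, with the response (age in
years) standardized too and de-standardized on output.  Accuracy is
summarized as the mean absolute deviation (MAD, years) and an adjusted R²
from the regression of chronological on predicted age.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.svm import SVR

from .melt_simulator import EDARADD, ELOVL2

#: Table-2 age bins used for per-bin MAD reporting.
AGE_BINS = ((0.0, 20.0), (20.0, 40.0), (40.0, 60.0), (60.0, np.inf))
AGE_BIN_LABELS = ("under 20", "20-39", "40-59", "over 60")

SVR_C = 1.1
SVR_GAMMA = 0.1
SVR_EPSILON = 0.1


@dataclass(frozen=True)
class MarkerAgeFit:
    marker_id: str
    form: str  # "log_linear" | "linear"
    intercept: float
    slope: float
    pearson_r: float
    n: int


@dataclass(frozen=True)
class AgePredictor:
    """Trained RBF epsilon-SVR on standardized (m1, m2) → standardized age.

    Prediction is carried out from the stored support vectors,

        age* = y_mean + y_sd · [ Σ_i α_i·exp(−γ‖x − x_i‖²) + b ],

    with x the standardized score pair; this makes a JSON round trip of the
    predictor exactly reproduce the fitted model's output.
    """

    support_vectors: np.ndarray  # (n_sv, 2), standardized feature space
    dual_coef: np.ndarray  # (n_sv,)
    intercept: float
    gamma: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    train_age_range: tuple[float, float]

    def predict(self, m1, m2) -> np.ndarray:
        return predict_age(self, m1, m2)

    def to_dict(self) -> dict:
        return {
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma": self.gamma,
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "train_age_range": list(self.train_age_range),
            "hyperparameters": {"C": SVR_C, "gamma": SVR_GAMMA, "epsilon": SVR_EPSILON},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AgePredictor":
        return cls(
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            gamma=float(d["gamma"]),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_sd=np.asarray(d["x_sd"], dtype=float),
            y_mean=float(d["y_mean"]),
            y_sd=float(d["y_sd"]),
            train_age_range=tuple(d["train_age_range"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "AgePredictor":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class EvaluationReport:
    mad: float
    adjusted_r2: float
    per_bin_mad: dict[str, float]
    per_bin_n: dict[str, int]
    n: int

    def to_dict(self) -> dict:
        return {
            "mad": self.mad,
            "adjusted_r2": self.adjusted_r2,
            "per_bin_mad": self.per_bin_mad,
            "per_bin_n": self.per_bin_n,
            "n": self.n,
        }


# ---------------------------------------------------------------------------
# Per-marker age relationships
# ---------------------------------------------------------------------------

def _score_column(marker_id: str) -> str:
    return {ELOVL2: "m1", EDARADD: "m2"}[marker_id]


def _regressor(age: np.ndarray, form: str) -> np.ndarray:
    age = np.asarray(age, dtype=float)
    if form == "log_linear":
        if np.any(age <= 0):
            raise ValueError("log_linear form requires positive ages")
        return np.log(age)
    if form == "linear":
        return age
    raise ValueError(f"unknown form {form!r}")


def fit_marker_age(
    cohort: pd.DataFrame, marker_id: str, form: str
) -> MarkerAgeFit:
    """Least-squares fit of score on ln(age) or age, with Pearson's r.

    ``cohort`` needs columns ``age`` and the marker's score column (``m1``
    for ELOVL2, ``m2`` for EDARADD).
    """
    col = _score_column(marker_id)
    sub = cohort.dropna(subset=["age", col])
    if len(sub) < 3:
        raise ValueError("need >= 3 samples to fit a marker-age relationship")
    x = _regressor(sub["age"].to_numpy(), form)
    y = sub[col].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance in age or score")
    slope, intercept = np.polyfit(x, y, 1)
    r = float(stats.pearsonr(x, y).statistic)
    return MarkerAgeFit(
        marker_id=marker_id,
        form=form,
        intercept=float(intercept),
        slope=float(slope),
        pearson_r=r,
        n=len(sub),
    )


def ancova_sex(cohort: pd.DataFrame, marker_id: str, form: str) -> dict:
    """ANCOVA for a sex effect on the score, adjusting for the age covariate.

    Fits score ~ regressor + sex by OLS and returns the type-II F-test
    p-value for the sex term (two-sided; the conventional alpha is 0.05).
    """
    col = _score_column(marker_id)
    sub = cohort.dropna(subset=["age", col, "sex"]).copy()
    counts = sub["sex"].value_counts()
    if len(counts) < 2 or counts.min() < 3:
        raise ValueError("ANCOVA requires both sexes with >= 3 samples each")
    sub["xreg"] = _regressor(sub["age"].to_numpy(), form)
    sub = sub.rename(columns={col: "score"})
    model = smf.ols("score ~ xreg + C(sex)", data=sub).fit()
    table = sm.stats.anova_lm(model, typ=2)
    p_sex = float(table.loc["C(sex)", "PR(>F)"])
    sex_coef = [c for c in model.params.index if c.startswith("C(sex)")]
    return {
        "marker": marker_id,
        "p_sex": p_sex,
        "F_sex": float(table.loc["C(sex)", "F"]),
        "sex_coefficient": float(model.params[sex_coef[0]]),
        "alpha": 0.05,
        "n": len(sub),
    }


# ---------------------------------------------------------------------------
# SVR age predictor
# ---------------------------------------------------------------------------

def train_predictor(train_cohort: pd.DataFrame, feature_cols=("m1", "m2")) -> AgePredictor:
    """Train the epsilon-SVR age predictor on a training cohort.

    Features and response are standardized to zero mean / unit SD with
    training-set statistics; the scaling is stored in the predictor.
    """
    sub = train_cohort.dropna(subset=["age", *feature_cols])
    if len(sub) < 10:
        raise ValueError("need >= 10 training samples")
    x = sub[list(feature_cols)].to_numpy(dtype=float)
    y = sub["age"].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")
    x_mean, x_sd = x.mean(axis=0), x.std(axis=0)
    if np.any(x_sd == 0):
        raise ValueError("zero-variance feature")
    y_mean, y_sd = float(y.mean()), float(y.std())
    if y_sd == 0:
        raise ValueError("zero-variance response")
    xs = (x - x_mean) / x_sd
    ys = (y - y_mean) / y_sd
    svr = SVR(kernel="rbf", C=SVR_C, gamma=SVR_GAMMA, epsilon=SVR_EPSILON)
    svr.fit(xs, ys)
    return AgePredictor(
        support_vectors=svr.support_vectors_.copy(),
        dual_coef=svr.dual_coef_.ravel().copy(),
        intercept=float(svr.intercept_[0]),
        gamma=SVR_GAMMA,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        train_age_range=(float(y.min()), float(y.max())),
    )


def predict_age(predictor: AgePredictor, m1, m2=None) -> np.ndarray:
    """Predict age (years) from methylation scores.

    ``m1`` may be an (n, k) feature matrix matching the training features,
    or the ELOVL2 score vector with ``m2`` the EDARADD scores.  Negative
    predictions are reported as-is with a warning (no clamping).
    """
    if m2 is None:
        x = np.asarray(m1, dtype=float)
        if x.ndim == 1:
            if predictor.x_mean.size != 1:
                raise ValueError(
                    "predictor expects "
                    f"{predictor.x_mean.size} features; pass m2 or an (n, k) matrix"
                )
            x = x[:, None]
    else:
        x = np.column_stack(
            [np.atleast_1d(np.asarray(m1, dtype=float)),
             np.atleast_1d(np.asarray(m2, dtype=float))]
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite scores")
    xs = (x - predictor.x_mean) / predictor.x_sd
    sq = (
        np.sum(xs**2, axis=1)[:, None]
        + np.sum(predictor.support_vectors**2, axis=1)[None, :]
        - 2.0 * xs @ predictor.support_vectors.T
    )
    k = np.exp(-predictor.gamma * sq)
    ys = k @ predictor.dual_coef + predictor.intercept
    ages = predictor.y_mean + predictor.y_sd * ys
    if np.any(ages < 0):
        warnings.warn("negative age prediction(s) reported unclamped", stacklevel=2)
    return ages


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(
    predictions, truths, bins=AGE_BINS, bin_labels=AGE_BIN_LABELS
) -> EvaluationReport:
    """MAD, adjusted R² and per-age-bin MAD of a prediction set.

    MAD = mean |prediction − truth| in years.  Adjusted R² uses the R² of
    the OLS regression of truth on prediction with p = 2 predictors:
    1 − (1 − R²)(n − 1)/(n − p − 1).
    """
    pred = np.asarray(predictions, dtype=float)
    truth = np.asarray(truths, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("predictions and truths must be 1-D and equal length")
    n = pred.size
    if n < 2:
        raise ValueError("need >= 2 samples to evaluate")
    mad = float(np.mean(np.abs(pred - truth)))
    p = 2
    if n <= p + 1:
        raise ValueError(f"adjusted R^2 undefined for n <= {p + 1}")
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        r2 = 0.0
    else:
        r2 = float(stats.pearsonr(truth, pred).statistic ** 2)
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    per_bin_mad, per_bin_n = {}, {}
    for (lo, hi), label in zip(bins, bin_labels):
        mask = (truth >= lo) & (truth < hi)
        per_bin_n[label] = int(mask.sum())
        per_bin_mad[label] = (
            float(np.mean(np.abs(pred[mask] - truth[mask]))) if mask.any() else float("nan")
        )
    return EvaluationReport(
        mad=mad, adjusted_r2=float(adj_r2), per_bin_mad=per_bin_mad,
        per_bin_n=per_bin_n, n=n,
    )
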