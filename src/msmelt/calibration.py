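"""PCR-bias standard-curve calibration: Df ↔ methylation score.

Because unmethylated (AT-rich after bisulfite conversion) template
amplifies more efficiently than methylated template, the relation between
a sample's Df and its true methylation level is generally non-linear.  A
standard series of control mixes (0–100 % methylated) calibrates this
relation per marker:

* hyperbolic model (biased markers, e.g. ELOVL2):

      a·M / (100 − M) = Df / (Df_max − Df)

  with a single shape coefficient ``a`` and ``Df_max`` the measured Df of
  the 100 % methylated control.  Fitted in the algebraically equivalent
  form Df(M) = Df_max·a·M / (a·M + 100 − M), which is finite at M = 100.

* linear model (unbiased markers, e.g. EDARADD): M = intercept + slope·Df,
  by ordinary least squares of nominal M on mean Df.

The methylation score of an unknown sample is the model's inverse
evaluated at the sample's Df.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .hrm_processing import DfMax


@dataclass(frozen=True)
class StandardSeries:
    """Per-level mean Df of a marker's standard series."""

    marker_id: str
    nominal_pct: np.ndarray
    mean_df: np.ndarray
    replicate_dfs: tuple[tuple[float, ...], ...] = ()

    def __post_init__(self) -> None:
        pct = np.asarray(self.nominal_pct, dtype=float)
        mdf = np.asarray(self.mean_df, dtype=float)
        object.__setattr__(self, "nominal_pct", pct)
        object.__setattr__(self, "mean_df", mdf)
        if pct.shape != mdf.shape or pct.ndim != 1:
            raise ValueError("nominal_pct and mean_df must be 1-D, same length")
        if np.unique(pct).size != pct.size:
            raise ValueError("nominal levels must be unique")
        if 0.0 not in pct:
            raise ValueError("standard series must include the 0% level")
        if np.any((pct < 0) | (pct > 100)):
            raise ValueError("nominal levels must lie in [0, 100]")

    @property
    def dfmax(self) -> DfMax:
        """Df_max from the 100 % level's mean Df."""
        idx = np.where(self.nominal_pct == 100.0)[0]
        if idx.size == 0:
            raise ValueError("series has no 100% level to define Df_max")
        return DfMax(self.marker_id, float(self.mean_df[idx[0]]))

    @classmethod
    def from_df_table(cls, table: pd.DataFrame, marker_id: str) -> "StandardSeries":
        """Build from a Df table restricted to ``set == 'standard'`` rows."""
        std = table[(table["marker"] == marker_id) & (table["set"] == "standard")]
        if std.empty:
            raise ValueError(f"no standard rows for marker {marker_id}")
        grouped = std.groupby("nominal_pct")["df"].mean().sort_index()
        return cls(
            marker_id=marker_id,
            nominal_pct=grouped.index.to_numpy(dtype=float),
            mean_df=grouped.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted Df ↔ methylation-score mapping for one marker."""

    marker_id: str
    kind: str  # "hyperbolic" | "linear"
    a: float | None = None
    dfmax: float | None = None
    intercept: float | None = None
    slope: float | None = None
    fit_residuals: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind == "hyperbolic":
            if self.a is None or self.a <= 0:
                raise ValueError("hyperbolic model requires a > 0")
            if self.dfmax is None or self.dfmax <= 0:
                raise ValueError("hyperbolic model requires dfmax > 0")
        elif self.kind == "linear":
            if self.slope is None or self.slope == 0:
                raise ValueError("linear model requires non-zero slope")
            if self.intercept is None:
                raise ValueError("linear model requires an intercept")
        else:
            raise ValueError(f"unknown calibration kind {self.kind!r}")

    def to_dict(self) -> dict:
        d = {"marker": self.marker_id, "kind": self.kind}
        if self.kind == "hyperbolic":
            d |= {"a": self.a, "dfmax": self.dfmax}
        else:
            d |= {"intercept": self.intercept, "slope": self.slope}
        d["fit_residuals"] = list(self.fit_residuals)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            marker_id=d["marker"],
            kind=d["kind"],
            a=d.get("a"),
            dfmax=d.get("dfmax"),
            intercept=d.get("intercept"),
            slope=d.get("slope"),
            fit_residuals=tuple(d.get("fit_residuals", ())),
        )


@dataclass(frozen=True)
class MethylationScore:
    sample_id: str
    marker_id: str
    score: float
    clamped: bool = False
    out_of_range: bool = False


def _hyperbolic_df(m: np.ndarray, a: float, dfmax: float) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    return dfmax * a * m / (a * m + 100.0 - m)


def fit_hyperbolic(series: StandardSeries) -> CalibrationModel:
    """Fit the hyperbolic standard curve with Df_max held fixed.

    Df_max is the measured mean Df of the 100 % control (not a free
    parameter); the single coefficient ``a`` is found by non-linear least
    squares of predicted Df on nominal M over all levels.
    """
    informative = series.nominal_pct > 0
    if informative.sum() < 3:
        raise ValueError("need >= 3 standard levels besides 0% to fit")
    dfmax = series.dfmax.dfmax
    try:
        popt, _ = curve_fit(
            lambda m, a: _hyperbolic_df(m, a, dfmax),
            series.nominal_pct,
            series.mean_df,
            p0=[1.0],
            bounds=([1e-6], [1e3]),
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
    except RuntimeError as exc:  # pragma: no cover - optimizer failure
        raise RuntimeError(f"hyperbolic fit failed for {series.marker_id}: {exc}")
    a = float(popt[0])
    if a <= 0:
        raise ValueError(f"fitted a = {a} is not positive")
    resid = series.mean_df - _hyperbolic_df(series.nominal_pct, a, dfmax)
    return CalibrationModel(
        marker_id=series.marker_id,
        kind="hyperbolic",
        a=a,
        dfmax=dfmax,
        fit_residuals=tuple(float(r) for r in resid),
    )


def fit_linear(series: StandardSeries) -> CalibrationModel:
    """OLS of nominal M on mean Df (the unbiased-marker standard line)."""
    if series.nominal_pct.size < 2:
        raise ValueError("need >= 2 standard levels to fit a line")
    x, y = series.mean_df, series.nominal_pct
    if np.ptp(x) == 0:
        raise ValueError("all standard Df values identical; line is vertical")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    return CalibrationModel(
        marker_id=series.marker_id,
        kind="linear",
        intercept=float(intercept),
        slope=float(slope),
        fit_residuals=tuple(float(r) for r in resid),
    )


def df_to_score(df: float, model: CalibrationModel, sample_id: str = "") -> MethylationScore:
    """Invert the calibration at a sample's Df.

    Hyperbolic: with r = Df/(Df_max − Df), score = 100·r/(a + r); a Df at
    or above Df_max clamps to score 100 with a warning, and a negative Df
    is rejected.  Linear: score = intercept + slope·Df, flagged (not
    clamped) outside [0, 100]; negative Df is accepted so the line's exact
    inverse is defined for scores below its intercept.
    """
    df = float(df)
    if not np.isfinite(df):
        raise ValueError(f"df must be finite, got {df}")
    if model.kind == "hyperbolic":
        if df < 0:
            raise ValueError(f"df must be >= 0 for hyperbolic inversion, got {df}")
        if df >= model.dfmax:
            warnings.warn(
                f"Df {df:.3f} >= Df_max {model.dfmax:.3f} for {model.marker_id}; "
                "score clamped to 100",
                stacklevel=2,
            )
            return MethylationScore(sample_id, model.marker_id, 100.0, clamped=True)
        r = df / (model.dfmax - df)
        score = 100.0 * r / (model.a + r)
        return MethylationScore(sample_id, model.marker_id, float(score))
    score = model.intercept + model.slope * df
    return MethylationScore(
        sample_id,
        model.marker_id,
        float(score),
        out_of_range=not (0.0 <= score <= 100.0),
    )


def score_to_df(score: float, model: CalibrationModel) -> float:
    """Exact inverse of :func:`df_to_score` (synthetic standards, round trips)."""
    score = float(score)
    if model.kind == "hyperbolic":
        if not (0.0 <= score <= 100.0):
            raise ValueError("hyperbolic score must lie in [0, 100]")
        return float(_hyperbolic_df(score, model.a, model.dfmax))
    return (score - model.intercept) / model.slope


def score_table(
    table: pd.DataFrame, models: dict[str, CalibrationModel]
) -> pd.DataFrame:
    """Apply per-marker calibrations to a Df table → scores frame."""
    rows = []
    for _, r in table.iterrows():
        model = models.get(r["marker"])
        if model is None:
            raise ValueError(f"no calibration for marker {r['marker']}")
        s = df_to_score(r["df"], model, sample_id=r["sample_id"])
        rows.append(
            {
                "sample_id": r["sample_id"],
                "marker": r["marker"],
                "score": s.score,
                "clamped": s.clamped,
                "out_of_range": s.out_of_range,
                "set": r.get("set", ""),
            }
        )
    return pd.DataFrame(rows)


def write_calibrations(models: dict[str, CalibrationModel], path) -> None:
    with open(path, "w") as fh:
        json.dump({m: mod.to_dict() for m, mod in models.items()}, fh, indent=2)


def read_calibrations(path) -> dict[str, CalibrationModel]:
    with open(path) as fh:
        raw = json.load(fh)
    return {m: CalibrationModel.from_dict(d) for m, d in raw.items()}
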