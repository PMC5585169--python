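"""Melt-curve normalization, difference plots and Df extraction.

Re-implements the gene-scanning computation of HRM instrument software:
each raw trace is normalized between two fitted baseline *lines* (one per
flanking temperature window where the product is assumed fully double- or
single-stranded), difference plots are taken against the 0 %-methylated
standard, and the per-sample statistic Df is the maximum absolute
difference in relative signal over temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .melt_simulator import EDARADD, ELOVL2, MeltCurve


@dataclass(frozen=True)
class MeltWindows:
    """Pre- and post-melt temperature windows for one marker (°C)."""

    marker_id: str
    pre_window: tuple[float, float]
    post_window: tuple[float, float]

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("pre_window", self.pre_window),
            ("post_window", self.post_window),
        ):
            if hi <= lo:
                raise ValueError(f"{name} is degenerate: [{lo}, {hi}]")
        if self.pre_window[1] >= self.post_window[0]:
            raise ValueError("pre_window must lie entirely below post_window")


#: Assay windows: pre-melt fully double-stranded, post-melt fully melted.
DEFAULT_WINDOWS = {
    ELOVL2: MeltWindows(ELOVL2, (68.0, 69.0), (82.0, 83.0)),
    EDARADD: MeltWindows(EDARADD, (65.0, 66.0), (80.0, 81.0)),
}


@dataclass(frozen=True)
class NormalizedCurve:
    """Relative signal (percent) on the grid between the two windows."""

    marker_id: str
    well_id: str
    temperatures: np.ndarray
    values: np.ndarray
    replicate_index: int = 1


@dataclass(frozen=True)
class DfValue:
    """Replicate-averaged Df for one sample × marker (percentage points)."""

    sample_id: str
    marker_id: str
    df: float
    n_replicates: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.df) or self.df < 0:
            raise ValueError("df must be finite and >= 0")


@dataclass(frozen=True)
class DfMax:
    """Df of the 100 %-methylated control: saturation of the calibration."""

    marker_id: str
    dfmax: float

    def __post_init__(self) -> None:
        if not self.dfmax > 0:
            raise ValueError("dfmax must be positive")


def _window_fit(curve: MeltCurve, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    mask = (curve.temperatures >= lo) & (curve.temperatures <= hi)
    if mask.sum() < 5:
        raise ValueError(
            f"window [{lo}, {hi}] holds {int(mask.sum())} grid points (< 5) "
            f"for well {curve.well_id}"
        )
    return np.polyfit(curve.temperatures[mask], curve.fluorescence[mask], 1)


def normalize_curve(curve: MeltCurve, windows: MeltWindows) -> NormalizedCurve:
    """Two-line normalization of a raw melt trace.

    Least-squares lines L_pre and L_post are fitted to the fluorescence
    within the pre- and post-melt windows; the relative signal is

        value(T) = 100 · (F(T) − L_post(T)) / (L_pre(T) − L_post(T)),

    restricted to [pre lo, post hi].  The result is invariant to affine
    transforms (gain and offset) of the raw fluorescence.
    """
    if curve.marker_id != windows.marker_id:
        raise ValueError(
            f"curve marker {curve.marker_id} != windows marker {windows.marker_id}"
        )
    pre = _window_fit(curve, windows.pre_window)
    post = _window_fit(curve, windows.post_window)
    lo, hi = windows.pre_window[0], windows.post_window[1]
    mask = (curve.temperatures >= lo) & (curve.temperatures <= hi)
    t = curve.temperatures[mask]
    denom = np.polyval(pre, t) - np.polyval(post, t)
    if np.any(denom <= 0):
        raise ValueError(
            f"non-positive pre/post separation for well {curve.well_id}: "
            "flat trace, failed PCR, or swapped windows"
        )
    values = 100.0 * (curve.fluorescence[mask] - np.polyval(post, t)) / denom
    return NormalizedCurve(
        marker_id=curve.marker_id,
        well_id=curve.well_id,
        temperatures=t,
        values=values,
        replicate_index=curve.replicate_index,
    )


def difference_plot(
    sample: NormalizedCurve, baseline: NormalizedCurve
) -> tuple[np.ndarray, np.ndarray]:
    """d(T) = sample(T) − baseline(T) on a common grid.

    Mismatched grids are re-gridded by linear interpolation onto the
    coarser grid over the overlapping temperature range.
    """
    if sample.marker_id != baseline.marker_id:
        raise ValueError(
            f"marker mismatch: {sample.marker_id} vs {baseline.marker_id}"
        )
    ts, tb = sample.temperatures, baseline.temperatures
    if ts.shape == tb.shape and np.allclose(ts, tb, atol=1e-9):
        return ts, sample.values - baseline.values
    lo, hi = max(ts[0], tb[0]), min(ts[-1], tb[-1])
    if hi <= lo:
        raise ValueError("normalized curves have non-overlapping grids")
    step_s = ts[1] - ts[0] if ts.size > 1 else np.inf
    step_b = tb[1] - tb[0] if tb.size > 1 else np.inf
    coarse = ts if step_s >= step_b else tb
    t = coarse[(coarse >= lo) & (coarse <= hi)]
    d = np.interp(t, ts, sample.values) - np.interp(t, tb, baseline.values)
    return t, d


def compute_df(differences: np.ndarray) -> float:
    """Df = max over the grid of |d(T)| (percentage points)."""
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("empty difference vector")
    return float(np.max(np.abs(d)))


def aggregate_replicates(
    dfs: list[float], sample_id: str = "", marker_id: str = ""
) -> DfValue:
    """Mean Df over a sample's replicates (same rule for any replicate count)."""
    if len(dfs) == 0:
        raise ValueError("no replicate Df values to aggregate")
    return DfValue(
        sample_id=sample_id,
        marker_id=marker_id,
        df=float(np.mean(dfs)),
        n_replicates=len(dfs),
    )


# ---------------------------------------------------------------------------
# Batch processing: curves + sample sheet -> Df table
# ---------------------------------------------------------------------------

def mean_baseline(curves: list[NormalizedCurve]) -> NormalizedCurve:
    """Mean normalized 0 %-standard curve across its replicates."""
    if not curves:
        raise ValueError("no baseline curves")
    t0 = curves[0].temperatures
    for c in curves[1:]:
        if c.temperatures.shape != t0.shape or not np.allclose(
            c.temperatures, t0, atol=1e-9
        ):
            raise ValueError("baseline replicates must share one grid")
    return NormalizedCurve(
        marker_id=curves[0].marker_id,
        well_id="baseline-mean",
        temperatures=t0,
        values=np.mean([c.values for c in curves], axis=0),
    )


def df_table(
    curves: list[MeltCurve],
    sample_sheet: pd.DataFrame,
    windows: dict[str, MeltWindows] | None = None,
) -> pd.DataFrame:
    """Compute the Df table for a run.

    ``sample_sheet`` must carry columns ``well_id``, ``sample_id``,
    ``marker``, ``set`` and, for standards, ``nominal_pct``.  Per marker the
    0 %-standard replicates define the mean baseline; Df is computed per
    replicate well against that baseline and averaged per sample.

    Returns a frame with columns sample_id, marker, df, n_replicates and,
    where applicable, set / nominal_pct carried over from the sheet.
    """
    if windows is None:
        windows = DEFAULT_WINDOWS
    required = {"well_id", "sample_id", "marker", "set"}
    missing = required - set(sample_sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    by_well = {c.well_id: c for c in curves}
    unknown = set(sample_sheet["well_id"]) - set(by_well)
    if unknown:
        raise ValueError(f"sample sheet references unknown wells: {sorted(unknown)[:5]}")

    normalized: dict[str, NormalizedCurve] = {
        w: normalize_curve(c, windows[c.marker_id]) for w, c in by_well.items()
    }

    rows = []
    for marker, sheet_m in sample_sheet.groupby("marker", sort=False):
        std0 = sheet_m[(sheet_m["set"] == "standard") & (sheet_m.get("nominal_pct", 0) == 0)]
        if std0.empty:
            raise ValueError(f"no 0% standard wells for marker {marker}")
        baseline = mean_baseline([normalized[w] for w in std0["well_id"]])
        for (sid, sset), grp in sheet_m.groupby(["sample_id", "set"], sort=False):
            dfs = [
                compute_df(difference_plot(normalized[w], baseline)[1])
                for w in grp["well_id"]
            ]
            agg = aggregate_replicates(dfs, sample_id=sid, marker_id=marker)
            row = {
                "sample_id": sid,
                "marker": marker,
                "df": agg.df,
                "n_replicates": agg.n_replicates,
                "set": sset,
            }
            if "nominal_pct" in grp.columns:
                row["nominal_pct"] = grp["nominal_pct"].iloc[0]
            rows.append(row)
    return pd.DataFrame(rows)
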