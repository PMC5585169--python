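"""Group comparisons: smoking habit and sample source.

One-way fixed-effects ANOVA on methylation scores and on predicted ages
across groups (non/former/current smokers, or cigarette butts vs smokers'
vs non-smokers' saliva), plus per-group MAD against chronological age for
the matched-donor design in which every donor shares one known age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p_value: float
    df_between: int
    df_within: int


def one_way_anova(values, labels) -> AnovaResult:
    """Classical equal-variance one-way ANOVA.

    Between/within sums of squares are computed directly; the p-value comes
    from the F(df_between, df_within) distribution.  Requires >= 2 groups
    with >= 2 values each.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be 1-D and equal length")
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("ANOVA requires >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs >= 2 values")
    grand = values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = values.size - len(groups)
    if ssw == 0:
        if ssb == 0:
            raise ValueError("zero total variance")
        return AnovaResult(float("inf"), 0.0, df_b, df_w)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), p, df_b, df_w)


def smoking_comparison(
    cohort: pd.DataFrame,
    group_col: str = "group",
    predicted_col: str = "predicted_age",
    age_col: str = "age",
    pair_col: str = "donor_id",
) -> dict:
    """Per-group MAD of predicted vs chronological age, with ANOVA on the
    predicted ages across groups.

    ``cohort`` carries one row per measured sample with its group label
    (e.g. ``butt`` / ``smoker_saliva`` / ``nonsmoker_saliva``), predicted
    age and chronological age (a single shared age in the matched design,
    or per-sample ages).  When ``pair_col`` is present, samples sharing a
    donor (the same smoker's butt and saliva) are reported side by side.
    """
    for col in (group_col, predicted_col, age_col):
        if col not in cohort.columns:
            raise ValueError(f"missing column {col!r}")
    if cohort[predicted_col].isna().any():
        raise ValueError("missing predicted ages")
    per_group_mad = {}
    for g, grp in cohort.groupby(group_col, sort=False):
        per_group_mad[g] = float(
            np.mean(np.abs(grp[predicted_col] - grp[age_col]))
        )
    predicted = cohort[predicted_col].to_numpy(dtype=float)
    if np.ptp(predicted) == 0:
        # Degenerate but well-defined: identical predictions everywhere
        # carry no between-group signal.
        anova = AnovaResult(
            0.0, 1.0, cohort[group_col].nunique() - 1,
            len(cohort) - cohort[group_col].nunique(),
        )
    else:
        anova = one_way_anova(predicted, cohort[group_col].to_numpy())
    result = {
        "per_group_mad": per_group_mad,
        "per_group_n": cohort.groupby(group_col, sort=False).size().to_dict(),
        "anova_F": anova.F,
        "anova_p": anova.p_value,
        "df_between": anova.df_between,
        "df_within": anova.df_within,
    }
    if pair_col in cohort.columns:
        paired = (
            cohort.dropna(subset=[pair_col])
            .groupby(pair_col)
            .filter(lambda d: d[group_col].nunique() > 1)
        )
        if not paired.empty:
            result["paired"] = (
                paired.pivot_table(
                    index=pair_col, columns=group_col, values=predicted_col
                )
                .reset_index()
                .to_dict(orient="list")
            )
    return result


def simulate_grouped_betas(
    n_per_group=(18, 18, 18),
    group_labels=("non", "former", "current"),
    mean_beta: float = 0.6,
    group_effect: float = 0.0,
    sd: float = 0.05,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Synthetic three-group methylation beta values with a configurable
    group effect (a public-array smoking cohort stand-in; no real data).

    Group k's mean is ``mean_beta + k·group_effect``; values are Gaussian
    with SD ``sd``, clipped to [0, 1].
    """
    if len(n_per_group) != len(group_labels):
        raise ValueError("n_per_group and group_labels must align")
    rng = np.random.default_rng(seed)
    rows = []
    for k, (n, label) in enumerate(zip(n_per_group, group_labels)):
        betas = np.clip(
            rng.normal(mean_beta + k * group_effect, sd, size=n), 0.0, 1.0
        )
        rows.append(pd.DataFrame({"group": label, "beta": betas}))
    return pd.concat(rows, ignore_index=True)
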