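"""Synthetic MS-HRM data generator.

Methylation-sensitive high-resolution melting (MS-HRM) amplifies
bisulfite-converted DNA and melts the product on a fine temperature grid.
Methylated template retains C:G pairs after conversion and therefore melts
at a higher temperature than unmethylated (A:T-rich) template.  This module
simulates everything the downstream analysis consumes:

* raw melt curves for a two-marker assay (``ELOVL2``, ``EDARADD``) whose
  shape depends on the methylation fraction of the template pool,
* the PCR bias that favours unmethylated template during amplification,
* standard dilution series (0–100 % methylated control mixes),
* donor cohorts with an aging signal: the ELOVL2 methylation score rises
  with the logarithm of age while the EDARADD score falls linearly.

The melt physics is a two-state (helix/coil) model: each duplex species
contributes a logistic helicity sigmoid centred on its melting temperature,
and the observed fluorescence is the bias-distorted mixture of the
methylated and unmethylated species riding on linear pre- and post-melt
baseline drifts, plus i.i.d. Gaussian instrument noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ELOVL2 = "ELOVL2"
EDARADD = "EDARADD"
MARKERS = (ELOVL2, EDARADD)

#: Default temperature grid: 60–95 °C at 0.1 °C, typical instrument resolution.
DEFAULT_GRID = (60.0, 95.0, 0.1)

#: Nominal methylation levels (%) of the control-DNA standard mixes.
STANDARD_LEVELS = (0.0, 25.0, 50.0, 65.0, 80.0, 90.0, 95.0, 100.0)

#: Training-cohort strata: (age lo, age hi, n male, n female).
TRAINING_STRATA = (
    (1, 19, 5, 5),
    (20, 39, 51, 49),
    (40, 59, 45, 36),
    (60, 73, 5, 1),
)

#: Test-cohort strata, same layout.
TEST_STRATA = (
    (1, 19, 2, 3),
    (20, 39, 10, 16),
    (40, 59, 13, 6),
    (60, 73, 0, 0),
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerModel:
    """Physical and amplification parameters of one MS-HRM marker.

    ``eff_meth``/``eff_unmeth`` are per-cycle amplification multipliers in
    (0, 2]; a ratio below one models PCR bias against methylated template.
    ``pre_slope``/``post_slope`` are linear baseline drifts (fluorescence
    units per °C) of the fully double- and single-stranded plateaus.
    """

    marker_id: str
    tm_unmeth: float
    tm_meth: float
    transition_width: float
    pre_slope: float = -0.15
    post_slope: float = -0.02
    amplitude: float = 100.0
    post_level: float = 5.0
    eff_meth: float = 1.9
    eff_unmeth: float = 1.9
    n_cycles: int = 40
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.tm_meth <= self.tm_unmeth:
            raise ValueError(
                f"{self.marker_id}: tm_meth ({self.tm_meth}) must exceed "
                f"tm_unmeth ({self.tm_unmeth}); methylated product melts higher"
            )
        if self.transition_width <= 0:
            raise ValueError("transition_width must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        for name in ("eff_meth", "eff_unmeth"):
            e = getattr(self, name)
            if not (0.0 < e <= 2.0):
                raise ValueError(f"{name} must lie in (0, 2], got {e}")

    @property
    def bias_coefficient(self) -> float:
        """(eff_meth/eff_unmeth)**n_cycles — the hyperbolic calibration 'a'."""
        return (self.eff_meth / self.eff_unmeth) ** self.n_cycles


@dataclass(frozen=True)
class MeltCurve:
    """One well's raw fluorescence-vs-temperature trace for one marker."""

    marker_id: str
    well_id: str
    replicate_index: int
    temperatures: np.ndarray
    fluorescence: np.ndarray
    true_meth_fraction: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "fluorescence", f)
        if t.ndim != 1 or t.size < 50:
            raise ValueError("temperature grid must be 1-D with >= 50 points")
        steps = np.diff(t)
        if not np.all(steps > 0):
            raise ValueError("temperatures must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
            raise ValueError("temperature grid must be uniform")
        if f.shape != t.shape:
            raise ValueError("fluorescence length must match temperatures")
        if not np.all(np.isfinite(f)):
            raise ValueError("fluorescence must be finite")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")

    @property
    def step(self) -> float:
        return float(self.temperatures[1] - self.temperatures[0])


@dataclass(frozen=True)
class AgingModel:
    """Mean methylation score as a function of chronological age.

    ``log_linear``: score = coef0 + coef1·ln(age); ``linear``:
    score = coef0 + coef1·age.  Gaussian donor-to-donor residual scatter
    with standard deviation ``residual_sd`` (score units).
    """

    marker_id: str
    form: str
    coef0: float
    coef1: float
    residual_sd: float

    def __post_init__(self) -> None:
        if self.form not in ("log_linear", "linear"):
            raise ValueError(f"unknown aging form {self.form!r}")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")

    def mean_score(self, age: np.ndarray | float) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        if self.form == "log_linear":
            if np.any(age <= 0):
                raise ValueError("log_linear aging model requires positive ages")
            return self.coef0 + self.coef1 * np.log(age)
        return self.coef0 + self.coef1 * age

    def regressor(self, age: np.ndarray) -> np.ndarray:
        """The age covariate the model is linear in (ln(age) or age)."""
        age = np.asarray(age, dtype=float)
        return np.log(age) if self.form == "log_linear" else age


@dataclass(frozen=True)
class CohortSpec:
    """Stratified cohort design: per-stratum age range and sex counts."""

    strata: tuple[tuple[float, float, int, int], ...]
    source: str = "saliva"
    smoking: str = "not_recorded"
    set_label: str = "train"

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValueError("strata must be non-empty")
        for lo, hi, n_m, n_f in self.strata:
            if lo > hi:
                raise ValueError(f"stratum age range inverted: [{lo}, {hi}]")
            if n_m < 0 or n_f < 0:
                raise ValueError("stratum counts must be >= 0")
        if self.n_total == 0:
            raise ValueError("cohort spec has zero total samples")

    @property
    def n_total(self) -> int:
        return sum(n_m + n_f for _, _, n_m, n_f in self.strata)


# ---------------------------------------------------------------------------
# Defaults anchored to the assay's melt windows
# ---------------------------------------------------------------------------

def default_marker_models() -> dict[str, MarkerModel]:
    """Marker defaults.

    ELOVL2 carries PCR bias (eff_meth = 0.96·eff_unmeth over 40 cycles) so
    its standard curve is visibly hyperbolic; EDARADD is unbiased so its
    standard relation is linear.  Melting temperatures sit between each
    marker's pre-melt and post-melt windows.
    """
    return {
        ELOVL2: MarkerModel(
            marker_id=ELOVL2,
            tm_unmeth=74.0,
            tm_meth=78.5,
            transition_width=1.5,
            eff_meth=0.96 * 1.9,
            eff_unmeth=1.9,
        ),
        EDARADD: MarkerModel(
            marker_id=EDARADD,
            tm_unmeth=71.0,
            tm_meth=75.5,
            transition_width=1.5,
        ),
    }


def default_aging_models() -> dict[str, AgingModel]:
    """Aging-signal defaults (synthetic; score units are percent-scale).

    ELOVL2: M1 = 5 + 20·ln(age), clipped to [0, 100]; EDARADD:
    M2 = 75 − 0.45·age.  Residual SDs are set from the generator's closed
    form r = σ_signal/√(σ_signal² + σ_resid²) so that the default training
    strata yield r ≈ 0.87 (ELOVL2) and r ≈ −0.52 (EDARADD).
    """
    return {
        ELOVL2: AgingModel(ELOVL2, "log_linear", 5.0, 20.0, 5.5),
        EDARADD: AgingModel(EDARADD, "linear", 75.0, -0.45, 10.1),
    }


# ---------------------------------------------------------------------------
# PCR bias
# ---------------------------------------------------------------------------

def apparent_fraction(
    p: float, eff_meth: float, eff_unmeth: float, n_cycles: int
) -> float:
    """Methylated fraction of the amplicon pool after biased PCR.

    Starting from template fractions (p, 1−p), each cycle multiplies the
    methylated pool by ``eff_meth`` and the unmethylated pool by
    ``eff_unmeth``; after ``n_cycles`` cycles the methylated share is

        p·E_m^n / (p·E_m^n + (1−p)·E_u^n).

    Pure templates (p = 0 or 1) are unaffected by bias.
    """
    p = float(p)
    if not math.isfinite(p) or not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be a fraction in [0, 1], got {p}")
    for name, e in (("eff_meth", eff_meth), ("eff_unmeth", eff_unmeth)):
        if not math.isfinite(e) or not (0.0 < e <= 2.0):
            raise ValueError(f"{name} must lie in (0, 2], got {e}")
    n_cycles = int(n_cycles)
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    # Work with the efficiency ratio to avoid overflow at large n.
    ratio = (eff_meth / eff_unmeth) ** n_cycles
    return p * ratio / (p * ratio + (1.0 - p))


# ---------------------------------------------------------------------------
# Melt-curve synthesis
# ---------------------------------------------------------------------------

def _helicity(t: np.ndarray, tm: float, width: float) -> np.ndarray:
    # Two-state helix fraction: 1 well below Tm, 0 well above, inflection at Tm.
    return 1.0 / (1.0 + np.exp(4.0 * (t - tm) / width))


def make_grid(grid: tuple[float, float, float] = DEFAULT_GRID) -> np.ndarray:
    lo, hi, step = grid
    if step <= 0:
        raise ValueError("grid step must be positive")
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def simulate_melt_curve(
    p: float,
    model: MarkerModel,
    grid: tuple[float, float, float] = DEFAULT_GRID,
    rng: np.random.Generator | int | None = None,
    well_id: str = "W1",
    replicate_index: int = 1,
) -> MeltCurve:
    """Synthesize one raw melt trace for template methylation fraction ``p``.

    The fluorescence interpolates between a drifting pre-melt line and a
    drifting post-melt line according to the helicity of the bias-distorted
    two-species mixture, with Gaussian noise of SD ``model.noise_sd``.
    """
    t = make_grid(grid)
    lo = t[0]
    if not (lo <= model.tm_unmeth - model.transition_width
            and t[-1] >= model.tm_meth + model.transition_width):
        raise ValueError(
            f"grid [{t[0]}, {t[-1]}] does not cover the melt transitions of "
            f"{model.marker_id}"
        )
    p_app = apparent_fraction(p, model.eff_meth, model.eff_unmeth, model.n_cycles)
    mix = (
        p_app * _helicity(t, model.tm_meth, model.transition_width)
        + (1.0 - p_app) * _helicity(t, model.tm_unmeth, model.transition_width)
    )
    pre_line = model.amplitude + model.pre_slope * (t - lo)
    post_line = model.post_level + model.post_slope * (t - lo)
    f = post_line + (pre_line - post_line) * mix
    if model.noise_sd > 0:
        rng = np.random.default_rng(rng)
        f = f + rng.normal(0.0, model.noise_sd, size=f.shape)
    return MeltCurve(
        marker_id=model.marker_id,
        well_id=well_id,
        replicate_index=replicate_index,
        temperatures=t,
        fluorescence=f,
        true_meth_fraction=float(p),
    )


def simulate_standard_series(
    levels: list[float] | tuple[float, ...] = STANDARD_LEVELS,
    model: MarkerModel | None = None,
    replicates: int = 3,
    seed: int | np.random.Generator | None = 0,
    grid: tuple[float, float, float] = DEFAULT_GRID,
) -> list[MeltCurve]:
    """Simulate the control-mix standard series (triplicate by default).

    The 0 % level is mandatory: it is the baseline of every difference plot.
    """
    if model is None:
        model = default_marker_models()[ELOVL2]
    levels = [float(v) for v in levels]
    if any(not (0.0 <= v <= 100.0) for v in levels):
        raise ValueError("standard levels must lie in [0, 100]")
    if 0.0 not in levels:
        raise ValueError("standard series must include the 0% baseline level")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    curves = []
    for i, level in enumerate(levels):
        for rep in range(1, replicates + 1):
            curves.append(
                simulate_melt_curve(
                    level / 100.0,
                    model,
                    grid=grid,
                    rng=rng,
                    well_id=f"STD-{model.marker_id}-{i}-{rep}",
                    replicate_index=rep,
                )
            )
    return curves


# ---------------------------------------------------------------------------
# Cohort synthesis
# ---------------------------------------------------------------------------

def _draw_ages(spec: CohortSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    ages, sexes = [], []
    for lo, hi, n_m, n_f in spec.strata:
        n = n_m + n_f
        ages.append(rng.uniform(lo, hi + 1.0, size=n))  # continuous ages in stratum
        sexes.append(np.array(["M"] * n_m + ["F"] * n_f))
    return np.concatenate(ages), np.concatenate(sexes)


def simulate_cohort(
    spec: CohortSpec,
    aging: dict[str, AgingModel] | None = None,
    marker_models: dict[str, MarkerModel] | None = None,
    seed: int | np.random.Generator | None = 0,
    replicates: int = 2,
    include_curves: bool = True,
    grid: tuple[float, float, float] = DEFAULT_GRID,
    id_prefix: str = "S",
) -> tuple[pd.DataFrame, list[MeltCurve]]:
    """Simulate a donor cohort with per-marker true methylation scores.

    Each donor receives an age drawn uniformly within their stratum, a true
    score per marker from the aging model (clipped to [0, 100]), and — when
    ``include_curves`` — ``replicates`` melt curves per marker (duplicate by
    default) whose true methylation fraction is the score / 100.

    Returns a samples table (sample_id, age, sex, source, smoking, set,
    m1_true, m2_true, well ids) and the list of melt curves.
    """
    if aging is None:
        aging = default_aging_models()
    if marker_models is None:
        marker_models = default_marker_models()
    for m in MARKERS:
        if m not in aging:
            raise ValueError(f"aging model missing for marker {m}")
        if include_curves and m not in marker_models:
            raise ValueError(f"marker model missing for marker {m}")
    rng = np.random.default_rng(seed)
    ages, sexes = _draw_ages(spec, rng)
    n = ages.size
    sample_ids = [f"{id_prefix}{i+1:04d}" for i in range(n)]

    true_scores = {}
    for m in MARKERS:
        mdl = aging[m]
        scores = mdl.mean_score(ages) + rng.normal(0.0, mdl.residual_sd, size=n)
        true_scores[m] = np.clip(scores, 0.0, 100.0)

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": ages,
            "sex": sexes,
            "source": spec.source,
            "smoking": spec.smoking,
            "set": spec.set_label,
            "m1_true": true_scores[ELOVL2],
            "m2_true": true_scores[EDARADD],
        }
    )

    curves: list[MeltCurve] = []
    if include_curves:
        for i, sid in enumerate(sample_ids):
            for m in MARKERS:
                for rep in range(1, replicates + 1):
                    curves.append(
                        simulate_melt_curve(
                            true_scores[m][i] / 100.0,
                            marker_models[m],
                            grid=grid,
                            rng=rng,
                            well_id=f"{sid}-{m}-{rep}",
                            replicate_index=rep,
                        )
                    )
    return samples, curves


def expected_pearson_r(
    spec: CohortSpec, aging: AgingModel
) -> float:
    """Closed-form |r| between true score and the aging regressor.

    With scores = coef0 + coef1·x + ε, ε ~ N(0, σ²), the population
    correlation is σ_x·|coef1| / √(coef1²·σ_x² + σ²) where σ_x is the SD of
    the regressor (age or ln age) under the stratified uniform age design.
    Ignores the [0, 100] clipping, which is rarely active at the defaults.
    """
    means, seconds, weights = [], [], []
    for lo, hi, n_m, n_f in spec.strata:
        w = n_m + n_f
        if w == 0:
            continue
        # ages ~ U(lo, hi+1): moments of x = age or ln(age) by quadrature
        from scipy.integrate import quad

        a, b = float(lo), float(hi) + 1.0
        if aging.form == "log_linear":
            fx = np.log
        else:
            fx = lambda v: v
        m1 = quad(lambda v: fx(v), a, b)[0] / (b - a)
        m2 = quad(lambda v: fx(v) ** 2, a, b)[0] / (b - a)
        means.append(m1)
        seconds.append(m2)
        weights.append(w)
    w = np.asarray(weights, float) / sum(weights)
    grand = float(np.dot(w, means))
    var_x = float(np.dot(w, seconds)) - grand**2
    signal = abs(aging.coef1) * math.sqrt(var_x)
    return signal / math.sqrt(signal**2 + aging.residual_sd**2)


def simulate_smoking_cohort(
    seed: int | np.random.Generator | None = 0,
    n_pairs: int = 9,
    n_nonsmokers: int = 7,
    donor_age: float = 40.0,
    butt_effect_m1: float = 0.0,
    aging: dict[str, AgingModel] | None = None,
    marker_models: dict[str, MarkerModel] | None = None,
    include_curves: bool = True,
) -> tuple[pd.DataFrame, list[MeltCurve]]:
    """Simulate the smoking comparison: paired cigarette-butt / saliva
    samples from ``n_pairs`` current smokers plus ``n_nonsmokers`` saliva
    samples from non-smokers, all donors of the same chronological age.

    ``butt_effect_m1`` adds a score offset to the ELOVL2 butt measurements
    (a configurable source effect; 0 under the no-effect null).  Butt and
    saliva samples from the same smoker share the donor's true biology and
    differ only through the source effect and measurement noise.
    """
    if aging is None:
        aging = default_aging_models()
    if marker_models is None:
        marker_models = default_marker_models()
    rng = np.random.default_rng(seed)

    rows = []
    true_fracs: list[dict[str, float]] = []

    def donor_scores() -> dict[str, float]:
        return {
            m: float(
                np.clip(
                    aging[m].mean_score(donor_age)
                    + rng.normal(0.0, aging[m].residual_sd),
                    0.0,
                    100.0,
                )
            )
            for m in MARKERS
        }

    for i in range(n_pairs):
        donor = f"SMK{i+1:02d}"
        scores = donor_scores()
        butt = dict(scores)
        butt[ELOVL2] = float(np.clip(butt[ELOVL2] + butt_effect_m1, 0.0, 100.0))
        rows.append((f"{donor}-butt", donor, "cigarette_butt", "current"))
        true_fracs.append(butt)
        rows.append((f"{donor}-saliva", donor, "saliva", "current"))
        true_fracs.append(scores)
    for i in range(n_nonsmokers):
        donor = f"NON{i+1:02d}"
        rows.append((f"{donor}-saliva", donor, "saliva", "non"))
        true_fracs.append(donor_scores())

    samples = pd.DataFrame(
        rows, columns=["sample_id", "donor_id", "source", "smoking"]
    )
    samples["age"] = donor_age
    samples["sex"] = "M"
    samples["set"] = "application"
    samples["m1_true"] = [s[ELOVL2] for s in true_fracs]
    samples["m2_true"] = [s[EDARADD] for s in true_fracs]

    curves: list[MeltCurve] = []
    if include_curves:
        for _, row in samples.iterrows():
            for m, col in ((ELOVL2, "m1_true"), (EDARADD, "m2_true")):
                for rep in (1, 2):
                    curves.append(
                        simulate_melt_curve(
                            row[col] / 100.0,
                            marker_models[m],
                            rng=rng,
                            well_id=f"{row.sample_id}-{m}-{rep}",
                            replicate_index=rep,
                        )
                    )
    return samples, curves


def curves_to_frame(curves: list[MeltCurve]) -> pd.DataFrame:
    """Long-format table of melt curves (well_id, marker, replicate,
    temperature, fluorescence)."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "well_id": c.well_id,
                    "marker": c.marker_id,
                    "replicate": c.replicate_index,
                    "temperature": c.temperatures,
                    "fluorescence": c.fluorescence,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
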