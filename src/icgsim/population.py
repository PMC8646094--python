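"""Synthetic virtual population for in-silico ICG liver function tests.

The generator emulates the covariate structure an adult, non-obese survey
cohort would supply: sex-specific heights, age-dependent BMI (body weight
rising to mid-life, then declining; women lighter on average), exclusion of
minors (age < 18), obese subjects (BMI > 30) and top-coded ages; the base
cohort is then oversampled with replacement to the target size.  Each
emitted individual also carries age-dependent, positively correlated draws
of liver volume per kg and hepatic blood flow per kg (both declining with
age) and an age/sex-independent lognormal OATP1B3 abundance factor.

Distribution defaults are artifact defaults chosen to be population-survey
realistic; every one of them is a config field.  A root seed spawns
independent named sub-streams (anthropometry, oversampling, physiology,
transporter) so adding a stage never perturbs another stage's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig", "sample_anthropometry", "apply_exclusions", "oversample",
    "sample_physiology", "sample_oatp1b3", "build_cohort",
    "AGE_GROUPS", "WEIGHT_CLASSES", "age_group", "weight_class",
    "load_cohort_csv",
]

#: stratification bins used throughout the analysis
AGE_GROUPS = ((18, 40), (41, 65), (66, 84))
WEIGHT_CLASSES = ((40, 60), (60, 80), (80, 100), (100, 140))

_ETHNICITIES = ("white", "black", "hispanic", "other")
_ETHNICITY_P = (0.62, 0.12, 0.17, 0.09)


@dataclass(frozen=True)
class SexAnthropometry:
    """Sex-specific anthropometry distribution parameters."""

    height_mean: float   # cm
    height_sd: float     # cm
    # piecewise-linear mean BMI over age knots (kg/m^2)
    bmi_age_knots: tuple[float, ...] = (18.0, 50.0, 85.0)
    bmi_means: tuple[float, ...] = (25.0, 28.5, 27.0)
    bmi_sd: float = 6.2   # NHANES adult BMI standard deviation [kg/m^2]
    max_body_weight: float | None = None  # kg, truncation (resampled), or None


@dataclass(frozen=True)
class PhysiologyTrends:
    """Age trends of liver volume and hepatic blood flow per kg body weight.

    Means decline linearly with age; draws come from a bivariate normal with
    the given coefficient of variation and positive correlation, truncated at
    physiologic floors.
    """

    age_knots: tuple[float, float] = (20.0, 84.0)
    liver_ml_per_kg: tuple[float, float] = (26.0, 20.0)    # mL liver / kg BW
    flow_ml_per_min_kg: tuple[float, float] = (19.0, 12.0)  # mL blood / min / kg BW
    cv: float = 0.15
    correlation: float = 0.5
    flow_ref_ml_per_min_kg: float = 14.0   # model reference hepatic blood flow
    floor_fraction: float = 0.2            # truncation floor as fraction of mean


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the virtual-cohort generator."""

    n_base: int = 35_427        # raw anthropometry draws (pre-exclusion)
    n_target: int = 100_000     # cohort size after oversampling
    seed: int = 0
    age_min: float = 18.0
    age_max: float = 85.0       # exclusive top-code limit
    age_beta: tuple[float, float] = (1.0, 1.3)  # young-skewed age density
    p_female: float = 0.5
    max_bmi: float = 30.0       # exclusion threshold
    male: SexAnthropometry = field(default_factory=lambda: SexAnthropometry(
        height_mean=175.7, height_sd=7.4,
        bmi_means=(24.5, 28.0, 26.5)))
    female: SexAnthropometry = field(default_factory=lambda: SexAnthropometry(
        height_mean=162.2, height_sd=6.8,
        bmi_means=(25.5, 29.0, 27.5), max_body_weight=100.0))
    physiology: PhysiologyTrends = field(default_factory=PhysiologyTrends)
    oatp1b3_median: float = 1.0
    oatp1b3_log_sd: float = 0.35

    def __post_init__(self) -> None:
        if not 1 <= self.n_base:
            raise ValueError("n_base must be >= 1")
        if self.n_target < 1:
            raise ValueError("n_target must be >= 1")
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be below age_max")
        if self.oatp1b3_median <= 0 or self.oatp1b3_log_sd < 0:
            raise ValueError("invalid OATP1B3 lognormal parameters")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("anthropometry", "oversample", "physiology", "transporter")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _piecewise(age, knots, values):
    return np.interp(age, knots, values)


def sample_anthropometry(config: CohortConfig,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the base cohort: sex, age, height, BMI, body weight, ethnicity.

    Ages are drawn from a young-skewed Beta density over the configured range;
    heights are sex-specific normal; BMI is normal around an age-dependent
    mean (rising to mid-life then declining).  BW = BMI · height².  A
    configured per-sex maximum body weight is enforced by resampling.
    """
    if rng is None:
        rng = _streams(config.seed)["anthropometry"]
    n = config.n_base
    a, b = config.age_beta
    age = config.age_min + (config.age_max - config.age_min) * rng.beta(a, b, size=n)
    sex = np.where(rng.random(n) < config.p_female, "F", "M")
    ethnicity = rng.choice(_ETHNICITIES, size=n, p=_ETHNICITY_P)

    height = np.empty(n)
    bmi = np.empty(n)
    for label, params in (("M", config.male), ("F", config.female)):
        m = sex == label
        k = int(m.sum())
        if k == 0:
            continue
        h = rng.normal(params.height_mean, params.height_sd, size=k)
        mu = _piecewise(age[m], params.bmi_age_knots, params.bmi_means)
        x = rng.normal(mu, params.bmi_sd)
        x = np.clip(x, 14.0, None)
        if params.max_body_weight is not None:
            bad = x * (h / 100.0) ** 2 > params.max_body_weight
            for _ in range(100):
                if not bad.any():
                    break
                x[bad] = np.clip(rng.normal(mu[bad], params.bmi_sd), 14.0, None)
                bad = x * (h / 100.0) ** 2 > params.max_body_weight
            else:
                raise RuntimeError("body-weight truncation failed to converge")
        height[m] = h
        bmi[m] = x

    df = pd.DataFrame({
        "base_id": np.arange(n),
        "age": age,
        "sex": sex,
        "height_cm": height,
        "bmi": bmi,
        "body_weight_kg": bmi * (height / 100.0) ** 2,
        "ethnicity": ethnicity,
    })
    return df


def apply_exclusions(records: pd.DataFrame,
                     config: CohortConfig) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop records violating the cohort rules; report counts removed per rule.

    Rules: age below 18 (minors), BMI above 30 (obesity), age at or above the
    top-code limit.
    """
    under_age = records["age"] < config.age_min
    obese = records["bmi"] > config.max_bmi
    top_coded = records["age"] >= config.age_max
    removed = {
        "age_below_minimum": int(under_age.sum()),
        "bmi_above_maximum": int((obese & ~under_age).sum()),
        "age_top_coded": int((top_coded & ~under_age & ~obese).sum()),
    }
    keep = ~(under_age | obese | top_coded)
    out = records.loc[keep].reset_index(drop=True)
    if out.empty:
        raise ValueError("all records excluded; check distribution parameters")
    return out, removed


def oversample(records: pd.DataFrame, n_target: int,
               rng: np.random.Generator) -> pd.DataFrame:
    """Resample the base cohort uniformly with replacement up to ``n_target``.

    Replicates of a base subject share anthropometry but later receive
    independent physiology and transporter draws.  If ``n_target`` is below
    the base size, a plain subsample without replacement is returned and
    flagged in the ``oversampled`` attribute.
    """
    n_base = len(records)
    if n_target >= n_base:
        idx = rng.integers(0, n_base, size=n_target)
        flag = True
    else:
        idx = rng.choice(n_base, size=n_target, replace=False)
        flag = False
    out = records.iloc[idx].reset_index(drop=True)
    out["replicate"] = out.groupby("base_id").cumcount()
    out["subject_id"] = np.arange(len(out))
    out.attrs["oversampled"] = flag
    return out


def sample_physiology(age: np.ndarray, trends: PhysiologyTrends,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw (FVli [L/kg], f_bloodflow [-]) for each age.

    Liver volume per kg and hepatic blood flow per kg come from a bivariate
    normal whose means decline linearly with age and whose correlation is
    positive; non-positive draws are rejected (resampled).  f_bloodflow is the
    sampled flow normalized to the model reference flow per kg.
    """
    age = np.asarray(age, dtype=float)
    n = age.size
    mu_v = _piecewise(age, trends.age_knots, trends.liver_ml_per_kg)
    mu_q = _piecewise(age, trends.age_knots, trends.flow_ml_per_min_kg)
    sd_v = trends.cv * mu_v
    sd_q = trends.cv * mu_q
    rho = trends.correlation

    z = rng.standard_normal((n, 2))
    z2 = rho * z[:, 0] + np.sqrt(max(0.0, 1.0 - rho**2)) * z[:, 1]
    vol = mu_v + sd_v * z[:, 0]
    flow = mu_q + sd_q * z2

    floor_v = trends.floor_fraction * mu_v
    floor_q = trends.floor_fraction * mu_q
    bad = (vol < floor_v) | (flow < floor_q)
    for _ in range(100):
        if not bad.any():
            break
        k = int(bad.sum())
        z = rng.standard_normal((k, 2))
        z2 = rho * z[:, 0] + np.sqrt(max(0.0, 1.0 - rho**2)) * z[:, 1]
        vol[bad] = mu_v[bad] + sd_v[bad] * z[:, 0]
        flow[bad] = mu_q[bad] + sd_q[bad] * z2
        bad = (vol < floor_v) | (flow < floor_q)
    else:
        raise RuntimeError("physiology truncation failed to converge")

    fv_liver = vol / 1000.0                      # mL/kg -> L/kg
    f_bloodflow = flow / trends.flow_ref_ml_per_min_kg
    return fv_liver, f_bloodflow


def sample_oatp1b3(n: int, median: float, log_sd: float,
                   rng: np.random.Generator) -> np.ndarray:
    """n independent lognormal OATP1B3 abundance factors (age/sex independent)."""
    if median <= 0:
        raise ValueError("median must be positive")
    if log_sd < 0:
        raise ValueError("log_sd must be >= 0")
    if log_sd == 0:
        return np.full(n, float(median))
    return rng.lognormal(mean=np.log(median), sigma=log_sd, size=n)


def age_group(age) -> pd.Series | str:
    """Age-group label: 18-40, 41-65, 66-84 (partition on whole years)."""
    bins = [18, 41, 66, 85]
    labels = ["18-40", "41-65", "66-84"]
    return pd.cut(np.asarray(age, dtype=float), bins=bins, labels=labels,
                  right=False, include_lowest=True)


def weight_class(bw) -> pd.Series:
    """Body-weight class label: 40-60, 60-80, 80-100, 100-140 kg."""
    bins = [40, 60, 80, 100, 140]
    labels = ["40-60", "60-80", "80-100", "100-140"]
    return pd.cut(np.asarray(bw, dtype=float), bins=bins, labels=labels,
                  right=False, include_lowest=True)


def build_cohort(config: CohortConfig) -> pd.DataFrame:
    """Compose the full generator: one row per virtual individual.

    Columns carry everything needed to individualize a simulation
    (body_weight_kg, fv_liver, f_bloodflow, f_oatp1b3; cardiac output,
    cirrhosis and bilirubin at reference), plus provenance (base_id,
    replicate) and stratification labels.  Identical config + seed give a
    byte-identical table.
    """
    streams = _streams(config.seed)
    base = sample_anthropometry(config, streams["anthropometry"])
    base, removed = apply_exclusions(base, config)
    cohort = oversample(base, config.n_target, streams["oversample"])

    fv_liver, f_bloodflow = sample_physiology(
        cohort["age"].to_numpy(), config.physiology, streams["physiology"])
    cohort["fv_liver"] = fv_liver
    cohort["f_bloodflow"] = f_bloodflow
    cohort["f_oatp1b3"] = sample_oatp1b3(
        len(cohort), config.oatp1b3_median, config.oatp1b3_log_sd,
        streams["transporter"])
    cohort["f_cardiac_output"] = 1.0
    cohort["f_cirrhosis"] = 0.0
    cohort["bil_ext"] = 1.0
    cohort["age_group"] = age_group(cohort["age"])
    cohort["weight_class"] = weight_class(cohort["body_weight_kg"])

    cols = ["subject_id", "base_id", "replicate", "age", "sex", "height_cm",
            "bmi", "body_weight_kg", "ethnicity", "fv_liver", "f_bloodflow",
            "f_oatp1b3", "f_cardiac_output", "f_cirrhosis", "bil_ext",
            "age_group", "weight_class"]
    out = cohort[cols]
    out.attrs["exclusion_counts"] = removed
    out.attrs["n_base_retained"] = len(base)
    return out


def load_cohort_csv(path) -> pd.DataFrame:
    """Adapter for a real cohort table (CSV with age, sex, weight, height).

    Missing physiology columns are not filled here; pass the table through
    ``attach_physiology`` below to sample them.
    """
    df = pd.read_csv(path)
    required = {"age", "sex"}
    rename = {"weight": "body_weight_kg", "height": "height_cm"}
    df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})
    missing = (required | {"body_weight_kg", "height_cm"}) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    if "bmi" not in df.columns:
        df["bmi"] = df["body_weight_kg"] / (df["height_cm"] / 100.0) ** 2
    return df


def attach_physiology(df: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Sample physiology and transporter columns for an external cohort table."""
    streams = _streams(config.seed)
    out = df.copy()
    fv, fb = sample_physiology(out["age"].to_numpy(), config.physiology,
                               streams["physiology"])
    out["fv_liver"] = fv
    out["f_bloodflow"] = fb
    out["f_oatp1b3"] = sample_oatp1b3(len(out), config.oatp1b3_median,
                                      config.oatp1b3_log_sd, streams["transporter"])
    for col, val in (("f_cardiac_output", 1.0), ("f_cirrhosis", 0.0), ("bil_ext", 1.0)):
        if col not in out.columns:
            out[col] = val
    out["age_group"] = age_group(out["age"])
    out["weight_class"] = weight_class(out["body_weight_kg"])
    return out
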