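"""Synthetic study data: climate, longitudinal physiology panels, demography.

The generators emulate the structure of a semi-captive working-elephant
study population in a tropical monsoon climate:

* a monthly climatology with temperatures peaking just before the monsoon
  (April–May) and rainfall concentrated in June–October;
* repeated monthly measurements of faecal glucocorticoid metabolites
  (GCM, ng/g dry faeces) and body weight (kg) on individually identified
  elephants, with individual random intercepts, a single-harmonic seasonal
  signal, AR(1) month-to-month noise, and weight observed only for adults
  and only in ten calendar months;
* multi-decade monthly birth and death counts with seasonal Poisson
  intensities (births peaking in the cool dry season, deaths at the
  dry/cool extremes).

All generators are deterministic functions of the configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .series import MONTHS, MonthlySeries

# stream ids so each generator draws from its own independent stream
_STREAM_CLIMATE = 1
_STREAM_POPULATION = 2
_STREAM_PANEL = 3
_STREAM_DEMOGRAPHY = 4

AGE_GROUPS_GCM = ("<=16", "17-44", ">=45")
AGE_GROUPS_WEIGHT = ("17-44", ">=45")
MAIN_CAMP = "Pyinmana"
EXTRA_CAMPS = (("Kawlin", 24), ("East Katha", 15), ("West Katha", 12))


def _cos12(month_peak: float) -> np.ndarray:
    """Unit-amplitude annual cosine peaking at ``month_peak`` (1–12)."""
    return np.cos(2.0 * np.pi * (MONTHS - month_peak) / 12.0)


def _default_birth_intensity() -> np.ndarray:
    # births peak in January, trough in July, max/min ratio 1.8;
    # mean rate ~3.7/month matches ~2350 births over 53 years
    ratio = 1.8
    beta = (ratio - 1.0) / (ratio + 1.0)
    return 3.7 * (1.0 + beta * _cos12(1))


def _default_death_intensity() -> np.ndarray:
    # deaths peak in January (cool season), trough in November (end of
    # monsoon), max/min ratio 2.0; mean ~1.6/month (~1040 deaths / 53 y)
    return np.array(
        [2.0, 1.8, 1.6, 1.5, 1.6, 1.7, 1.6, 1.5, 1.3, 1.1, 1.0, 1.5]
    )


@dataclass
class SynthConfig:
    """All generator parameters.

    The defaults encode the study conditions: 75 focal animals (43 female)
    measured monthly for a year, 51 supplementary weight-only adults from
    three other camps, weight missing in August and November, and 53 years
    of demographic records.
    """

    # population
    n_individuals: int = 75
    prop_female: float = 43 / 75
    age_group_weights: tuple = (0.13, 0.60, 0.27)
    n_weight_extra: int = 51

    # climate (deterministic climatology)
    rain_base_mm: float = 300.0
    rain_amplitude_mm: float = 600.0
    rain_peak_month: float = 8.0
    temp_mean_c: float = 24.0
    temp_amplitude_c: float = 10.0
    temp_peak_month: float = 4.5

    # physiology panel
    gcm_baseline: float = 50.0
    weight_baseline: float = 2500.0  # adult female, kg
    weight_male_multiplier: float = 1.26
    weight_old_multiplier: float = 1.075
    seasonal_amplitude_gcm: float = 15.0
    seasonal_amplitude_weight: float = 60.0
    seasonal_peak_month_gcm: float = 7.0
    seasonal_peak_month_weight: float = 9.0
    sigma_individual_gcm: float = 12.0
    sigma_individual_weight: float = 150.0
    ar1_phi: float = 0.3
    sigma_noise_gcm: float = 8.0
    sigma_noise_weight: float = 30.0
    missing_months_weight: frozenset = frozenset({8, 11})

    # demography
    years_demography: int = 53
    birth_intensity_by_month: np.ndarray = field(
        default_factory=_default_birth_intensity
    )
    death_intensity_by_month: np.ndarray = field(
        default_factory=_default_death_intensity
    )
    gestation_months: int = 22

    seed: int = 0

    def __post_init__(self) -> None:
        self.age_group_weights = tuple(float(w) for w in self.age_group_weights)
        self.missing_months_weight = frozenset(int(m) for m in self.missing_months_weight)
        self.birth_intensity_by_month = np.asarray(
            self.birth_intensity_by_month, dtype=float
        )
        self.death_intensity_by_month = np.asarray(
            self.death_intensity_by_month, dtype=float
        )
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.prop_female <= 1.0:
            raise ConfigError("prop_female must lie in [0, 1]")
        if len(self.age_group_weights) != 3 or any(
            w < 0 for w in self.age_group_weights
        ):
            raise ConfigError("age_group_weights must be 3 nonnegative fractions")
        if abs(sum(self.age_group_weights) - 1.0) > 1e-9:
            raise ConfigError("age_group_weights must sum to 1 (tolerance 1e-9)")
        if not abs(self.ar1_phi) < 1.0:
            raise ConfigError("ar1_phi must satisfy |phi| < 1")
        for name in (
            "sigma_individual_gcm", "sigma_individual_weight",
            "sigma_noise_gcm", "sigma_noise_weight",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("seasonal_peak_month_gcm", "seasonal_peak_month_weight"):
            if not 1.0 <= getattr(self, name) <= 12.0:
                raise ConfigError(f"{name} must lie in 1..12")
        if any(m < 1 or m > 12 for m in self.missing_months_weight):
            raise ConfigError("missing_months_weight must be calendar months 1..12")
        for name in ("birth_intensity_by_month", "death_intensity_by_month"):
            arr = getattr(self, name)
            if arr.shape != (12,):
                raise ConfigError(f"{name} must have 12 entries")
            if np.any(arr < 0):
                raise ConfigError(f"{name} must be nonnegative")
        if self.years_demography < 1:
            raise ConfigError("years_demography must be >= 1")
        if self.n_weight_extra < 0:
            raise ConfigError("n_weight_extra must be >= 0")
        if self.gestation_months < 0:
            raise ConfigError("gestation_months must be >= 0")

    # -- weight baselines --------------------------------------------------

    def weight_baseline_by_sex_age(self) -> dict:
        """Baseline adult weight (kg) per (sex, age-group) cell."""
        base = {}
        for sex in ("female", "male"):
            for grp in AGE_GROUPS_WEIGHT:
                value = self.weight_baseline
                if sex == "male":
                    value *= self.weight_male_multiplier
                if grp == ">=45":
                    value *= self.weight_old_multiplier
                base[(sex, grp)] = value
        return base

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["missing_months_weight"] = sorted(self.missing_months_weight)
        out["birth_intensity_by_month"] = self.birth_intensity_by_month.tolist()
        out["death_intensity_by_month"] = self.death_intensity_by_month.tolist()
        out["age_group_weights"] = list(self.age_group_weights)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "SynthConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "SynthConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(data, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class ClimateSeries:
    """Monthly climatology: total rainfall (mm) and mean temperature (°C)."""

    rainfall: MonthlySeries
    temperature: MonthlySeries

    def __post_init__(self) -> None:
        if np.any(np.isnan(self.rainfall.values)) or np.any(
            np.isnan(self.temperature.values)
        ):
            raise ConfigError("climate series must cover all 12 months")
        if np.any(self.rainfall.values < 0):
            raise ConfigError("rainfall must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": MONTHS,
                "rainfall_mm": self.rainfall.values,
                "temperature_c": self.temperature.values,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def read_csv(cls, path: str | Path) -> "ClimateSeries":
        frame = pd.read_csv(path)
        ones = np.ones(12, dtype=int)
        return cls(
            rainfall=MonthlySeries(
                "rainfall", "mm", frame["rainfall_mm"].to_numpy(float), ones
            ),
            temperature=MonthlySeries(
                "temperature", "degC", frame["temperature_c"].to_numpy(float), ones
            ),
        )


@dataclass
class ElephantRecord:
    """One animal in the sampling frame."""

    id: str
    sex: str
    age_years: float
    age_group_gcm: str
    age_group_weight: str | None
    camp: str

    @property
    def is_adult(self) -> bool:
        return self.age_group_weight is not None


def _age_group_gcm(age: float) -> str:
    if age <= 16:
        return "<=16"
    if age <= 44:
        return "17-44"
    return ">=45"


def _age_group_weight(age: float) -> str | None:
    if age <= 16:
        return None
    return "17-44" if age <= 44 else ">=45"


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed), spawn_key=(stream,))
    )


# ---------------------------------------------------------------------------
# generators


def gen_climate(config: SynthConfig) -> ClimateSeries:
    """Deterministic monsoon climatology.

    Rainfall is a truncated annual cosine (negative values clipped to 0, so
    the dry-season months are rainless); temperature is an un-truncated
    cosine.  Defaults give rainfall 0–900 mm peaking in August and
    temperature 14–34 °C peaking in April–May.
    """
    rain = np.maximum(
        0.0, config.rain_base_mm + config.rain_amplitude_mm * _cos12(config.rain_peak_month)
    )
    temp = config.temp_mean_c + config.temp_amplitude_c * _cos12(config.temp_peak_month)
    ones = np.ones(12, dtype=int)
    return ClimateSeries(
        rainfall=MonthlySeries("rainfall", "mm", rain, ones),
        temperature=MonthlySeries("temperature", "degC", temp, ones),
    )


def gen_population(config: SynthConfig) -> list[ElephantRecord]:
    """Sample the animal roster.

    Returns the ``n_individuals`` focal animals of the main camp (measured
    for both GCM and, when adult, weight) followed by ``n_weight_extra``
    supplementary adults from the three other camps (weight only).
    """
    if config.n_individuals < 1:
        raise ConfigError("n_individuals must be >= 1")
    rng = _rng(config, _STREAM_POPULATION)
    records: list[ElephantRecord] = []

    ranges = {"<=16": (4.0, 16.0), "17-44": (17.0, 44.0), ">=45": (45.0, 69.0)}
    groups = rng.choice(3, size=config.n_individuals, p=config.age_group_weights)
    sexes = np.where(rng.random(config.n_individuals) < config.prop_female,
                     "female", "male")
    for i in range(config.n_individuals):
        grp = AGE_GROUPS_GCM[groups[i]]
        lo, hi = ranges[grp]
        age = float(rng.uniform(lo, hi))
        records.append(
            ElephantRecord(
                id=f"E{i + 1:03d}",
                sex=str(sexes[i]),
                age_years=age,
                age_group_gcm=_age_group_gcm(age),
                age_group_weight=_age_group_weight(age),
                camp=MAIN_CAMP,
            )
        )

    # supplementary weight-only adults, allocated across camps in the
    # configured proportions (24 : 15 : 12)
    camp_names = [c for c, _ in EXTRA_CAMPS]
    camp_w = np.array([w for _, w in EXTRA_CAMPS], dtype=float)
    camp_w /= camp_w.sum()
    w_adult = np.array(config.age_group_weights[1:], dtype=float)
    if w_adult.sum() == 0:
        w_adult = np.array([0.5, 0.5])
    w_adult = w_adult / w_adult.sum()
    for j in range(config.n_weight_extra):
        grp = AGE_GROUPS_WEIGHT[int(rng.choice(2, p=w_adult))]
        lo, hi = ranges[grp]
        age = float(rng.uniform(lo, hi))
        sex = "female" if rng.random() < config.prop_female else "male"
        camp = camp_names[int(rng.choice(len(camp_names), p=camp_w))]
        records.append(
            ElephantRecord(
                id=f"X{j + 1:03d}",
                sex=sex,
                age_years=age,
                age_group_gcm=_age_group_gcm(age),
                age_group_weight=_age_group_weight(age),
                camp=camp,
            )
        )
    return records


def population_frame(population: Sequence[ElephantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in population],
            "sex": [r.sex for r in population],
            "age_years": [r.age_years for r in population],
            "age_group": [r.age_group_gcm for r in population],
            "camp": [r.camp for r in population],
        }
    )


def _ar1_noise(
    rng: np.random.Generator, n_series: int, phi: float, sigma: float
) -> np.ndarray:
    """Stationary AR(1) residual series, one row per individual, 12 columns."""
    eps = np.zeros((n_series, 12))
    if sigma == 0:
        return eps
    sd0 = sigma / np.sqrt(1.0 - phi**2)
    eps[:, 0] = rng.normal(0.0, sd0, size=n_series)
    for t in range(1, 12):
        eps[:, t] = phi * eps[:, t - 1] + rng.normal(0.0, sigma, size=n_series)
    return eps


def gen_panel(
    population: Sequence[ElephantRecord],
    climate: ClimateSeries,
    config: SynthConfig,
) -> pd.DataFrame:
    """Simulate the longitudinal physiology panel.

    For each individual *i*, variable and calendar month *m*:

        value = baseline(sex, age group) + b_i
                + A · cos(2π (m − peak) / 12) + ε_m

    with ``b_i ~ N(0, sigma_individual²)`` and ε a stationary AR(1) process
    (coefficient ``ar1_phi``, innovation SD ``sigma_noise``).  GCM rows are
    produced for main-camp animals of every age; weight rows only for
    adults, and not in the configured missing months.

    Returns a tidy frame with columns
    ``id, sex, age_years, age_group, camp, month, variable, value``.
    """
    if not population:
        raise ConfigError("population must be non-empty")
    rng = _rng(config, _STREAM_PANEL)
    weight_base = config.weight_baseline_by_sex_age()

    gcm_season = config.seasonal_amplitude_gcm * _cos12(config.seasonal_peak_month_gcm)
    wt_season = config.seasonal_amplitude_weight * _cos12(
        config.seasonal_peak_month_weight
    )

    rows: list[dict] = []

    gcm_animals = [r for r in population if r.camp == MAIN_CAMP]
    b_gcm = rng.normal(0.0, config.sigma_individual_gcm, size=len(gcm_animals))
    eps_gcm = _ar1_noise(rng, len(gcm_animals), config.ar1_phi, config.sigma_noise_gcm)
    for i, rec in enumerate(gcm_animals):
        values = config.gcm_baseline + b_gcm[i] + gcm_season + eps_gcm[i]
        for m in range(12):
            rows.append(
                {
                    "id": rec.id, "sex": rec.sex, "age_years": rec.age_years,
                    "age_group": rec.age_group_gcm, "camp": rec.camp,
                    "month": m + 1, "variable": "gcm", "value": values[m],
                }
            )

    adults = [r for r in population if r.is_adult]
    b_wt = rng.normal(0.0, config.sigma_individual_weight, size=len(adults))
    eps_wt = _ar1_noise(rng, len(adults), config.ar1_phi, config.sigma_noise_weight)
    for i, rec in enumerate(adults):
        base = weight_base[(rec.sex, rec.age_group_weight)]
        values = base + b_wt[i] + wt_season + eps_wt[i]
        for m in range(12):
            if (m + 1) in config.missing_months_weight:
                continue
            rows.append(
                {
                    "id": rec.id, "sex": rec.sex, "age_years": rec.age_years,
                    "age_group": rec.age_group_weight, "camp": rec.camp,
                    "month": m + 1, "variable": "weight", "value": values[m],
                }
            )
    return pd.DataFrame(rows)


def gen_demography(config: SynthConfig) -> pd.DataFrame:
    """Simulate monthly birth and death events over ``years_demography`` years.

    Counts in year *y*, month *m* are independent Poisson draws from the
    configured monthly intensities.  Returns one row per event:
    ``type, year, month``.
    """
    rng = _rng(config, _STREAM_DEMOGRAPHY)
    rows: list[dict] = []
    years = config.years_demography
    for etype, lam in (
        ("birth", config.birth_intensity_by_month),
        ("death", config.death_intensity_by_month),
    ):
        counts = rng.poisson(np.broadcast_to(lam, (years, 12)))
        for y in range(years):
            for m in range(12):
                for _ in range(int(counts[y, m])):
                    rows.append({"type": etype, "year": y + 1, "month": m + 1})
    return pd.DataFrame(rows, columns=["type", "year", "month"])
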