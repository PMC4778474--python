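"""Permutation test for a calendar-month effect on a repeated-measures panel.

The month effect is tested on within-individual centred values with an
F-like ratio (between-month mean square over within-month mean square),
calibrated by permuting month labels *within* each individual.  Shuffling
within individuals destroys any seasonal alignment across the population
while exactly preserving each animal's own set of values (and hence all
between-individual heterogeneity), so the null distribution respects the
repeated-measures structure without any parametric correlation model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InsufficientDataError
from .prep import center_within_individual, _select_variable
from .series import MonthlySeries


@dataclass
class SeasonalTestResult:
    """Month-effect test on centred values."""

    statistic: float  # between-month MS / within-month MS of centred values
    per_month_effect: MonthlySeries  # month means of centred values
    p_perm: float
    n_perm: int
    seed: int
    n_obs: int
    n_individuals: int
    n_months: int

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_perm": self.p_perm,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "n_obs": self.n_obs,
            "n_individuals": self.n_individuals,
            "n_months": self.n_months,
            "per_month_effect": self.per_month_effect.values.tolist(),
        }


def _f_statistic(v: np.ndarray, month_idx: np.ndarray, n_m: np.ndarray) -> float:
    """One-way F-like ratio of v grouped by calendar month."""
    present = n_m > 0
    k = int(present.sum())
    n = v.size
    sum_m = np.bincount(month_idx, weights=v, minlength=12)
    mean_m = np.zeros(12)
    mean_m[present] = sum_m[present] / n_m[present]
    grand = v.mean()
    ssb = float(np.sum(n_m[present] * (mean_m[present] - grand) ** 2))
    ssw = float(np.sum(v * v) - np.sum(n_m[present] * mean_m[present] ** 2))
    msb = ssb / (k - 1)
    if ssw <= 0:
        return float("inf") if msb > 0 else 0.0
    return msb / (ssw / (n - k))


def month_effect_test(
    panel: pd.DataFrame,
    variable: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> SeasonalTestResult:
    """Test whether a variable differs systematically by calendar month.

    The p-value uses the add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_perm)`` so it can never be zero;
    its smallest attainable value is ``1/(n_perm + 1)``.
    """
    if n_perm < 99:
        raise ConfigError("n_perm must be >= 99")
    centred = center_within_individual(panel, variable)
    obs = centred.observations.sort_values(["id", "month"], kind="stable")
    v = obs["value_centred"].to_numpy(dtype=float)
    month_idx = obs["month"].to_numpy(dtype=int) - 1
    indiv_codes = pd.factorize(obs["id"])[0]

    n_m = np.bincount(month_idx, minlength=12)
    if int((n_m > 0).sum()) < 2:
        raise InsufficientDataError(
            "month-effect test needs >= 2 calendar months represented"
        )

    stat = _f_statistic(v, month_idx, n_m)

    rng = np.random.default_rng(seed)
    exceed = 0
    # shuffle values within each individual's block: lexsort by (individual,
    # random key) is a within-block permutation because the rows are already
    # ordered by individual
    for _ in range(n_perm):
        order = np.lexsort((rng.random(v.size), indiv_codes))
        null = _f_statistic(v[order], month_idx, n_m)
        if null >= stat:
            exceed += 1
    p_perm = (1 + exceed) / (1 + n_perm)

    sum_m = np.bincount(month_idx, weights=v, minlength=12)
    effect = np.full(12, np.nan)
    effect[n_m > 0] = sum_m[n_m > 0] / n_m[n_m > 0]
    per_month = MonthlySeries(
        f"{variable} centred month effect", "", effect, n_m
    )
    return SeasonalTestResult(
        statistic=stat,
        per_month_effect=per_month,
        p_perm=float(p_perm),
        n_perm=n_perm,
        seed=seed,
        n_obs=int(v.size),
        n_individuals=int(indiv_codes.max() + 1),
        n_months=int((n_m > 0).sum()),
    )


@dataclass
class GroupContrast:
    """Percent difference between two covariate levels, with bootstrap CI."""

    percent: float
    ci_low: float
    ci_high: float
    level_a: str
    level_b: str
    n_a: int
    n_b: int
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "percent": self.percent,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level_a": self.level_a,
            "level_b": self.level_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def group_contrast(
    panel: pd.DataFrame,
    variable: str,
    grouping_field: str,
    level_a: str,
    level_b: str,
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
) -> GroupContrast:
    """Percent difference of level ``a`` relative to level ``b``.

    Computed on per-individual means (one value per animal), so repeated
    monthly measures do not inflate the effective sample size.  The
    interval is a seeded percentile bootstrap over individuals.
    """
    sub = _select_variable(panel, variable)
    if grouping_field not in sub.columns:
        raise InsufficientDataError(f"grouping field {grouping_field!r} absent")
    indiv = sub.groupby(["id", grouping_field])["value"].mean().reset_index()
    a = indiv.loc[indiv[grouping_field] == level_a, "value"].to_numpy()
    b = indiv.loc[indiv[grouping_field] == level_b, "value"].to_numpy()
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError(
            f"empty level: {level_a!r} (n={a.size}) or {level_b!r} (n={b.size})"
        )
    pct = 100.0 * (a.mean() - b.mean()) / b.mean()

    rng = np.random.default_rng(seed)
    boot_a = a[rng.integers(0, a.size, size=(n_boot, a.size))].mean(axis=1)
    boot_b = b[rng.integers(0, b.size, size=(n_boot, b.size))].mean(axis=1)
    boot = 100.0 * (boot_a - boot_b) / boot_b
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return GroupContrast(
        percent=float(pct),
        ci_low=float(lo),
        ci_high=float(hi),
        level_a=str(level_a),
        level_b=str(level_b),
        n_a=int(a.size),
        n_b=int(b.size),
        n_boot=n_boot,
        seed=seed,
    )
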