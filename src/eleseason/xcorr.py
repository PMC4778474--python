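"""Sign-constrained lagged Spearman cross-correlation of monthly series.

The central question the pipeline answers is whether two 12-slot
calendar-month profiles (say, a physiological marker and rainfall) follow
the same seasonal pattern, and with what time shift.  For each allowed lag
*k* the month-*m* value of the first series is paired with the month-*m+k*
value of the second, Spearman's ρ is computed over complete pairs, and the
lag maximizing |ρ| is selected.  Directionality assumptions (e.g. deaths
may follow, but not precede, the marker) are encoded as the allowed lag
set.  Significance comes from permuting the 12 calendar slots of the
second series, with both per-lag p-values and a selection-adjusted p-value
for the maximal-|ρ| statistic (which accounts for the best lag being
chosen post hoc).

Lag sign convention: ``k > 0`` means the **second** series follows the
first by ``k`` months.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateSeriesError, InsufficientDataError
from .series import MonthlySeries

log = logging.getLogger(__name__)

ALIGNMENTS = ("circular", "truncated")

PAIR_TYPES = (
    "marker_vs_deaths",
    "marker_vs_births",
    "climate_vs_marker",
    "marker_vs_marker",
)


# ---------------------------------------------------------------------------
# Spearman correlation


def spearman(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of midranks.

    Positions where either input is NaN are dropped pairwise.  Requires at
    least 3 complete pairs and non-constant ranks on both sides.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("inputs must be equal-length 1-d sequences")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise InsufficientDataError(
            f"need >= 3 complete pairs, got {x.size}"
        )
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise DegenerateSeriesError("constant input: ranks have zero variance")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    # clamp tiny float excursions outside [-1, 1]
    return float(min(1.0, max(-1.0, rho)))


def spearman_pvalue_t(rho: float, n: int) -> float:
    """Two-sided p from the Student-t approximation for Spearman's ρ.

    Crude at n = 12; provided for comparison with the permutation p only.
    """
    if n < 4:
        return float("nan")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


# ---------------------------------------------------------------------------
# lag specification


@dataclass(frozen=True)
class LagSpec:
    """Allowed integer month lags for a variable pair.

    ``alignment`` controls how months outside 1..12 are handled when the
    second series is shifted: ``circular`` wraps modulo 12 (December and
    January are adjacent — the series are annual climatologies), while
    ``truncated`` drops out-of-range months.
    """

    allowed_lags: tuple
    max_abs_lag: int
    alignment: str = "circular"
    direction_label: str = ""

    def __post_init__(self) -> None:
        lags = tuple(sorted(int(k) for k in self.allowed_lags))
        object.__setattr__(self, "allowed_lags", lags)
        if not lags:
            raise ConfigError("allowed_lags must be non-empty")
        if any(abs(k) > self.max_abs_lag for k in lags):
            raise ConfigError("allowed_lags exceed max_abs_lag")
        if self.alignment not in ALIGNMENTS:
            raise ConfigError(f"alignment must be one of {ALIGNMENTS}")


def build_lag_spec(
    pair_type: str, max_abs_lag: int = 3, alignment: str = "circular"
) -> LagSpec:
    """Encode the directionality assumption for a variable pair.

    With the convention that lag k > 0 means the second series follows the
    first by k months:

    * ``marker_vs_deaths`` — deaths may follow, never precede, the marker:
      lags ``{0..+K}``;
    * ``climate_vs_marker`` — the marker responds to climate, never the
      reverse: lags ``{0..+K}`` (climate first, marker second);
    * ``marker_vs_births`` — births also stand for conceptions ~22 months
      earlier, so either direction is meaningful: lags ``{−K..+K}``;
    * ``marker_vs_marker`` — no a-priori ordering: lags ``{−K..+K}``.
    """
    if max_abs_lag < 0:
        raise ConfigError("max_abs_lag must be >= 0")
    if pair_type in ("marker_vs_deaths", "climate_vs_marker"):
        lags = tuple(range(0, max_abs_lag + 1))
    elif pair_type in ("marker_vs_births", "marker_vs_marker"):
        lags = tuple(range(-max_abs_lag, max_abs_lag + 1))
    else:
        raise ConfigError(
            f"unknown pair_type {pair_type!r}; expected one of {PAIR_TYPES}"
        )
    return LagSpec(
        allowed_lags=lags,
        max_abs_lag=max_abs_lag,
        alignment=alignment,
        direction_label=pair_type,
    )


# ---------------------------------------------------------------------------
# lagged cross-correlation


@dataclass
class CrossCorrResult:
    """Per-lag Spearman ρ, best lag, and permutation significance."""

    rho_by_lag: dict
    n_pairs_by_lag: dict
    best_lag: int
    best_rho: float
    spec: LagSpec
    label_a: str = ""
    label_b: str = ""
    p_by_lag: dict = field(default_factory=dict)
    p_selected: float | None = None
    n_perm: int = 0
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        lags = sorted(self.rho_by_lag)
        return pd.DataFrame(
            {
                "lag": lags,
                "rho": [self.rho_by_lag[k] for k in lags],
                "n_pairs": [self.n_pairs_by_lag[k] for k in lags],
                "p": [self.p_by_lag.get(k, np.nan) for k in lags],
            }
        )

    def to_dict(self) -> dict:
        return {
            "series_a": self.label_a,
            "series_b": self.label_b,
            "pair_type": self.spec.direction_label,
            "alignment": self.spec.alignment,
            "allowed_lags": list(self.spec.allowed_lags),
            "rho_by_lag": {str(k): v for k, v in self.rho_by_lag.items()},
            "n_pairs_by_lag": {str(k): v for k, v in self.n_pairs_by_lag.items()},
            "best_lag": self.best_lag,
            "best_rho": self.best_rho,
            "p_by_lag": {str(k): v for k, v in self.p_by_lag.items()},
            "p_selected": self.p_selected,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def _lagged_pairs(
    a: np.ndarray, b: np.ndarray, lag: int, alignment: str
) -> tuple[np.ndarray, np.ndarray]:
    """Value pairs (a[m], b[m+k]) for one lag, before NaN deletion."""
    m = np.arange(12)
    if alignment == "circular":
        return a, b[(m + lag) % 12]
    keep = (m + lag >= 0) & (m + lag <= 11)
    return a[keep], b[(m + lag)[keep]]


def _select_best(rho_by_lag: dict) -> int:
    """Maximal |ρ|; ties broken toward smaller |lag|, then the negative lag."""
    return min(rho_by_lag, key=lambda k: (-abs(rho_by_lag[k]), abs(k), k))


def lagged_xcorr(
    a: MonthlySeries, b: MonthlySeries, spec: LagSpec
) -> CrossCorrResult:
    """Spearman ρ between two monthly series at every allowed lag.

    Lags with fewer than 3 complete pairs (or constant ranks) are dropped
    with a warning; if no lag survives an error is raised.
    """
    rho_by_lag: dict = {}
    n_pairs: dict = {}
    for k in spec.allowed_lags:
        xa, xb = _lagged_pairs(a.values, b.values, k, spec.alignment)
        mask = ~(np.isnan(xa) | np.isnan(xb))
        try:
            rho_by_lag[k] = spearman(xa, xb)
            n_pairs[k] = int(mask.sum())
        except (InsufficientDataError, DegenerateSeriesError) as exc:
            log.warning("dropping lag %+d: %s", k, exc)
    if not rho_by_lag:
        raise InsufficientDataError(
            "no allowed lag has >= 3 complete non-degenerate pairs"
        )
    best = _select_best(rho_by_lag)
    return CrossCorrResult(
        rho_by_lag=rho_by_lag,
        n_pairs_by_lag=n_pairs,
        best_lag=best,
        best_rho=rho_by_lag[best],
        spec=spec,
        label_a=a.label,
        label_b=b.label,
    )


def _perm_rhos_fast(
    a: np.ndarray, b: np.ndarray, lags, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized null ρ matrix (n_perm × n_lags): complete data, circular.

    Ranking commutes with a permutation of the 12 slots, so the permuted
    rank vectors are permutations of the observed midranks and every null
    correlation reduces to a dot product.
    """
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    ra_c = ra - ra.mean()
    sa = ra.std()
    sb = rb.std()
    perm_idx = np.argsort(rng.random((n_perm, 12)), axis=1)
    rb_perm = rb[perm_idx]  # (n_perm, 12)
    out = np.empty((n_perm, len(lags)))
    m = np.arange(12)
    for j, k in enumerate(lags):
        cols = (m + k) % 12
        shifted = rb_perm[:, cols]
        out[:, j] = (shifted - rb.mean()).dot(ra_c) / (12.0 * sa * sb)
    return np.clip(out, -1.0, 1.0)


def xcorr_significance(
    a: MonthlySeries,
    b: MonthlySeries,
    spec: LagSpec,
    n_perm: int = 10_000,
    seed: int = 0,
) -> CrossCorrResult:
    """Permutation significance of the lagged cross-correlation.

    The null is generated by randomly permuting the 12 calendar slots of
    series ``b`` (``a`` held fixed), which destroys any seasonal alignment
    while preserving both marginal distributions.  Two p-values are
    reported with the add-one estimator:

    * ``p_by_lag[k]`` — two-sided tail probability of |ρ_k| at each lag;
    * ``p_selected`` — tail probability of max over allowed lags of |ρ|,
      the honest p-value for a best lag chosen post hoc.
    """
    if n_perm < 99:
        raise ConfigError("n_perm must be >= 99")
    result = lagged_xcorr(a, b, spec)
    lags = sorted(result.rho_by_lag)
    obs = np.array([result.rho_by_lag[k] for k in lags])
    rng = np.random.default_rng(seed)

    complete = a.n_present == 12 and b.n_present == 12
    if complete and spec.alignment == "circular":
        null = _perm_rhos_fast(a.values, b.values, lags, n_perm, rng)
    else:
        null = np.full((n_perm, len(lags)), np.nan)
        bv = b.values
        for p in range(n_perm):
            perm = rng.permutation(12)
            bp = bv[perm]
            for j, k in enumerate(lags):
                xa, xb = _lagged_pairs(a.values, bp, k, spec.alignment)
                try:
                    null[p, j] = spearman(xa, xb)
                except (InsufficientDataError, DegenerateSeriesError):
                    null[p, j] = 0.0  # uninformative permutation

    abs_null = np.abs(null)
    eps = 1e-12  # guard against float jitter in ties with the observed value
    p_by_lag = {
        k: float((1 + np.sum(abs_null[:, j] >= abs(obs[j]) - eps)) / (n_perm + 1))
        for j, k in enumerate(lags)
    }
    max_null = abs_null.max(axis=1)
    obs_max = np.abs(obs).max()
    p_selected = float((1 + np.sum(max_null >= obs_max - eps)) / (n_perm + 1))

    result.p_by_lag = p_by_lag
    result.p_selected = p_selected
    result.n_perm = n_perm
    result.seed = seed
    return result
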