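"""End-to-end runner: generate → prep → seasonality → cross-correlations.

Reproduces the full analysis design on generated (or user-supplied) data:
monthly pooled series for the physiological markers, demographic monthly
profiles, permutation month-effect tests, and the nine sign-constrained
lagged cross-correlation pairs (marker–marker, marker–climate,
marker–births, marker–deaths), consolidated into a Markdown + JSON report.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .prep import (
    center_within_individual,
    monthly_event_profile,
    monthly_group_means,
    pct_diff,
    zscore,
)
from .seasonal import group_contrast, month_effect_test
from .series import MONTH_NAMES, MonthlySeries, conception_month, shift_month
from .synthetic import (
    ClimateSeries,
    SynthConfig,
    gen_climate,
    gen_demography,
    gen_panel,
    gen_population,
    population_frame,
)
from .xcorr import build_lag_spec, xcorr_significance

log = logging.getLogger(__name__)

ADULT_GROUPS = ("17-44", ">=45")

# (name, first series, second series, pair type); names are resolved
# against the prepared series at run time
PAIR_PLAN = (
    ("gcm_weight", "gcm_pooled", "weight_pooled", "marker_vs_marker"),
    ("gcm_rainfall", "rainfall", "gcm_pooled", "climate_vs_marker"),
    ("gcm_temperature", "temperature", "gcm_pooled", "climate_vs_marker"),
    ("gcm_births", "gcm_adult_female", "births", "marker_vs_births"),
    ("gcm_deaths", "gcm_pooled", "deaths", "marker_vs_deaths"),
    ("weight_rainfall", "rainfall", "weight_pooled", "climate_vs_marker"),
    ("weight_temperature", "temperature", "weight_pooled", "climate_vs_marker"),
    ("weight_births", "weight_adult_female", "births", "marker_vs_births"),
    ("weight_deaths", "weight_pooled", "deaths", "marker_vs_deaths"),
)

BIRTH_PAIRS = {"gcm_births", "weight_births"}


@dataclass
class RunManifest:
    """Record of one pipeline run: inputs, seed, outputs."""

    config_path: str
    seed: int
    stage_outputs: dict = field(default_factory=dict)
    versions: str = ""
    timestamps: dict = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "config_path": self.config_path,
                    "seed": self.seed,
                    "stage_outputs": self.stage_outputs,
                    "versions": self.versions,
                    "timestamps": self.timestamps,
                },
                indent=2,
            )
            + "\n"
        )


def adult_female_series(
    panel: pd.DataFrame, variable: str, units: str = ""
) -> MonthlySeries:
    """Pooled monthly series restricted to adult females (> 16 years)."""
    sub = panel[
        (panel["sex"] == "female") & (panel["age_group"].isin(ADULT_GROUPS))
    ]
    gm = monthly_group_means(sub, variable, ("age_group",), units=units)
    pooled = gm.pooled
    pooled.label = f"{variable} adult females"
    return pooled


def prepare_series(
    panel: pd.DataFrame, events: pd.DataFrame, climate: ClimateSeries
) -> tuple[dict, dict]:
    """Build every monthly series the cross-correlation stage consumes.

    Returns ``(series, profiles)`` where ``series`` maps name → MonthlySeries
    (markers pooled over sex–age groups, adult-female marker series,
    climate, demographic rates) and ``profiles`` maps event type →
    DemographicSeries.
    """
    series: dict = {}
    gcm = monthly_group_means(panel, "gcm", ("sex", "age_group"), units="ng/g")
    series["gcm_pooled"] = gcm.pooled
    series["gcm_pooled"].label = "gcm pooled"
    wt = monthly_group_means(panel, "weight", ("sex", "age_group"), units="kg")
    series["weight_pooled"] = wt.pooled
    series["weight_pooled"].label = "weight pooled"
    series["gcm_adult_female"] = adult_female_series(panel, "gcm", "ng/g")
    series["weight_adult_female"] = adult_female_series(panel, "weight", "kg")
    series["rainfall"] = climate.rainfall
    series["temperature"] = climate.temperature

    profiles = {
        etype: monthly_event_profile(events, etype) for etype in ("birth", "death")
    }
    series["births"] = profiles["birth"].per_month_mean
    series["births"].label = "births"
    series["deaths"] = profiles["death"].per_month_mean
    series["deaths"].label = "deaths"
    return series, profiles


def run_pipeline(
    config: SynthConfig | str | Path | None = None,
    out_dir: str | Path = "run",
    seed: int | None = None,
    n_perm: int = 10_000,
    max_abs_lag: int = 3,
    alignment: str = "circular",
    resume: bool = False,
) -> RunManifest:
    """Execute the full analysis on generated data.

    ``seed`` overrides the config seed.  All stage outputs are written
    under ``out_dir``; ``report.md`` and ``report.json`` are deterministic
    functions of (config, seed), so two runs with the same inputs produce
    byte-identical reports.  With ``resume=True``, stages whose output
    files already exist are skipped and their outputs reloaded.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_path = ""
    if config is None:
        config = SynthConfig()
    elif isinstance(config, (str, Path)):
        config_path = str(config)
        config = SynthConfig.from_file(config)
    if seed is not None:
        config = SynthConfig.from_dict({**config.to_dict(), "seed": int(seed)})
    manifest = RunManifest(
        config_path=config_path, seed=config.seed, versions=f"eleseason {__version__}"
    )
    seed_stream = np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed), spawn_key=(100,))
    )
    child_seed = lambda: int(seed_stream.integers(2**31))  # noqa: E731

    def _stamp(stage: str) -> None:
        manifest.timestamps[stage] = datetime.datetime.now().isoformat(
            timespec="seconds"
        )

    # -- stage: generate ---------------------------------------------------
    gen_files = {
        "climate": out / "climate.csv",
        "population": out / "population.csv",
        "panel": out / "panel.csv",
        "events": out / "events.csv",
        "config": out / "config_used.json",
    }
    if resume and all(p.exists() for p in gen_files.values()):
        log.info("resume: skipping generate stage")
    else:
        climate = gen_climate(config)
        population = gen_population(config)
        panel = gen_panel(population, climate, config)
        events = gen_demography(config)
        climate.to_csv(gen_files["climate"])
        population_frame(population).to_csv(gen_files["population"], index=False)
        panel.to_csv(gen_files["panel"], index=False, float_format="%.10g")
        events.to_csv(gen_files["events"], index=False)
        config.to_file(gen_files["config"])
    # downstream stages always consume the written files, so a resumed run
    # sees bit-identical inputs
    climate = ClimateSeries.read_csv(gen_files["climate"])
    panel = pd.read_csv(gen_files["panel"])
    events = pd.read_csv(gen_files["events"])
    manifest.stage_outputs["generate"] = {k: str(v) for k, v in gen_files.items()}
    _stamp("generate")

    # -- stage: prep -------------------------------------------------------
    series, profiles = prepare_series(panel, events, climate)
    prep_files = {}
    for name, s in series.items():
        path = out / f"series_{name}.csv"
        s.to_csv(path)
        prep_files[name] = str(path)
    for variable in ("gcm", "weight"):
        centred = center_within_individual(panel, variable)
        path = out / f"centred_{variable}.csv"
        centred.observations.to_csv(path, index=False, float_format="%.10g")
        prep_files[f"centred_{variable}"] = str(path)
    manifest.stage_outputs["prep"] = prep_files
    _stamp("prep")

    # -- stage: seasonality ------------------------------------------------
    seasonality = {}
    for variable in ("gcm", "weight"):
        res = month_effect_test(panel, variable, n_perm=n_perm, seed=child_seed())
        seasonality[variable] = res
        res.per_month_effect.to_csv(out / f"month_effect_{variable}.csv")
    manifest.stage_outputs["seasonality"] = {
        v: str(out / f"month_effect_{v}.csv") for v in seasonality
    }
    _stamp("seasonality")

    # -- stage: cross-correlations ----------------------------------------
    xcorr_results = {}
    xcorr_files = {}
    for name, key_a, key_b, pair_type in PAIR_PLAN:
        spec = build_lag_spec(pair_type, max_abs_lag=max_abs_lag, alignment=alignment)
        res = xcorr_significance(
            series[key_a], series[key_b], spec, n_perm=n_perm, seed=child_seed()
        )
        xcorr_results[name] = res
        path = out / f"xcorr_{name}.csv"
        res.to_frame().to_csv(path, index=False, float_format="%.10g")
        xcorr_files[name] = str(path)
        # z-scored overlay for external plotting
        overlay = pd.DataFrame(
            {
                "month": np.arange(1, 13),
                "series_a_z": zscore(series[key_a]).values,
                "series_b_z": zscore(series[key_b]).values,
            }
        )
        overlay.to_csv(out / f"overlay_{name}.csv", index=False, float_format="%.10g")
    manifest.stage_outputs["xcorr"] = xcorr_files
    _stamp("xcorr")

    # -- stage: report -----------------------------------------------------
    report = build_report(
        config, series, profiles, seasonality, xcorr_results, panel
    )
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    (out / "report.md").write_text(render_report_md(report))
    manifest.stage_outputs["report"] = {
        "json": str(out / "report.json"),
        "md": str(out / "report.md"),
    }
    _stamp("report")

    manifest.write(out / "manifest.json")
    for stage, outputs in manifest.stage_outputs.items():
        for key, path in outputs.items():
            p = Path(path)
            if not p.exists() or p.stat().st_size == 0:
                raise RuntimeError(f"stage {stage} output {key} missing or empty")
    return manifest


def build_report(
    config: SynthConfig,
    series: dict,
    profiles: dict,
    seasonality: dict,
    xcorr_results: dict,
    panel: pd.DataFrame,
) -> dict:
    """Assemble the consolidated machine-readable report."""
    rain = series["rainfall"]
    max_rain, min_rain = rain.argmax_month(), rain.argmin_month()

    contrasts = {}
    # marker contrast across rainfall extremes (same month for GCM, one
    # month later for weight, which lags rainfall)
    contrasts["gcm_pct_diff_max_vs_min_rain_month"] = {
        "percent": pct_diff(series["gcm_pooled"], max_rain, min_rain),
        "month_a": MONTH_NAMES[max_rain - 1],
        "month_b": MONTH_NAMES[min_rain - 1],
    }
    wt_a = shift_month(max_rain, 1)
    wt_b = shift_month(min_rain, 1)
    try:
        contrasts["weight_pct_diff_month_after_rain_extremes"] = {
            "percent": pct_diff(series["weight_adult_female"], wt_a, wt_b),
            "month_a": MONTH_NAMES[wt_a - 1],
            "month_b": MONTH_NAMES[wt_b - 1],
        }
    except Exception as exc:  # month after an extreme may be unobserved
        contrasts["weight_pct_diff_month_after_rain_extremes"] = {"error": str(exc)}

    adults = panel[panel["age_group"].isin(ADULT_GROUPS)]
    contrasts["weight_male_vs_female"] = group_contrast(
        adults, "weight", "sex", "male", "female", seed=config.seed
    ).to_dict()
    females = panel[panel["sex"] == "female"]
    contrasts["weight_old_vs_adult_female"] = group_contrast(
        females, "weight", "age_group", ">=45", "17-44", seed=config.seed
    ).to_dict()

    demography = {}
    for etype, prof in profiles.items():
        demography[etype] = {
            "total_events": prof.total_events,
            "years_covered": prof.years_covered,
            "max_month": MONTH_NAMES[prof.max_month - 1] if prof.max_month else None,
            "min_month": MONTH_NAMES[prof.min_month - 1] if prof.min_month else None,
            "max_min_ratio": prof.max_min_ratio,
        }
        if etype == "birth" and prof.max_month:
            demography[etype]["peak_conception_month"] = MONTH_NAMES[
                conception_month(prof.max_month, config.gestation_months) - 1
            ]

    pairs = {}
    for name, res in xcorr_results.items():
        entry = res.to_dict()
        if name in BIRTH_PAIRS:
            entry["gestation_months"] = config.gestation_months
            entry["note"] = (
                f"a birth in month m reflects a conception "
                f"{config.gestation_months} months earlier"
            )
        pairs[name] = entry

    return {
        "seed": config.seed,
        "n_individuals": int(config.n_individuals),
        "seasonality": {v: r.to_dict() for v, r in seasonality.items()},
        "cross_correlations": pairs,
        "demography": demography,
        "contrasts": contrasts,
    }


def render_report_md(report: dict) -> str:
    """Human-readable Markdown rendering of the report dictionary."""
    lines = [
        "# Seasonal physiology and demography report",
        "",
        f"Seed: {report['seed']}",
        "",
        "## Month-effect tests (centred values, within-individual permutation)",
        "",
        "| variable | statistic | p (perm) | n obs | n individuals |",
        "|---|---|---|---|---|",
    ]
    for var, res in report["seasonality"].items():
        lines.append(
            f"| {var} | {res['statistic']:.3f} | {res['p_perm']:.4g} "
            f"| {res['n_obs']} | {res['n_individuals']} |"
        )
    lines += [
        "",
        "## Lagged Spearman cross-correlations",
        "",
        "Lag k > 0: the second series follows the first by k months.",
        "",
        "| pair | best lag | rho | p (per-lag) | p (selection-adjusted) |",
        "|---|---|---|---|---|",
    ]
    for name, res in report["cross_correlations"].items():
        p_lag = res["p_by_lag"].get(str(res["best_lag"]), float("nan"))
        lines.append(
            f"| {name} | {res['best_lag']:+d} | {res['best_rho']:.3f} "
            f"| {p_lag:.4g} | {res['p_selected']:.4g} |"
        )
    lines += ["", "## Demographic seasonality", ""]
    for etype, d in report["demography"].items():
        ratio = d["max_min_ratio"]
        ratio_s = f"{ratio:.2f}" if ratio is not None else "undefined"
        lines.append(
            f"- {etype}s: {d['total_events']} events over {d['years_covered']} "
            f"years; peak {d['max_month']}, trough {d['min_month']}, "
            f"max/min ratio {ratio_s}"
        )
        if "peak_conception_month" in d:
            lines.append(
                f"  (peak conception month: {d['peak_conception_month']})"
            )
    lines += ["", "## Contrasts", ""]
    for name, c in report["contrasts"].items():
        if "error" in c:
            lines.append(f"- {name}: unavailable ({c['error']})")
        elif "ci_low" in c:
            lines.append(
                f"- {name}: {c['percent']:+.1f}% "
                f"[{c['ci_low']:+.1f}, {c['ci_high']:+.1f}] "
                f"({c['level_a']} vs {c['level_b']})"
            )
        else:
            lines.append(
                f"- {name}: {c['percent']:+.1f}% "
                f"({c['month_a']} vs {c['month_b']})"
            )
    return "\n".join(lines) + "\n"
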