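"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from eleseason import SynthConfig


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; no shared code with the package)


def brute_midranks(x):
    """Midranks computed by explicit tie-group enumeration."""
    x = np.asarray(x, dtype=float)
    ranks = np.empty(len(x))
    order = np.argsort(x, kind="stable")
    sorted_x = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        # positions i..j share value -> average of ranks i+1..j+1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_spearman(x, y):
    """Rank-then-Pearson with the naive midranks above."""
    rx = brute_midranks(x)
    ry = brute_midranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def brute_lagged_rho(a, b, lag, alignment):
    """Explicit pair-list construction for one lag, then brute Spearman."""
    pairs = []
    for m in range(12):
        j = m + lag
        if alignment == "circular":
            j = j % 12
        elif j < 0 or j > 11:
            continue
        if not (np.isnan(a[m]) or np.isnan(b[j])):
            pairs.append((a[m], b[j]))
    if len(pairs) < 3:
        return None
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        return None
    return brute_spearman(xs, ys)


def make_panel(values_by_id: dict, variable: str = "gcm", **covariates) -> pd.DataFrame:
    """Tiny tidy panel from {id: {month: value}}."""
    rows = []
    for eid, by_month in values_by_id.items():
        for month, value in by_month.items():
            row = {
                "id": eid, "sex": "female", "age_years": 30.0,
                "age_group": "17-44", "camp": "Pyinmana",
                "month": month, "variable": variable, "value": value,
            }
            row.update(covariates)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def small_config() -> SynthConfig:
    """Down-scaled generator configuration for fast unit tests."""
    return SynthConfig(n_individuals=10, n_weight_extra=5, years_demography=5, seed=42)


@pytest.fixture
def noise_free_config() -> SynthConfig:
    """All random components switched off: panel is an exact cosine."""
    return SynthConfig(
        n_individuals=6,
        n_weight_extra=0,
        sigma_individual_gcm=0.0,
        sigma_individual_weight=0.0,
        sigma_noise_gcm=0.0,
        sigma_noise_weight=0.0,
        ar1_phi=0.0,
        seed=7,
    )
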