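"""Calendar-month series: the 12-slot container every analysis stage consumes.

A :class:`MonthlySeries` holds one value per calendar month (January = 1 …
December = 12).  Missing months are ``NaN`` and carry ``n_contributing = 0``.
All cross-correlation and standardization code operates on this container,
so climate, physiology and demographic series share one representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError

MONTHS = np.arange(1, 13)
MONTH_NAMES = [
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
]


@dataclass
class MonthlySeries:
    """One value per calendar month, with the contributing sample size.

    Parameters
    ----------
    label:
        Human-readable name of the quantity (e.g. ``"gcm pooled mean"``).
    units:
        Measurement units (``"ng/g"``, ``"kg"``, ``"mm"``, ``"events/year"``,
        ``"z"`` ...).
    values:
        Array of 12 floats indexed by calendar month − 1; ``NaN`` marks a
        month with no data.
    n_contributing:
        Number of raw observations behind each monthly value.  Must be 0
        wherever the value is missing.
    """

    label: str
    units: str
    values: np.ndarray
    n_contributing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (12,):
            raise SchemaError(
                f"MonthlySeries needs exactly 12 slots, got shape {self.values.shape}"
            )
        if self.n_contributing is None:
            self.n_contributing = np.where(np.isnan(self.values), 0, 1)
        self.n_contributing = np.asarray(self.n_contributing, dtype=int)
        if self.n_contributing.shape != (12,):
            raise SchemaError("n_contributing must have 12 slots")
        if np.any((self.n_contributing == 0) & ~np.isnan(self.values)):
            raise SchemaError("non-missing value with n_contributing = 0")

    # -- accessors ---------------------------------------------------------

    @property
    def present(self) -> np.ndarray:
        """Boolean mask of months with data."""
        return ~np.isnan(self.values)

    @property
    def n_present(self) -> int:
        return int(self.present.sum())

    def value(self, month: int) -> float:
        """Value at calendar ``month`` (1–12); NaN if missing."""
        if not 1 <= month <= 12:
            raise SchemaError(f"month must be in 1..12, got {month}")
        return float(self.values[month - 1])

    def argmax_month(self) -> int:
        """Calendar month of the maximum (ignoring missing slots)."""
        return int(np.nanargmax(self.values)) + 1

    def argmin_month(self) -> int:
        return int(np.nanargmin(self.values)) + 1

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"month": MONTHS, "value": self.values, "n": self.n_contributing}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, label: str = "", units: str = ""
    ) -> "MonthlySeries":
        required = {"month", "value"}
        if not required <= set(frame.columns):
            raise SchemaError(f"series table needs columns {sorted(required)}")
        values = np.full(12, np.nan)
        counts = np.zeros(12, dtype=int)
        months = frame["month"].to_numpy(dtype=int)
        if np.any((months < 1) | (months > 12)):
            raise SchemaError("month column outside 1..12")
        values[months - 1] = frame["value"].to_numpy(dtype=float)
        if "n" in frame.columns:
            counts[months - 1] = frame["n"].to_numpy(dtype=int)
        else:
            counts[months - 1] = (~np.isnan(values[months - 1])).astype(int)
        counts[np.isnan(values)] = 0
        return cls(label=label, units=units, values=values, n_contributing=counts)

    @classmethod
    def read_csv(cls, path: str | Path, label: str = "", units: str = "") -> "MonthlySeries":
        return cls.from_frame(pd.read_csv(path), label=label or Path(path).stem, units=units)


def shift_month(month: int, k: int) -> int:
    """Calendar month ``k`` months after ``month``, wrapping the year."""
    return (month - 1 + k) % 12 + 1


def conception_month(birth_month: int, gestation_months: int = 22) -> int:
    """Calendar month of conception for a birth in ``birth_month``.

    Asian elephant gestation lasts about 22 months, so a birth observed in
    month *m* reflects a conception in calendar month *m* − 22 (mod 12).
    """
    return shift_month(birth_month, -gestation_months)
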