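"""UK financial years (1 April to 31 March), the study's unit of time."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True, order=True)
class FinancialYear:
    """One financial year, e.g. label ``2010-2011`` running 2010-04-01..2011-03-31."""

    start: pd.Timestamp
    end: pd.Timestamp
    label: str

    @classmethod
    def from_start_year(cls, year: int) -> "FinancialYear":
        start = pd.Timestamp(year=year, month=4, day=1)
        end = pd.Timestamp(year=year + 1, month=3, day=31)
        return cls(start=start, end=end, label=f"{year}-{year + 1}")

    def contains(self, dates: pd.Series) -> pd.Series:
        return (dates >= self.start) & (dates <= self.end)


def fy_start_year(dates) -> np.ndarray:
    """Financial-year start year of each date (April..March convention)."""
    dates = pd.DatetimeIndex(np.asarray(dates, dtype="datetime64[ns]"))
    return np.where(dates.month >= 4, dates.year, dates.year - 1)


def financial_years(study_start, study_end) -> list[FinancialYear]:
    """Contiguous, non-overlapping financial years covering the study window."""
    start = pd.Timestamp(study_start)
    end = pd.Timestamp(study_end)
    if start >= end:
        raise ValueError("study_start must precede study_end")
    first = int(fy_start_year([start])[0])
    last = int(fy_start_year([end])[0])
    return [FinancialYear.from_start_year(y) for y in range(first, last + 1)]
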