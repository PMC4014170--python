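"""Calculation/measurement agreement as min-max dose-ratio ranges.

Accuracy of a predicted dose distribution is summarised by the per-site
ratio 100 * calculated / measured (%) over the interior dosimeters, and
reported as its (min, max) range; the single-number figure of merit is the
largest deviation of that range from 100%.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regression import MeasurementSet, _round_half_away

__all__ = ["AgreementSummary", "agreement_range", "max_deviation", "ratio_table"]


def _doses(x) -> tuple[list, np.ndarray]:
    if isinstance(x, MeasurementSet):
        return x.site_ids, x.dose
    arr = np.asarray(x, dtype=float)
    return list(range(arr.size)), arr


def ratio_table(predicted, measured) -> pd.Series:
    """Per-site ratio 100 * calculated/measured (%), aligned by site order."""
    ids_p, cal = _doses(predicted)
    ids_m, meas = _doses(measured)
    if isinstance(predicted, MeasurementSet) and isinstance(measured, MeasurementSet):
        if set(ids_p) != set(ids_m):
            raise ValueError("site sets differ")
        meas_s = pd.Series(meas, index=ids_m).loc[ids_p]
        meas = meas_s.to_numpy()
        ids_m = ids_p
    elif cal.shape != meas.shape:
        raise ValueError("shape mismatch")
    if cal.size == 0:
        raise ValueError("empty site set")
    if np.any(meas <= 0):
        raise ValueError("measured doses must be positive")
    return pd.Series(100.0 * cal / meas, index=ids_p, name="ratio_pct")


def agreement_range(predicted, measured) -> tuple[int, int]:
    """(min %, max %) of the per-site calculation/measurement ratio."""
    r = ratio_table(predicted, measured)
    return _round_half_away(float(r.min())), _round_half_away(float(r.max()))


def max_deviation(range_pct) -> int:
    """Largest deviation of an agreement range from 100%."""
    lo, hi = range_pct
    if lo > hi:
        raise ValueError("invalid range: min > max")
    return max(abs(lo - 100), abs(hi - 100))


@dataclass(frozen=True)
class AgreementSummary:
    """With/without-regression agreement for one scenario."""

    scenario_id: str
    range_without: tuple[int, int]
    range_with: tuple[int, int]
    ratios_without: pd.Series
    ratios_with: pd.Series

    @property
    def max_deviation_without(self) -> int:
        return max_deviation(self.range_without)

    @property
    def max_deviation_with(self) -> int:
        return max_deviation(self.range_with)

    @property
    def improved(self) -> bool:
        return self.max_deviation_with < self.max_deviation_without

    def as_row(self) -> dict:
        return {
            "scenario": self.scenario_id,
            "without_min_pct": self.range_without[0],
            "without_max_pct": self.range_without[1],
            "with_min_pct": self.range_with[0],
            "with_max_pct": self.range_with[1],
            "max_dev_without_pct": self.max_deviation_without,
            "max_dev_with_pct": self.max_deviation_with,
        }


def summarize_agreement(scenario_id: str,
                        predicted_without: MeasurementSet,
                        predicted_with: MeasurementSet,
                        measured: MeasurementSet) -> AgreementSummary:
    rw = ratio_table(predicted_without, measured)
    rr = ratio_table(predicted_with, measured)
    return AgreementSummary(
        scenario_id=scenario_id,
        range_without=(_round_half_away(float(rw.min())), _round_half_away(float(rw.max()))),
        range_with=(_round_half_away(float(rr.min())), _round_half_away(float(rr.max()))),
        ratios_without=rw,
        ratios_with=rr,
    )
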