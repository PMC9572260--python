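"""Bench/field trial error statistics: device vs. manual impurity rates.

For one batch (bench) or trip (field) the device records a series of
impurity-rate detections P_Sz,i and manual sampling yields P_Mz,i.  The
agreement statistics are

    R_az  = |mean(P_Sz) - mean(P_Mz)|              absolute error, pp
    R_rz  = R_az / mean(P_Mz) * 100                relative error, %
    R_Scv = std(P_Sz) / mean(P_Sz) * 100           device CV, %
    R_Mcv = std(P_Mz) / mean(P_Mz) * 100           manual CV, %

with the sample standard deviation (divisor N-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrialSeries",
    "TrialSummary",
    "absolute_error",
    "relative_error",
    "coefficient_of_variation",
    "summarize_trial",
    "trial_report",
]


@dataclass(frozen=True)
class TrialSeries:
    """Paired measurement series for one batch/trip (values in percent)."""

    device: tuple[float, ...]
    manual: tuple[float, ...]
    label: str = ""

    def __post_init__(self):
        if not self.device or not self.manual:
            raise ValueError("both measurement series must be non-empty")
        for name, series in (("device", self.device), ("manual", self.manual)):
            if any(not 0 <= v <= 100 for v in series):
                raise ValueError(f"{name} rates must lie in [0, 100] percent")


@dataclass(frozen=True)
class TrialSummary:
    label: str
    mean_device: float
    mean_manual: float
    r_scv: float
    r_mcv: float
    r_az: float
    r_rz: float


def absolute_error(mean_device: float, mean_manual: float) -> float:
    """|mean_device - mean_manual| in percentage points."""
    if not (np.isfinite(mean_device) and np.isfinite(mean_manual)):
        raise ValueError("means must be finite")
    return abs(mean_device - mean_manual)


def relative_error(mean_device: float, mean_manual: float) -> float:
    """Absolute error relative to the manual mean, in percent."""
    if mean_manual <= 0:
        raise ValueError("manual mean must be positive")
    return abs(mean_device - mean_manual) / mean_manual * 100.0


def coefficient_of_variation(series) -> float:
    """Sample standard deviation over mean, in percent (N >= 2)."""
    x = np.asarray(list(series), dtype=float)
    if x.size < 2:
        raise ValueError("coefficient of variation needs at least 2 values")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("series mean must be positive")
    return float(x.std(ddof=1) / mean * 100.0)


def summarize_trial(series: TrialSeries) -> TrialSummary:
    mean_device = float(np.mean(series.device))
    mean_manual = float(np.mean(series.manual))
    return TrialSummary(
        label=series.label,
        mean_device=mean_device,
        mean_manual=mean_manual,
        r_scv=coefficient_of_variation(series.device),
        r_mcv=coefficient_of_variation(series.manual),
        r_az=absolute_error(mean_device, mean_manual),
        r_rz=relative_error(mean_device, mean_manual),
    )


def trial_report(summaries) -> pd.DataFrame:
    """Table with one row per batch/trip, mirroring the device trial report."""
    return pd.DataFrame(
        [
            {
                "label": s.label,
                "P_Sz_mean": s.mean_device,
                "P_Mz_mean": s.mean_manual,
                "R_Scv": s.r_scv,
                "R_Mcv": s.r_mcv,
                "R_az": s.r_az,
                "R_rz": s.r_rz,
            }
            for s in summaries
        ]
    )
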