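"""Pixel-count to impurity-rate quantification.

The impurity rate of a harvested sample is a *mass* percentage, but the
camera sees *pixels*.  The bridge is the calibration constant delta: the
ratio of the average mass of grain to the average mass of impurity carried
by 1000 pixels.  With T_w grain pixels and T_z impurity pixels in a
segmented image,

    P_z  = T_z / (T_z + delta * T_w) * 100        (pixel-based rate, %)
    P_cz = w_z / w * 100                          (manual mass-based rate, %)

When delta equals the true per-1000-pixel mass ratio and the masks are
exact, the two definitions coincide.  The laboratory-calibrated default is
``DEFAULT_DELTA`` = 11.8906; recalibrate with :func:`calibrate_delta` for a
different crop, lighting geometry or camera distance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import UNDEFINED

__all__ = [
    "DEFAULT_DELTA",
    "PixelCounts",
    "CalibrationSample",
    "CalibrationResult",
    "DetectionRecord",
    "manual_rate",
    "pixel_rate",
    "calibrate_delta",
    "detect",
    "append_detection",
]

#: grain/impurity mass ratio per 1000 pixels, laboratory-calibrated default
DEFAULT_DELTA = 11.8906


@dataclass(frozen=True)
class PixelCounts:
    """Grain (t_w) and impurity (t_z) pixel tallies of one predicted mask."""

    t_w: int
    t_z: int

    def __post_init__(self):
        if self.t_w < 0 or self.t_z < 0:
            raise ValueError("pixel counts must be non-negative")

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "PixelCounts":
        mask = np.asarray(mask)
        return cls(
            t_w=int(np.count_nonzero(mask == 1)),
            t_z=int(np.count_nonzero(mask == 2)),
        )


@dataclass(frozen=True)
class CalibrationSample:
    """One weighed sample: pixel counts plus total and impurity mass (g)."""

    counts: PixelCounts
    w: float
    w_z: float

    def __post_init__(self):
        if not 0 <= self.w_z <= self.w:
            raise ValueError("need 0 <= w_z <= w")


@dataclass(frozen=True)
class CalibrationResult:
    delta: float
    n_samples: int
    dispersion: float  # CV of the per-sample delta ratios
    method: str = "ratio-of-means"

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be positive")

    def to_json(self, path, note: str = ""):
        Path(path).write_text(
            json.dumps(
                {
                    "delta": self.delta,
                    "n_samples": self.n_samples,
                    "dispersion": self.dispersion,
                    "method": self.method,
                    "note": note,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path) -> "CalibrationResult":
        doc = json.loads(Path(path).read_text())
        return cls(
            delta=doc["delta"],
            n_samples=doc["n_samples"],
            dispersion=doc["dispersion"],
            method=doc.get("method", "ratio-of-means"),
        )


@dataclass(frozen=True)
class DetectionRecord:
    image_id: str
    counts: PixelCounts
    delta: float
    p_z: float  # percent; NaN when undefined (no grain or impurity visible)
    timestamp: str


def manual_rate(w_z: float, w: float) -> float:
    """Mass-based impurity rate in percent: w_z / w * 100."""
    if w <= 0:
        raise ValueError("sample mass w must be positive")
    if not 0 <= w_z <= w:
        raise ValueError("impurity mass must satisfy 0 <= w_z <= w")
    return w_z / w * 100.0


def pixel_rate(counts: PixelCounts, delta: float = DEFAULT_DELTA) -> float:
    """Pixel-based impurity rate in percent: T_z / (T_z + delta*T_w) * 100.

    Returns the undefined marker (NaN) when the image shows neither grain
    nor impurity pixels.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if counts.t_w == 0 and counts.t_z == 0:
        return UNDEFINED
    return counts.t_z / (counts.t_z + delta * counts.t_w) * 100.0


def calibrate_delta(samples, method: str = "ratio-of-means") -> CalibrationResult:
    """Estimate delta from weighed, pixel-counted samples.

    Per sample, grain mass per 1000 px is ``1000*(w - w_z)/t_w`` and
    impurity mass per 1000 px is ``1000*w_z/t_z``.  The default estimator
    divides the *means* of those two quantities (robust when individual
    samples carry few impurity pixels); ``method="mean-of-ratios"``
    averages the per-sample ratios instead.  The dispersion reported is
    the coefficient of variation of the per-sample ratios.
    """
    samples = list(samples)
    grain_kpx = [
        1000.0 * (s.w - s.w_z) / s.counts.t_w
        for s in samples
        if s.counts.t_w > 0 and s.w - s.w_z > 0
    ]
    imp_kpx = [
        1000.0 * s.w_z / s.counts.t_z
        for s in samples
        if s.counts.t_z > 0 and s.w_z > 0
    ]
    if not grain_kpx or not imp_kpx:
        raise ValueError(
            "calibration needs at least one sample with grain mass and pixels "
            "and one with impurity mass and pixels"
        )
    ratios = [
        1000.0 * (s.w - s.w_z) / s.counts.t_w / (1000.0 * s.w_z / s.counts.t_z)
        for s in samples
        if s.counts.t_w > 0 and s.counts.t_z > 0 and s.w_z > 0 and s.w - s.w_z > 0
    ]
    if method == "ratio-of-means":
        delta = float(np.mean(grain_kpx) / np.mean(imp_kpx))
    elif method == "mean-of-ratios":
        if not ratios:
            raise ValueError("mean-of-ratios needs samples with both components")
        delta = float(np.mean(ratios))
    else:
        raise ValueError(f"unknown calibration method {method!r}")
    dispersion = (
        float(np.std(ratios, ddof=1) / np.mean(ratios)) if len(ratios) > 1 else 0.0
    )
    return CalibrationResult(
        delta=delta,
        n_samples=len(samples),
        dispersion=dispersion,
        method=method,
    )


def detect(image, model, delta: float = DEFAULT_DELTA, image_id: str = "",
           log_path=None) -> DetectionRecord:
    """Segment one image and convert its pixel tallies to an impurity rate."""
    from .model import predict_mask  # deferred: keeps this module lightweight

    mask = predict_mask(model, image)
    counts = PixelCounts.from_mask(mask)
    p_z = pixel_rate(counts, delta)
    record = DetectionRecord(
        image_id=image_id,
        counts=counts,
        delta=delta,
        p_z=p_z,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    if log_path is not None:
        append_detection(record, log_path)
    return record


def append_detection(record: DetectionRecord, path):
    path = Path(path)
    row = pd.DataFrame(
        [
            {
                "image_id": record.image_id,
                "t_w": record.counts.t_w,
                "t_z": record.counts.t_z,
                "delta": record.delta,
                "p_z": record.p_z,
                "timestamp": record.timestamp,
            }
        ]
    )
    row.to_csv(path, mode="a", header=not path.exists(), index=False)
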