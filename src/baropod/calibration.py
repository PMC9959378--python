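"""Force-sensing-resistor calibration: rational load→reading curve and percent mapping.

The insole's film pressure sensors respond nonlinearly to load.  A bench
experiment (known masses on a single sensor, ten repeats each) yields
load/reading pairs; the raw rig accumulates to a 0–65,535 scale which is
floor-divided by 16 down to the ADC's native 12-bit range.  A three-parameter
rational curve

    reading(load) = (a·load + b) / (load + c)

is fitted by least squares.  Its algebraic inverse

    load(reading) = (−c·reading + b) / (reading − a)

recovers grams from counts, and a linear remap against the sensor's 10 kg
full scale produces the integer percent (0–100) that travels on the wire.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "LoadReadingPair",
    "CalibrationCurve",
    "DEFAULT_CURVE",
    "FULL_SCALE_G",
    "scale_raw16",
    "predict_reading",
    "invert_reading",
    "fit_curve",
    "load_to_percent",
    "reading_to_percent",
    "percent_table",
    "read_pairs_csv",
    "save_curve",
    "load_curve",
    "table3_pairs",
]

#: Manufacturer full-scale load of one sensor, grams ("up to 10 kg").
FULL_SCALE_G = 10_000.0

#: Trigger force below which the sensor does not respond, grams.
TRIGGER_FORCE_G = 500.0

_CURVE_FORMAT_VERSION = 1


class CalibrationError(ValueError):
    """Invalid calibration input or degenerate fit."""


@dataclass(frozen=True)
class LoadReadingPair:
    """One bench measurement: applied mass and the averaged raw rig reading."""

    load_g: float
    reading_raw16: int

    def __post_init__(self) -> None:
        if not self.load_g > 0:
            raise CalibrationError(f"load_g must be positive, got {self.load_g}")
        if not 0 <= self.reading_raw16 <= 65_535:
            raise CalibrationError(
                f"reading_raw16 must be in [0, 65535], got {self.reading_raw16}"
            )


@dataclass(frozen=True)
class CalibrationCurve:
    """Parameters of the rational load→reading map.

    ``a`` is the asymptotic reading in 12-bit counts, ``b`` the numerator
    offset (counts·grams), ``c`` the denominator offset (grams).  The
    constraint ``a·c > b`` makes the curve strictly increasing for load ≥ 0.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise CalibrationError(f"c must be positive, got {self.c}")
        if not self.a > 0:
            raise CalibrationError(f"a must be positive, got {self.a}")
        if not self.a * self.c > self.b:
            raise CalibrationError(
                f"curve not strictly increasing: a*c={self.a * self.c} <= b={self.b}"
            )


#: The curve shipped in the firmware: reading = (3500·load − 5500)/(load + 300).
DEFAULT_CURVE = CalibrationCurve(a=3500.0, b=-5500.0, c=300.0)


def scale_raw16(reading_raw16: int) -> int:
    """Scale a 0–65,535 rig reading to the 12-bit 0–4095 range (floor of /16)."""
    if not 0 <= reading_raw16 <= 65_535:
        raise CalibrationError(
            f"reading_raw16 must be in [0, 65535], got {reading_raw16}"
        )
    return int(reading_raw16) // 16


def predict_reading(curve: CalibrationCurve, load_g):
    """Expected 12-bit reading (real-valued) for a load in grams.

    Strictly increasing in ``load_g`` and bounded above by ``curve.a``.
    Accepts a scalar or array.
    """
    load = np.asarray(load_g, dtype=float)
    if np.any(load < 0):
        raise CalibrationError("load_g must be non-negative")
    out = (curve.a * load + curve.b) / (load + curve.c)
    return float(out) if out.ndim == 0 else out


def invert_reading(curve: CalibrationCurve, reading):
    """Estimated load in grams for a 12-bit reading — exact inverse of the curve.

    Singular at the asymptote ``reading = a``; callers clamp first (see
    :func:`reading_to_percent`).
    """
    y = np.asarray(reading, dtype=float)
    if np.any(y >= curve.a):
        raise CalibrationError(
            f"reading must be below the asymptote a={curve.a}; clamp upstream"
        )
    out = (-curve.c * y + curve.b) / (y - curve.a)
    return float(out) if out.ndim == 0 else out


def fit_curve(
    pairs: Sequence[LoadReadingPair] | Iterable[LoadReadingPair],
    scale: bool = True,
) -> CalibrationCurve:
    """Least-squares fit of the rational curve to load/reading pairs.

    With ``scale`` set (the default), raw 16-bit rig readings are first passed
    through :func:`scale_raw16`.  Initialization is fixed at
    ``(max(y), −max(y), median(x))`` so the fit is deterministic.
    """
    pairs = list(pairs)
    x = np.array([p.load_g for p in pairs], dtype=float)
    if len(pairs) < 3 or len(np.unique(x)) < 3:
        raise CalibrationError(
            f"need at least 3 pairs with distinct loads, got {len(np.unique(x))}"
        )
    if scale:
        y = np.array([scale_raw16(p.reading_raw16) for p in pairs], dtype=float)
    else:
        y = np.array([p.reading_raw16 for p in pairs], dtype=float)

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, b, c = theta
        return (a * x + b) / (x + c) - y

    theta0 = np.array([y.max(), -y.max(), float(np.median(x))])
    sol = least_squares(residuals, theta0, method="lm", xtol=1e-14, ftol=1e-14)
    a, b, c = sol.x
    if not (c > 0 and a > 0 and a * c > b):
        raise CalibrationError(
            f"degenerate fit (a={a:.3g}, b={b:.3g}, c={c:.3g}): curve not increasing"
        )
    return CalibrationCurve(a=float(a), b=float(b), c=float(c))


def _round_half_away(x: float) -> int:
    # round-half-away-from-zero; inputs here are always >= 0
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def load_to_percent(load_g: float, full_scale_g: float = FULL_SCALE_G) -> int:
    """Linear percent of full scale, clamped to [0, 100] and rounded to integer."""
    if not full_scale_g > 0:
        raise CalibrationError(f"full_scale_g must be positive, got {full_scale_g}")
    frac = min(max(load_g / full_scale_g, 0.0), 1.0)
    return _round_half_away(100.0 * frac)


def reading_to_percent(curve: CalibrationCurve, reading: int) -> int:
    """Map a 12-bit reading to the integer 0–100% wire scale.

    Readings at or above the asymptote are clamped just below it, which lands
    on 100% — physical saturation of the sensor.  Monotone non-decreasing.
    """
    if not 0 <= reading <= 4095:
        raise CalibrationError(f"reading must be in [0, 4095], got {reading}")
    clamped = min(float(reading), curve.a - 1.0)
    load = invert_reading(curve, clamped)
    return load_to_percent(load)


def percent_table(curve: CalibrationCurve) -> np.ndarray:
    """Lookup table: percent for each of the 4096 possible readings."""
    return np.array(
        [reading_to_percent(curve, r) for r in range(4096)], dtype=np.int64
    )


# ---------------------------------------------------------------------------
# IO

def read_pairs_csv(path: str | Path) -> list[LoadReadingPair]:
    """Read calibration pairs from a CSV with header ``load_g,reading_raw16``."""
    df = pd.read_csv(path)
    missing = {"load_g", "reading_raw16"} - set(df.columns)
    if missing:
        raise CalibrationError(f"calibration CSV missing columns: {sorted(missing)}")
    return [
        LoadReadingPair(load_g=float(row.load_g), reading_raw16=int(row.reading_raw16))
        for row in df.itertuples()
    ]


def table3_pairs() -> list[LoadReadingPair]:
    """The packaged bench-experiment fixture (six averaged mass/reading rows)."""
    return read_pairs_csv(Path(__file__).parent / "data" / "table3.csv")


def save_curve(curve: CalibrationCurve, path: str | Path) -> None:
    """Serialize a curve to JSON with a format-version field."""
    payload = {
        "format_version": _CURVE_FORMAT_VERSION,
        "a": curve.a,
        "b": curve.b,
        "c": curve.c,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_curve(path: str | Path) -> CalibrationCurve:
    """Load a curve from its JSON serialization."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _CURVE_FORMAT_VERSION:
        raise CalibrationError(
            f"unsupported curve format version: {payload.get('format_version')}"
        )
    return CalibrationCurve(a=payload["a"], b=payload["b"], c=payload["c"])
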