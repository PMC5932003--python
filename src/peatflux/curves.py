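"""Radiocarbon calibration curves.

A calibration curve maps calendar age theta (cal yr BP, before 1950) to the
expected radiocarbon age mu(theta) with a 1-sigma curve error tau(theta).
Curves are read from the IntCal text dialect: comma-separated columns
``cal BP, 14C age, error``; lines starting with ``#`` are comments; further
columns (Delta14C etc.) are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CurveFormatError

__all__ = [
    "CalibrationCurve",
    "load_calibration_curve",
    "write_calibration_curve",
    "synthetic_calibration_curve",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Knots of a radiocarbon calibration curve.

    Attributes
    ----------
    cal_age : ndarray
        Calendar years BP at the knots, strictly increasing.
    c14_age : ndarray
        Radiocarbon years BP at each knot.
    curve_sigma : ndarray
        1 SD of the radiocarbon age at each knot, all > 0.
    name : str
        Free-text provenance label.
    """

    cal_age: np.ndarray
    c14_age: np.ndarray
    curve_sigma: np.ndarray
    name: str = "unnamed"

    def __post_init__(self) -> None:
        cal = np.asarray(self.cal_age, dtype=float)
        c14 = np.asarray(self.c14_age, dtype=float)
        sig = np.asarray(self.curve_sigma, dtype=float)
        if not (cal.size == c14.size == sig.size):
            raise ValueError("curve arrays must have equal length")
        if cal.size < 2:
            raise ValueError("curve needs at least 2 knots")
        if not np.all(np.diff(cal) > 0):
            raise ValueError("cal_age must be strictly increasing")
        if not np.all(sig > 0):
            raise ValueError("curve_sigma must be positive")
        object.__setattr__(self, "cal_age", cal)
        object.__setattr__(self, "c14_age", c14)
        object.__setattr__(self, "curve_sigma", sig)

    @property
    def n_knots(self) -> int:
        return int(self.cal_age.size)

    def mu(self, theta: np.ndarray) -> np.ndarray:
        """Expected 14C age at calendar age(s) ``theta`` (linear interpolation)."""
        return np.interp(theta, self.cal_age, self.c14_age)

    def tau(self, theta: np.ndarray) -> np.ndarray:
        """Curve 1-sigma at calendar age(s) ``theta`` (linear interpolation)."""
        return np.interp(theta, self.cal_age, self.curve_sigma)


def load_calibration_curve(path: str | Path) -> CalibrationCurve:
    """Parse an IntCal-dialect text file into a :class:`CalibrationCurve`.

    Rows are ``calBP, c14age, sigma`` (extra columns ignored); leading ``#``
    lines and blank lines are skipped; a header line of column names is
    tolerated.  Rows are re-sorted ascending in calendar age if needed.

    Raises
    ------
    CurveFormatError
        On missing columns, non-numeric values or fewer than 2 data rows,
        naming the offending line.
    """
    path = Path(path)
    cal, c14, sig = [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 3:
                raise CurveFormatError(
                    f"{path.name}:{lineno}: expected >= 3 comma-separated "
                    f"columns, got {len(parts)}: {line!r}"
                )
            try:
                vals = [float(parts[0]), float(parts[1]), float(parts[2])]
            except ValueError:
                # tolerate a single textual header line
                if not cal and _looks_like_header(parts):
                    continue
                raise CurveFormatError(
                    f"{path.name}:{lineno}: non-numeric value in {line!r}"
                ) from None
            cal.append(vals[0])
            c14.append(vals[1])
            sig.append(vals[2])
    if len(cal) < 2:
        raise CurveFormatError(f"{path.name}: fewer than 2 data rows")
    order = np.argsort(np.asarray(cal))
    return CalibrationCurve(
        cal_age=np.asarray(cal)[order],
        c14_age=np.asarray(c14)[order],
        curve_sigma=np.asarray(sig)[order],
        name=path.stem,
    )


def _looks_like_header(parts: list[str]) -> bool:
    joined = ",".join(parts).lower()
    return any(w in joined for w in ("cal", "age", "bp", "sigma", "error"))


def write_calibration_curve(curve: CalibrationCurve, path: str | Path) -> None:
    """Write a curve in the IntCal text dialect (``# `` comment header)."""
    with open(path, "w") as fh:
        fh.write(f"# calibration curve: {curve.name}\n")
        fh.write("# cal BP, 14C age BP, 1 SD error\n")
        for a, r, s in zip(curve.cal_age, curve.c14_age, curve.curve_sigma):
            fh.write(f"{a:.1f},{r:.1f},{s:.1f}\n")


# ---------------------------------------------------------------------------
# Synthetic stand-in curve
# ---------------------------------------------------------------------------

# Anchor points (cal BP, cal-minus-14C offset in yr) sketching the broadly
# known shape of the Holocene/late-glacial radiocarbon timescale: near-zero
# offset in the last two millennia, ~800 yr by the mid-Holocene, several
# thousand years by the late glacial.
_OFFSET_ANCHORS = np.array(
    [
        (0.0, 0.0),
        (500.0, -30.0),
        (1000.0, -60.0),
        (2000.0, -30.0),
        (3000.0, 150.0),
        (4000.0, 400.0),
        (5000.0, 650.0),
        (6000.0, 800.0),
        (7000.0, 830.0),
        (8000.0, 900.0),
        (9000.0, 950.0),
        (10000.0, 1200.0),
        (12000.0, 1900.0),
        (15000.0, 2900.0),
        (20000.0, 4500.0),
        (25000.0, 6000.0),
        (30000.0, 7000.0),
        (40000.0, 8300.0),
        (50000.0, 8800.0),
    ]
)


def synthetic_calibration_curve(
    cal_max: float = 50_000.0,
    wiggle_amplitude: float = 18.0,
    name: str = "synthetic-intcal-standin",
) -> CalibrationCurve:
    """Deterministic synthetic stand-in for a Northern Hemisphere curve.

    This is NOT a measured calibration curve.  It is a synthetic surrogate
    with the qualitative structure of the real radiocarbon timescale — a
    smoothly growing calendar-minus-radiocarbon offset, short centennial
    wiggles, and a curve error growing with age — built so that every
    calibration, age-model and simulation code path can be exercised without
    the measured dataset.  Results calibrated against it are not comparable
    with published calendar ages.

    Knot spacing mimics the measured curves: 5 yr to 13,900 cal BP, 10 yr to
    25,000, 20 yr beyond.  The curve is strictly monotone in both axes.
    """
    grids = [np.arange(0.0, min(13_900.0, cal_max) + 1e-9, 5.0)]
    if cal_max > 13_900.0:
        grids.append(np.arange(13_910.0, min(25_000.0, cal_max) + 1e-9, 10.0))
    if cal_max > 25_000.0:
        grids.append(np.arange(25_020.0, cal_max + 1e-9, 20.0))
    cal = np.concatenate(grids)

    from scipy.interpolate import PchipInterpolator

    offset = PchipInterpolator(_OFFSET_ANCHORS[:, 0], _OFFSET_ANCHORS[:, 1])(cal)
    # centennial-scale wiggles; derivative bounded well below 1 so that
    # mu(theta) = theta - offset + wiggle stays strictly increasing
    wiggle = wiggle_amplitude * np.sin(2 * np.pi * cal / 512.0) + 3.0 * np.sin(
        2 * np.pi * cal / 91.0
    )
    c14 = cal - offset + wiggle
    sigma = 4.0 + 0.0035 * cal + 40.0 * np.clip((cal - 25_000.0) / 25_000.0, 0.0, 1.0) ** 2
    return CalibrationCurve(cal_age=cal, c14_age=c14, curve_sigma=sigma, name=name)
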