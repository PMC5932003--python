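"""Calibration of single radiocarbon dates.

A measured radiocarbon age r +/- sigma is converted to a probability mass
function over calendar age theta using the likelihood

    L(theta) = exp(-(r - mu(theta))^2 / (2 (sigma^2 + tau(theta)^2)))
               / sqrt(sigma^2 + tau(theta)^2)

with mu and tau linearly interpolated from the calibration curve.  The
1/sqrt(sigma^2 + tau^2) factor follows the convention of the standard
calibration programs.  The density is evaluated on a uniform calendar grid,
truncated to the smallest window leaving < 1e-6 of the mass outside, and
normalised to sum exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import CalibrationCurve
from .errors import CalibrationRangeError

__all__ = ["RadiocarbonDate", "CalibratedDistribution", "calibrate", "hpd_ranges"]

_TAIL_MASS = 1e-6


@dataclass(frozen=True)
class RadiocarbonDate:
    """One dated level: depth (cm below surface) and a 14C measurement."""

    depth: float
    lab_id: str
    c14_age: float
    c14_error: float
    material: str = ""
    is_bulk: bool = False

    def __post_init__(self) -> None:
        if self.c14_error <= 0:
            raise ValueError(f"{self.lab_id}: c14_error must be > 0")
        if self.depth < 0:
            raise ValueError(f"{self.lab_id}: depth must be >= 0")


@dataclass(frozen=True)
class CalibratedDistribution:
    """Probability mass over calendar age for one date, on a uniform grid."""

    cal_age_grid: np.ndarray
    prob: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.cal_age_grid, dtype=float)
        prob = np.asarray(self.prob, dtype=float)
        if grid.size != prob.size or grid.size < 1:
            raise ValueError("grid and prob must be equal-length, non-empty")
        if grid.size > 1:
            steps = np.diff(grid)
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
                raise ValueError("grid step must be uniform")
        if np.any(prob < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(prob.sum() - 1.0) > 1e-9:
            raise ValueError("probability mass must sum to 1 within 1e-9")
        object.__setattr__(self, "cal_age_grid", grid)
        object.__setattr__(self, "prob", prob)

    @property
    def grid_step(self) -> float:
        g = self.cal_age_grid
        return float(g[1] - g[0]) if g.size > 1 else 1.0

    def mean(self) -> float:
        return float(np.sum(self.cal_age_grid * self.prob))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw calendar ages; each grid point is drawn with its mass (no
        within-bin jitter — immaterial at 1-yr grids)."""
        idx = rng.choice(self.cal_age_grid.size, size=n, p=self.prob)
        return self.cal_age_grid[idx]


def calibrate(
    date: RadiocarbonDate,
    curve: CalibrationCurve,
    grid_step: float = 1.0,
) -> CalibratedDistribution:
    """Calibrate one date against a curve.

    Raises
    ------
    CalibrationRangeError
        If the measured age lies outside
        [min(c14_age) - 10 sigma, max(c14_age) + 10 sigma] of the curve.
    """
    r, sig = date.c14_age, date.c14_error
    lo = curve.c14_age.min() - 10.0 * sig
    hi = curve.c14_age.max() + 10.0 * sig
    if not (lo <= r <= hi):
        raise CalibrationRangeError(
            f"{date.lab_id}: 14C age {r} outside curve support [{lo:.0f}, {hi:.0f}]"
        )

    theta = np.arange(curve.cal_age[0], curve.cal_age[-1] + grid_step / 2, grid_step)
    mu = curve.mu(theta)
    tau = curve.tau(theta)
    var = sig**2 + tau**2
    logl = -((r - mu) ** 2) / (2.0 * var) - 0.5 * np.log(var)
    dens = np.exp(logl - logl.max())
    total = dens.sum()
    if total <= 0:
        raise CalibrationRangeError(f"{date.lab_id}: zero likelihood everywhere")
    prob = dens / total

    # truncate: smallest contiguous window with outside mass < _TAIL_MASS
    cum = np.cumsum(prob)
    left = int(np.searchsorted(cum, _TAIL_MASS / 2.0))
    right = int(np.searchsorted(cum, 1.0 - _TAIL_MASS / 2.0)) + 1
    left = max(left, 0)
    right = min(right, prob.size)
    prob = prob[left:right]
    theta = theta[left:right]
    prob = prob / prob.sum()
    return CalibratedDistribution(cal_age_grid=theta, prob=prob)


def hpd_ranges(
    dist: CalibratedDistribution, level: float = 0.95
) -> tuple[list[tuple[float, float]], tuple[float, float]]:
    """Highest-posterior-density intervals at the given level.

    Grid points are ranked by probability (ties broken by older age first)
    and accumulated until the target mass is reached; contiguous runs are
    merged into ``[younger, older]`` intervals.  Returns ``(intervals,
    envelope)`` where envelope is ``(min over intervals, max over
    intervals)`` — the single printed-range convention.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    prob = dist.prob
    grid = dist.cal_age_grid
    # sort by descending probability; among ties, older (larger age) first
    order = np.lexsort((-grid, -prob))
    cum = np.cumsum(prob[order])
    n_keep = int(np.searchsorted(cum, level)) + 1
    keep = np.sort(order[:n_keep])

    intervals: list[tuple[float, float]] = []
    start = keep[0]
    prev = keep[0]
    for idx in keep[1:]:
        if idx == prev + 1:
            prev = idx
            continue
        intervals.append((float(grid[start]), float(grid[prev])))
        start = prev = idx
    intervals.append((float(grid[start]), float(grid[prev])))
    envelope = (intervals[0][0], intervals[-1][1])
    return intervals, envelope
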