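"""Smooth-spline age-depth modelling with Monte-Carlo uncertainty.

The model follows the classical-calibration approach: per iteration one
calendar age is drawn from each date's calibrated distribution
(probability-weighted), a cubic smoothing spline of age on depth is fitted,
and the iteration is kept only if the fitted ages are non-decreasing with
depth (stratigraphic order).  The point estimate is the per-depth mean of
accepted iterations and the 95% envelope the per-depth 2.5/97.5 percentiles.

Ages are calendar years BP (before 1950), increasing downward.  The
``smoothing`` parameter is a unitless 0-1 knob mapped to the roughness
penalty lambda = 256**(3*smoothing - 1) on depth standardised to [0, 1]
(the same functional form the classical spline smoothers use), so 0.3 is a
light smoothing and values near 1 approach a straight line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import cho_factor, cho_solve

from .calibrate import CalibratedDistribution, RadiocarbonDate, calibrate, hpd_ranges
from .curves import CalibrationCurve
from .errors import ReversalError
from ._rng import substream

__all__ = [
    "AgeModelEnsemble",
    "fit_age_depth",
    "sedimentation_rates",
    "flag_outliers",
]

_MIN_ACCEPT_FRACTION = 0.01


@dataclass(frozen=True)
class AgeModelEnsemble:
    """Accepted Monte-Carlo spline iterations evaluated on a depth grid."""

    depth_grid: np.ndarray          # cm
    iterations: np.ndarray          # (n_accepted, n_depths) ages, cal yr BP
    point_estimate: np.ndarray      # per-depth mean age
    envelope_low: np.ndarray        # per-depth 2.5 percentile
    envelope_high: np.ndarray       # per-depth 97.5 percentile
    smoothing_parameter: float
    n_accepted: int
    n_proposed: int
    seed: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.point_estimate) < -1e-6):
            raise ValueError("point_estimate must be non-decreasing with depth")
        if np.any(self.envelope_low > self.point_estimate + 1e-9) or np.any(
            self.point_estimate > self.envelope_high + 1e-9
        ):
            raise ValueError("envelope must bracket the point estimate")

    def age_at(self, depth: np.ndarray) -> np.ndarray:
        """Point-estimate age interpolated at arbitrary depths (cm)."""
        return np.interp(depth, self.depth_grid, self.point_estimate)

    def envelope_at(self, depth: float) -> tuple[float, float]:
        lo = float(np.interp(depth, self.depth_grid, self.envelope_low))
        hi = float(np.interp(depth, self.depth_grid, self.envelope_high))
        return lo, hi


class _SmoothSpline:
    """Natural cubic smoothing spline (Reinsch form), reusable across draws.

    Minimises ||y - g||^2 + lambda g' K g with the classical second-
    difference penalty K = Q R^-1 Q'.  The 0-1 ``spar`` knob maps to
    lambda = r * 256**(3*spar - 1) with r = n / tr(K), the same functional
    form the reference spline smoothers use, so spar ~0.3 is light
    smoothing and spar -> 1 approaches a straight line.  The fitted curve
    is the natural cubic interpolant of the shrunk values, which is exact
    for this penalty.  Works from n = 4 knots up.
    """

    def __init__(self, x: np.ndarray, spar: float):
        x = np.asarray(x, dtype=float)
        n = x.size
        h = np.diff(x)
        Q = np.zeros((n, n - 2))
        R = np.zeros((n - 2, n - 2))
        for j in range(n - 2):
            i = j + 1
            Q[i - 1, j] = 1.0 / h[i - 1]
            Q[i, j] = -(1.0 / h[i - 1] + 1.0 / h[i])
            Q[i + 1, j] = 1.0 / h[i]
            R[j, j] = (h[i - 1] + h[i]) / 3.0
            if j + 1 < n - 2:
                R[j, j + 1] = R[j + 1, j] = h[i] / 6.0
        K = Q @ np.linalg.solve(R, Q.T)
        lam = float(256.0 ** (3.0 * spar - 1.0)) * n / np.trace(K)
        self.x = x
        self._cho = cho_factor(np.eye(n) + lam * K)

    def __call__(self, y: np.ndarray, x_eval: np.ndarray) -> np.ndarray:
        fitted = cho_solve(self._cho, np.asarray(y, dtype=float))
        return CubicSpline(self.x, fitted, bc_type="natural")(x_eval)


def fit_age_depth(
    dates: list[RadiocarbonDate],
    curve: CalibrationCurve,
    smoothing_parameter: float = 0.3,
    n_iterations: int = 1000,
    grid_step_cm: float = 1.0,
    seed: int = 0,
    depth_grid: np.ndarray | None = None,
    enforce_monotonic: bool = True,
    calibrated: dict[str, CalibratedDistribution] | None = None,
) -> AgeModelEnsemble:
    """Fit the Monte-Carlo smooth-spline age-depth model.

    Parameters beyond the spec surface: ``depth_grid`` overrides the default
    evaluation grid (min to max date depth at ``grid_step_cm``);
    ``enforce_monotonic=False`` keeps every iteration (used internally by
    the outlier screen, where reversing date sets must still yield a model);
    ``calibrated`` lets callers reuse already-calibrated distributions.

    Raises
    ------
    ValueError
        Fewer than 4 dates or duplicated depths.
    ReversalError
        If fewer than 1% of proposed iterations respect stratigraphic order.
    """
    if len(dates) < 4:
        raise ValueError("age-depth model needs at least 4 dates")
    depths = np.array([d.depth for d in dates], dtype=float)
    order = np.argsort(depths, kind="stable")
    dates = [dates[i] for i in order]
    depths = depths[order]
    if np.any(np.diff(depths) <= 0):
        raise ValueError("dates must be at distinct depths")

    if calibrated is None:
        calibrated = {}
    dists = [
        calibrated.get(d.lab_id) or calibrate(d, curve) for d in dates
    ]

    if depth_grid is None:
        depth_grid = np.arange(depths[0], depths[-1] + grid_step_cm / 2, grid_step_cm)
    depth_grid = np.asarray(depth_grid, dtype=float)

    rng = substream(seed, "agemodel")
    ages = np.column_stack([dist.sample(n_iterations, rng) for dist in dists])

    spline = _SmoothSpline(depths, smoothing_parameter)

    accepted = []
    for it in range(n_iterations):
        fitted = spline(ages[it], depth_grid)
        if enforce_monotonic and np.any(np.diff(fitted) < -1e-9):
            continue
        accepted.append(fitted)

    frac = len(accepted) / n_iterations
    if enforce_monotonic and frac < _MIN_ACCEPT_FRACTION:
        raise ReversalError(
            f"only {len(accepted)}/{n_iterations} iterations respect "
            "stratigraphic order; check the date set for reversals/outliers"
        )
    iterations = np.asarray(accepted)
    point = iterations.mean(axis=0)
    if enforce_monotonic:
        lo, hi = np.percentile(iterations, [2.5, 97.5], axis=0)
    else:
        # without the order constraint the mean curve may wiggle backwards;
        # report it monotonised so downstream consumers keep their invariants
        point = np.maximum.accumulate(point)
        lo, hi = np.percentile(iterations, [2.5, 97.5], axis=0)
        lo = np.minimum(lo, point)
        hi = np.maximum(hi, point)
    return AgeModelEnsemble(
        depth_grid=depth_grid,
        iterations=iterations,
        point_estimate=point,
        envelope_low=lo,
        envelope_high=hi,
        smoothing_parameter=smoothing_parameter,
        n_accepted=iterations.shape[0],
        n_proposed=n_iterations,
        seed=seed,
    )


def sedimentation_rates(
    model: AgeModelEnsemble, max_rate: float = 10.0
) -> dict[str, np.ndarray]:
    """Per-interval sedimentation rate (cm/yr) with a 95% envelope.

    For each accepted iteration the rate over grid interval i is
    thickness / (age at bottom - age at top).  Zero (or numerically tiny)
    age increments are capped at ``max_rate`` with a warning.  Returns a dict
    with ``depth_mid``, ``mean``, ``low``, ``high`` (2.5/97.5 percentiles).
    """
    if model.depth_grid.size < 2:
        raise ValueError("model needs at least 2 depth-grid points")
    dz = np.diff(model.depth_grid)
    dt = np.diff(model.iterations, axis=1)
    with np.errstate(divide="ignore", over="ignore"):
        rates = dz / dt
    capped = ~np.isfinite(rates) | (rates > max_rate) | (dt <= 0)
    if np.any(capped):
        warnings.warn(
            f"{int(capped.sum())} rate draws capped at {max_rate} cm/yr "
            "(zero age increment)",
            stacklevel=2,
        )
        rates = np.where(capped, max_rate, rates)
    lo, hi = np.percentile(rates, [2.5, 97.5], axis=0)
    # rate from the point-estimate chronology: preferred deterministic value
    # downstream (mean of 1/dt across iterations is biased high by Jensen)
    dt_pt = np.diff(model.point_estimate)
    with np.errstate(divide="ignore"):
        point = np.where(dt_pt > dz / max_rate, dz / np.maximum(dt_pt, 1e-300), max_rate)
    return {
        "depth_mid": 0.5 * (model.depth_grid[:-1] + model.depth_grid[1:]),
        "point": point,
        "mean": rates.mean(axis=0),
        "low": lo,
        "high": hi,
    }


def flag_outliers(
    dates: list[RadiocarbonDate],
    curve: CalibrationCurve,
    level: float = 0.95,
    seed: int = 0,
    **fit_kwargs,
) -> list[str]:
    """Iteratively flag dates whose calibrated range never meets the model.

    An outlier is a date that is stratigraphically inconsistent: its
    calibrated envelope at the given level lies *entirely older* than the
    envelope of some deeper date (a reversal).  The screen iterates over
    the most severe reversing pair (largest age gap between the shallower
    date's younger bound and the deeper date's older bound) and flags one
    member of the pair:

    * if exactly one member is a bulk-peat date, the bulk date is flagged —
      bulk fen peat carries dissolved/reworked old carbon and is the
      standard suspect when it conflicts with macrofossil dates;
    * otherwise the member whose removal leaves the smaller total misfit
      (summed envelope gaps against a spline model refitted without it)
      is flagged.  Scoring removals rather than own-gaps is masking-proof:
      a reversing pair pulls the model between its members, so the largest
      single gap often sits on an innocent neighbour.

    Dates that merely sit away from the model without reversing the
    stratigraphy are not flagged.  The tie-break model is fitted without
    the stratigraphic-order rejection (reversing date sets must still
    yield a model).  Returns flagged lab_ids in flagging order.
    """
    remaining = sorted(dates, key=lambda d: d.depth)
    dists = {d.lab_id: calibrate(d, curve) for d in dates}
    envelopes = {
        lab: hpd_ranges(dist, level)[1] for lab, dist in dists.items()
    }

    def fit_gap_total(subset):
        if len(subset) < 4:
            return 0.0
        model = fit_age_depth(
            subset,
            curve,
            seed=seed,
            enforce_monotonic=False,
            calibrated=dists,
            **fit_kwargs,
        )
        total = 0.0
        for d in subset:
            a, b = envelopes[d.lab_id]
            lo, hi = model.envelope_at(d.depth)
            total += max(0.0, a - hi, lo - b)
        return total

    flagged: list[str] = []
    while len(remaining) > 4:
        worst_pair, worst_gap = None, 0.0
        for i, upper in enumerate(remaining):
            a_up, _ = envelopes[upper.lab_id]
            for lower in remaining[i + 1 :]:
                _, b_low = envelopes[lower.lab_id]
                gap = a_up - b_low  # >0: shallower date entirely older
                if gap > worst_gap:
                    worst_pair, worst_gap = (upper, lower), gap
        if worst_pair is None:
            break
        upper, lower = worst_pair
        if upper.is_bulk != lower.is_bulk:
            victim = upper if upper.is_bulk else lower
        else:
            without_upper = [d for d in remaining if d.lab_id != upper.lab_id]
            without_lower = [d for d in remaining if d.lab_id != lower.lab_id]
            victim = (
                upper
                if fit_gap_total(without_upper) <= fit_gap_total(without_lower)
                else lower
            )
        flagged.append(victim.lab_id)
        remaining = [d for d in remaining if d.lab_id != victim.lab_id]
    return flagged
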