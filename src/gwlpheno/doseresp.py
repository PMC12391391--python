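"""Four-parameter log-logistic (4PL) dose-response fitting.

The curve follows the LL.4 convention

    f(x) = lower + (upper - lower) / (1 + exp(slope * (ln x - ln midpoint)))

so that with a positive slope the response decreases from ``upper`` at dose 0
towards ``lower`` at saturating dose, and ``f(midpoint) = (lower + upper)/2``.
The midpoint is the EC50/ED50 depending on the readout. Dose 0 is handled by
the asymptote limit, not by a log-dose offset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


@dataclass(frozen=True)
class FourPL:
    """4PL curve parameters. Callable on scalar or array doses (µM)."""

    slope: float
    lower: float
    upper: float
    midpoint: float

    def __post_init__(self) -> None:
        if self.midpoint <= 0:
            raise ValueError("midpoint must be positive")

    def __call__(self, dose):
        dose = np.asarray(dose, dtype=float)
        if np.any(dose < 0):
            raise ValueError("doses must be non-negative")
        out = np.empty(dose.shape, dtype=float)
        zero = dose == 0
        # limit of the log-logistic form as x -> 0+
        out[zero] = self.upper if self.slope > 0 else self.lower
        with np.errstate(over="ignore"):
            z = self.slope * (np.log(dose[~zero]) - math.log(self.midpoint))
            out[~zero] = self.lower + (self.upper - self.lower) / (1.0 + np.exp(z))
        return out if out.shape else float(out)


@dataclass
class FourPLFit:
    """Result of a least-squares 4PL fit.

    ``midpoint`` is the estimated EC50/ED50 in the dose units of the input.
    Standard errors come from the numerical curvature (Gauss-Newton
    approximation of the Hessian) at the optimum and may be NaN when the
    curvature matrix is singular.
    """

    slope: float
    lower: float
    upper: float
    midpoint: float
    sse: float
    converged: bool
    n_points: int
    se: dict = field(default_factory=dict)
    dose_min_pos: float = float("nan")
    dose_max: float = float("nan")

    @property
    def curve(self) -> FourPL:
        return FourPL(self.slope, self.lower, self.upper, self.midpoint)

    @property
    def midpoint_estimable(self) -> bool:
        """Whether the midpoint is bracketed by the tested dose range.

        A midpoint outside [min positive dose, max dose] is an extrapolation
        the data cannot support; it is reported but flagged non-estimable
        (the dose-response convention of quoting "ED50 > max dose").
        """
        if np.isnan(self.dose_min_pos):
            return True
        return bool(self.dose_min_pos <= self.midpoint <= self.dose_max)


def _pack(theta):
    slope, lower, upper, logm = theta
    return FourPL(slope, lower, upper, math.exp(logm))


def fit_4pl(doses, responses, init=None, bounds=None) -> FourPLFit:
    """Fit a 4PL curve by unweighted least squares.

    Parameters
    ----------
    doses, responses : array-like
        Paired observations; doses in µM, non-negative. At least four
        distinct doses are required.
    init : optional (slope, lower, upper, midpoint)
        Starting point. When omitted a coarse grid over midpoint and slope
        sign/steepness picks the best SSE start.
    bounds : optional ((lo...), (hi...)) on (slope, lower, upper, log midpoint)
        Defaults keep the midpoint within [min positive dose / 10,
        max dose x 10].
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must have equal length")
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    if not np.all(np.isfinite(responses)):
        raise ValueError("responses must be finite")
    if np.unique(doses).size < 4:
        raise ValueError("at least 4 distinct doses are required for a 4PL fit")

    pos = doses[doses > 0]
    lo_m, hi_m = pos.min() / 10.0, doses.max() * 10.0

    def residuals(theta):
        return _pack(theta)(doses) - responses

    rmin, rmax = responses.min(), responses.max()
    if init is not None:
        slope0, lower0, upper0, m0 = init
        starts = [np.array([slope0, lower0, upper0, math.log(m0)])]
    else:
        starts = []
        m_grid = np.geomspace(max(lo_m, 1e-12), hi_m, 7)
        for m0 in m_grid:
            for s0 in (-4.0, -1.0, 1.0, 4.0):
                starts.append(np.array([s0, rmin, rmax, math.log(m0)]))
        starts.sort(key=lambda th: float(np.sum(residuals(th) ** 2)))
        starts = starts[:3]

    if bounds is None:
        span = rmax - rmin if rmax > rmin else max(abs(rmax), 1.0)
        bounds = (
            np.array([-50.0, rmin - 10 * span, rmin - 10 * span, math.log(lo_m)]),
            np.array([50.0, rmax + 10 * span, rmax + 10 * span, math.log(hi_m)]),
        )

    best = None
    for th0 in starts:
        th0 = np.clip(th0, bounds[0] + 1e-9, bounds[1] - 1e-9)
        sol = least_squares(
            residuals, th0, bounds=bounds, xtol=1e-12, ftol=1e-12, gtol=1e-12
        )
        if best is None or sol.cost < best.cost:
            best = sol

    curve = _pack(best.x)
    sse = float(2 * best.cost)
    # a midpoint pinned to its box (a noisy series carrying no sigmoidal
    # signal lets it run away) is not an interior optimum
    width = bounds[1][3] - bounds[0][3]
    at_bound = bool((best.x[3] - bounds[0][3] < 1e-6 * width)
                    or (bounds[1][3] - best.x[3] < 1e-6 * width))
    converged = bool(best.success) and not at_bound

    se = {}
    try:
        J = best.jac
        dof = doses.size - 4
        if dof > 0:
            cov = np.linalg.inv(J.T @ J) * (sse / dof)
            sd = np.sqrt(np.diag(cov))
            se = {
                "slope": float(sd[0]),
                "lower": float(sd[1]),
                "upper": float(sd[2]),
                # delta method: midpoint = exp(log midpoint)
                "midpoint": float(sd[3] * curve.midpoint),
            }
    except np.linalg.LinAlgError:
        pass

    if not converged:
        warnings.warn("4PL fit did not converge", stacklevel=2)
    return FourPLFit(
        slope=curve.slope,
        lower=curve.lower,
        upper=curve.upper,
        midpoint=curve.midpoint,
        sse=sse,
        converged=converged,
        n_points=int(doses.size),
        se=se,
        dose_min_pos=float(pos.min()),
        dose_max=float(doses.max()),
    )


def fit_replicates(table, dose_col="dose", response_col="response",
                   replicate_col="replicate", **kwargs) -> list[FourPLFit]:
    """Fit one 4PL per replicate series of a long-format table."""
    fits = []
    for _, sub in table.groupby(replicate_col, sort=True):
        fits.append(fit_4pl(sub[dose_col].to_numpy(), sub[response_col].to_numpy(),
                            **kwargs))
    return fits


def ed50_with_replicates(fits) -> tuple[float, float]:
    """Mean and sample SD of midpoints over converged replicate fits.

    Non-converged fits, and fits whose midpoint falls outside the tested
    dose range (non-estimable extrapolations), are excluded with a warning;
    each remaining independent experiment contributes its own ED50.
    """
    good = [f for f in fits if f.converged and f.midpoint_estimable]
    if len(fits) - len(good):
        warnings.warn(
            f"excluding {len(fits) - len(good)} non-converged or "
            "non-estimable fit(s)", stacklevel=2
        )
    if not good:
        raise ValueError("all fits failed to converge")
    if len(good) < 2:
        raise ValueError("need at least 2 converged fits for mean +/- SD")
    mids = np.array([f.midpoint for f in good])
    return float(mids.mean()), float(mids.std(ddof=1))


def normalize_to_max(values):
    """Divide a response series by its maximum (which must be positive)."""
    values = np.asarray(values, dtype=float)
    m = values.max()
    if not m > 0:
        raise ValueError("maximum must be positive to normalise")
    return values / m


def proliferation_auc(doses, normalised_counts) -> float:
    """Trapezoidal area under a normalised count-vs-dose profile."""
    doses = np.asarray(doses, dtype=float)
    counts = np.asarray(normalised_counts, dtype=float)
    if doses.size != counts.size:
        raise ValueError("length mismatch")
    if np.any(np.diff(doses) < 0):
        raise ValueError("doses must be ascending")
    return float(np.trapezoid(counts, doses))
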