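"""Chaperone activity from aggregation-prevention and refolding assays.

The quantification scheme is standard-curve back-interpolation: a titration
of wild-type chaperone against a fixed client defines a monotone calibration
from chaperone:client molar ratio to an assay readout (a light-scattering
endpoint, an aggregation-rate slope, or a refolding yield).  A variant's
readout is then inverted through the calibration to the "effective ratio" of
wild type that would give the same readout, and

    fold activity = effective_ratio / added_ratio.

Three calibration families are supported:

    exponential  y = A + B * exp(-k * x)      (alpha-lactalbumin endpoints)
    quadratic    y = a2*x^2 + a1*x + a0       (aldolase aggregation slopes)
    power        y = c * (x + x0)^p           (aldolase refolding yields)

Each is monotone over its valid domain (decreasing for the aggregation
families, increasing for the power family) and is inverted analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import FitRejectedError, InvalidInputError, OutOfRangeError

__all__ = [
    "AggregationTrace",
    "StandardCurve",
    "RelativeActivity",
    "ActivityObservation",
    "extract_endpoints",
    "fit_aggregation_slope",
    "fit_standard_curve",
    "invert_standard_curve",
    "relative_activity",
    "refolding_yield",
    "ALPHA_LA_400S_CURVE",
    "ALDOLASE_AGG_CURVE",
    "ALDOLASE_REFOLD_CURVE",
]

EXPONENTIAL = "exponential"
QUADRATIC = "quadratic"
POWER = "power"

_SLOPE_WINDOW = (50.0, 600.0)  # s, aggregation-rate fit window (inclusive)


@dataclass(frozen=True)
class AggregationTrace:
    """Light-scattering trace of a client aggregating at a chaperone ratio."""

    time: np.ndarray  # s
    scattering: np.ndarray  # a.u.
    assay: str  # "alpha_la" | "aldolase"
    chaperone_ratio: float  # chaperone:client molar ratio
    variant_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.scattering, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "scattering", y)
        if not np.all(np.diff(t) > 0):
            raise InvalidInputError("time must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise InvalidInputError("scattering must be finite")
        if self.chaperone_ratio < 0:
            raise InvalidInputError("chaperone:client ratio must be >= 0")


@dataclass(frozen=True)
class StandardCurve:
    """A fitted monotone calibration ratio -> readout.

    coefficients:
        exponential: (A, B, k); quadratic: (a2, a1, a0); power: (c, x0, p)
    """

    family: str
    coefficients: tuple[float, ...]
    domain: tuple[float, float] = (0.0, 2.0)
    endpoint_s: float | None = None  # alpha-LA endpoint this curve belongs to
    covariance: np.ndarray | None = None
    r_squared: float = float("nan")

    def __post_init__(self):
        if self.family not in (EXPONENTIAL, QUADRATIC, POWER):
            raise InvalidInputError(f"unknown curve family {self.family!r}")
        if len(self.coefficients) != 3:
            raise InvalidInputError("every family takes exactly 3 coefficients")

    def __call__(self, x):
        return evaluate_standard_curve(self.family, self.coefficients, x)

    @property
    def increasing(self) -> bool:
        return self.family == POWER


def evaluate_standard_curve(family: str, coeffs: Sequence[float], x):
    x = np.asarray(x, dtype=float)
    if family == EXPONENTIAL:
        a, b, k = coeffs
        return a + b * np.exp(-k * x)
    if family == QUADRATIC:
        a2, a1, a0 = coeffs
        return a2 * x**2 + a1 * x + a0
    if family == POWER:
        c, x0, p = coeffs
        return c * (x + x0) ** p
    raise InvalidInputError(f"unknown curve family {family!r}")


#: Printed calibrations from the wild-type titrations (the 400 s
#: light-scattering endpoint for alpha-LA, the 50-600 s aggregation slope
#: for aldolase, and the aldolase refolding yield).
ALPHA_LA_400S_CURVE = StandardCurve(
    EXPONENTIAL, (0.004, 0.108, 8.46), domain=(0.0, 2.0), endpoint_s=400.0
)
ALDOLASE_AGG_CURVE = StandardCurve(
    QUADRATIC, (29.0861, -65.0189, 37.9414), domain=(0.0, 1.0)
)
ALDOLASE_REFOLD_CURVE = StandardCurve(
    POWER, (1.27711, 0.02196, 0.18859), domain=(0.0, 1.75)
)


def extract_endpoints(trace: AggregationTrace, times: Iterable[float]) -> np.ndarray:
    """Scattering at the requested times, linearly interpolated between
    bracketing samples (exact on grids that contain the requested time)."""
    times = np.asarray(list(times), dtype=float)
    t = trace.time
    if np.any(times < t[0]) or np.any(times > t[-1]):
        bad = times[(times < t[0]) | (times > t[-1])]
        raise OutOfRangeError(
            f"endpoint(s) {bad.tolist()} s outside trace range [{t[0]}, {t[-1]}] s"
        )
    return np.interp(times, t, trace.scattering)


def fit_aggregation_slope(trace: AggregationTrace) -> float:
    """Least-squares slope (a.u./s) over exactly the 50-600 s window."""
    lo, hi = _SLOPE_WINDOW
    mask = (trace.time >= lo) & (trace.time <= hi)
    if trace.time[0] > lo or trace.time[-1] < hi or mask.sum() < 2:
        raise InvalidInputError(
            f"trace must cover the {lo:g}-{hi:g} s aggregation-rate window"
        )
    slope, _ = np.polyfit(trace.time[mask], trace.scattering[mask], 1)
    return float(slope)


_N_COEFFS = 3


def fit_standard_curve(
    points: Sequence[tuple[float, float]],
    family: str,
    endpoint_s: float | None = None,
) -> StandardCurve:
    """Least-squares fit of a calibration family to (ratio, readout) points.

    Rejects fits that are not strictly monotone over the data span, since a
    non-monotone calibration cannot be inverted.
    """
    if len(points) < _N_COEFFS + 1:
        raise InvalidInputError(
            f"need >= {_N_COEFFS + 1} points to fit a {family} curve"
        )
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)

    if family == QUADRATIC:
        coef, cov = np.polyfit(x, y, 2, cov=True)
        popt = tuple(coef)
    elif family == EXPONENTIAL:
        a0 = float(np.min(y))
        b0 = float(np.max(y) - np.min(y)) or 1.0
        p0 = [a0, b0, 1.0 / max(np.ptp(x), 1e-6)]
        popt, cov = optimize.curve_fit(
            lambda xx, a, b, k: a + b * np.exp(-k * xx), x, y, p0=p0, maxfev=20000
        )
        popt = tuple(popt)
    elif family == POWER:
        p0 = [float(np.max(y)) or 1.0, 0.02, 0.2]
        popt, cov = optimize.curve_fit(
            lambda xx, c, x0, p: c * (xx + x0) ** p, x, y, p0=p0, maxfev=20000
        )
        popt = tuple(popt)
    else:
        raise InvalidInputError(f"unknown curve family {family!r}")

    domain = (float(np.min(x)), float(np.max(x)))
    grid = np.linspace(domain[0], domain[1], 512)
    vals = evaluate_standard_curve(family, popt, grid)
    diffs = np.diff(vals)
    if not (np.all(diffs < 0) or np.all(diffs > 0)):
        raise FitRejectedError(
            f"fitted {family} curve is not monotone over the data span {domain}"
        )
    ss_res = float(np.sum((y - evaluate_standard_curve(family, popt, x)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return StandardCurve(
        family, popt, domain=domain, endpoint_s=endpoint_s,
        covariance=np.asarray(cov), r_squared=r2,
    )


def invert_standard_curve(curve: StandardCurve, readout: float) -> float:
    """Back-interpolate a readout to the effective wild-type ratio.

    Analytic inversion per family; the quadratic uses the root on the
    decreasing branch left of the vertex (the smaller root).
    """
    y = float(readout)
    if curve.family == EXPONENTIAL:
        a, b, k = curve.coefficients
        if y <= a:
            raise OutOfRangeError(
                f"readout {y:g} at or below the exponential floor A = {a:g}"
            )
        if y > a + b:
            raise OutOfRangeError(
                f"readout {y:g} above the zero-ratio maximum A+B = {a + b:g}"
            )
        return float(np.log(b / (y - a)) / k)
    if curve.family == QUADRATIC:
        a2, a1, a0 = curve.coefficients
        disc = a1**2 - 4.0 * a2 * (a0 - y)
        if disc < 0:
            vertex_y = evaluate_standard_curve(QUADRATIC, curve.coefficients,
                                               -a1 / (2.0 * a2))
            raise OutOfRangeError(
                f"readout {y:g} below the quadratic minimum {float(vertex_y):g}"
            )
        root = (-a1 - np.sqrt(disc)) / (2.0 * a2)
        return float(root)
    if curve.family == POWER:
        c, x0, p = curve.coefficients
        if y <= 0 or c <= 0:
            raise OutOfRangeError(f"readout {y:g} outside the power-law range")
        x = (y / c) ** (1.0 / p) - x0
        if x < -1e-9:
            raise OutOfRangeError(
                f"readout {y:g} maps to a negative ratio {x:g}"
            )
        return float(max(x, 0.0))
    raise InvalidInputError(f"unknown curve family {curve.family!r}")


@dataclass(frozen=True)
class ActivityObservation:
    """One assay readout for a variant at a known added chaperone ratio."""

    added_ratio: float
    readout: float
    endpoint_s: float | None = None  # matches a curve's endpoint_s if set


@dataclass(frozen=True)
class RelativeActivity:
    """Fold activity of a variant relative to wild type."""

    fold_vs_wt: float
    standard_error: float
    n_values_averaged: int
    assay: str = ""
    folds: tuple[float, ...] = field(default_factory=tuple)


def _curve_inversion_variance(curve: StandardCurve, readout: float) -> float:
    """First-order variance of the inverted ratio from the calibration's
    coefficient covariance (zero when the curve has no covariance)."""
    if curve.covariance is None:
        return 0.0
    coeffs = np.asarray(curve.coefficients, dtype=float)
    grad = np.empty_like(coeffs)
    for i in range(coeffs.size):
        h = 1e-6 * max(abs(coeffs[i]), 1e-6)
        cp, cm = coeffs.copy(), coeffs.copy()
        cp[i] += h
        cm[i] -= h
        xp = invert_standard_curve(
            StandardCurve(curve.family, tuple(cp), curve.domain, curve.endpoint_s),
            readout,
        )
        xm = invert_standard_curve(
            StandardCurve(curve.family, tuple(cm), curve.domain, curve.endpoint_s),
            readout,
        )
        grad[i] = (xp - xm) / (2.0 * h)
    return float(grad @ curve.covariance @ grad)


def relative_activity(
    observations: Sequence[ActivityObservation],
    curves: Sequence[StandardCurve],
    assay: str = "",
) -> RelativeActivity:
    """Fold activity vs wild type, averaged over observation x curve values.

    Each observation is inverted through every applicable curve (curves with
    an ``endpoint_s`` only apply to observations carrying the same endpoint;
    curves without apply to observations without).  The reported error
    combines the scatter of the individual folds with the propagated
    calibration-coefficient variance.
    """
    if not observations or not curves:
        raise InvalidInputError("need at least one observation and one curve")
    folds = []
    curve_vars = []
    for obs in observations:
        applicable = [
            cv for cv in curves
            if (cv.endpoint_s is None and obs.endpoint_s is None)
            or (cv.endpoint_s is not None and obs.endpoint_s == cv.endpoint_s)
        ]
        if not applicable:
            raise InvalidInputError(
                f"no applicable standard curve for endpoint {obs.endpoint_s}"
            )
        if obs.added_ratio <= 0:
            raise InvalidInputError("added ratio must be positive")
        for cv in applicable:
            try:
                eff = invert_standard_curve(cv, obs.readout)
            except OutOfRangeError as exc:
                raise OutOfRangeError(
                    f"observation (ratio={obs.added_ratio}, readout={obs.readout}, "
                    f"endpoint={obs.endpoint_s}) not invertible: {exc}"
                ) from exc
            folds.append(eff / obs.added_ratio)
            curve_vars.append(
                _curve_inversion_variance(cv, obs.readout) / obs.added_ratio**2
            )
    folds_arr = np.asarray(folds)
    n = folds_arr.size
    mean = float(folds_arr.mean())
    sem2 = float(folds_arr.var(ddof=1) / n) if n > 1 else 0.0
    curve_var = float(np.mean(curve_vars))
    return RelativeActivity(
        fold_vs_wt=mean,
        standard_error=float(np.sqrt(sem2 + curve_var)),
        n_values_averaged=n,
        assay=assay,
        folds=tuple(folds),
    )


def refolding_yield(
    activity_trace: Sequence[tuple[float, float]],
    native_reference_slope: float,
) -> float:
    """Refolded-enzyme activity as a fraction of the native-enzyme rate.

    ``activity_trace`` is a list of (time, A340) points of the coupled
    enzymatic assay; the fitted A340 slope divided by the native slope gives
    the fractional refolding yield.
    """
    pts = np.asarray(activity_trace, dtype=float)
    if pts.shape[0] < 10:
        raise InvalidInputError("refolding activity trace needs >= 10 points")
    if native_reference_slope == 0:
        raise InvalidInputError("native reference slope must be nonzero")
    slope, _ = np.polyfit(pts[:, 0], pts[:, 1], 1)
    return float(slope / native_reference_slope)


def read_activity_table(path) -> pd.DataFrame:
    """Read a delimited activity-observation table
    (assay, variant, added_ratio, endpoint_s, readout)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"assay", "variant", "added_ratio", "readout"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"activity table missing columns: {sorted(missing)}")
    return df
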