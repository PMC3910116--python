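"""Bio-layer interferometry 1:1 binding kinetics.

Association traces are fit per analyte concentration with

    y = a * (1 - exp(-kobs * t)) + y0 * t        (y0: linear drift slope)

and dissociation traces with

    y = y0 + a * exp(-koff * t)                  (y0: constant offset).

The observed rates follow kobs = kon * [analyte] + koff, so kon is the OLS
slope of kobs against concentration and KD = koff / kon.  The headline koff
is the inverse-variance weighted mean of the per-concentration dissociation
fits; the kobs-line intercept serves as a consistency check.

Concentrations are molar internally; micromolar is accepted at I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitRejectedError, GridMismatchError, InvalidInputError

__all__ = [
    "BLITrace",
    "KineticsResult",
    "subtract_reference",
    "fit_association",
    "fit_dissociation",
    "kon_from_kobs",
    "dissociation_constant",
    "fit_traceset",
    "read_trace_table",
]

ASSOCIATION = "association"
DISSOCIATION = "dissociation"


@dataclass(frozen=True)
class BLITrace:
    """One sensorgram phase: nm shift vs time from phase start."""

    time: np.ndarray  # s, starts at 0, strictly increasing
    signal: np.ndarray  # nm
    phase: str  # "association" | "dissociation"
    analyte_concentration: float = float("nan")  # molar
    variant_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", y)
        if self.phase not in (ASSOCIATION, DISSOCIATION):
            raise InvalidInputError(f"unknown phase {self.phase!r}")
        if t.size != y.size:
            raise InvalidInputError("time and signal lengths differ")
        if t.size and (t[0] != 0 or not np.all(np.diff(t) > 0)):
            raise InvalidInputError("time must start at 0 and strictly increase")
        if self.phase == ASSOCIATION and not self.analyte_concentration > 0:
            raise InvalidInputError("association trace needs a positive concentration")


@dataclass(frozen=True)
class KineticsResult:
    """Per-variant kinetic summary for one variant-client pair."""

    variant_id: str
    kon: float  # 1/(M*s)
    koff: float  # 1/s (weighted mean of dissociation fits)
    KD: float  # molar
    koff_intercept: float  # 1/s, from the kobs-vs-concentration line
    kobs_by_concentration: dict[float, float] = field(default_factory=dict)
    stderr: dict[str, float] = field(default_factory=dict)


def _phase_fit_precheck(trace: BLITrace, phase: str) -> None:
    if trace.phase != phase:
        raise InvalidInputError(f"expected a {phase} trace, got {trace.phase}")
    if trace.time.size < 20:
        raise InvalidInputError(f"{phase} fit needs >= 20 points")
    if np.ptp(trace.signal) < 1e-12:
        raise FitRejectedError(
            "constant trace: amplitude ~ 0, rate unidentifiable"
        )


def subtract_reference(trace: BLITrace, reference: BLITrace) -> BLITrace:
    """Pointwise subtraction of a buffer-only reference sensorgram."""
    if trace.time.shape != reference.time.shape or not np.allclose(
        trace.time, reference.time
    ):
        raise GridMismatchError("trace and reference are on different time grids")
    return BLITrace(
        time=trace.time,
        signal=trace.signal - reference.signal,
        phase=trace.phase,
        analyte_concentration=trace.analyte_concentration,
        variant_id=trace.variant_id,
    )


def _association_model(t, a, kobs, y0):
    return a * (1.0 - np.exp(-kobs * t)) + y0 * t


def _dissociation_model(t, a, koff, y0):
    return y0 + a * np.exp(-koff * t)


def fit_association(trace: BLITrace) -> dict[str, float]:
    """Fit a, kobs and the drift slope y0; returns estimates and errors."""
    _phase_fit_precheck(trace, ASSOCIATION)
    t, y = trace.time, trace.signal
    a0 = float(y[-1]) if y[-1] != 0 else float(np.max(np.abs(y)))
    # crude half-rise time for the rate guess
    half = 0.5 * a0
    above = np.nonzero(y >= half)[0] if a0 > 0 else np.nonzero(y <= half)[0]
    t_half = t[above[0]] if above.size and above[0] > 0 else t[-1] / 10.0
    k0 = np.log(2.0) / max(t_half, t[1])
    try:
        popt, pcov = optimize.curve_fit(
            _association_model, t, y, p0=[a0, k0, 0.0], maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover
        raise FitRejectedError(f"association fit did not converge: {exc}") from exc
    a, kobs, y0 = popt
    if kobs <= 0:
        raise FitRejectedError(f"fitted kobs = {kobs:.3g} <= 0 /s")
    perr = np.sqrt(np.diag(pcov))
    return {
        "a": a, "kobs": kobs, "y0": y0,
        "a_err": perr[0], "kobs_err": perr[1], "y0_err": perr[2],
    }


def fit_dissociation(trace: BLITrace) -> dict[str, float]:
    """Fit a, koff and the constant baseline offset y0."""
    _phase_fit_precheck(trace, DISSOCIATION)
    t, y = trace.time, trace.signal
    y0_0 = float(y[-1])
    a0 = float(y[0] - y[-1])
    if abs(a0) < 1e-12:
        raise FitRejectedError("no decay amplitude: a ~ 0, koff unidentifiable")
    k0 = np.log(2.0) / max(t[-1] / 5.0, t[1])
    try:
        popt, pcov = optimize.curve_fit(
            _dissociation_model, t, y, p0=[a0, k0, y0_0], maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover
        raise FitRejectedError(f"dissociation fit did not converge: {exc}") from exc
    a, koff, y0 = popt
    if koff <= 0:
        raise FitRejectedError(f"fitted koff = {koff:.3g} <= 0 /s")
    perr = np.sqrt(np.diag(pcov))
    return {
        "a": a, "koff": koff, "y0": y0,
        "a_err": perr[0], "koff_err": perr[1], "y0_err": perr[2],
    }


def kon_from_kobs(pairs: list[tuple[float, float]]) -> dict[str, float]:
    """OLS of kobs on concentration: slope = kon, intercept = koff."""
    if len(pairs) < 3:
        raise InvalidInputError("kon regression needs >= 3 (concentration, kobs) pairs")
    c = np.array([p[0] for p in pairs], dtype=float)
    k = np.array([p[1] for p in pairs], dtype=float)
    if np.unique(c).size < 3:
        raise InvalidInputError("need >= 3 distinct concentrations")
    res = stats.linregress(c, k)
    if res.slope <= 0:
        raise FitRejectedError(f"fitted kon = {res.slope:.3g} <= 0 /(M*s)")
    return {
        "kon": float(res.slope),
        "koff_intercept": float(res.intercept),
        "kon_err": float(res.stderr),
        "koff_intercept_err": float(res.intercept_stderr),
    }


def dissociation_constant(kon: float, koff: float) -> float:
    """KD = koff / kon, in molar."""
    if kon <= 0:
        raise InvalidInputError(f"kon must be positive, got {kon:.3g}")
    return koff / kon


def fit_traceset(traces: list[BLITrace], variant_id: str = "") -> KineticsResult:
    """Full two-step analysis of one variant's sensorgram set.

    Association traces give per-concentration kobs; their regression on
    concentration gives kon (slope) and a consistency-check koff
    (intercept).  Dissociation fits are combined by inverse-variance
    weighting into the headline koff; KD = koff/kon.
    """
    assoc = [tr for tr in traces if tr.phase == ASSOCIATION]
    dissoc = [tr for tr in traces if tr.phase == DISSOCIATION]
    if not assoc:
        raise InvalidInputError("no association traces supplied")
    kobs_map: dict[float, float] = {}
    pairs = []
    for tr in assoc:
        fit = fit_association(tr)
        kobs_map[tr.analyte_concentration] = fit["kobs"]
        pairs.append((tr.analyte_concentration, fit["kobs"]))
    line = kon_from_kobs(pairs)
    if dissoc:
        koffs = np.empty(len(dissoc))
        weights = np.empty(len(dissoc))
        for i, tr in enumerate(dissoc):
            fit = fit_dissociation(tr)
            koffs[i] = fit["koff"]
            err = fit["koff_err"]
            weights[i] = 1.0 / err**2 if np.isfinite(err) and err > 0 else 1.0
        if not np.all(np.isfinite(weights)):
            weights = np.ones_like(weights)
        koff = float(np.average(koffs, weights=weights))
        koff_err = float(np.sqrt(1.0 / np.sum(weights)))
    else:
        koff = line["koff_intercept"]
        koff_err = line["koff_intercept_err"]
    kon = line["kon"]
    kd = dissociation_constant(kon, koff)
    kd_err = kd * np.hypot(
        line["kon_err"] / kon, koff_err / koff if koff else 0.0
    )
    return KineticsResult(
        variant_id=variant_id,
        kon=kon,
        koff=koff,
        KD=kd,
        koff_intercept=line["koff_intercept"],
        kobs_by_concentration=kobs_map,
        stderr={
            "kon": line["kon_err"],
            "koff": koff_err,
            "koff_intercept": line["koff_intercept_err"],
            "KD": float(kd_err),
        },
    )


def read_trace_table(path) -> dict[str, list[BLITrace]]:
    """Read a delimited trace table (variant, phase, concentration_uM,
    time_s, signal_nm) into per-variant trace lists (concentration -> M)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"variant", "phase", "concentration_uM", "time_s", "signal_nm"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"trace table missing columns: {sorted(missing)}")
    out: dict[str, list[BLITrace]] = {}
    keys = ["variant", "phase", "concentration_uM"]
    for (variant, phase, conc_um), grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("time_s")
        out.setdefault(str(variant), []).append(
            BLITrace(
                time=grp["time_s"].to_numpy(float),
                signal=grp["signal_nm"].to_numpy(float),
                phase=str(phase),
                analyte_concentration=float(conc_um) * 1e-6,
                variant_id=str(variant),
            )
        )
    return out
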