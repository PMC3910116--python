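"""Two-state thermal denaturation analysis.

A circular-dichroism melt of a reversibly unfolding protein is modeled as a
two-state (native/unfolded) equilibrium with linear pre- and post-transition
baselines.  Within a single melt the free energy of unfolding is taken as

    dG(T) = dHm * (1 - T/Tm)

(the heat-capacity term is omitted per curve; dCp is obtained separately as
the slope of dHm against Tm across a pH series) and the observed signal is
the population-weighted average of the two baselines,

    theta(T) = [theta_N(T) + theta_U(T) * K(T)] / (1 + K(T)),
    K(T) = exp(-dG(T) / (R * T)).

Free energies at an arbitrary temperature come from the modified
Gibbs-Helmholtz relation

    dG(T) = dHm * (1 - T/Tm) - dCp * [(Tm - T) + T * ln(T/Tm)].

All temperatures are Kelvin internally; Celsius is accepted at I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .constants import R_KCAL, celsius_to_kelvin, kelvin_to_celsius
from .errors import FitRejectedError, GridMismatchError, InvalidInputError

__all__ = [
    "MeltCurve",
    "TwoStateModel",
    "VariantThermo",
    "two_state_signal",
    "fit_melt_curve",
    "reversibility",
    "delta_cp_from_ph_series",
    "gibbs_free_energy",
    "ddg",
    "read_melt_table",
]


@dataclass(frozen=True)
class MeltCurve:
    """One CD melt: signal at 222 nm vs temperature, at a single pH."""

    temperature: np.ndarray  # K, strictly increasing
    ellipticity: np.ndarray  # arbitrary CD units
    ph: float = 7.5
    variant_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.temperature, dtype=float)
        y = np.asarray(self.ellipticity, dtype=float)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "ellipticity", y)
        if t.size < 20:
            raise InvalidInputError(f"melt curve needs >= 20 points, got {t.size}")
        if t.size != y.size:
            raise InvalidInputError("temperature and ellipticity lengths differ")
        if not np.all(np.diff(t) > 0):
            raise InvalidInputError("temperatures must be strictly increasing")


@dataclass(frozen=True)
class TwoStateModel:
    """Fitted two-state melt parameters (baselines as intercept/slope)."""

    Tm: float  # K
    dHm: float  # kcal/mol, van 't Hoff enthalpy at Tm
    baseline_native: tuple[float, float]
    baseline_unfolded: tuple[float, float]
    stderr: dict[str, float] = field(default_factory=dict)
    rss: float = float("nan")

    @property
    def Tm_celsius(self) -> float:
        return kelvin_to_celsius(self.Tm)

    def predict(self, temperature: np.ndarray) -> np.ndarray:
        return two_state_signal(
            np.asarray(temperature, dtype=float),
            self.Tm,
            self.dHm,
            *self.baseline_native,
            *self.baseline_unfolded,
        )

    def fraction_unfolded(self, temperature: np.ndarray) -> np.ndarray:
        t = np.asarray(temperature, dtype=float)
        k = _equilibrium_constant(t, self.Tm, self.dHm)
        return k / (1.0 + k)


@dataclass(frozen=True)
class VariantThermo:
    """Thermodynamic summary for one variant (one stability-table row)."""

    variant_id: str
    Tm: float  # K
    dHm: float  # kcal/mol
    dCp: float  # kcal/(K*mol)
    dG_NU: float  # kcal/mol at `temperature`
    temperature: float = 298.15  # K at which dG_NU is quoted
    stderr: dict[str, float] = field(default_factory=dict)
    reversibility: float = float("nan")

    @property
    def Tm_celsius(self) -> float:
        return kelvin_to_celsius(self.Tm)


def _equilibrium_constant(t: np.ndarray, tm: float, dhm: float) -> np.ndarray:
    dg = dhm * (1.0 - t / tm)
    return np.exp(-dg / (R_KCAL * t))


def two_state_signal(
    t: np.ndarray,
    tm: float,
    dhm: float,
    bn0: float,
    bn1: float,
    bu0: float,
    bu1: float,
) -> np.ndarray:
    """Two-state melt signal with linear native/unfolded baselines."""
    k = _equilibrium_constant(t, tm, dhm)
    theta_n = bn0 + bn1 * t
    theta_u = bu0 + bu1 * t
    return (theta_n + theta_u * k) / (1.0 + k)


def _transition_index(t: np.ndarray, y: np.ndarray) -> int:
    # smooth before differentiating so measurement noise cannot masquerade
    # as the unfolding transition; widen the window if the apparent maximum
    # sits on the scan edge (noise-dominated derivative)
    n = y.size
    idx = 0
    for window in (21, 41, 81):
        window = min(window, n if n % 2 else n - 1)
        ys = y
        if window >= 5:
            ys = signal.savgol_filter(y, window_length=window, polyorder=3)
        dy = np.gradient(ys, t)
        idx = int(np.argmax(np.abs(dy)))
        if 2 < idx < n - 3:
            return idx
    return idx


def fit_melt_curve(curve: MeltCurve) -> TwoStateModel:
    """Nonlinear least-squares fit of {Tm, dHm, 4 baseline coefficients}.

    Initialization: Tm at max |d theta/dT|, dHm = 50 kcal/mol, baselines from
    the outer 15% of points.  Raises :class:`FitRejectedError` when the
    transition is not interior to the scanned range, when the optimizer does
    not converge, or when the fitted dHm is non-positive.
    """
    t, y = curve.temperature, curve.ellipticity
    n = t.size
    idx = _transition_index(t, y)
    if idx < 2 or idx > n - 3:
        raise FitRejectedError(
            "no interior unfolding transition: max |d(signal)/dT| at "
            f"index {idx} of {n} (need the transition inside the scan range)"
        )
    edge = max(3, int(round(0.15 * n)))
    lo = np.polyfit(t[:edge], y[:edge], 1)  # slope, intercept
    hi = np.polyfit(t[-edge:], y[-edge:], 1)
    p0 = [t[idx], 50.0, lo[1], lo[0], hi[1], hi[0]]
    try:
        popt, pcov = optimize.curve_fit(
            two_state_signal, t, y, p0=p0, maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - depends on data
        raise FitRejectedError(f"melt fit did not converge: {exc}") from exc
    tm, dhm = popt[0], popt[1]
    if dhm <= 0:
        raise FitRejectedError(f"fitted dHm = {dhm:.3g} <= 0 kcal/mol")
    if not (t[0] < tm < t[-1]):
        raise FitRejectedError(f"fitted Tm = {tm:.2f} K outside the data range")
    perr = np.sqrt(np.diag(pcov))
    resid = y - two_state_signal(t, *popt)
    names = ["Tm", "dHm", "bn0", "bn1", "bu0", "bu1"]
    return TwoStateModel(
        Tm=tm,
        dHm=dhm,
        baseline_native=(popt[2], popt[3]),
        baseline_unfolded=(popt[4], popt[5]),
        stderr=dict(zip(names, perr)),
        rss=float(resid @ resid),
    )


def reversibility(
    pre_spectrum: tuple[np.ndarray, np.ndarray],
    post_spectrum: tuple[np.ndarray, np.ndarray],
    wavelength_nm: float = 222.0,
    threshold: float = 0.95,
) -> tuple[float, bool]:
    """Fraction of the initial CD signal regained after renaturation.

    Both spectra are (wavelength, signal) pairs on the same grid.  Returns
    (fraction, passes) where passes means fraction >= threshold (0.95, the
    conventional criterion for calling a melt reversible).
    """
    wl_pre, sig_pre = (np.asarray(a, dtype=float) for a in pre_spectrum)
    wl_post, sig_post = (np.asarray(a, dtype=float) for a in post_spectrum)
    if wl_pre.shape != wl_post.shape or not np.allclose(wl_pre, wl_post):
        raise GridMismatchError("pre and post spectra are on different wavelength grids")
    i = int(np.argmin(np.abs(wl_pre - wavelength_nm)))
    if sig_pre[i] == 0:
        raise InvalidInputError("initial signal at the probe wavelength is zero")
    frac = float(sig_post[i] / sig_pre[i])
    return frac, frac >= threshold


def delta_cp_from_ph_series(
    points: list[tuple[float, float]]
) -> tuple[float, float]:
    """Heat-capacity change as the OLS slope of dHm (kcal/mol) on Tm (K).

    `points` holds (Tm, dHm) pairs from melts across a pH series; returns
    (dCp, standard error) in kcal/(K*mol).
    """
    if len(points) < 3:
        raise InvalidInputError("dCp regression needs >= 3 (Tm, dHm) points")
    tm = np.array([p[0] for p in points], dtype=float)
    dhm = np.array([p[1] for p in points], dtype=float)
    if np.ptp(tm) == 0:
        raise InvalidInputError("all Tm values identical; slope undefined")
    res = stats.linregress(tm, dhm)
    return float(res.slope), float(res.stderr)


def gibbs_free_energy(Tm: float, dHm: float, dCp: float, T: float = 298.15) -> float:
    """Unfolding free energy (kcal/mol) at temperature T (K).

    Evaluates dG(T) = dHm*(1 - T/Tm) - dCp*[(Tm - T) + T*ln(T/Tm)].
    """
    if Tm <= 0 or T <= 0:
        raise InvalidInputError("temperatures must be positive (Kelvin)")
    return dHm * (1.0 - T / Tm) - dCp * ((Tm - T) + T * np.log(T / Tm))


def ddg(variant: VariantThermo, reference: VariantThermo) -> float:
    """Stability change dG(variant) - dG(reference), same quote temperature."""
    if variant.temperature != reference.temperature:
        raise InvalidInputError(
            "ddG requires both dG values at the same temperature "
            f"({variant.temperature} K vs {reference.temperature} K)"
        )
    return variant.dG_NU - reference.dG_NU


def read_melt_table(path) -> list[MeltCurve]:
    """Read a delimited melt table (variant, pH, temperature_C, signal).

    Returns one :class:`MeltCurve` per (variant, pH) group, temperatures
    converted to Kelvin and sorted.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"variant", "pH", "temperature_C", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"melt table missing columns: {sorted(missing)}")
    curves = []
    for (variant, ph), grp in df.groupby(["variant", "pH"], sort=False):
        grp = grp.sort_values("temperature_C")
        curves.append(
            MeltCurve(
                temperature=celsius_to_kelvin(grp["temperature_C"].to_numpy(float)),
                ellipticity=grp["signal"].to_numpy(float),
                ph=float(ph),
                variant_id=str(variant),
            )
        )
    return curves
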