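"""Expression-normalized in vivo chaperone activity.

The in vivo assay couples client-protein stability to penicillin resistance
through a beta-lactamase folding biosensor: the minimal inhibitory
concentration (MIC) of penicillin read off a spot-titration grid measures
how well a chaperone variant stabilizes the client.  Because variants are
expressed at different steady-state levels, the maximal MIC of each variant
is divided by the wild-type MIC at the *matched* expression level
(interpolated along the wild-type IPTG titration), giving the dimensionless
specific activity MIC_norm (wild type = 1 by construction).

Expression levels come from quantitative western blots: the slope of band
intensity against loading for the target, divided by the loading-control
(MBP) slope, rescaled so wild type = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, OutOfRangeError

__all__ = [
    "SpotGrid",
    "DilutionSeries",
    "ExpressionLevel",
    "MicNorm",
    "mic_from_grid",
    "expression_level",
    "normalized_mic",
    "linear_correlation",
    "UNBOUNDED_MIC",
]

#: Sentinel returned when growth persists at every tested concentration.
UNBOUNDED_MIC = float("inf")


@dataclass(frozen=True)
class SpotGrid:
    """Growth/no-growth matrix from a penicillin spot titration.

    growth[i, j] is True if the culture grew at penicillin_concentration[i]
    and dilution[j] (log10 dilution factors, e.g. -1 ... -5).
    """

    penicillin_concentration: np.ndarray  # ug/ml
    dilution: np.ndarray  # log10 factors
    growth: np.ndarray  # boolean matrix (conc x dilution)
    iptg: float = 0.5  # mM
    strain_id: str = ""

    def __post_init__(self):
        conc = np.asarray(self.penicillin_concentration, dtype=float)
        dil = np.asarray(self.dilution, dtype=float)
        grw = np.asarray(self.growth, dtype=bool)
        object.__setattr__(self, "penicillin_concentration", conc)
        object.__setattr__(self, "dilution", dil)
        object.__setattr__(self, "growth", grw)
        if grw.shape != (conc.size, dil.size):
            raise InvalidInputError(
                f"growth matrix shape {grw.shape} does not match "
                f"{conc.size} concentrations x {dil.size} dilutions"
            )


@dataclass(frozen=True)
class DilutionSeries:
    """Western-blot band intensities across lysate loadings."""

    loading: np.ndarray  # relative amount loaded
    intensity: np.ndarray  # band intensity, a.u.
    label: str = ""

    def __post_init__(self):
        ld = np.asarray(self.loading, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "loading", ld)
        object.__setattr__(self, "intensity", it)
        if ld.size < 3:
            raise InvalidInputError("dilution series needs >= 3 loadings")
        if ld.size != it.size:
            raise InvalidInputError("loading and intensity lengths differ")


@dataclass(frozen=True)
class ExpressionLevel:
    variant_id: str
    level: float  # target/control slope ratio, wild type = 1
    iptg: float = 0.5
    stderr: float = float("nan")

    def __post_init__(self):
        if not self.level > 0:
            raise InvalidInputError("expression level must be positive")


@dataclass(frozen=True)
class MicNorm:
    variant_id: str
    mic_max: float  # ug/ml
    wt_mic_at_matched_level: float  # ug/ml
    mic_norm: float  # dimensionless
    warnings: tuple[str, ...] = field(default_factory=tuple)


def mic_from_grid(grid: SpotGrid, scoring_dilution: float = -3.0) -> tuple[float, list[str]]:
    """MIC: lowest tested concentration with no growth at the scoring dilution.

    Returns (MIC in ug/ml, warnings).  Growth at every concentration returns
    the +inf sentinel.  A non-monotone growth column (growth reappearing at a
    higher concentration) is flagged in the warnings, never silently fixed.
    """
    matches = np.nonzero(np.isclose(grid.dilution, scoring_dilution))[0]
    if matches.size == 0:
        raise InvalidInputError(
            f"scoring dilution {scoring_dilution} not in grid dilutions "
            f"{grid.dilution.tolist()}"
        )
    j = int(matches[0])
    order = np.argsort(grid.penicillin_concentration)
    conc = grid.penicillin_concentration[order]
    col = grid.growth[order, j]
    warnings = []
    # growth should be monotone non-increasing along increasing penicillin
    if np.any(np.diff(col.astype(int)) > 0):
        warnings.append(
            f"non-monotone growth along penicillin at dilution {scoring_dilution}"
        )
    no_growth = np.nonzero(~col)[0]
    if no_growth.size == 0:
        return UNBOUNDED_MIC, warnings
    return float(conc[no_growth[0]]), warnings


def expression_level(
    series: DilutionSeries,
    control_series: DilutionSeries,
    variant_id: str = "",
    wt_ratio: float = 1.0,
    iptg: float = 0.5,
) -> ExpressionLevel:
    """Target/control intensity-slope ratio, rescaled so wild type = 1.

    ``wt_ratio`` is the same slope ratio measured for wild type; pass 1.0 to
    get the unscaled ratio.
    """
    t = stats.linregress(series.loading, series.intensity)
    c = stats.linregress(control_series.loading, control_series.intensity)
    if c.slope <= 0:
        raise InvalidInputError(f"control slope {c.slope:.3g} <= 0")
    ratio = t.slope / c.slope
    rel = ratio / wt_ratio
    rel_err = rel * np.hypot(
        t.stderr / t.slope if t.slope else 0.0, c.stderr / c.slope
    )
    return ExpressionLevel(variant_id=variant_id, level=rel, iptg=iptg,
                           stderr=float(rel_err))


def normalized_mic(
    variant_mic_max: float,
    wt_curve: Sequence[tuple[float, float]],
    variant_level: float,
    variant_id: str = "",
) -> MicNorm:
    """MIC_norm = variant maximal MIC / WT MIC at the matched expression level.

    ``wt_curve`` is the wild-type (expression level, MIC) titration; the WT
    MIC at the variant's level is obtained by piecewise-linear interpolation.
    Levels outside the titration range raise rather than extrapolate.
    """
    pts = sorted((float(lv), float(mic)) for lv, mic in wt_curve)
    if len(pts) < 1:
        raise InvalidInputError("empty wild-type level->MIC curve")
    levels = np.array([p[0] for p in pts])
    mics = np.array([p[1] for p in pts])
    if not (levels[0] <= variant_level <= levels[-1]):
        raise OutOfRangeError(
            f"variant level {variant_level:g} outside the wild-type titration "
            f"range [{levels[0]:g}, {levels[-1]:g}]; refusing to extrapolate"
        )
    wt_mic = float(np.interp(variant_level, levels, mics))
    if wt_mic <= 0:
        raise InvalidInputError("interpolated wild-type MIC must be positive")
    return MicNorm(
        variant_id=variant_id,
        mic_max=float(variant_mic_max),
        wt_mic_at_matched_level=wt_mic,
        mic_norm=float(variant_mic_max) / wt_mic,
    )


def linear_correlation(x: Sequence[float], y: Sequence[float]) -> dict[str, float]:
    """OLS fit of y on x with Pearson r and R^2 (R^2 = r^2 exactly)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise InvalidInputError("correlation needs >= 3 paired finite values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidInputError("correlation inputs must be finite")
    if np.ptp(x) == 0:
        raise InvalidInputError("zero variance in x; regression undefined")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "r_squared": float(res.rvalue**2),
        "n": int(x.size),
        "p_value": float(res.pvalue),
    }


def read_spot_grid_table(path) -> list[SpotGrid]:
    """Read delimited spot-grid rows
    (strain, iptg_mM, penicillin_ugml, dilution_log10, growth)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"strain", "iptg_mM", "penicillin_ugml", "dilution_log10", "growth"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"spot grid table missing columns: {sorted(missing)}")
    grids = []
    for (strain, iptg), grp in df.groupby(["strain", "iptg_mM"], sort=False):
        pivot = grp.pivot_table(
            index="penicillin_ugml", columns="dilution_log10", values="growth"
        ).sort_index()
        grids.append(
            SpotGrid(
                penicillin_concentration=pivot.index.to_numpy(float),
                dilution=pivot.columns.to_numpy(float),
                growth=pivot.to_numpy() > 0.5,
                iptg=float(iptg),
                strain_id=str(strain),
            )
        )
    return grids
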