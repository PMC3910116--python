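"""Seeded generators for every raw input the pipeline consumes.

Each generator fabricates one assay's raw data from known ground-truth
parameters, so every downstream fitting stage can be validated by parameter
recovery: at zero noise the generator composed with its analysis stage is
the identity on the truth, and at finite noise the recovery error can be
characterized over many seeds.

Noise is additive Gaussian on the measured signal.  Randomness derives from
one root seed with an independent child stream per generator, so assays are
mutually independent but the whole dataset is reproducible bit-for-bit.

Default acquisition grids mirror the real instruments at desk scale: CD
melts from 283.15 to 353.15 K every 0.25 K, BLI association 0-600 s and
dissociation 0-900 s at 1 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from pyteomics import mass as pytmass

from .binding_kinetics import ASSOCIATION, DISSOCIATION, BLITrace
from .chaperone_activity import (
    ALDOLASE_AGG_CURVE,
    ALDOLASE_REFOLD_CURVE,
    ALPHA_LA_400S_CURVE,
    AggregationTrace,
)
from .constants import D_H_MASS_DIFF, N15_N14_MASS_DIFF
from .errors import InvalidInputError
from .hdx_topdown import FragmentSeries
from .invivo_activity import DilutionSeries, SpotGrid
from .thermostability import MeltCurve, two_state_signal
from .xlink_match import CrosslinkCandidate

__all__ = [
    "GeneratorConfig",
    "Synthetic",
    "gen_melt_curve",
    "gen_bli_traceset",
    "gen_aggregation_trace",
    "gen_refolding_yield",
    "gen_spot_grid",
    "gen_western_series",
    "gen_fragment_series",
    "gen_xlink_features",
]

# fixed child-stream ids so assays draw from independent substreams
_STREAMS = {
    "melt": 1,
    "bli": 2,
    "aggregation": 3,
    "refolding": 4,
    "spot": 5,
    "western": 6,
    "fragments": 7,
    "xlink": 8,
}

_DEFAULT_MELT_BASELINES = (-11.0, 0.004, -2.5, 0.006)  # bn0, bn1, bu0, bu1


@dataclass(frozen=True)
class GeneratorConfig:
    """Seed, noise level and truth bookkeeping for one generated dataset."""

    seed: int = 0
    noise_sd: float = 0.0  # signal units of the assay being generated
    n_points: int | None = None
    truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if self.n_points is not None and self.n_points < 4:
            raise InvalidInputError("n_points must be >= 4")


@dataclass(frozen=True)
class Synthetic:
    """A generated dataset together with the ground truth that made it."""

    data: Any
    truth: dict[str, Any]


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stream]])


def gen_melt_curve(
    truth: Mapping[str, Any],
    t_range: tuple[float, float] = (283.15, 353.15),
    config: GeneratorConfig = GeneratorConfig(),
    step: float = 0.25,
    ph: float = 7.5,
    variant_id: str = "synthetic",
) -> Synthetic:
    """Two-state CD melt with linear baselines and Gaussian noise.

    truth: Tm (K), dHm (kcal/mol), optional baselines (bn0, bn1, bu0, bu1).
    """
    tm = float(truth["Tm"])
    dhm = float(truth["dHm"])
    baselines = tuple(truth.get("baselines", _DEFAULT_MELT_BASELINES))
    lo, hi = t_range
    if not lo < tm < hi:
        raise InvalidInputError(f"Tm = {tm} K outside the scan range {t_range}")
    if dhm <= 0:
        raise InvalidInputError("dHm must be positive")
    t = np.arange(lo, hi + step / 2, step)
    y = two_state_signal(t, tm, dhm, *baselines)
    if config.noise_sd > 0:
        y = y + config.noise_sd * _rng(config, "melt").standard_normal(t.size)
    curve = MeltCurve(temperature=t, ellipticity=y, ph=ph, variant_id=variant_id)
    return Synthetic(curve, {"Tm": tm, "dHm": dhm, "baselines": baselines})


def gen_bli_traceset(
    truth: Mapping[str, Any],
    concentrations: Sequence[float],
    config: GeneratorConfig = GeneratorConfig(),
    t_assoc: float = 600.0,
    t_dissoc: float = 900.0,
    dt: float = 1.0,
    variant_id: str = "synthetic",
) -> Synthetic:
    """BLI association/dissociation traces across analyte concentrations.

    truth: kon (1/(M s)), koff (1/s), optional amplitude_max (nm, Langmuir
    saturation amplitude, default 1.0), drift (nm/s association drift
    slope, default 0) and offset (nm dissociation baseline, default 0).
    Association: a*(1-exp(-kobs*t)) + drift*t with kobs = kon*c + koff;
    dissociation: offset + a*exp(-koff*t).
    """
    concentrations = list(concentrations)
    if not concentrations:
        raise InvalidInputError("empty concentration list")
    if len(set(concentrations)) != len(concentrations):
        raise InvalidInputError("concentrations must be distinct")
    if any(c <= 0 for c in concentrations):
        raise InvalidInputError("concentrations must be positive (molar)")
    kon = float(truth["kon"])
    koff = float(truth["koff"])
    if kon <= 0 or koff <= 0:
        raise InvalidInputError("kon and koff must be positive")
    amp_max = float(truth.get("amplitude_max", 1.0))
    drift = float(truth.get("drift", 0.0))
    offset = float(truth.get("offset", 0.0))
    kd = koff / kon
    rng = _rng(config, "bli")
    t_a = np.arange(0.0, t_assoc + dt / 2, dt)
    t_d = np.arange(0.0, t_dissoc + dt / 2, dt)
    traces: list[BLITrace] = []
    for c in concentrations:
        kobs = kon * c + koff
        a = amp_max * c / (c + kd)  # Langmuir occupancy sets the amplitude
        y_a = a * (1.0 - np.exp(-kobs * t_a)) + drift * t_a
        y_d = offset + a * np.exp(-koff * t_d)
        if config.noise_sd > 0:
            y_a = y_a + config.noise_sd * rng.standard_normal(t_a.size)
            y_d = y_d + config.noise_sd * rng.standard_normal(t_d.size)
        traces.append(BLITrace(t_a, y_a, ASSOCIATION, c, variant_id))
        traces.append(BLITrace(t_d, y_d, DISSOCIATION, c, variant_id))
    truth_out = {
        "kon": kon, "koff": koff, "KD": kd,
        "amplitude_max": amp_max, "drift": drift, "offset": offset,
        "kobs": {c: kon * c + koff for c in concentrations},
    }
    return Synthetic(traces, truth_out)


def gen_aggregation_trace(
    assay: str,
    effective_ratio: float,
    config: GeneratorConfig = GeneratorConfig(),
    t_end: float = 600.0,
    dt: float = 1.0,
    variant_id: str = "synthetic",
) -> Synthetic:
    """Light-scattering trace whose summary statistic sits on the wild-type
    calibration at ``effective_ratio``.

    alpha_la: the trace plateaus before 300 s at the 400 s-calibration
    endpoint value, so all four endpoint reads (300/400/500/600 s) return
    it.  aldolase: the trace is linear with the calibrated 50-600 s slope.
    """
    if effective_ratio < 0:
        raise InvalidInputError("effective ratio must be >= 0")
    t = np.arange(0.0, t_end + dt / 2, dt)
    if assay == "alpha_la":
        endpoint = float(ALPHA_LA_400S_CURVE(effective_ratio))
        ramp_end = 250.0  # reaches plateau before the first endpoint read
        y = np.where(t < ramp_end, endpoint * t / ramp_end, endpoint)
        truth = {"effective_ratio": effective_ratio, "endpoint": endpoint}
    elif assay == "aldolase":
        slope = float(ALDOLASE_AGG_CURVE(effective_ratio))
        y = slope * t
        truth = {"effective_ratio": effective_ratio, "slope": slope}
    else:
        raise InvalidInputError(f"unknown aggregation assay {assay!r}")
    if config.noise_sd > 0:
        y = y + config.noise_sd * _rng(config, "aggregation").standard_normal(t.size)
    trace = AggregationTrace(t, y, assay, effective_ratio, variant_id)
    return Synthetic(trace, truth)


def gen_refolding_yield(
    effective_ratio: float,
    config: GeneratorConfig = GeneratorConfig(),
) -> Synthetic:
    """Relative refolding yield drawn from the wild-type refolding
    calibration at ``effective_ratio`` (plus noise)."""
    if effective_ratio < 0:
        raise InvalidInputError("effective ratio must be >= 0")
    y = float(ALDOLASE_REFOLD_CURVE(effective_ratio))
    noisy = y
    if config.noise_sd > 0:
        noisy = y + config.noise_sd * float(_rng(config, "refolding").standard_normal())
    return Synthetic(noisy, {"effective_ratio": effective_ratio, "yield": y})


def gen_spot_grid(
    true_mic: float,
    config: GeneratorConfig = GeneratorConfig(),
    concentrations: Sequence[float] = (500, 1000, 2000, 3000, 4000, 5000, 6000, 7000),
    dilutions: Sequence[float] = (-1, -2, -3, -4, -5),
    iptg: float = 0.5,
    strain_id: str = "synthetic",
) -> Synthetic:
    """Spot-titration grid with growth wherever penicillin < true MIC."""
    if true_mic <= 0:
        raise InvalidInputError("true MIC must be positive")
    conc = np.asarray(concentrations, dtype=float)
    dil = np.asarray(dilutions, dtype=float)
    growth = np.broadcast_to((conc < true_mic)[:, None], (conc.size, dil.size)).copy()
    grid = SpotGrid(conc, dil, growth, iptg=iptg, strain_id=strain_id)
    return Synthetic(grid, {"mic": true_mic})


def gen_western_series(
    true_level: float,
    config: GeneratorConfig = GeneratorConfig(),
    loadings: Sequence[float] = (0.5, 1.0, 2.0, 4.0),
    control_slope: float = 1000.0,
    label: str = "synthetic",
) -> Synthetic:
    """Target and loading-control dilution series for one lysate.

    The target band intensity is ``true_level`` x control slope per unit
    loading, so the target/control slope ratio recovers ``true_level``.
    """
    if true_level <= 0:
        raise InvalidInputError("expression level must be positive")
    ld = np.asarray(loadings, dtype=float)
    rng = _rng(config, "western")
    target = true_level * control_slope * ld
    control = control_slope * ld
    if config.noise_sd > 0:
        target = target + config.noise_sd * rng.standard_normal(ld.size)
        control = control + config.noise_sd * rng.standard_normal(ld.size)
    data = (
        DilutionSeries(ld, target, label=f"{label}:target"),
        DilutionSeries(ld, control, label=f"{label}:control"),
    )
    return Synthetic(data, {"level": true_level})


def gen_fragment_series(
    sequence: str,
    deuteration_per_residue: Sequence[float],
    config: GeneratorConfig = GeneratorConfig(),
    ion_type: str = "c",
    protein_state: str = "free",
) -> Synthetic:
    """Unlabeled and deuterated c- or z-ion centroid series for one state.

    ``deuteration_per_residue`` gives the deuterons carried by each
    residue's backbone amide (fraction in [0, 1]); the N-terminal residue
    and prolines must carry 0 since they have no slowly exchanging NH.
    The deuterated centroid of a fragment is the unlabeled centroid plus
    (D-H mass difference) x (summed deuterons of the residues it covers).
    """
    deut = np.asarray(deuteration_per_residue, dtype=float)
    if deut.size != len(sequence):
        raise InvalidInputError("deuteration list length must match sequence")
    if np.any((deut < 0) | (deut > 1)):
        raise InvalidInputError("per-residue deuteration must be in [0, 1]")
    if deut.size and deut[0] != 0:
        raise InvalidInputError("the N-terminal residue carries no amide deuteron")
    for i, aa in enumerate(sequence):
        if aa == "P" and deut[i] != 0:
            raise InvalidInputError(f"proline at residue {i + 1} cannot be deuterated")
    if ion_type not in ("c", "z"):
        raise InvalidInputError("ion_type must be 'c' or 'z'")
    length = len(sequence)
    rng = _rng(config, "fragments")
    indices = np.arange(1, length + 1)
    unlabeled = np.empty(length)
    deuterons = np.empty(length)
    for n in indices:
        if ion_type == "c":
            frag = sequence[:n]
            covered = deut[1:n]  # amides of residues 2..n
        else:
            frag = sequence[length - n:]
            covered = deut[length - n:]  # residue 1 and prolines carry 0

        unlabeled[n - 1] = pytmass.fast_mass(frag, ion_type=ion_type, charge=0)
        deuterons[n - 1] = float(np.sum(covered))
    labeled = unlabeled + D_H_MASS_DIFF * deuterons
    if config.noise_sd > 0:
        unlabeled = unlabeled + config.noise_sd * rng.standard_normal(length)
        labeled = labeled + config.noise_sd * rng.standard_normal(length)
    pair = (
        FragmentSeries(protein_state, "unlabeled", ion_type, indices, unlabeled, sequence),
        FragmentSeries(protein_state, "deuterated", ion_type, indices, labeled, sequence),
    )
    return Synthetic(pair, {
        "deuteration_per_residue": deut.tolist(),
        "deuterons_per_fragment": deuterons.tolist(),
    })


def gen_xlink_features(
    candidates: Sequence[CrosslinkCandidate],
    label_scheme: str,
    config: GeneratorConfig = GeneratorConfig(),
    intensity: float = 1e6,
) -> Synthetic:
    """Light/heavy (mass, intensity) feature pairs for crosslink candidates.

    label_scheme: "cbdps" (8.05 Da), "abas" (6.02 Da) or "n15" (B-side
    peptide nitrogen count x 0.9970349 Da).  Mass noise is Gaussian with
    config.noise_sd Da on each feature.
    """
    scheme = label_scheme.lower()
    rng = _rng(config, "xlink")
    features: list[tuple[float, float]] = []
    deltas: list[float] = []
    for cand in candidates:
        if scheme == "cbdps":
            delta = 8.05
        elif scheme == "abas":
            delta = 6.02
        elif scheme == "n15":
            delta = cand.peptide_b.n_atoms * N15_N14_MASS_DIFF
        else:
            raise InvalidInputError(f"unknown label scheme {label_scheme!r}")
        light = cand.theoretical_mass
        heavy = light + delta
        if config.noise_sd > 0:
            light = light + config.noise_sd * float(rng.standard_normal())
            heavy = heavy + config.noise_sd * float(rng.standard_normal())
        features.append((light, intensity))
        features.append((heavy, intensity / 2.0))
        deltas.append(delta)
    return Synthetic(features, {"deltas": deltas, "n_pairs": len(deltas)})
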