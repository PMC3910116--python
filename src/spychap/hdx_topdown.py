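"""Top-down hydrogen-deuterium exchange (HDX) analysis.

In a top-down HDX experiment the intact deuterated protein is fragmented by
electron capture dissociation into c-ions (N-terminal, covering residues
1..n) and z-ions (C-terminal, covering the last n residues).  The deuteron
content of a fragment is the centroid-mass shift between the deuterated and
unlabeled forms divided by the D-H mass difference.  Because consecutive
fragments differ by one residue, the deuteron increment between c_{n-1} and
c_n attributes exchange to the backbone amide of residue n (mirrored from
the C terminus for z-ions).

Conventions used throughout:

* exchangeable sites are backbone amide NH protons; prolines (no NH) and
  the N-terminal residue (fast-exchanging amine) are excluded;
* a c_n fragment carries the amides of residues 2..n; a z_n fragment
  (residues L-n+1..L) carries the amides of its residues, again excluding
  prolines and residue 1;
* "protection" is positive when the client-bound complex takes up fewer
  deuterons than the free protein at that residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .constants import D_H_MASS_DIFF
from .errors import DataInconsistencyError, InvalidInputError

__all__ = [
    "FragmentSeries",
    "ProtectionMap",
    "deuteron_count",
    "fractional_deuteration",
    "exchangeable_amides",
    "per_residue_deuterons",
    "differential_map",
    "protected_fraction",
]

FREE = "free"
COMPLEX = "complex"
UNLABELED = "unlabeled"
DEUTERATED = "deuterated"

#: Deuterated centroids lighter than unlabeled by more than this are data
#: inconsistencies rather than noise.
_MASS_TOLERANCE_DA = 0.1


@dataclass(frozen=True)
class FragmentSeries:
    """Ordered c- or z-ion centroid masses for one protein state/labeling."""

    protein_state: str  # "free" | "complex"
    labeling: str  # "unlabeled" | "deuterated"
    ion_type: str  # "c" | "z"
    fragment_index: np.ndarray  # residues from the respective terminus
    centroid_mass: np.ndarray  # Da
    sequence: str = ""  # full protein sequence (mature numbering)

    def __post_init__(self):
        idx = np.asarray(self.fragment_index, dtype=int)
        m = np.asarray(self.centroid_mass, dtype=float)
        object.__setattr__(self, "fragment_index", idx)
        object.__setattr__(self, "centroid_mass", m)
        if self.protein_state not in (FREE, COMPLEX):
            raise InvalidInputError(f"unknown state {self.protein_state!r}")
        if self.labeling not in (UNLABELED, DEUTERATED):
            raise InvalidInputError(f"unknown labeling {self.labeling!r}")
        if self.ion_type not in ("c", "z"):
            raise InvalidInputError(f"ion type must be 'c' or 'z'")
        if idx.size != m.size:
            raise InvalidInputError("index and mass lengths differ")
        if idx.size and np.any(np.diff(idx) <= 0):
            raise InvalidInputError("fragment indices must strictly increase")
        if not np.all(np.isfinite(m)):
            raise InvalidInputError("centroid masses must be finite")


@dataclass(frozen=True)
class ProtectionMap:
    """Differential protection between free and client-bound states."""

    residues: np.ndarray  # residue numbers with an attribution
    protection: np.ndarray  # deuterons protected (free - complex), per residue
    per_fragment_delta: dict[str, dict[int, float]] = field(default_factory=dict)
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def protected_residues(self, min_deuterons: float = 0.5) -> np.ndarray:
        return self.residues[self.protection >= min_deuterons]


def deuteron_count(unlabeled_mass: float, labeled_mass: float) -> float:
    """Deuterons from the centroid shift: (labeled - unlabeled)/(mD - mH)."""
    if unlabeled_mass <= 0 or labeled_mass <= 0:
        raise InvalidInputError("centroid masses must be positive")
    if labeled_mass < unlabeled_mass - _MASS_TOLERANCE_DA:
        raise DataInconsistencyError(
            f"deuterated centroid {labeled_mass:.4f} Da lighter than unlabeled "
            f"{unlabeled_mass:.4f} Da beyond {_MASS_TOLERANCE_DA} Da"
        )
    return (labeled_mass - unlabeled_mass) / D_H_MASS_DIFF


def fractional_deuteration(
    deuterons: float, exchangeable: int, d2o_fraction: float = 0.8
) -> float:
    """Deuterons per exchangeable amide, corrected for the D2O fraction."""
    if exchangeable <= 0:
        raise InvalidInputError("no exchangeable amide sites in fragment")
    if not 0.0 < d2o_fraction <= 1.0:
        raise InvalidInputError("d2o_fraction must be in (0, 1]")
    return deuterons / (exchangeable * d2o_fraction)


def exchangeable_amides(fragment_sequence: str, is_protein_nterm: bool = True) -> int:
    """Backbone amides in a fragment minus prolines, minus the protein
    N-terminal residue when the fragment contains it."""
    if not fragment_sequence:
        raise InvalidInputError("empty fragment sequence")
    n = len(fragment_sequence) - fragment_sequence.count("P")
    if is_protein_nterm and fragment_sequence[0] != "P":
        n -= 1
    return max(n, 0)


def _series_deuterons(
    unlabeled: FragmentSeries, labeled: FragmentSeries
) -> dict[int, float]:
    """Per-fragment deuteron counts from an unlabeled/deuterated series pair."""
    if unlabeled.ion_type != labeled.ion_type:
        raise InvalidInputError("series pair mixes ion types")
    u = dict(zip(unlabeled.fragment_index.tolist(), unlabeled.centroid_mass))
    d = dict(zip(labeled.fragment_index.tolist(), labeled.centroid_mass))
    common = sorted(set(u) & set(d))
    return {n: deuteron_count(u[n], d[n]) for n in common}


def per_residue_deuterons(
    unlabeled: FragmentSeries, labeled: FragmentSeries, protein_length: int
) -> dict[int, float]:
    """Attribute deuterons to residues from consecutive-fragment increments.

    For c-ions the increment between c_{n-1} and c_n is assigned to residue
    n; for z-ions the increment between z_{n-1} and z_n is assigned to
    residue L-n+1.  Requires consecutive fragment indices; gaps simply leave
    those residues unattributed.
    """
    counts = _series_deuterons(unlabeled, labeled)
    out: dict[int, float] = {}
    for n in sorted(counts):
        prev = counts.get(n - 1, 0.0 if n == 1 else None)
        if prev is None:
            continue
        inc = counts[n] - prev
        if unlabeled.ion_type == "c":
            residue = n
        else:
            residue = protein_length - n + 1
        out[residue] = inc
    return out


def differential_map(
    free: Iterable[FragmentSeries],
    complex_: Iterable[FragmentSeries],
    protein_length: int | None = None,
) -> ProtectionMap:
    """Per-fragment and per-residue protection of the complex vs free state.

    ``free`` and ``complex_`` each hold the unlabeled and deuterated series
    (c and/or z).  Fragment indices present in only one state are excluded
    with a warning.  Positive protection at a residue corresponds to a sharp
    drop between consecutive c-ions (rise for z-ions) in the complex's
    differential deuteration plot.
    """
    free_pairs = _pair_by_ion(list(free))
    cx_pairs = _pair_by_ion(list(complex_))
    warnings: list[str] = []
    per_fragment: dict[str, dict[int, float]] = {}
    residue_prot: dict[int, float] = {}
    length = protein_length
    for ion in sorted(set(free_pairs) | set(cx_pairs)):
        if ion not in free_pairs or ion not in cx_pairs:
            warnings.append(f"{ion}-series present in only one state; skipped")
            continue
        fu, fd = free_pairs[ion]
        cu, cd = cx_pairs[ion]
        if length is None:
            if not fu.sequence:
                raise InvalidInputError(
                    "protein_length or a series sequence is required"
                )
            length = len(fu.sequence)
        d_free = _series_deuterons(fu, fd)
        d_cx = _series_deuterons(cu, cd)
        common = sorted(set(d_free) & set(d_cx))
        dropped = sorted(set(d_free) ^ set(d_cx))
        if dropped:
            warnings.append(
                f"unmatched {ion}-fragment indices excluded: {dropped}"
            )
        per_fragment[ion] = {n: d_cx[n] - d_free[n] for n in common}
        # residue attribution from consecutive increments, protection = free - complex
        free_res = per_residue_deuterons(
            _subset(fu, common), _subset(fd, common), length
        )
        cx_res = per_residue_deuterons(
            _subset(cu, common), _subset(cd, common), length
        )
        for res in set(free_res) & set(cx_res):
            prot = free_res[res] - cx_res[res]
            # where both ion series cover a residue they agree on clean
            # data; average to be robust to noise
            if res in residue_prot:
                residue_prot[res] = 0.5 * (residue_prot[res] + prot)
            else:
                residue_prot[res] = prot
    residues = np.array(sorted(residue_prot), dtype=int)
    protection = np.array([residue_prot[r] for r in residues])
    return ProtectionMap(
        residues=residues,
        protection=protection,
        per_fragment_delta=per_fragment,
        warnings=tuple(warnings),
    )


def _pair_by_ion(
    series: list[FragmentSeries],
) -> dict[str, tuple[FragmentSeries, FragmentSeries]]:
    pairs: dict[str, dict[str, FragmentSeries]] = {}
    for s in series:
        pairs.setdefault(s.ion_type, {})[s.labeling] = s
    out = {}
    for ion, lab in pairs.items():
        if UNLABELED in lab and DEUTERATED in lab:
            out[ion] = (lab[UNLABELED], lab[DEUTERATED])
    return out


def _subset(series: FragmentSeries, indices: list[int]) -> FragmentSeries:
    mask = np.isin(series.fragment_index, indices)
    return FragmentSeries(
        protein_state=series.protein_state,
        labeling=series.labeling,
        ion_type=series.ion_type,
        fragment_index=series.fragment_index[mask],
        centroid_mass=series.centroid_mass[mask],
        sequence=series.sequence,
    )


def protected_fraction(
    unlabeled: FragmentSeries,
    labeled: FragmentSeries,
    sequence: str,
    d2o_fraction: float = 0.8,
    threshold: float = 0.2,
) -> float:
    """Percentage of exchangeable amides scored as protected.

    An amide is protected when its fractional deuteration (per-residue
    deuterons corrected for the D2O fraction) is at or below ``threshold``
    (default 0.2).  Used as an apparent-flexibility metric: fewer protected
    protons means a more disordered protein.
    """
    if not sequence:
        raise InvalidInputError("protein sequence required")
    counts = _series_deuterons(unlabeled, labeled)
    if not counts:
        raise InvalidInputError("empty fragment series")
    res_deut = per_residue_deuterons(unlabeled, labeled, len(sequence))
    scored = []
    for res, deut in res_deut.items():
        aa = sequence[res - 1]
        if aa == "P" or res == 1:
            continue  # no exchangeable backbone NH
        frac = fractional_deuteration(max(deut, 0.0), 1, d2o_fraction)
        scored.append(frac <= threshold)
    if not scored:
        raise InvalidInputError("no exchangeable residues covered by the series")
    return 100.0 * float(np.mean(scored))


def read_fragment_table(path) -> list[FragmentSeries]:
    """Read a delimited fragment table
    (state, labeling, ion_type, index, centroid_mass[, sequence])."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"state", "labeling", "ion_type", "index", "centroid_mass"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"fragment table missing columns: {sorted(missing)}")
    out = []
    for (state, labeling, ion), grp in df.groupby(
        ["state", "labeling", "ion_type"], sort=False
    ):
        grp = grp.sort_values("index")
        seq = str(grp["sequence"].iloc[0]) if "sequence" in grp.columns else ""
        out.append(
            FragmentSeries(
                protein_state=str(state),
                labeling=str(labeling),
                ion_type=str(ion),
                fragment_index=grp["index"].to_numpy(int),
                centroid_mass=grp["centroid_mass"].to_numpy(float),
                sequence=seq,
            )
        )
    return out
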