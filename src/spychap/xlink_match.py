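"""Crosslinked-peptide candidate enumeration and isotope-coded selection.

Given two protein sequences, an enzyme digestion and a crosslinking
chemistry, this module enumerates every theoretical inter-protein peptide
pair whose residues satisfy the chemistry's reactivity rule, computes its
monoisotopic mass, and selects observed MS features by the chemistry's
isotope-pair mass-difference signature:

* CBDPS-H8/D8 (amine-reactive, 14 A): light/heavy pairs split by 8.05 Da;
* ABAS-12C6/13C6 (photo-reactive, 7 A): pairs split by 6.02 Da;
* zero-length chemistries (EDC, PICUP) with an equimolar 14N/15N-labeled
  client: pairs split by (client-peptide nitrogen count) x 0.9970349 Da.

Candidate-to-feature matching is scored by the relative mass error in ppm.
Monoisotopic masses and elemental compositions come from pyteomics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as pytmass

from .constants import HYDROGEN_MONO, N15_N14_MASS_DIFF, WATER_MONO
from .errors import InvalidInputError

__all__ = [
    "PeptideFragment",
    "CrosslinkCandidate",
    "digest",
    "peptide_mass",
    "peptide_nitrogens",
    "enumerate_candidates",
    "isotope_pair_select",
    "match_observed",
    "candidates_to_table",
    "CHEMISTRIES",
    "ISOTOPE_DELTAS",
]

TRYPSIN = "trypsin"
PROTEINASE_K = "proteinase_k"
CHEMISTRIES = ("CBDPS", "ABAS", "EDC", "PICUP")
#: Printed light/heavy mass splits (Da) for the isotope-coded reagents.
ISOTOPE_DELTAS = {"cbdps": 8.05, "abas": 6.02}

_STD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PeptideFragment:
    """A proteolytic peptide located in its parent's mature sequence."""

    parent_protein: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    sequence: str
    missed_cleavages: int = 0

    def __post_init__(self):
        bad = set(self.sequence) - _STD_RESIDUES
        if bad:
            raise InvalidInputError(f"non-standard residues {sorted(bad)}")
        if self.end - self.start + 1 != len(self.sequence):
            raise InvalidInputError(
                f"coordinates {self.start}-{self.end} inconsistent with "
                f"{len(self.sequence)}-residue sequence"
            )

    @property
    def monoisotopic_mass(self) -> float:
        return peptide_mass(self.sequence)

    @property
    def n_atoms(self) -> int:
        return peptide_nitrogens(self.sequence)

    @property
    def is_protein_nterm(self) -> bool:
        return self.start == 1


@dataclass(frozen=True)
class CrosslinkCandidate:
    """A theoretical crosslinked peptide pair with its isotope signature."""

    peptide_a: PeptideFragment
    peptide_b: PeptideFragment
    linked_residue_a: int  # residue number in protein A
    linked_residue_b: int
    chemistry: str
    theoretical_mass: float  # Da
    isotope_delta: float = float("nan")  # Da, light/heavy split
    observed_mass: float | None = None
    ppm_error: float = float("nan")


def digest(
    sequence: str,
    enzyme: str,
    parent: str = "",
    max_missed: int = 0,
    min_len: int = 1,
    max_len: int = 50,
) -> list[PeptideFragment]:
    """In-silico digestion with 1-based coordinates.

    Trypsin cleaves after K or R (including before proline); peptides up to
    ``max_missed`` missed cleavages are reported.  Proteinase K is modeled
    as unspecific: every substring with length in [min_len, max_len].
    """
    if not sequence:
        raise InvalidInputError("empty sequence")
    if max_missed < 0:
        raise InvalidInputError("max_missed must be >= 0")
    bad = set(sequence) - _STD_RESIDUES
    if bad:
        raise InvalidInputError(f"non-standard residues {sorted(bad)}")
    frags: list[PeptideFragment] = []
    if enzyme == TRYPSIN:
        # cut positions (0-based index after which a cut occurs), plus ends
        cuts = [0] + [i + 1 for i, aa in enumerate(sequence) if aa in "KR"]
        if cuts[-1] != len(sequence):
            cuts.append(len(sequence))
        for i in range(len(cuts) - 1):
            for j in range(i + 1, min(i + 2 + max_missed, len(cuts))):
                start, end = cuts[i], cuts[j]
                seq = sequence[start:end]
                if min_len <= len(seq) <= max_len:
                    frags.append(
                        PeptideFragment(parent, start + 1, end, seq,
                                        missed_cleavages=j - i - 1)
                    )
    elif enzyme == PROTEINASE_K:
        for length in range(min_len, min(max_len, len(sequence)) + 1):
            for start in range(len(sequence) - length + 1):
                frags.append(
                    PeptideFragment(
                        parent, start + 1, start + length,
                        sequence[start:start + length],
                    )
                )
    else:
        raise InvalidInputError(f"unknown enzyme {enzyme!r}")
    return frags


def peptide_mass(sequence: str) -> float:
    """Neutral monoisotopic peptide mass (residue masses + water), Da."""
    try:
        return float(pytmass.fast_mass(sequence))
    except Exception as exc:
        raise InvalidInputError(f"cannot compute mass of {sequence!r}: {exc}") from exc


def peptide_nitrogens(sequence: str) -> int:
    """Total nitrogen atoms (backbone plus side chains)."""
    try:
        comp = pytmass.Composition(sequence=sequence)
    except Exception as exc:
        raise InvalidInputError(
            f"cannot compute composition of {sequence!r}: {exc}"
        ) from exc
    return int(comp.get("N", 0))


def _amine_sites(pep: PeptideFragment) -> list[int]:
    """Lysine side chains plus the protein N-terminal alpha-amine."""
    sites = [pep.start + i for i, aa in enumerate(pep.sequence) if aa == "K"]
    if pep.is_protein_nterm and pep.start not in sites:
        sites.insert(0, pep.start)
    return sites


def _carboxyl_sites(pep: PeptideFragment, protein_length: int | None) -> list[int]:
    """Aspartate/glutamate side chains plus the protein C-terminal carboxyl."""
    sites = [pep.start + i for i, aa in enumerate(pep.sequence) if aa in "DE"]
    if protein_length is not None and pep.end == protein_length:
        if pep.end not in sites:
            sites.append(pep.end)
    return sites


def enumerate_candidates(
    peptides_a: Iterable[PeptideFragment],
    peptides_b: Iterable[PeptideFragment],
    chemistry: str,
    linker_added_mass: float = 0.0,
    protein_b_length: int | None = None,
    isotope_scheme: str | None = None,
) -> list[CrosslinkCandidate]:
    """Enumerate inter-protein candidates under a chemistry's reactivity rule.

    CBDPS links two amines (K side chain or protein N-terminus) and adds the
    configured linker mass.  ABAS links an amine on the A side to any residue
    on the B side (photo end), also adding its linker mass.  EDC condenses a
    carboxyl (D/E or protein C-terminus, B side) with an amine (A side),
    losing one water.  PICUP couples two tyrosines, losing two hydrogens.
    Isotope deltas: CBDPS 8.05 Da, ABAS 6.02 Da; for the zero-length
    chemistries with a 15N-labeled B-side protein the delta is the B
    peptide's nitrogen count x 0.9970349 Da (isotope_scheme="n15").
    """
    chemistry = chemistry.upper()
    if chemistry not in CHEMISTRIES:
        raise InvalidInputError(f"unknown chemistry {chemistry!r}")
    out: list[CrosslinkCandidate] = []
    peptides_b = list(peptides_b)
    for pa in peptides_a:
        for pb in peptides_b:
            if chemistry == "CBDPS":
                pairs = [(ra, rb) for ra in _amine_sites(pa)
                         for rb in _amine_sites(pb)]
                mass_fn = lambda: pa.monoisotopic_mass + pb.monoisotopic_mass + linker_added_mass
                delta = ISOTOPE_DELTAS["cbdps"]
            elif chemistry == "ABAS":
                # NHS end on the A side, photo end anywhere on the B side
                pairs = [(ra, rb) for ra in _amine_sites(pa)
                         for rb in range(pb.start, pb.end + 1)]
                mass_fn = lambda: pa.monoisotopic_mass + pb.monoisotopic_mass + linker_added_mass
                delta = ISOTOPE_DELTAS["abas"]
            elif chemistry == "EDC":
                pairs = [(ra, rb) for ra in _amine_sites(pa)
                         for rb in _carboxyl_sites(pb, protein_b_length)]
                mass_fn = lambda: pa.monoisotopic_mass + pb.monoisotopic_mass - WATER_MONO
                delta = float("nan")
            else:  # PICUP
                tyr_a = [pa.start + i for i, aa in enumerate(pa.sequence) if aa == "Y"]
                tyr_b = [pb.start + i for i, aa in enumerate(pb.sequence) if aa == "Y"]
                pairs = [(ra, rb) for ra in tyr_a for rb in tyr_b]
                mass_fn = lambda: pa.monoisotopic_mass + pb.monoisotopic_mass - 2.0 * HYDROGEN_MONO
                delta = float("nan")
            if not pairs:
                continue
            if isotope_scheme == "n15" or (
                isotope_scheme is None and chemistry in ("EDC", "PICUP")
            ):
                delta = pb.n_atoms * N15_N14_MASS_DIFF
            m = mass_fn()
            for ra, rb in pairs:
                out.append(
                    CrosslinkCandidate(
                        peptide_a=pa, peptide_b=pb,
                        linked_residue_a=ra, linked_residue_b=rb,
                        chemistry=chemistry, theoretical_mass=m,
                        isotope_delta=delta,
                    )
                )
    return out


def isotope_pair_select(
    features: Sequence[tuple[float, float]],
    scheme: str,
    candidate_nitrogens: int | None = None,
    tol: float = 0.01,
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Select feature pairs split by the scheme's light/heavy mass difference.

    ``features`` are (mass, intensity) tuples; ``scheme`` is "cbdps"
    (8.05 Da), "abas" (6.02 Da) or "n15" (candidate_nitrogens x 0.9970349
    Da).  Returns every (light, heavy) pair whose mass difference matches
    within ``tol``.
    """
    if tol <= 0:
        raise InvalidInputError("tol must be positive")
    scheme = scheme.lower()
    if scheme == "n15":
        if candidate_nitrogens is None:
            raise InvalidInputError(
                "n15 scheme requires the client peptide's nitrogen count"
            )
        delta = candidate_nitrogens * N15_N14_MASS_DIFF
    elif scheme in ISOTOPE_DELTAS:
        delta = ISOTOPE_DELTAS[scheme]
    else:
        raise InvalidInputError(f"unknown isotope scheme {scheme!r}")
    feats = sorted(features, key=lambda f: f[0])
    masses = np.array([f[0] for f in feats])
    pairs = []
    for i, (m, _) in enumerate(feats):
        target = m + delta
        js = np.nonzero(np.abs(masses - target) <= tol)[0]
        for j in js:
            if j != i:
                pairs.append((feats[i], feats[j]))
    return pairs


def match_observed(
    candidates: Iterable[CrosslinkCandidate],
    observed_mass: float,
    ppm_tol: float = 10.0,
) -> list[CrosslinkCandidate]:
    """Candidates within ppm_tol of an observed mass, sorted by |ppm error|."""
    if ppm_tol <= 0:
        raise InvalidInputError("ppm_tol must be positive")
    scored = []
    for cand in candidates:
        ppm = (observed_mass - cand.theoretical_mass) / cand.theoretical_mass * 1e6
        if abs(ppm) <= ppm_tol:
            scored.append(replace(cand, observed_mass=observed_mass, ppm_error=ppm))
    scored.sort(key=lambda c: abs(c.ppm_error))
    return scored


def candidates_to_table(candidates: Iterable[CrosslinkCandidate]) -> pd.DataFrame:
    """Crosslink report: mass, ppm error, per-protein coordinates, linked
    residues, sequences, chemistry."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "mass_da": c.theoretical_mass,
                "observed_da": c.observed_mass,
                "delta_ppm": c.ppm_error,
                "protein_1": c.peptide_a.parent_protein,
                "start_1": c.peptide_a.start,
                "end_1": c.peptide_a.end,
                "residue_1": c.linked_residue_a,
                "sequence_1": c.peptide_a.sequence,
                "protein_2": c.peptide_b.parent_protein,
                "start_2": c.peptide_b.start,
                "end_2": c.peptide_b.end,
                "residue_2": c.linked_residue_b,
                "sequence_2": c.peptide_b.sequence,
                "chemistry": c.chemistry,
                "isotope_delta_da": c.isotope_delta,
            }
        )
    return pd.DataFrame(rows)
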