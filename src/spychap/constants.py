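"""Physical constants used throughout the package.

All thermodynamic math is done in kcal and Kelvin; all mass spectrometry
math in monoisotopic Daltons.
"""

#: Gas constant in kcal/(K*mol); kcal units match the stability tables.
R_KCAL: float = 1.987204e-3

#: Additive offset between Celsius and Kelvin.
KELVIN_OFFSET: float = 273.15

#: Monoisotopic mass of water (Da), the condensation loss per peptide bond.
WATER_MONO: float = 18.010565

#: Monoisotopic mass of a hydrogen atom (Da).
HYDROGEN_MONO: float = 1.007825

#: Deuterium minus protium monoisotopic mass difference (Da).
D_H_MASS_DIFF: float = 1.006277

#: 15N minus 14N monoisotopic mass difference (Da).
N15_N14_MASS_DIFF: float = 0.9970349


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + KELVIN_OFFSET


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - KELVIN_OFFSET
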