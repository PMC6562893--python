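"""Physical constants and unit conversions (atomic units internally).

All quantities inside the package are in Hartree atomic units:
lengths in bohr, masses in electron masses (m_e), energies in hartree
(E_h), angular frequencies in E_h/hbar.
"""

# CODATA-2018 values
BOHR_PER_ANGSTROM = 1.8897259886
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

#: electron masses per unified atomic mass unit
ME_PER_AMU = 1822.888486209

#: E_h/hbar -> cm^-1 (hartree expressed in wavenumbers)
WAVENUMBER_PER_HARTREE = 219474.6313632

#: Gaussian width assigned to translation/rotation modes: they are modelled
#: as harmonic-oscillator ground states at this angular frequency, which
#: localizes and orients the molecule without introducing extra structure.
TRANS_ROT_FREQUENCY = 0.5  # E_h/hbar

#: Isotope-averaged standard atomic masses (u); D and T are the exact
#: isotope masses so that isotopologues can be built by relabelling.
ATOMIC_MASSES_AMU = {
    "H": 1.008,
    "D": 2.014101778,
    "T": 3.016049281,
    "He": 4.002602,
    "Li": 6.94,
    "Be": 9.0121831,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403163,
    "Ne": 20.1797,
    "Na": 22.98976928,
    "Mg": 24.305,
    "Al": 26.9815385,
    "Si": 28.085,
    "P": 30.973761998,
    "S": 32.06,
    "Cl": 35.45,
    "Ar": 39.948,
}

#: Nuclear charges used in cube-file atom records.
ATOMIC_NUMBERS = {
    "H": 1, "D": 1, "T": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6,
    "N": 7, "O": 8, "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13,
    "Si": 14, "P": 15, "S": 16, "Cl": 17, "Ar": 18,
}


def mass_of(label: str) -> float:
    """Mass of an element/isotope label in electron masses."""
    try:
        return ATOMIC_MASSES_AMU[label] * ME_PER_AMU
    except KeyError:
        raise KeyError(f"no mass tabulated for element/isotope label {label!r}") from None
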