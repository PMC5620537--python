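"""Physical constants for peptide mass spectrometry.

Monoisotopic values throughout. Residue masses are taken from the standard
amino-acid table shipped with pyteomics; the few composite constants below
are fixed here so every module agrees to the last digit.
"""

from pyteomics import mass as _pmass

#: Mass of a proton (Da) — charge carrier for positive-mode ions.
PROTON = 1.007276

#: Monoisotopic mass of water (Da) — released on peptide-bond formation.
WATER = 18.010565

#: Monoisotopic mass of ammonia (Da) — b→c ion offset.
NH3 = 17.026549

#: y→z-dot ion offset (loss of NH2, Da). z ions are modeled as the
#: radical z-dot species observed in ETD.
Z_OFFSET = 16.018724

#: Average spacing between adjacent isotope peaks of a singly-charged ion
#: (Da); ~mass difference between 13C and 12C.
ISOTOPE_SPACING = 1.0033548

#: Monoisotopic residue masses of the 20 canonical amino acids (Da).
RESIDUE_MASS: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}
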