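"""Theoretical peptide and fragment-ion mass engine with spectrum annotation.

The calculator answers the questions asked during manual spectral
validation: what does this sequence weigh, what are its b/y (CAD/HCD) or
c/z (ETD) fragment ions at a given charge, and which spectrum peaks match
them. Modifications are positioned mass deltas that can be moved between
candidate sites — the core move when testing phosphorylation-site
localization against the same MS/MS spectrum.

Conventions: z ions are the z-dot radical species (y − 16.018724 Da);
c = b + NH3. Modification position 0 is the N-terminus, 1..n the residues,
n+1 the C-terminus; at most one modification per position.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .constants import NH3, PROTON, RESIDUE_MASS, WATER, Z_OFFSET
from .errors import DataError
from .model import Peak, Spectrum

SERIES = ("b", "y", "c", "z")
N_TERMINAL_SERIES = {"b", "c"}

#: Default modification vocabulary (label -> monoisotopic delta, Da).
MOD_DELTAS: dict[str, float] = {
    "phospho": 79.966331,
    "oxidation": 15.994915,
    "carbamidomethyl": 57.021464,
    "acetyl": 42.010565,
    "methyl": 14.015650,
    "tmt6": 229.162932,
    "itraq4": 144.102063,
}


@dataclass(frozen=True)
class Modification:
    position: int  # 0 = N-term, 1..n = residue, n+1 = C-term
    delta: float   # monoisotopic mass shift (Da)
    label: str


@dataclass(frozen=True)
class Peptide:
    sequence: str
    mods: tuple[Modification, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError("empty peptide sequence")
        bad = set(self.sequence) - set(RESIDUE_MASS)
        if bad:
            raise DataError(f"unknown residue(s): {sorted(bad)}")
        object.__setattr__(self, "mods", tuple(self.mods))
        n = len(self.sequence)
        positions = [m.position for m in self.mods]
        if any(p < 0 or p > n + 1 for p in positions):
            raise DataError("modification position out of range")
        if len(set(positions)) != len(positions):
            raise DataError("at most one modification per position")

    def __len__(self) -> int:
        return len(self.sequence)

    def mods_text(self) -> str:
        """Canonical "pos: label" list, e.g. ``4: phospho; 7: oxidation``."""
        return "; ".join(f"{m.position}: {m.label}"
                         for m in sorted(self.mods, key=lambda m: m.position))


def parse_mods(text: str, vocabulary: Optional[dict[str, float]] = None
               ) -> tuple[Modification, ...]:
    """Parse "4:phospho; 7:oxidation" into Modification objects."""
    vocab = MOD_DELTAS if vocabulary is None else vocabulary
    out = []
    for item in filter(None, (t.strip() for t in text.split(";"))):
        pos_s, label = (x.strip() for x in item.split(":", 1))
        if label not in vocab:
            raise DataError(f"unknown modification label {label!r}")
        out.append(Modification(int(pos_s), vocab[label], label))
    return tuple(out)


@dataclass(frozen=True)
class FragmentIon:
    series: str
    index: int
    charge: int
    neutral_mass: float

    @property
    def mz(self) -> float:
        return (self.neutral_mass + self.charge * PROTON) / self.charge

    @property
    def name(self) -> str:
        plus = "+" * self.charge
        return f"{self.series}{self.index}{plus}"


@dataclass(frozen=True)
class IonMatch:
    fragment: FragmentIon
    peak: Peak
    error_ppm: float


def peptide_mass(p: Peptide) -> float:
    """Monoisotopic neutral mass: residues + water + modification deltas."""
    return (sum(RESIDUE_MASS[a] for a in p.sequence) + WATER
            + sum(m.delta for m in p.mods))


def _prefix_masses(p: Peptide) -> np.ndarray:
    """Cumulative residue+mod mass of the first i residues (i = 0..n).

    The N-terminal mod (position 0) belongs to every prefix; a residue mod at
    position j enters prefixes with i >= j.
    """
    n = len(p)
    deltas = np.zeros(n + 2)
    for m in p.mods:
        deltas[m.position] += m.delta
    res = np.array([RESIDUE_MASS[a] for a in p.sequence])
    prefix = np.concatenate([[0.0], np.cumsum(res + deltas[1:n + 1])])
    return prefix + deltas[0]


def fragment_ions(
    p: Peptide,
    series_set: Iterable[str] = ("b", "y"),
    max_charge: int = 1,
) -> list[FragmentIon]:
    """All fragment ions for the requested series at charges 1..max_charge.

    Cleavage index i runs 1..n−1. Modifications on or before the cleavage
    point go to the N-terminal-side ion (b/c); after it, to the C-terminal
    side (y/z). The C-terminal mod (position n+1) always stays with y/z.
    """
    series_set = tuple(series_set)
    if not series_set:
        raise DataError("series_set must not be empty")
    unknown = set(series_set) - set(SERIES)
    if unknown:
        raise DataError(f"unknown ion series {sorted(unknown)}")
    if max_charge < 1:
        raise DataError("max_charge must be >= 1")

    n = len(p)
    prefix = _prefix_masses(p)
    total = peptide_mass(p)
    ions = []
    for series in series_set:
        for i in range(1, n):
            if series in N_TERMINAL_SERIES:
                base = prefix[i]  # b-ion neutral: residues 1..i (+ their mods)
                neutral = base + (NH3 if series == "c" else 0.0)
            else:
                base = total - prefix[n - i]  # y-ion neutral: last i residues + water
                neutral = base - (Z_OFFSET if series == "z" else 0.0)
            for z in range(1, max_charge + 1):
                ions.append(FragmentIon(series, i, z, neutral))
    return ions


def reposition_mod(p: Peptide, label: str, new_position: int) -> Peptide:
    """Move the unique modification ``label`` to ``new_position``.

    Total peptide mass is invariant; only fragments whose cleavage point lies
    between the old and new site change.
    """
    hits = [m for m in p.mods if m.label == label]
    if not hits:
        raise DataError(f"no modification labelled {label!r}")
    if len(hits) > 1:
        raise DataError(f"modification label {label!r} is ambiguous")
    mod = hits[0]
    occupied = {m.position for m in p.mods} - {mod.position}
    if new_position in occupied:
        raise DataError(f"position {new_position} is already modified")
    new_mods = tuple(replace(m, position=new_position) if m is mod else m
                     for m in p.mods)
    return Peptide(p.sequence, new_mods)


def candidate_site_peptides(
    p: Peptide, label: str, allowed_residues: Iterable[str]
) -> list[Peptide]:
    """All C(m, k) placements of the k ``label`` mods over the m allowed sites.

    Order is deterministic: lexicographic by the sorted position vector.
    Every returned isoform has the same total mass — they differ only in
    fragment masses, which is what site localization leans on.
    """
    allowed = set(allowed_residues)
    labelled = [m for m in p.mods if m.label == label]
    others = tuple(m for m in p.mods if m.label != label)
    if not labelled:
        raise DataError(f"peptide carries no {label!r} modification")
    k = len(labelled)
    occupied = {m.position for m in others}
    sites = [i + 1 for i, aa in enumerate(p.sequence)
             if aa in allowed and (i + 1) not in occupied]
    if len(sites) < k:
        raise DataError(f"only {len(sites)} candidate sites for {k} mods")
    delta = labelled[0].delta
    out = []
    for combo in itertools.combinations(sites, k):
        mods = others + tuple(Modification(pos, delta, label) for pos in combo)
        out.append(Peptide(p.sequence, mods))
    return out


def annotate_spectrum(
    s: Spectrum, ions: Sequence[FragmentIon], tol_ppm: float = 10.0
) -> list[IonMatch]:
    """Match each theoretical ion to its nearest peak within ``tol_ppm``.

    One peak may serve several ions; each ion gets at most one peak. Ties in
    distance break toward the lower-m/z peak. Matches are returned sorted by
    series, index, then charge.
    """
    if tol_ppm <= 0:
        raise DataError("tolerance must be positive")
    if not s.centroided:
        raise DataError("annotation requires a centroided spectrum")
    matches = []
    order = {ser: k for k, ser in enumerate(SERIES)}
    for ion in sorted(ions, key=lambda f: (order[f.series], f.index, f.charge)):
        idx = _nearest_within(s.mz, ion.mz, ion.mz * tol_ppm * 1e-6)
        if idx is None:
            continue
        peak = Peak(float(s.mz[idx]), float(s.intensity[idx]))
        err = (peak.mz - ion.mz) / ion.mz * 1e6
        matches.append(IonMatch(ion, peak, err))
    return matches


def _nearest_within(mz: np.ndarray, target: float, half: float) -> Optional[int]:
    if mz.size == 0:
        return None
    j = int(np.searchsorted(mz, target))
    best, best_d = None, None
    for idx in (j - 1, j):
        if 0 <= idx < mz.size:
            d = abs(mz[idx] - target)
            # strict < keeps the tie on the lower-m/z (earlier) candidate
            if d <= half and (best_d is None or d < best_d):
                best, best_d = idx, d
    return best
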