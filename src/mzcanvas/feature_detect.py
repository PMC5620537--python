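"""Unbiased MS1 feature detection.

A *feature* is an isotopic cluster (envelope) traced over a contiguous
retention-time range, with a charge state, an integrated area, and the
MS/MS scans whose precursors fall on it. Detection is two-stage:

1. per-scan envelope detection — greedy highest-intensity-first grouping of
   peaks at 1.0033548/z spacings, scored against an averagine-predicted
   isotope pattern by cosine similarity;
2. cross-scan linking of envelopes with matching charge and monoisotopic
   m/z, tolerating short dropouts.

Features never claimed by a peptide-spectrum match can then be mined and
re-submitted for sequence assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .averagine import envelope_cosine
from .constants import ISOTOPE_SPACING, PROTON
from .errors import DataError
from .model import Spectrum
from .spectra_io import Run


@dataclass
class DetectorParams:
    """Tunables for envelope detection and feature linking.

    Tolerances are ppm; retention times minutes. ``min_score`` gates the
    cosine between observed envelope intensities and the averagine
    prediction at the envelope's neutral mass.
    """

    charge_range: tuple[int, int] = (1, 6)
    spacing_tol_ppm: float = 10.0
    min_score: float = 0.9
    min_isotopes: int = 2
    max_isotopes: int = 8
    link_tol_ppm: float = 10.0
    max_gap: int = 1
    min_scans: int = 3
    rt_pad: float = 0.2


@dataclass
class IsotopeEnvelope:
    mono_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray
    score: float
    peak_indices: tuple[int, ...] = ()

    @property
    def n_isotopes(self) -> int:
        return int(self.mz.size)

    @property
    def mono_intensity(self) -> float:
        return float(self.intensity[0])

    @property
    def neutral_mass(self) -> float:
        return (self.mono_mz - PROTON) * self.charge


@dataclass
class Feature:
    mono_mz: float
    charge: int
    rt_start: float
    rt_end: float
    apex_rt: float
    apex_intensity: float
    area: float
    scan_ids: list[int]
    ms2_scan_ids: list[int] = field(default_factory=list)
    assigned: bool = False
    envelopes: list[IsotopeEnvelope] = field(default_factory=list)

    @property
    def n_scans(self) -> int:
        return len(self.scan_ids)

    @property
    def max_isotopes(self) -> int:
        return max((e.n_isotopes for e in self.envelopes), default=1)


def detect_envelopes(s: Spectrum, params: Optional[DetectorParams] = None
                     ) -> list[IsotopeEnvelope]:
    """Greedy isotope-envelope detection in one centroided spectrum.

    Seeds are visited in descending intensity (ties toward lower m/z); each
    seed tries every charge in ``charge_range``, collecting unused peaks at
    expected spacings within ``spacing_tol_ppm``. The candidate with the
    most isotopes (then highest averagine score, then lowest charge) wins if
    it has at least ``min_isotopes`` peaks and scores ``min_score`` or
    better. Each peak belongs to at most one envelope.
    """
    params = params or DetectorParams()
    if not s.centroided:
        raise DataError("envelope detection requires a centroided spectrum")
    n = s.n_peaks
    used = np.zeros(n, dtype=bool)
    order = sorted(range(n), key=lambda i: (-s.intensity[i], s.mz[i]))
    out: list[IsotopeEnvelope] = []
    zmin, zmax = params.charge_range
    for seed in order:
        if used[seed]:
            continue
        best: Optional[tuple[tuple, int, list[int]]] = None
        for z in range(zmin, zmax + 1):
            members = _collect(s, seed, z, used, params)
            if len(members) < params.min_isotopes:
                continue
            inten = s.intensity[members]
            neutral = (s.mz[seed] - PROTON) * z
            score = envelope_cosine(inten, neutral)
            if score < params.min_score:
                continue
            key = (len(members), score, -z)
            if best is None or key > best[0]:
                best = (key, z, members)
        if best is None:
            continue
        key, z, members = best
        used[members] = True
        out.append(IsotopeEnvelope(
            mono_mz=float(s.mz[seed]), charge=z,
            mz=s.mz[members].copy(), intensity=s.intensity[members].copy(),
            score=key[1], peak_indices=tuple(members)))
    out.sort(key=lambda e: e.mono_mz)
    return out


def _collect(s: Spectrum, seed: int, charge: int, used: np.ndarray,
             params: DetectorParams) -> list[int]:
    members = [seed]
    mono = s.mz[seed]
    for k in range(1, params.max_isotopes):
        expect = mono + k * ISOTOPE_SPACING / charge
        half = expect * params.spacing_tol_ppm * 1e-6
        lo = int(np.searchsorted(s.mz, expect - half, "left"))
        hi = int(np.searchsorted(s.mz, expect + half, "right"))
        cands = [i for i in range(lo, hi) if not used[i] and i not in members]
        if not cands:
            break
        members.append(min(cands, key=lambda i: (abs(s.mz[i] - expect), s.mz[i])))
    return members


# ---------------------------------------------------------------------------
# Cross-scan linking
# ---------------------------------------------------------------------------

@dataclass
class _Trace:
    charge: int
    entries: list[tuple[int, float, IsotopeEnvelope]]  # (scan_id, rt, env)
    gap: int = 0

    @property
    def last_mz(self) -> float:
        return self.entries[-1][2].mono_mz


def detect_features(run: Run, params: Optional[DetectorParams] = None
                    ) -> list[Feature]:
    """Detect features across the MS1 scans of a run.

    Envelopes in consecutive MS1 scans are joined when charges match and
    monoisotopic m/z agrees within ``link_tol_ppm``; dropouts up to
    ``max_gap`` scans are bridged. Traces spanning fewer than ``min_scans``
    scans are dropped. Area is the trapezoidal integral of the monoisotope
    intensity over retention time.
    """
    params = params or DetectorParams()
    ms1 = run.scans(ms_level=1)
    if not ms1:
        return []
    active: list[_Trace] = []
    closed: list[_Trace] = []
    for scan in ms1:
        envs = detect_envelopes(scan, params)
        taken = [False] * len(envs)
        matched_traces = set()
        # intensity-first assignment keeps the strongest signal stable
        for ei in sorted(range(len(envs)), key=lambda i: -envs[i].mono_intensity):
            env = envs[ei]
            best_t, best_d = None, None
            for ti, tr in enumerate(active):
                if ti in matched_traces or tr.charge != env.charge:
                    continue
                d = abs(tr.last_mz - env.mono_mz)
                if d <= tr.last_mz * params.link_tol_ppm * 1e-6 and (
                        best_d is None or d < best_d):
                    best_t, best_d = ti, d
            if best_t is not None:
                active[best_t].entries.append((scan.scan_id, scan.rt, env))
                active[best_t].gap = 0
                matched_traces.add(best_t)
                taken[ei] = True
        still_active = []
        for ti, tr in enumerate(active):
            if ti in matched_traces:
                still_active.append(tr)
            else:
                tr.gap += 1
                (still_active if tr.gap <= params.max_gap else closed).append(tr)
        active = still_active
        for ei, env in enumerate(envs):
            if not taken[ei]:
                active.append(_Trace(env.charge, [(scan.scan_id, scan.rt, env)]))
    closed.extend(active)

    features = []
    for tr in closed:
        if len(tr.entries) < params.min_scans:
            continue
        rts = np.array([rt for _, rt, _ in tr.entries])
        mono = np.array([e.mono_intensity for _, _, e in tr.entries])
        mzs = np.array([e.mono_mz for _, _, e in tr.entries])
        apex = int(np.argmax(mono))
        features.append(Feature(
            mono_mz=float(np.average(mzs, weights=mono)),
            charge=tr.charge,
            rt_start=float(rts[0]), rt_end=float(rts[-1]),
            apex_rt=float(rts[apex]), apex_intensity=float(mono[apex]),
            area=float(np.trapezoid(mono, rts)),
            scan_ids=[sid for sid, _, _ in tr.entries],
            envelopes=[e for _, _, e in tr.entries]))
    features.sort(key=lambda f: (f.rt_start, f.mono_mz))
    return features


def link_ms2(features: Sequence[Feature], run: Run, rt_pad: float = 0.2,
             mz_tol_ppm: float = 10.0) -> list[Feature]:
    """Attach MS/MS scans to features in place (and return the features).

    A scan links to a feature when its precursor m/z lies within
    ``mz_tol_ppm`` of any isotope of the feature's envelope and its rt falls
    in the feature's padded range; a scan links to at most one feature, the
    one with the nearest monoisotopic m/z.
    """
    for f in features:
        f.ms2_scan_ids = []
    for scan in run.scans(ms_level=2):
        if scan.precursor_mz is None:
            continue
        pmz = scan.precursor_mz
        best_f, best_d = None, None
        for f in features:
            if not (f.rt_start - rt_pad <= scan.rt <= f.rt_end + rt_pad):
                continue
            iso = f.mono_mz + np.arange(f.max_isotopes) * ISOTOPE_SPACING / f.charge
            if np.min(np.abs(iso - pmz)) > pmz * mz_tol_ppm * 1e-6:
                continue
            d = abs(f.mono_mz - pmz)
            if best_d is None or d < best_d:
                best_f, best_d = f, d
        if best_f is not None:
            best_f.ms2_scan_ids.append(scan.scan_id)
    return list(features)


def unassigned_features(features: Sequence[Feature], db,
                        run_basename: Optional[str] = None) -> list[Feature]:
    """Features with no MS/MS scan matched in the results store.

    ``db`` is a :class:`~mzcanvas.results_store.ResultsDB`. Output is sorted
    by descending area — the biggest unexplained signals first.
    """
    matched = db.matched_scan_ids(run_basename)
    out = []
    for f in features:
        f.assigned = bool(set(f.ms2_scan_ids) & matched)
        if not f.assigned:
            out.append(f)
    return sorted(out, key=lambda f: -f.area)
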