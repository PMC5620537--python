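"""Deterministic synthetic LC-MS/MS generator with ground truth.

Every other module is tested against runs produced here: peptides elute as
Gaussian profiles, their MS1 isotope envelopes follow the same averagine
model the detector scores against, MS/MS scans contain exact theoretical
fragment peaks (b/y for HCD/CAD, c/z for ETD) plus configurable noise, and
a truth table records what was planted where. Identical seeds give
byte-identical mzML files.

Default conditions emulate a short high-resolution gradient segment:
0.05 min between MS1 scans, 0.08 min elution sigma (~10 scans per feature),
four isotopes per envelope, and exponential-intensity chemical noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .averagine import isotope_distribution
from .constants import ISOTOPE_SPACING, PROTON
from .errors import DataError
from .model import Spectrum
from .pepcalc import Peptide, fragment_ions, peptide_mass
from .spectra_io import atomic_write_text, write_mzml


@dataclass
class SyntheticPeptideSpec:
    peptide: Peptide
    charge: int = 2
    apex_rt: float = 5.0          # minutes
    sigma: float = 0.08           # Gaussian elution width (min)
    abundance: float = 1e6        # apex intensity of the envelope
    include_ms2: bool = True
    isotope_depth: int = 4
    activation: str = "HCD"

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.abundance <= 0:
            raise DataError("sigma and abundance must be positive")
        if self.isotope_depth < 2:
            raise DataError("isotope_depth must be >= 2")

    @property
    def neutral_mass(self) -> float:
        return peptide_mass(self.peptide)

    @property
    def mono_mz(self) -> float:
        return (self.neutral_mass + self.charge * PROTON) / self.charge


@dataclass
class NoiseModel:
    """Chemical noise: uniform random m/z, exponential intensity, plus a
    small Gaussian m/z jitter on signal peaks. Density 0 means no noise."""

    baseline_density: float = 0.0   # noise peaks per 100 Th per MS1 scan
    intensity_scale: float = 1e3    # mean of the exponential intensity law
    mz_jitter_ppm: float = 0.0


#: Elution profile is emitted while above this fraction of the apex.
_ELUTION_CUTOFF = 0.01


def _merge_sorted(mz: list[float], inten: list[float],
                  tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(mz, kind="stable")
    out_mz: list[float] = []
    out_in: list[float] = []
    for i in order:
        if out_mz and mz[i] - out_mz[-1] <= tol:
            out_in[-1] += inten[i]
        else:
            out_mz.append(mz[i])
            out_in.append(inten[i])
    return np.array(out_mz), np.array(out_in)


def _noise_peaks(rng: np.random.Generator, noise: NoiseModel,
                 mz_range: tuple[float, float]) -> tuple[list, list]:
    span = mz_range[1] - mz_range[0]
    n = rng.poisson(noise.baseline_density * span / 100.0)
    if n == 0:
        return [], []
    mzs = sorted(rng.uniform(*mz_range, size=n).tolist())
    ints = rng.exponential(noise.intensity_scale, size=n).tolist()
    return mzs, ints


def _jitter(rng: np.random.Generator, mz: float, ppm: float) -> float:
    return mz * (1 + rng.normal(0.0, ppm) * 1e-6) if ppm > 0 else mz


def make_msms(
    p: Peptide,
    charge: int,
    activation: str = "HCD",
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    scan_id: int = 1,
    rt: float = 0.0,
    fragment_charges: Sequence[int] = (1,),
    fragment_isotopes: int = 1,
    reporter_peaks: Optional[Sequence[tuple[float, float]]] = None,
    extra_peaks: Optional[Sequence[tuple[float, float]]] = None,
    base_intensity: float = 1e4,
) -> Spectrum:
    """Build one MS/MS spectrum with exact theoretical fragment peaks.

    Series follow the activation mode (b/y for HCD/CAD, c/z for ETD).
    ``fragment_isotopes`` > 1 plants averagine-shaped isotope envelopes per
    fragment; ``fragment_charges`` beyond (1,) plants multiply charged
    fragments — together these exercise de-isotoping and charge reduction.
    ``reporter_peaks``/``extra_peaks`` are planted verbatim.
    """
    rng = np.random.default_rng(seed)
    noise = noise or NoiseModel()
    series = ("c", "z") if activation == "ETD" else ("b", "y")
    ions = fragment_ions(p, series, max_charge=max(fragment_charges))
    mzs: list[float] = []
    ints: list[float] = []
    for ion in ions:
        if ion.charge not in fragment_charges:
            continue
        # deterministic pseudo-random but reproducible intensity pattern
        rel = 0.3 + 0.7 * (((ion.index * 37 + ord(ion.series) * 11
                             + ion.charge * 5) % 17) / 16.0)
        amp = base_intensity * rel / ion.charge
        fracs = (isotope_distribution(ion.neutral_mass, fragment_isotopes)
                 if fragment_isotopes > 1 else np.array([1.0]))
        for k, frac in enumerate(fracs):
            mz_k = ion.mz + k * ISOTOPE_SPACING / ion.charge
            mzs.append(_jitter(rng, mz_k, noise.mz_jitter_ppm))
            ints.append(amp * float(frac))
    for coll in (reporter_peaks or []), (extra_peaks or []):
        for mz, inten in coll:
            mzs.append(float(mz))
            ints.append(float(inten))
    if noise.baseline_density > 0:
        lo = min(mzs) - 50 if mzs else 100.0
        nmz, nint = _noise_peaks(rng, noise, (max(lo, 50.0),
                                              (max(mzs) if mzs else 1500) + 50))
        mzs += nmz
        ints += nint
    mz_arr, int_arr = _merge_sorted(mzs, ints)
    total = peptide_mass(p)
    return Spectrum(
        scan_id=scan_id, ms_level=2, rt=rt, mz=mz_arr, intensity=int_arr,
        precursor_mz=(total + charge * PROTON) / charge,
        precursor_charge=charge, activation=activation, centroided=True)


def make_run(
    specs: Sequence[SyntheticPeptideSpec],
    noise: Optional[NoiseModel] = None,
    gradient: tuple[float, float] = (10.0, 0.05),
    seed: int = 0,
    out_path: Optional[str] = None,
    mz_range: tuple[float, float] = (200.0, 2000.0),
    run_id: str = "synthetic",
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Simulate a run; optionally write mzML; return spectra + truth table.

    ``gradient`` is (rt span minutes, MS1 scan interval minutes). One MS/MS
    scan is inserted directly after the MS1 scan nearest each spec's apex
    (when ``include_ms2``). The truth table has one row per spec with the
    planted feature's m/z, charge, rt extent, member-scan count and linked
    MS/MS scan ids.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    span, interval = gradient
    if interval <= 0 or span <= 0:
        raise DataError("gradient span and scan interval must be positive")
    for a, sa in enumerate(specs):
        if not (mz_range[0] <= sa.mono_mz <= mz_range[1]):
            raise DataError(f"spec {a}: mono m/z {sa.mono_mz:.3f} outside "
                            f"instrument range {mz_range}")
        for b in range(a + 1, len(specs)):
            sb = specs[b]
            if (sa.charge == sb.charge
                    and abs(sa.mono_mz - sb.mono_mz) < ISOTOPE_SPACING / sa.charge
                    and abs(sa.apex_rt - sb.apex_rt) < 2 * max(sa.sigma, sb.sigma)):
                warnings.warn(f"specs {a} and {b} overlap within one isotope "
                              "spacing; their envelopes will merge")

    ms1_times = np.arange(0.0, span + 1e-9, interval)
    # ms2 insertion: after the MS1 scan nearest each apex
    ms2_after: dict[int, list[int]] = {}
    for si, spec in enumerate(specs):
        if spec.include_ms2:
            ms2_after.setdefault(int(np.argmin(np.abs(ms1_times - spec.apex_rt))),
                                 []).append(si)

    spectra: list[Spectrum] = []
    scan_id = 0
    truth_scans: dict[int, list[int]] = {si: [] for si in range(len(specs))}
    truth_rts: dict[int, list[float]] = {si: [] for si in range(len(specs))}
    truth_ms2: dict[int, list[int]] = {si: [] for si in range(len(specs))}
    for ti, t in enumerate(ms1_times):
        scan_id += 1
        mzs: list[float] = []
        ints: list[float] = []
        for si, spec in enumerate(specs):
            g = spec.abundance * np.exp(-0.5 * ((t - spec.apex_rt) / spec.sigma) ** 2)
            if g < spec.abundance * _ELUTION_CUTOFF:
                continue
            truth_scans[si].append(scan_id)
            truth_rts[si].append(float(t))
            fracs = isotope_distribution(spec.neutral_mass, spec.isotope_depth)
            for k, frac in enumerate(fracs):
                mz_k = spec.mono_mz + k * ISOTOPE_SPACING / spec.charge
                mzs.append(_jitter(rng, mz_k, noise.mz_jitter_ppm))
                ints.append(g * float(frac))
        if noise.baseline_density > 0:
            nmz, nint = _noise_peaks(rng, noise, mz_range)
            mzs += nmz
            ints += nint
        mz_arr, int_arr = _merge_sorted(mzs, ints)
        spectra.append(Spectrum(scan_id=scan_id, ms_level=1, rt=float(t),
                                mz=mz_arr, intensity=int_arr))
        for si in ms2_after.get(ti, []):
            scan_id += 1
            spec = specs[si]
            ms2 = make_msms(spec.peptide, spec.charge, spec.activation,
                            noise=noise, seed=int(rng.integers(2 ** 31)),
                            scan_id=scan_id, rt=float(t) + 1e-4)
            spectra.append(ms2)
            truth_ms2[si].append(scan_id)

    rows = []
    for si, spec in enumerate(specs):
        member = truth_scans[si]
        rts = truth_rts[si]
        rows.append({
            "spec": si,
            "sequence": spec.peptide.sequence,
            "mods": spec.peptide.mods_text(),
            "charge": spec.charge,
            "neutral_mass": spec.neutral_mass,
            "mono_mz": spec.mono_mz,
            "apex_rt": spec.apex_rt,
            "rt_start": rts[0] if rts else float("nan"),
            "rt_end": rts[-1] if rts else float("nan"),
            "abundance": spec.abundance,
            "n_scans": len(member),
            "ms1_scan_ids": ";".join(map(str, member)),
            "ms2_scan_ids": ";".join(map(str, truth_ms2[si])),
        })
    truth = pd.DataFrame(rows)
    if out_path is not None:
        write_mzml(spectra, out_path, run_id=run_id)
    return spectra, truth


# ---------------------------------------------------------------------------
# Search-result fixtures
# ---------------------------------------------------------------------------

_TSV_DIALECTS = {
    "canonical": ["Run", "Scan", "Peptide Sequence", "Variable Modifications",
                  "Charge", "Peptide Score", "Engine", "Protein Accessions",
                  "Precursor MZ", "RT"],
    "comet": ["spectrum file", "scan number", "peptide", "modifications",
              "precursor charge", "xcorr", "search engine", "protein",
              "precursor m/z", "retention time"],
}


def make_results_fixture(
    truth: pd.DataFrame,
    path: str,
    run_name: str = "synthetic",
    engine_style: str = "canonical",
    fmt: str = "tsv",
    assigned_specs: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> int:
    """Write PSM rows for the MS/MS scans of chosen specs; returns row count.

    ``fmt`` is "tsv" (column dialect per ``engine_style``) or "pepxml".
    ``assigned_specs`` selects which planted peptides get results rows
    (default: all that produced MS/MS scans).
    """
    rng = np.random.default_rng(seed)
    chosen = (set(assigned_specs) if assigned_specs is not None
              else set(truth["spec"]))
    psms = []
    for _, row in truth.iterrows():
        if row["spec"] not in chosen or not row["ms2_scan_ids"]:
            continue
        for sid in str(row["ms2_scan_ids"]).split(";"):
            if not sid:
                continue
            psms.append({
                "run": run_name, "scan": int(sid),
                "peptide": row["sequence"], "mods": row["mods"],
                "charge": int(row["charge"]),
                "score": float(np.round(20 + 60 * rng.random(), 2)),
                "engine": "comet", "protein": f"SYN|{row['sequence'][:4]}",
                "mz": float(row["mono_mz"]), "rt": float(row["apex_rt"]),
            })
    if fmt == "tsv":
        _write_tsv_fixture(psms, path, engine_style)
    elif fmt == "pepxml":
        _write_pepxml_fixture(psms, path, run_name)
    else:
        raise DataError(f"unknown fixture format {fmt!r}")
    return len(psms)


def _write_tsv_fixture(psms: list[dict], path: str, engine_style: str) -> None:
    if engine_style not in _TSV_DIALECTS:
        raise DataError(f"unknown engine style {engine_style!r}")
    headers = _TSV_DIALECTS[engine_style]
    keys = ["run", "scan", "peptide", "mods", "charge", "score", "engine",
            "protein", "mz", "rt"]
    lines = ["\t".join(headers)]
    for p in psms:
        lines.append("\t".join(str(p[k]) for k in keys))
    atomic_write_text(path, "\n".join(lines) + "\n")


def _write_pepxml_fixture(psms: list[dict], path: str, run_name: str) -> None:
    from xml.sax.saxutils import quoteattr

    parts = ['<?xml version="1.0" encoding="UTF-8"?>',
             '<msms_pipeline_analysis '
             'xmlns="http://regis-web.systemsbiology.net/pepXML">',
             f'<msms_run_summary base_name={quoteattr(run_name)} '
             'raw_data_type="raw" raw_data=".mzML">',
             '<search_summary search_engine="Comet" search_id="1"/>']
    for p in psms:
        neutral = p["mz"] * p["charge"] - p["charge"] * PROTON
        spectrum = f'{p["run"]}.{p["scan"]}.{p["scan"]}.{p["charge"]}'
        parts.append(
            f'<spectrum_query spectrum={quoteattr(spectrum)} '
            f'start_scan="{p["scan"]}" end_scan="{p["scan"]}" '
            f'precursor_neutral_mass="{neutral:.6f}" '
            f'assumed_charge="{p["charge"]}" '
            f'retention_time_sec="{p["rt"] * 60.0:.3f}">')
        parts.append('<search_result>')
        parts.append(
            f'<search_hit hit_rank="1" peptide={quoteattr(p["peptide"])} '
            f'protein={quoteattr(p["protein"])} '
            f'calc_neutral_pep_mass="{neutral:.6f}" massdiff="0.0" '
            'num_tot_proteins="1">')
        parts.append(f'<search_score name="xcorr" value="{p["score"]}"/>')
        parts.append('</search_hit></search_result></spectrum_query>')
    parts.append('</msms_run_summary></msms_pipeline_analysis>')
    atomic_write_text(path, "\n".join(parts) + "\n")


# ---------------------------------------------------------------------------
# Canned peptide set for demos and fixtures
# ---------------------------------------------------------------------------

DEMO_SEQUENCES = [
    "LGEYGFQNAILVR", "DAFLGSFLYEYSR", "YLYEIARR", "HPYFYAPELLFFAK",
    "TCVADESAENCDK", "AEFVEVTK", "QTALVELLK", "LVNELTEFAK",
    "SLHTLFGDELCK", "YICDNQDTISSK",
]


def demo_specs(n: int = 10, base_rt: float = 2.0, rt_step: float = 0.6,
               abundance: float = 1e6, include_ms2: bool = True,
               ) -> list[SyntheticPeptideSpec]:
    """n well-separated peptide specs over a gradient — the standard test bed."""
    out = []
    for i in range(n):
        seq = DEMO_SEQUENCES[i % len(DEMO_SEQUENCES)]
        out.append(SyntheticPeptideSpec(
            peptide=Peptide(seq),
            charge=2 + (i % 2),
            apex_rt=base_rt + i * rt_step,
            abundance=abundance * (1 + 0.2 * (i % 3)),
            include_ms2=include_ms2))
    return out
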