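"""Quantification utilities: XIC areas, reporter ions, impurity correction.

Isobaric labeling (TMT, iTRAQ) reads out relative abundance from low-mass
reporter ions, but each reagent lot leaks a known fraction of signal into
neighboring channels (−2/−1/+1/+2 Da isotopic impurities). Observed
intensities therefore satisfy ``observed = C · true`` with C the impurity
matrix (column j = reagent j's leakage profile); correction is the full
linear solve, with negative solutions clamped to zero and flagged. Further
scalars normalize for protein input per channel and for the instrument's
ion injection time (corrected = value × reference_time / injection_time).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .model import Chromatogram, Spectrum, mz_window


@dataclass(frozen=True)
class ReporterPanel:
    name: str
    labels: tuple[str, ...]
    mzs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.mzs) or len(self.mzs) < 2:
            raise DataError("panel needs >= 2 aligned channels")
        if any(b <= a for a, b in zip(self.mzs, self.mzs[1:])):
            raise DataError("channel m/z must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return len(self.mzs)


PANELS: dict[str, ReporterPanel] = {
    "itraq4": ReporterPanel(
        "iTRAQ4", ("114", "115", "116", "117"),
        (114.11068, 115.10771, 116.11107, 117.11441)),
    "itraq8": ReporterPanel(
        "iTRAQ8", ("113", "114", "115", "116", "117", "118", "119", "121"),
        (113.10787, 114.11068, 115.10771, 116.11107, 117.11441, 118.11174,
         119.11471, 121.12200)),
    "tmt6": ReporterPanel(
        "TMT6", ("126", "127", "128", "129", "130", "131"),
        (126.127726, 127.131081, 128.134436, 129.137790, 130.141145,
         131.138180)),
    "tmt10": ReporterPanel(
        "TMT10", ("126", "127N", "127C", "128N", "128C", "129N", "129C",
                  "130N", "130C", "131"),
        (126.127726, 127.124761, 127.131081, 128.128116, 128.134436,
         129.131471, 129.137790, 130.134825, 130.141145, 131.138180)),
}


@dataclass
class ImpurityMatrix:
    """C[i][j] = fraction of channel j's reagent signal observed in channel i."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.matrix, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise DataError("impurity matrix must be square")
        if np.any(C < 0):
            raise DataError("impurity matrix entries must be non-negative")
        if np.any(C.sum(axis=0) > 1 + 1e-9):
            raise DataError("impurity matrix columns must sum to <= 1")
        off = C.sum(axis=0) - np.diag(C)
        if np.any(np.diag(C) <= off):
            raise DataError("impurity matrix must be diagonally dominant")
        self.matrix = C

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]


def load_impurity_csv(path: str) -> ImpurityMatrix:
    """Build an impurity matrix from a vendor-certificate CSV.

    Expected columns: channel, -2, -1, +1, +2 — percentages of each
    reagent's signal appearing that many channels away. The diagonal is
    100 minus the stated leakage.
    """
    df = pd.read_csv(path)
    cols = {str(c).strip().lower(): c for c in df.columns}
    offsets = [(-2, "-2"), (-1, "-1"), (1, "+1"), (2, "+2")]
    n = len(df)
    C = np.zeros((n, n))
    for j in range(n):
        leak = 0.0
        for off, name in offsets:
            if name not in cols:
                continue
            frac = float(df.iloc[j][cols[name]]) / 100.0
            leak += frac
            if 0 <= j + off < n:
                C[j + off, j] = frac
        C[j, j] = 1.0 - leak
    return ImpurityMatrix(C)


@dataclass
class QuantRow:
    scan_id: int
    raw: np.ndarray
    corrected: np.ndarray
    clamped: bool = False
    protein_factors: Optional[np.ndarray] = None
    injection_scale: Optional[float] = None


def reporter_intensities(s: Spectrum, panel: ReporterPanel, tol: float = 0.003,
                         tol_unit: str = "Th") -> np.ndarray:
    """Per channel: the most intense peak within tol of the channel m/z, else 0."""
    if s.ms_level < 2:
        raise DataError("reporter extraction requires an MS/MS spectrum")
    out = np.zeros(panel.n_channels)
    for k, cmz in enumerate(panel.mzs):
        lo, hi = mz_window(cmz, tol, tol_unit)
        i0, i1 = np.searchsorted(s.mz, lo, "left"), np.searchsorted(s.mz, hi, "right")
        if i1 > i0:
            out[k] = float(s.intensity[i0:i1].max())
    return out


def impurity_correct(raw: Sequence[float], C: ImpurityMatrix
                     ) -> tuple[np.ndarray, bool]:
    """Solve C · x = raw; clamp negative components to 0 (flag returned)."""
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (C.n_channels,):
        raise DataError(f"raw vector length {raw.size} != {C.n_channels} channels")
    try:
        x = np.linalg.solve(C.matrix, raw)
    except np.linalg.LinAlgError as exc:
        raise DataError(f"impurity matrix is singular: {exc}") from exc
    clamped = bool(np.any(x < 0))
    return np.maximum(x, 0.0), clamped


def quantify_scan(s: Spectrum, panel: ReporterPanel,
                  C: Optional[ImpurityMatrix] = None,
                  tol: float = 0.003) -> QuantRow:
    raw = reporter_intensities(s, panel, tol)
    if C is None:
        return QuantRow(s.scan_id, raw, raw.copy())
    corrected, clamped = impurity_correct(raw, C)
    return QuantRow(s.scan_id, raw, corrected, clamped=clamped)


def normalize(rows: Sequence[QuantRow],
              protein_factors: Optional[Sequence[float]] = None,
              injection_times: Optional[dict[int, float]] = None,
              reference_time: float = 1.0) -> list[QuantRow]:
    """Scale corrected intensities for protein input and injection time.

    Each channel is divided by its protein factor; each scan is multiplied
    by reference_time / its injection time (longer fills accumulated more
    ions, so their intensities are scaled down toward the reference).
    Factors are recorded on the rows.
    """
    if protein_factors is not None:
        pf = np.asarray(protein_factors, dtype=float)
        if np.any(pf <= 0):
            raise DataError("protein factors must be positive")
    if reference_time <= 0:
        raise DataError("reference time must be positive")
    for row in rows:
        if protein_factors is not None:
            row.corrected = row.corrected / pf
            row.protein_factors = pf.copy()
        if injection_times is not None:
            it = injection_times.get(row.scan_id)
            if it is None:
                continue
            if it <= 0:
                raise DataError(f"non-positive injection time for scan {row.scan_id}")
            scale = reference_time / it
            row.corrected = row.corrected * scale
            row.injection_scale = scale
    return list(rows)


def xic_area(c: Chromatogram, rt_range: Optional[tuple[float, float]] = None
             ) -> float:
    """Trapezoidal area of a chromatogram within rt_range (min × intensity)."""
    mask = np.ones(len(c), dtype=bool)
    if rt_range is not None:
        mask = (c.rt >= rt_range[0]) & (c.rt <= rt_range[1])
    if mask.sum() < 2:
        raise DataError("need at least two chromatogram points in range")
    return float(np.trapezoid(c.intensity[mask], c.rt[mask]))
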