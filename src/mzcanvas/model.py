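"""Core in-memory data model: peaks, spectra, chromatograms.

Peak data live in parallel numpy arrays on :class:`Spectrum` for speed; the
``peaks`` property exposes the (mz, intensity) pair view used in reports and
tests. All m/z values are in Thomson (Th), retention times in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, NamedTuple, Optional

import numpy as np

ACTIVATIONS = ("CAD", "HCD", "ETD", "unknown")


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """One scan: a centroided (or profile) peak list with scan metadata.

    ``peak_charges`` is an optional per-peak charge annotation used by the
    spectral-processing pipeline (filled in by de-isotoping, consumed by
    charge reduction); 0 means "unknown".
    """

    scan_id: int
    ms_level: int
    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None
    precursor_charge: Optional[int] = None
    activation: str = "unknown"
    centroided: bool = True
    peak_charges: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("peaks must be strictly sorted by m/z")
        if self.mz.size and (np.any(self.mz <= 0) or np.any(self.intensity < 0)):
            raise ValueError("require mz > 0 and intensity >= 0")
        if self.ms_level < 1:
            raise ValueError("ms_level must be >= 1")
        if self.ms_level == 1 and self.precursor_mz is not None:
            raise ValueError("MS1 spectrum cannot carry a precursor")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.peak_charges is not None:
            self.peak_charges = np.asarray(self.peak_charges, dtype=int)
            if self.peak_charges.shape != self.mz.shape:
                raise ValueError("peak_charges must align with peaks")

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(float(m), float(i)) for m, i in zip(self.mz, self.intensity)]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def with_peaks(
        self,
        mz: np.ndarray,
        intensity: np.ndarray,
        peak_charges: Optional[np.ndarray] = None,
    ) -> "Spectrum":
        """Copy of this spectrum with a replaced peak list (metadata kept)."""
        return replace(
            self, mz=np.asarray(mz, float), intensity=np.asarray(intensity, float),
            peak_charges=peak_charges,
        )


@dataclass
class Chromatogram:
    """Extracted ion chromatogram: intensity vs retention time in an m/z window."""

    query_mz: float
    tol: float
    tol_unit: str  # "ppm" or "Th"
    rt: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.size > 1 and np.any(np.diff(self.rt) <= 0):
            raise ValueError("chromatogram rts must be strictly increasing")

    @property
    def points(self) -> list[tuple[float, float]]:
        return [(float(t), float(i)) for t, i in zip(self.rt, self.intensity)]

    def __len__(self) -> int:
        return int(self.rt.size)


def mz_window(mz: float, tol: float, unit: str = "ppm") -> tuple[float, float]:
    """Closed m/z interval [lo, hi] around ``mz`` for a ppm or absolute tolerance."""
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if unit == "ppm":
        half = mz * tol * 1e-6
    elif unit in ("Th", "th", "da", "Da"):
        half = tol
    else:
        raise ValueError(f"unknown tolerance unit {unit!r}")
    return mz - half, mz + half
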