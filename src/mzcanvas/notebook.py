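"""Provenance notebook: annotated, self-contained evidence items.

Each entry embeds its own data — a peak list (raw or processed, with its
ProcessingRecord), a chromatogram, or a results excerpt — plus drawing
annotations and attachments (scripts, search parameters, notes). A saved
bundle is a zip of one JSON document per entry with a digest manifest, so
it renders, verifies, and replays with zero access to any raw run file:
the evidence travels with the claim.
"""

from __future__ import annotations

import hashlib
import io
import json
import time
import zipfile
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DataError
from .model import Chromatogram, Spectrum
from .spec_process import ProcessingRecord, replay
from .spectra_io import atomic_write_text

ANNOTATION_KINDS = ("text", "arrow", "bracket", "highlight-region")
ITEM_KINDS = ("spectrum", "processed_spectrum", "chromatogram", "results")


@dataclass
class Annotation:
    kind: str
    x: float          # data coordinate: m/z (spectra) or rt (chromatograms)
    y: float          # intensity coordinate
    payload: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise DataError(f"unknown annotation kind {self.kind!r}")


def _spectrum_to_dict(s: Spectrum) -> dict:
    return {
        "scan_id": s.scan_id, "ms_level": s.ms_level, "rt": s.rt,
        "mz": [float(v) for v in s.mz],
        "intensity": [float(v) for v in s.intensity],
        "precursor_mz": s.precursor_mz, "precursor_charge": s.precursor_charge,
        "activation": s.activation, "centroided": s.centroided,
        "peak_charges": None if s.peak_charges is None
                        else [int(v) for v in s.peak_charges],
    }


def _spectrum_from_dict(d: dict) -> Spectrum:
    return Spectrum(
        scan_id=d["scan_id"], ms_level=d["ms_level"], rt=d["rt"],
        mz=np.array(d["mz"], dtype=float),
        intensity=np.array(d["intensity"], dtype=float),
        precursor_mz=d["precursor_mz"], precursor_charge=d["precursor_charge"],
        activation=d["activation"], centroided=d["centroided"],
        peak_charges=None if d.get("peak_charges") is None
                     else np.array(d["peak_charges"], dtype=int),
    )


@dataclass
class NotebookEntry:
    entry_id: int
    title: str
    kind: str
    item: dict
    annotations: list[Annotation] = field(default_factory=list)
    attachments: dict[str, object] = field(default_factory=dict)
    created: float = field(default_factory=time.time)
    modified: float = field(default_factory=time.time)
    tampered: bool = False

    # -- data access ------------------------------------------------------

    def spectrum(self) -> Spectrum:
        if self.kind == "spectrum":
            return _spectrum_from_dict(self.item)
        if self.kind == "processed_spectrum":
            return _spectrum_from_dict(self.item["output"])
        raise DataError(f"entry {self.entry_id} holds no peak list")

    def input_spectrum(self) -> Spectrum:
        if self.kind != "processed_spectrum":
            raise DataError("not a processed-spectrum entry")
        return _spectrum_from_dict(self.item["input"])

    def record(self) -> ProcessingRecord:
        if self.kind != "processed_spectrum":
            raise DataError("not a processed-spectrum entry")
        return ProcessingRecord.from_dict(self.item["record"])

    def chromatogram(self) -> Chromatogram:
        if self.kind != "chromatogram":
            raise DataError("not a chromatogram entry")
        d = self.item
        return Chromatogram(query_mz=d["query_mz"], tol=d["tol"],
                            tol_unit=d["tol_unit"],
                            rt=np.array(d["rt"]), intensity=np.array(d["intensity"]))

    def _xy_range(self) -> tuple[float, float, float]:
        if self.kind in ("spectrum", "processed_spectrum"):
            s = self.spectrum()
            if s.n_peaks == 0:
                raise DataError("cannot anchor annotations on an empty spectrum")
            return float(s.mz.min()), float(s.mz.max()), float(s.intensity.max())
        if self.kind == "chromatogram":
            c = self.chromatogram()
            if len(c) == 0:
                raise DataError("cannot anchor annotations on an empty chromatogram")
            return float(c.rt.min()), float(c.rt.max()), float(c.intensity.max())
        raise DataError(f"entries of kind {self.kind!r} take no annotations")

    def to_dict(self) -> dict:
        return {
            "entry_id": self.entry_id, "title": self.title, "kind": self.kind,
            "item": self.item,
            "annotations": [{"kind": a.kind, "x": a.x, "y": a.y,
                             "payload": a.payload} for a in self.annotations],
            "attachments": self.attachments,
            "created": self.created, "modified": self.modified,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NotebookEntry":
        return cls(
            entry_id=d["entry_id"], title=d["title"], kind=d["kind"],
            item=d["item"],
            annotations=[Annotation(**a) for a in d["annotations"]],
            attachments=d["attachments"],
            created=d["created"], modified=d["modified"],
        )


@dataclass
class Notebook:
    entries: list[NotebookEntry] = field(default_factory=list)

    def add_entry(self, item, title: str,
                  record: Optional[ProcessingRecord] = None,
                  input_spectrum: Optional[Spectrum] = None) -> NotebookEntry:
        """Append an evidence item.

        ``item`` may be a Spectrum (pass ``record`` and ``input_spectrum``
        to make it a processed-spectrum entry), a Chromatogram, or a list of
        dict rows (results excerpt).
        """
        eid = max((e.entry_id for e in self.entries), default=0) + 1
        if isinstance(item, Spectrum):
            if record is not None:
                if input_spectrum is None:
                    raise DataError("a processed entry needs its input spectrum")
                payload = {"input": _spectrum_to_dict(input_spectrum),
                           "output": _spectrum_to_dict(item),
                           "record": record.to_dict()}
                entry = NotebookEntry(eid, title, "processed_spectrum", payload)
            else:
                entry = NotebookEntry(eid, title, "spectrum",
                                      _spectrum_to_dict(item))
        elif isinstance(item, Chromatogram):
            entry = NotebookEntry(eid, title, "chromatogram", {
                "query_mz": item.query_mz, "tol": item.tol,
                "tol_unit": item.tol_unit,
                "rt": [float(v) for v in item.rt],
                "intensity": [float(v) for v in item.intensity]})
        elif isinstance(item, (list, tuple)):
            entry = NotebookEntry(eid, title, "results", {"rows": list(item)})
        else:
            raise DataError(f"cannot store item of type {type(item).__name__}")
        self.entries.append(entry)
        return entry

    def annotate(self, entry: NotebookEntry, annotation: Annotation) -> None:
        x0, x1, ymax = entry._xy_range()
        if not (x0 <= annotation.x <= x1) or not (0 <= annotation.y <= ymax):
            raise DataError(
                f"annotation anchor ({annotation.x}, {annotation.y}) outside "
                f"data range x:[{x0}, {x1}] y:[0, {ymax}]")
        entry.annotations.append(annotation)
        entry.modified = time.time()

    def attach(self, entry: NotebookEntry, kind: str, payload) -> None:
        entry.attachments[kind] = payload
        entry.modified = time.time()

    def replay_entry(self, entry: NotebookEntry) -> Spectrum:
        """Re-derive a processed entry's peaks from its embedded input and
        record — the self-containment guarantee, no raw file involved."""
        out = replay(entry.record(), entry.input_spectrum())
        stored = entry.spectrum()
        if not (np.array_equal(out.mz, stored.mz)
                and np.array_equal(out.intensity, stored.intensity)):
            raise DataError(f"entry {entry.entry_id}: replay does not reproduce "
                            "the stored processed peaks")
        return out


# ---------------------------------------------------------------------------
# Bundle save / load
# ---------------------------------------------------------------------------

def _entry_bytes(entry: NotebookEntry) -> bytes:
    return json.dumps(entry.to_dict(), sort_keys=True, indent=1).encode()


def save_bundle(nb: Notebook, path: str) -> None:
    """Write the notebook as a zip archive with a digest manifest."""
    manifest = {"format": "mzcanvas-notebook-1", "entries": []}
    blobs = []
    for entry in nb.entries:
        payload = _entry_bytes(entry)
        name = f"entry_{entry.entry_id}.json"
        manifest["entries"].append(
            {"id": entry.entry_id, "file": name,
             "sha256": hashlib.sha256(payload).hexdigest()})
        blobs.append((name, payload))
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        for name, payload in blobs:
            zf.writestr(name, payload)


def load_bundle(path: str) -> Notebook:
    """Read a bundle, verifying each entry against the manifest digests.

    Entries whose payload fails verification are still loaded but flagged
    ``tampered`` so a viewer can refuse to present them as evidence.
    """
    nb = Notebook()
    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            for meta in manifest["entries"]:
                payload = zf.read(meta["file"])
                entry = NotebookEntry.from_dict(json.loads(payload))
                entry.tampered = (
                    hashlib.sha256(payload).hexdigest() != meta["sha256"])
                nb.entries.append(entry)
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise DataError(f"corrupt notebook bundle {path}: {exc}") from exc
    return nb


# ---------------------------------------------------------------------------
# Graphics export
# ---------------------------------------------------------------------------

_SVG_SIZE = (640, 400)
_MARGIN = 50


def _svg_spectrum(s: Spectrum, annotations: Sequence[Annotation]) -> str:
    w, h = _SVG_SIZE
    x0, x1 = (float(s.mz.min()), float(s.mz.max())) if s.n_peaks else (0.0, 1.0)
    if x1 == x0:
        x0, x1 = x0 - 1, x1 + 1
    ymax = float(s.intensity.max()) if s.n_peaks else 1.0
    span = x1 - x0

    def X(v): return _MARGIN + (v - x0) / span * (w - 2 * _MARGIN)
    def Y(v): return (h - _MARGIN) - v / ymax * (h - 2 * _MARGIN)

    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}" height="{h}">',
             f'<line class="axis" x1="{_MARGIN}" y1="{h - _MARGIN}" '
             f'x2="{w - _MARGIN}" y2="{h - _MARGIN}" stroke="black"/>']
    for mz, inten in zip(s.mz, s.intensity):
        parts.append(
            f'<line class="peak" x1="{X(mz):.2f}" y1="{h - _MARGIN}" '
            f'x2="{X(mz):.2f}" y2="{Y(inten):.2f}" stroke="black"/>')
    parts.extend(_svg_annotations(annotations, X, Y))
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def _svg_chromatogram(c: Chromatogram, annotations: Sequence[Annotation]) -> str:
    w, h = _SVG_SIZE
    x0, x1 = (float(c.rt.min()), float(c.rt.max())) if len(c) else (0.0, 1.0)
    if x1 == x0:
        x0, x1 = x0 - 1, x1 + 1
    ymax = float(c.intensity.max()) or 1.0

    def X(v): return _MARGIN + (v - x0) / (x1 - x0) * (w - 2 * _MARGIN)
    def Y(v): return (h - _MARGIN) - v / ymax * (h - 2 * _MARGIN)

    pts = " ".join(f"{X(t):.2f},{Y(i):.2f}" for t, i in zip(c.rt, c.intensity))
    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}" height="{h}">',
             f'<polyline class="trace" points="{pts}" fill="none" stroke="black"/>']
    parts.extend(_svg_annotations(annotations, X, Y))
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def _svg_annotations(annotations, X, Y) -> list[str]:
    parts = []
    for a in annotations:
        x, y = X(a.x), Y(a.y)
        if a.kind == "text":
            parts.append(f'<text class="note" x="{x:.2f}" y="{y - 4:.2f}" '
                         f'font-size="11">{_esc(a.payload)}</text>')
        elif a.kind == "arrow":
            parts.append(f'<line class="arrow" x1="{x:.2f}" y1="{y - 30:.2f}" '
                         f'x2="{x:.2f}" y2="{y - 4:.2f}" stroke="red"/>')
        elif a.kind == "bracket":
            parts.append(f'<path class="bracket" d="M {x - 15:.2f} {y - 10:.2f} '
                         f'L {x - 15:.2f} {y - 16:.2f} L {x + 15:.2f} {y - 16:.2f} '
                         f'L {x + 15:.2f} {y - 10:.2f}" fill="none" stroke="blue"/>')
        elif a.kind == "highlight-region":
            parts.append(f'<rect class="highlight" x="{x - 10:.2f}" y="{y - 20:.2f}" '
                         f'width="20" height="20" fill="yellow" opacity="0.4"/>')
    return parts


def _esc(text: str) -> str:
    return (text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;"))


def export_graphic(entry: NotebookEntry, fmt: str, path: str) -> None:
    """Render an entry to svg, png, or pdf.

    SVG is generated directly (byte-deterministic for identical entries);
    PNG and PDF render the same geometry through matplotlib.
    """
    fmt = fmt.lower()
    if fmt not in ("svg", "png", "pdf"):
        raise DataError(f"unsupported export format {fmt!r} "
                        "(supported: svg, png, pdf)")
    if entry.kind in ("spectrum", "processed_spectrum"):
        data = ("spectrum", entry.spectrum())
    elif entry.kind == "chromatogram":
        data = ("chromatogram", entry.chromatogram())
    else:
        raise DataError(f"entries of kind {entry.kind!r} cannot be rendered")

    if fmt == "svg":
        if data[0] == "spectrum":
            atomic_write_text(path, _svg_spectrum(data[1], entry.annotations))
        else:
            atomic_write_text(path, _svg_chromatogram(data[1], entry.annotations))
        return

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6.4, 4.0))
    if data[0] == "spectrum":
        s = data[1]
        ax.vlines(s.mz, 0, s.intensity, colors="black", linewidth=0.8)
        ax.set_xlabel("m/z")
    else:
        c = data[1]
        ax.plot(c.rt, c.intensity, color="black")
        ax.set_xlabel("retention time (min)")
    ax.set_ylabel("intensity")
    ax.set_title(entry.title)
    for a in entry.annotations:
        if a.kind == "text":
            ax.annotate(a.payload, (a.x, a.y), fontsize=8)
        elif a.kind == "arrow":
            ax.annotate("", (a.x, a.y),
                        xytext=(a.x, a.y * 1.1 + 1),
                        arrowprops={"arrowstyle": "->", "color": "red"})
    fig.savefig(path, format=fmt)
    plt.close(fig)


# ---------------------------------------------------------------------------
# MSP peak-list export
# ---------------------------------------------------------------------------

def export_peaklist(entry: NotebookEntry, path: str) -> None:
    """Write the entry's peak list as a NIST MSP text record.

    For processed entries the processed (not raw) peaks are exported — the
    form of the spectrum that the library search should see.
    """
    s = entry.spectrum()
    lines = [f"Name: {entry.title}"]
    if s.precursor_mz is not None:
        lines.append(f"PrecursorMZ: {s.precursor_mz:.6f}")
    if s.precursor_charge:
        lines.append(f"Charge: {s.precursor_charge}")
    lines.append(f"Num peaks: {s.n_peaks}")
    lines += [f"{mz:.6f} {inten:.6f}" for mz, inten in zip(s.mz, s.intensity)]
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_msp(path: str) -> list[dict]:
    """Parse MSP records (Name/PrecursorMZ/Charge/Num peaks + peak lines)."""
    records, current = [], None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                current = None
                continue
            if line.lower().startswith("name:"):
                current = {"name": line.split(":", 1)[1].strip(), "peaks": []}
                records.append(current)
            elif current is not None and ":" in line and not line[0].isdigit():
                key, val = (x.strip() for x in line.split(":", 1))
                current[key.lower().replace(" ", "_")] = val
            elif current is not None:
                mz_s, int_s = line.split()[:2]
                current["peaks"].append((float(mz_s), float(int_s)))
    return records
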