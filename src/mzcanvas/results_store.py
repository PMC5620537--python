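"""Relational PSM results store with importers, query shortcuts, and scan linkage.

Search results from Mascot, Proteome Discoverer, Comet, or X!Tandem — as
delimited text or pepXML — land in a single SQLite table with
worksheet-style canonical column names. Queries are read-only SELECTs; short
aliases ("varmods", "seq", "score", ...) expand to the canonical columns
before execution, and a small completer suggests SQL keywords and column
names. Each record remembers its run basename so a PSM can be walked back
to its MS/MS scan through a RunCache.
"""

from __future__ import annotations

import os
import re
import sqlite3
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import DataError, QueryError
from .model import Spectrum
from .spectra_io import RunCache

ENGINES = ("mascot", "xtandem", "comet", "proteome_discoverer", "internal")

TABLE = "psms"

#: Canonical (worksheet-style) column names, in storage order.
COLUMNS = [
    "Run",
    "Scan",
    "Peptide Sequence",
    "Variable Modifications",
    "Charge",
    "Peptide Score",
    "Engine",
    "Protein Accessions",
    "Precursor MZ",
    "RT",
]

#: Query shortcuts: alias -> canonical column.
SHORTCUTS = {
    "run": "Run",
    "scan": "Scan",
    "seq": "Peptide Sequence",
    "peptide": "Peptide Sequence",
    "varmods": "Variable Modifications",
    "mods": "Variable Modifications",
    "charge": "Charge",
    "score": "Peptide Score",
    "engine": "Engine",
    "protein": "Protein Accessions",
    "accessions": "Protein Accessions",
    "mz": "Precursor MZ",
    "rt": "RT",
}

SQL_KEYWORDS = [
    "AND", "AS", "ASC", "BETWEEN", "BY", "COUNT", "DESC", "DISTINCT", "FROM",
    "GROUP", "HAVING", "IN", "LIKE", "LIMIT", "NOT", "OR", "ORDER", "SELECT",
    "WHERE",
]


@dataclass
class PSMRecord:
    run: str
    scan_id: int
    peptide: str
    varmods: str = ""
    charge: int = 1
    score: float = 0.0
    engine: str = "internal"
    proteins: tuple[str, ...] = field(default_factory=tuple)
    precursor_mz: Optional[float] = None
    rt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.scan_id < 1:
            raise DataError("scan_id must be >= 1")
        if self.charge < 1:
            raise DataError("charge must be >= 1")
        if self.engine not in ENGINES:
            raise DataError(f"engine must be one of {ENGINES}, got {self.engine!r}")

    def as_row(self) -> tuple:
        return (self.run, self.scan_id, self.peptide, self.varmods, self.charge,
                self.score, self.engine, "; ".join(self.proteins),
                self.precursor_mz, self.rt)


class ResultsDB:
    """SQLite-backed table of PSM records.

    ``path=":memory:"`` keeps the store transient; any other path persists a
    single-file database.
    """

    def __init__(self, path: str = ":memory:"):
        self.path = path
        self._conn = sqlite3.connect(path)
        cols = ", ".join(f'"{c}" ' + t for c, t in zip(COLUMNS, (
            "TEXT", "INTEGER", "TEXT", "TEXT", "INTEGER", "REAL", "TEXT",
            "TEXT", "REAL", "REAL")))
        self._conn.execute(f'CREATE TABLE IF NOT EXISTS {TABLE} ({cols})')
        self._conn.commit()

    # -- loading ----------------------------------------------------------

    def add_records(self, records: Iterable[PSMRecord]) -> int:
        records = list(records)
        seen = set()
        for r in records:
            key = (r.run, r.scan_id, r.peptide, r.varmods, r.charge)
            if key in seen:
                raise DataError(f"duplicate PSM in import batch: {key}")
            seen.add(key)
        ph = ", ".join("?" * len(COLUMNS))
        self._conn.executemany(
            f'INSERT INTO {TABLE} VALUES ({ph})', [r.as_row() for r in records])
        self._conn.commit()
        return len(records)

    def records(self) -> list[PSMRecord]:
        rows = self._conn.execute(
            f'SELECT * FROM {TABLE} ORDER BY "Run", "Scan"').fetchall()
        return [_row_to_record(row) for row in rows]

    def __len__(self) -> int:
        return self._conn.execute(f"SELECT COUNT(*) FROM {TABLE}").fetchone()[0]

    # -- querying ---------------------------------------------------------

    def query(self, expression: str) -> pd.DataFrame:
        """Run a read-only SELECT with column shortcuts expanded.

        Anything other than a single SELECT statement is rejected.
        """
        sql = expand_shortcuts(expression)
        stripped = sql.strip().rstrip(";").strip()
        if ";" in stripped:
            raise QueryError("only a single statement is allowed")
        if not re.match(r"(?is)^\s*select\b", stripped):
            raise QueryError("results store is read-only: SELECT statements only")
        self._conn.execute("PRAGMA query_only=ON")
        try:
            return pd.read_sql_query(stripped, self._conn)
        except (sqlite3.Error, pd.errors.DatabaseError) as exc:
            raise QueryError(str(exc)) from exc
        finally:
            self._conn.execute("PRAGMA query_only=OFF")

    def matched_scan_ids(self, run_basename: Optional[str] = None) -> set[int]:
        if run_basename is None:
            rows = self._conn.execute(f'SELECT "Scan" FROM {TABLE}')
        else:
            rows = self._conn.execute(
                f'SELECT "Scan" FROM {TABLE} WHERE "Run" = ?', (run_basename,))
        return {r[0] for r in rows}

    def close(self) -> None:
        self._conn.close()


def _row_to_record(row: tuple) -> PSMRecord:
    proteins = tuple(p for p in (x.strip() for x in (row[7] or "").split(";")) if p)
    return PSMRecord(run=row[0], scan_id=row[1], peptide=row[2], varmods=row[3],
                     charge=row[4], score=row[5], engine=row[6],
                     proteins=proteins, precursor_mz=row[8], rt=row[9])


# ---------------------------------------------------------------------------
# Shortcut expansion and completion
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r'"[^"]*"|\'[^\']*\'|[A-Za-z_][A-Za-z0-9_]*')


def expand_shortcuts(sql: str) -> str:
    """Replace shortcut identifiers with quoted canonical column names.

    Quoted strings are left untouched; matching is case-insensitive.
    """
    def sub(m: re.Match) -> str:
        tok = m.group(0)
        if tok[0] in "\"'":
            return tok
        return f'"{SHORTCUTS[tok.lower()]}"' if tok.lower() in SHORTCUTS else tok

    return _TOKEN_RE.sub(sub, sql)


def complete(fragment: str, cursor: Optional[int] = None) -> list[str]:
    """Completions for the token ending at ``cursor`` (default: end).

    Keywords come before column names/shortcuts; each group alphabetical;
    prefix match is case-insensitive. An empty token yields everything.
    """
    if cursor is None:
        cursor = len(fragment)
    head = fragment[:cursor]
    m = re.search(r"[A-Za-z_][A-Za-z0-9_]*$", head)
    prefix = (m.group(0) if m else "").lower()
    kw = sorted(k for k in SQL_KEYWORDS if k.lower().startswith(prefix))
    cols = sorted(
        {c for a, c in SHORTCUTS.items() if a.startswith(prefix)}
        | {c for c in COLUMNS if c.lower().startswith(prefix)})
    return kw + cols


# ---------------------------------------------------------------------------
# Importers / exporter
# ---------------------------------------------------------------------------

#: Acceptable header spellings per canonical column for delimited imports.
_HEADER_ALIASES = {
    "Run": ["run", "run basename", "file", "raw file", "spectrum file"],
    "Scan": ["scan", "scan number", "first scan", "scannumber"],
    "Peptide Sequence": ["peptide sequence", "peptide", "sequence"],
    "Variable Modifications": ["variable modifications", "varmods",
                               "modifications"],
    "Charge": ["charge", "z", "precursor charge"],
    "Peptide Score": ["peptide score", "score", "ions score", "xcorr",
                      "hyperscore", "expect"],
    "Engine": ["engine", "search engine"],
    "Protein Accessions": ["protein accessions", "protein", "proteins",
                           "accession"],
    "Precursor MZ": ["precursor mz", "m/z", "mz", "precursor m/z"],
    "RT": ["rt", "retention time", "rt (min)"],
}

_REQUIRED = ["Run", "Scan", "Peptide Sequence", "Charge"]


def import_results(path: str, fmt: Optional[str] = None,
                   db: Optional[ResultsDB] = None,
                   engine: str = "internal",
                   top_rank_only: bool = True) -> ResultsDB:
    """Import a results file (tsv, csv, or pepxml) into a ResultsDB.

    The format is inferred from the extension when not given. Combined
    multi-run files are fine — every record keeps its run basename.
    """
    if fmt is None:
        low = path.lower()
        if low.endswith((".pep.xml", ".pepxml", ".xml")):
            fmt = "pepxml"
        elif low.endswith(".csv"):
            fmt = "csv"
        else:
            fmt = "tsv"
    if fmt in ("tsv", "csv"):
        records = _read_delimited(path, sep="," if fmt == "csv" else "\t",
                                  engine=engine)
    elif fmt == "pepxml":
        records = _read_pepxml(path, top_rank_only=top_rank_only)
    else:
        raise DataError(f"unknown results format {fmt!r}")
    db = db or ResultsDB()
    db.add_records(records)
    return db


def _read_delimited(path: str, sep: str, engine: str) -> list[PSMRecord]:
    if not os.path.exists(path):
        raise DataError(f"results file not found: {path}")
    df = pd.read_csv(path, sep=sep)
    colmap = {}
    lower = {str(c).strip().lower(): c for c in df.columns}
    for canon, aliases in _HEADER_ALIASES.items():
        for alias in [canon.lower()] + aliases:
            if alias in lower:
                colmap[canon] = lower[alias]
                break
    missing = [c for c in _REQUIRED if c not in colmap]
    if missing:
        raise DataError(f"results file {path} lacks required columns: {missing}")

    def get(row, canon, default=None):
        if canon not in colmap:
            return default
        v = row[colmap[canon]]
        return default if pd.isna(v) else v

    records = []
    for _, row in df.iterrows():
        records.append(PSMRecord(
            run=str(get(row, "Run")),
            scan_id=int(get(row, "Scan")),
            peptide=str(get(row, "Peptide Sequence")),
            varmods=str(get(row, "Variable Modifications", "") or ""),
            charge=int(get(row, "Charge")),
            score=float(get(row, "Peptide Score", 0.0) or 0.0),
            engine=str(get(row, "Engine", engine) or engine),
            proteins=tuple(p.strip() for p in
                           str(get(row, "Protein Accessions", "") or "").split(";")
                           if p.strip()),
            precursor_mz=(lambda v: None if v is None else float(v))(
                get(row, "Precursor MZ")),
            rt=(lambda v: None if v is None else float(v))(get(row, "RT")),
        ))
    return records


def _read_pepxml(path: str, top_rank_only: bool = True) -> list[PSMRecord]:
    from pyteomics import pepxml

    if not os.path.exists(path):
        raise DataError(f"results file not found: {path}")
    records = []
    with pepxml.read(path) as reader:
        for query in reader:
            hits = query.get("search_hit", [])
            if top_rank_only:
                hits = [h for h in hits if h.get("hit_rank", 1) == 1]
            spectrum = query.get("spectrum", "")
            run = spectrum.split(".")[0] if spectrum else "unknown"
            rt_s = query.get("retention_time_sec")
            z = int(query.get("assumed_charge", 1))
            neutral = query.get("precursor_neutral_mass")
            pmz = None
            if neutral is not None:
                pmz = (float(neutral) + z * 1.007276) / z
            for hit in hits:
                scores = hit.get("search_score", {})
                score = float(next(iter(scores.values()))) if scores else 0.0
                mods = hit.get("modifications") or []
                varmods = "; ".join(
                    f"{int(m['position'])}: {m.get('mass', 0):+.4f}" for m in mods)
                records.append(PSMRecord(
                    run=run,
                    scan_id=int(query.get("start_scan", 0) or 0) or 1,
                    peptide=hit["peptide"],
                    varmods=varmods,
                    charge=z,
                    score=score,
                    engine="internal",
                    proteins=tuple(p.get("protein", "") for p in
                                   hit.get("proteins", []) if p.get("protein")),
                    precursor_mz=pmz,
                    rt=None if rt_s is None else float(rt_s) / 60.0,
                ))
    return records


def export_results(db: ResultsDB, path: str) -> None:
    """Write the store as canonical TSV (losslessly re-importable)."""
    df = pd.DataFrame([r.as_row() for r in db.records()], columns=COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def psm_to_scan(db: ResultsDB, record: PSMRecord, cache: RunCache) -> Spectrum:
    """Resolve a PSM back to its MS/MS spectrum through the run cache."""
    try:
        run = cache.get_by_basename(record.run)
    except DataError:
        raise DataError(f"raw file for run {record.run!r} is not available") from None
    return run.get_scan(record.scan_id)
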