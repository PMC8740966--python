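"""Readers and writers for absorbance spectra and their sample metadata.

The central data structure is :class:`SpectrumSet`: a wavenumber grid
(stored high-to-low, the acquisition order of a mid-IR instrument scanning
4000 to 400 cm^-1), an ``n_spectra x n_points`` absorbance matrix and one
metadata record per spectrum.  Three on-disk forms are supported:

* a wide delimited table (CSV/TSV) or XLSX workbook, rows = wavenumbers and
  columns = spectra (or transposed), plus an optional metadata sidecar CSV;
* a directory of per-spectrum two-column text files (wavenumber, absorbance),
  as produced by exporting instrument-native files to plain text;
* :func:`write_spectrum_set` emits the wide CSV + sidecar form and
  round-trips exactly through :func:`read_spectra_table`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumSet",
    "SpectrumMeta",
    "ParseError",
    "GridMismatchError",
    "META_COLUMNS",
    "UNKNOWN",
    "CANONICAL_TAXA",
    "KNOTWEED_COMPLEX",
    "OUT_SPECIES",
    "normalize_taxon",
    "read_spectra_table",
    "read_opus_txt_dir",
    "write_spectrum_set",
]


class ParseError(ValueError):
    """A cell or file could not be parsed as numeric spectral data."""


class GridMismatchError(ValueError):
    """Wavenumber grids disagree where they are required to be identical."""


META_COLUMNS = [
    "spectrum_id",
    "sample_id",
    "plant_type",
    "leaf_surface",
    "location",
    "collection_year",
]

#: Explicit token used for metadata fields that were not supplied.
UNKNOWN = "unknown"

#: Canonical labels for the sixteen plant types of the herbarium panel.
CANONICAL_TAXA = [
    "Reynoutria japonica var. japonica",
    "Reynoutria japonica var. compacta",
    "Reynoutria japonica var. uzenensis",
    "Fallopia baldschuanica",
    "Reynoutria sachalinensis",
    "Reynoutria x bohemica",
    "Reynoutria sachalinensis x Fallopia baldschuanica",
    "Reynoutria japonica x Fallopia baldschuanica",
    "Reynoutria japonica var. compacta x baldschuanica",
    "Reynoutria japonica var. compacta x sachalinensis",
    "Reynoutria japonica var. japonica x compacta",
    "Fallopia cilinodis",
    "Fallopia convolvulus",
    "Fallopia multiflora",
    "Fagopyrum esculentum",
    "Rumex acetosella",
]

#: The eleven interbreeding knotweed-complex taxa (species, varieties, hybrids).
KNOTWEED_COMPLEX = CANONICAL_TAXA[:11]

#: The five more distantly related Polygonaceae out-species.
OUT_SPECIES = CANONICAL_TAXA[11:]

# Printed genus usage is inconsistent for these plants (Reynoutria vs
# Fallopia, several hybrid spellings); map every known variant onto one
# canonical label so class vocabularies stay consistent.
_SYNONYMS = {
    "fallopia japonica": "Reynoutria japonica var. japonica",
    "fallopia japonica var. japonica": "Reynoutria japonica var. japonica",
    "reynoutria japonica": "Reynoutria japonica var. japonica",
    "fallopia japonica var. compacta": "Reynoutria japonica var. compacta",
    "fallopia compacta": "Reynoutria japonica var. compacta",
    "fallopia japonica var. uzenensis": "Reynoutria japonica var. uzenensis",
    "fallopia baldschuanica": "Fallopia baldschuanica",
    "fallopia sachalinensis": "Reynoutria sachalinensis",
    "reynoutria x bohemica": "Reynoutria x bohemica",
    "fallopia x bohemica": "Reynoutria x bohemica",
    "reynoutria japonica x sachalinensis": "Reynoutria x bohemica",
    "reynoutria japonica var. japonica x sachalinensis": "Reynoutria x bohemica",
    "reynoutria japonica x sachalinensis (reynoutria x bohemica)": "Reynoutria x bohemica",
    "reynoutria japonica x baldschuanica": "Reynoutria japonica x Fallopia baldschuanica",
    "reynoutria japonica var. japonica x fallopia baldschuanica": "Reynoutria japonica x Fallopia baldschuanica",
    "fallopia japonica var. compacta x baldschuanica": "Reynoutria japonica var. compacta x baldschuanica",
    "reynoutria japonica var. compacta x reynoutria sachalinensis": "Reynoutria japonica var. compacta x sachalinensis",
    "reynoutria japonica var. japonica x reynoutria japonica var. compacta": "Reynoutria japonica var. japonica x compacta",
}


def normalize_taxon(name: str) -> str:
    """Map a printed taxon name onto its canonical label.

    Case, surrounding whitespace, the multiplication sign and doubled
    spaces are ignored.  Names with no known canonical form (for example
    synthetic class labels) are returned stripped but otherwise unchanged.
    """
    key = re.sub(r"\s+", " ", name.strip().replace("×", "x")).lower()
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    for canon in CANONICAL_TAXA:
        if key == canon.lower():
            return canon
    return name.strip()


@dataclass(frozen=True)
class SpectrumMeta:
    """Metadata record for one spectrum."""

    spectrum_id: str
    sample_id: str = UNKNOWN
    plant_type: str = UNKNOWN
    leaf_surface: str = UNKNOWN
    location: str = UNKNOWN
    collection_year: int | None = None


@dataclass
class SpectrumSet:
    """A wavenumber grid, absorbance matrix and per-spectrum metadata.

    Parameters
    ----------
    wavenumbers
        Strictly decreasing grid in cm^-1 (acquisition order 4000 -> 400).
    absorbance
        Matrix of shape ``(n_spectra, len(wavenumbers))``, finite throughout.
    meta
        One row per spectrum with columns :data:`META_COLUMNS`;
        ``spectrum_id`` values must be unique.
    attrs
        Free-form provenance dictionary (e.g. simulation ground truth).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: pd.DataFrame
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.wavenumbers.ndim != 1:
            raise ValueError("wavenumbers must be one-dimensional")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise ValueError("wavenumbers contain non-finite values")
        d = np.diff(self.wavenumbers)
        if len(self.wavenumbers) > 1 and not np.all(d < 0):
            raise ValueError("wavenumber grid must be strictly decreasing")
        if self.absorbance.shape[1] != len(self.wavenumbers):
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns but the "
                f"grid has {len(self.wavenumbers)} points"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains missing or non-finite values")
        if not isinstance(self.meta, pd.DataFrame):
            self.meta = pd.DataFrame([vars(m) for m in self.meta])
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        for c in missing:
            self.meta[c] = None if c == "collection_year" else UNKNOWN
        self.meta = self.meta[META_COLUMNS].reset_index(drop=True)
        if len(self.meta) != self.absorbance.shape[0]:
            raise ValueError(
                f"{len(self.meta)} metadata records for "
                f"{self.absorbance.shape[0]} spectra"
            )
        ids = self.meta["spectrum_id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate spectrum_id {dup!r}")

    # -- conveniences -------------------------------------------------

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.absorbance.shape[1]

    @property
    def spectrum_ids(self) -> list[str]:
        return self.meta["spectrum_id"].astype(str).tolist()

    def labels(self, field_name: str = "plant_type") -> np.ndarray:
        if field_name not in self.meta.columns:
            raise KeyError(f"unknown metadata field {field_name!r}")
        return self.meta[field_name].to_numpy()

    def subset(self, index: Sequence[int] | np.ndarray) -> "SpectrumSet":
        """Row subset (spectra), keeping the grid and attrs."""
        index = np.asarray(index)
        return SpectrumSet(
            self.wavenumbers.copy(),
            self.absorbance[index],
            self.meta.iloc[index].reset_index(drop=True),
            dict(self.attrs),
        )

    def with_absorbance(self, absorbance: np.ndarray,
                        wavenumbers: np.ndarray | None = None) -> "SpectrumSet":
        """Same metadata, new values (and optionally a new grid)."""
        wn = self.wavenumbers if wavenumbers is None else wavenumbers
        return SpectrumSet(np.asarray(wn, float).copy(), absorbance,
                           self.meta.copy(), dict(self.attrs))


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

def _read_table(path: Path, sheet: int | str, delimiter: str | None) -> pd.DataFrame:
    if path.suffix.lower() in {".xlsx", ".xlsm", ".xls"}:
        from openpyxl import load_workbook

        wb = load_workbook(path, read_only=True, data_only=True)
        ws = wb[wb.sheetnames[sheet]] if isinstance(sheet, int) else wb[sheet]
        rows = list(ws.iter_rows(values_only=True))
        wb.close()
        if not rows:
            raise ParseError(f"{path}: empty worksheet")
        header = [str(c) for c in rows[0]]
        df = pd.DataFrame(rows[1:], columns=header)
        df = df.set_index(df.columns[0])
        return df
    sep = delimiter
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if len(header) != len(set(header)):
        dup = next(h for h in header if header.count(h) > 1)
        raise ValueError(f"{path}: duplicate spectrum id {dup!r} in header")
    # read cells as text: exact float round-trip via to_numeric, and parse
    # errors can report the offending cell verbatim
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return df.set_index(df.columns[0])


def _to_numeric_block(df: pd.DataFrame, path: Path) -> np.ndarray:
    # float() is correctly rounded, so text written at repr precision
    # converts back bit-for-bit (pandas' fast parsers do not guarantee this)
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        values = df[col].to_numpy()
        try:
            out[:, j] = values.astype(float)
        except (TypeError, ValueError):
            for i, v in enumerate(values):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}: non-numeric value {v!r} at row "
                        f"{df.index[i]!r}, column {col!r}"
                    ) from None
            raise
    if not np.all(np.isfinite(out)):
        i, j = np.argwhere(~np.isfinite(out))[0]
        raise ParseError(
            f"{path}: missing or non-finite value at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    return out


def _join_meta(spectrum_ids: Iterable[str], meta_path: str | Path | None) -> pd.DataFrame:
    ids = [str(s) for s in spectrum_ids]
    if len(ids) != len(set(ids)):
        dup = next(s for s in ids if ids.count(s) > 1)
        raise ValueError(f"duplicate spectrum id {dup!r}")
    meta = pd.DataFrame({"spectrum_id": ids})
    if meta_path is not None:
        side = pd.read_csv(meta_path, dtype={"spectrum_id": str})
        if "spectrum_id" not in side.columns:
            raise ParseError(f"{meta_path}: sidecar lacks a spectrum_id column")
        if side["spectrum_id"].duplicated().any():
            raise ValueError(f"{meta_path}: duplicate spectrum ids in sidecar")
        missing = set(ids) - set(side["spectrum_id"])
        if missing:
            raise ValueError(
                f"{meta_path}: sidecar does not cover spectrum ids "
                f"{sorted(missing)[:5]}"
            )
        meta = meta.merge(side, on="spectrum_id", how="left")
    for c in META_COLUMNS:
        if c not in meta.columns:
            meta[c] = None if c == "collection_year" else UNKNOWN
    meta["plant_type"] = [
        normalize_taxon(str(t)) if t is not None and not pd.isna(t) else UNKNOWN
        for t in meta["plant_type"]
    ]
    for c in ("sample_id", "leaf_surface", "location"):
        meta[c] = meta[c].where(~meta[c].isna(), UNKNOWN)
    year = pd.to_numeric(meta["collection_year"], errors="coerce")
    meta["collection_year"] = [None if pd.isna(y) else int(y) for y in year]
    return meta[META_COLUMNS]


def read_spectra_table(
    path: str | Path,
    orientation: str = "wide_rows_are_wavenumbers",
    meta_path: str | Path | None = None,
    sheet: int | str = 0,
    delimiter: str | None = None,
) -> SpectrumSet:
    """Load a wide spectra table (CSV/TSV/XLSX) into a :class:`SpectrumSet`.

    ``orientation`` selects whether table rows carry wavenumbers (columns are
    spectra, the usual export layout) or spectra.  A metadata sidecar CSV is
    joined by ``spectrum_id``; absent fields become the ``unknown`` token.
    The grid is re-ordered to strictly decreasing; a grid that is not
    strictly monotone after sorting raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if orientation not in {"wide_rows_are_wavenumbers", "wide_rows_are_spectra"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path, sheet, delimiter)
    if orientation == "wide_rows_are_spectra":
        df = df.T
    try:
        grid = np.asarray([float(v) for v in df.index], dtype=float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric wavenumber label: {exc}") from exc
    values = _to_numeric_block(df, path).T  # spectra x points
    order = np.argsort(grid)[::-1]
    grid, values = grid[order], values[:, order]
    if len(grid) > 1 and not np.all(np.diff(grid) < 0):
        raise GridMismatchError(f"{path}: wavenumber grid has duplicate points")
    meta = _join_meta(df.columns, meta_path)
    return SpectrumSet(grid, values, meta)


def read_opus_txt_dir(
    directory: str | Path,
    meta_path: str | Path | None = None,
    pattern: str = "*.txt",
    grid_tol: float = 1e-6,
) -> SpectrumSet:
    """Load a directory of two-column (wavenumber, absorbance) text files.

    All files must share an identical grid within ``grid_tol`` cm^-1; the
    file stem becomes the ``spectrum_id``.
    """
    directory = Path(directory)
    files = sorted(directory.glob(pattern))
    if not files:
        raise FileNotFoundError(f"no {pattern} files in {directory}")
    grid = None
    rows, ids = [], []
    for f in files:
        try:
            arr = np.loadtxt(f, delimiter=None)
        except ValueError:
            arr = np.loadtxt(f, delimiter=",")
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ParseError(f"{f}: expected two numeric columns")
        wn, ab = arr[:, 0], arr[:, 1]
        order = np.argsort(wn)[::-1]
        wn, ab = wn[order], ab[order]
        if grid is None:
            grid = wn
        elif wn.shape != grid.shape or np.max(np.abs(wn - grid)) > grid_tol:
            raise GridMismatchError(
                f"{f}: wavenumber grid differs from {files[0].name}"
            )
        rows.append(ab)
        ids.append(f.stem)
    meta = _join_meta(ids, meta_path)
    return SpectrumSet(grid, np.vstack(rows), meta)


def write_spectrum_set(
    sset: SpectrumSet,
    path: str | Path,
    meta_path: str | Path | None = None,
) -> Path:
    """Write the wide CSV + metadata sidecar form; returns the sidecar path.

    Values are written with full ``repr`` precision so that
    :func:`read_spectra_table` reproduces them bit-for-bit.
    """
    path = Path(path)
    if meta_path is None:
        meta_path = path.with_name(path.stem + "_meta.csv")
    meta_path = Path(meta_path)
    wide = pd.DataFrame(
        sset.absorbance.T,
        index=pd.Index(sset.wavenumbers, name="wavenumber"),
        columns=sset.spectrum_ids,
    )
    wide.to_csv(path)
    sset.meta.to_csv(meta_path, index=False)
    return meta_path
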