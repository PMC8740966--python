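"""Biomarker extraction from PCA loadings.

Second-derivative preprocessing inverts band signs, so candidate peaks are
local extrema of the loading's *absolute* value; a greedy pass in decreasing
magnitude enforces a minimum wavenumber separation between reported peaks.
Peaks are matched against a wavenumber->compound lookup shipped with the
package, and class direction is assigned from the sign of the class-mean
difference at each peak.  Band-intensity ratios (concentration) use
rubber-band-corrected class means; horizontal peak shifts (structure) use
vector-normalised class means.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .preprocess import l2_normalize_rows, rubberband_correct_row
from .spectra_io import SpectrumSet

__all__ = [
    "PeakTable",
    "BiomarkerLookup",
    "pick_loading_peaks",
    "assign_peaks",
    "annotate_direction",
    "band_intensity_ratio",
    "peak_shift",
]

PEAK_COLUMNS = ["wavenumber", "loading_value", "direction", "assignment", "reference"]


@dataclass
class PeakTable:
    """Peak-picked loading extrema, sorted by descending wavenumber."""

    table: pd.DataFrame
    min_separation: float

    def __post_init__(self) -> None:
        for c in PEAK_COLUMNS:
            if c not in self.table.columns:
                self.table[c] = None
        self.table = (
            self.table[PEAK_COLUMNS]
            .sort_values("wavenumber", ascending=False)
            .reset_index(drop=True)
        )
        wn = self.table["wavenumber"].to_numpy(dtype=float)
        if len(wn) > 1 and np.min(np.abs(np.diff(wn))) < self.min_separation - 1e-9:
            raise ValueError("peaks closer than the configured minimum separation")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.table["wavenumber"].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        out = self.table.rename(columns={
            "wavenumber": "Wavenumber_cm",
            "loading_value": "LoadingValue",
            "direction": "Direction",
            "assignment": "Assignment",
            "reference": "Reference",
        })
        out.to_csv(path, index=False)


@dataclass
class BiomarkerLookup:
    """Wavenumber -> tentative chemical assignment lookup."""

    entries: pd.DataFrame
    tolerance: float = 4.0  # cm^-1; one grid step at 4 cm^-1 spacing

    def __post_init__(self) -> None:
        if self.entries["wavenumber"].duplicated().any():
            raise ValueError("lookup wavenumbers must be unique")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")

    @classmethod
    def default(cls, tolerance: float = 4.0) -> "BiomarkerLookup":
        """The packaged lookup of characterised diagnostic wavenumbers."""
        with resources.files("irchemo.data").joinpath("biomarker_lookup.csv").open() as fh:
            entries = pd.read_csv(fh)
        return cls(entries=entries, tolerance=tolerance)


def pick_loading_peaks(
    wavenumbers: np.ndarray,
    loading: np.ndarray,
    min_separation: float = 20.0,
    max_peaks: int | None = None,
) -> PeakTable:
    """Pick loading extrema at least ``min_separation`` cm^-1 apart.

    Candidates are interior local maxima of ``|loading|``; they are accepted
    greedily in decreasing magnitude, discarding any candidate within
    ``min_separation`` of an already-accepted peak.  A constant loading
    yields an empty table.
    """
    wn = np.asarray(wavenumbers, dtype=float)
    l = np.asarray(loading, dtype=float)
    if wn.shape != l.shape:
        raise ValueError("loading length must equal grid length")
    spacing = float(np.median(np.abs(np.diff(wn)))) if len(wn) > 1 else 0.0
    if min_separation <= spacing:
        raise ValueError("min_separation must exceed the grid spacing")
    mag = np.abs(l)
    candidates = [
        i for i in range(1, len(l) - 1)
        if mag[i] > mag[i - 1] and mag[i] >= mag[i + 1] and mag[i] > 0
    ]
    # decreasing magnitude; deterministic tie-break on wavenumber
    candidates.sort(key=lambda i: (-mag[i], -wn[i]))
    accepted: list[int] = []
    for i in candidates:
        if all(abs(wn[i] - wn[j]) >= min_separation for j in accepted):
            accepted.append(i)
        if max_peaks is not None and len(accepted) >= max_peaks:
            break
    table = pd.DataFrame({
        "wavenumber": wn[accepted],
        "loading_value": l[accepted],
        "direction": None,
        "assignment": None,
        "reference": None,
    })
    return PeakTable(table=table, min_separation=min_separation)


def assign_peaks(peaks: PeakTable, lookup: BiomarkerLookup | None = None) -> PeakTable:
    """Annotate each peak with the nearest lookup entry within tolerance.

    Ties go to the nearer entry, then the lower wavenumber; unmatched peaks
    are labelled ``"unassigned"``.
    """
    lookup = lookup or BiomarkerLookup.default()
    ref_wn = lookup.entries["wavenumber"].to_numpy(dtype=float)
    table = peaks.table.copy()
    assignments, references = [], []
    for wn in table["wavenumber"].to_numpy(dtype=float):
        dist = np.abs(ref_wn - wn)
        order = sorted(range(len(ref_wn)), key=lambda k: (dist[k], ref_wn[k]))
        best = order[0] if len(order) else None
        if best is not None and dist[best] <= lookup.tolerance:
            assignments.append(lookup.entries["assignment"].iloc[best])
            references.append(lookup.entries["reference"].iloc[best])
        else:
            assignments.append("unassigned")
            references.append(None)
    table["assignment"] = assignments
    table["reference"] = references
    return PeakTable(table=table, min_separation=peaks.min_separation)


def annotate_direction(
    peaks: PeakTable,
    wavenumbers: np.ndarray,
    mean_a: np.ndarray,
    mean_b: np.ndarray,
    label_a: str = "A",
    label_b: str = "B",
    rel_tol: float = 1e-3,
) -> PeakTable:
    """Mark each peak as higher in class A or B (or structural if neither).

    Direction is taken from the sign of the class-mean difference at the
    peak's wavenumber, not from the loading sign, because the second
    derivative inverts band polarity.
    """
    wn = np.asarray(wavenumbers, dtype=float)
    diff = np.asarray(mean_a, float) - np.asarray(mean_b, float)
    scale = max(np.max(np.abs(mean_a)), np.max(np.abs(mean_b)), 1e-30)
    table = peaks.table.copy()
    directions = []
    for p in table["wavenumber"].to_numpy(dtype=float):
        i = int(np.argmin(np.abs(wn - p)))
        if abs(diff[i]) <= rel_tol * scale:
            directions.append("structural")
        elif diff[i] > 0:
            directions.append(f"higher_in_{label_a}")
        else:
            directions.append(f"higher_in_{label_b}")
    table["direction"] = directions
    return PeakTable(table=table, min_separation=peaks.min_separation)


def _window_mask(wavenumbers: np.ndarray, center: float, half_width: float) -> np.ndarray:
    mask = np.abs(np.asarray(wavenumbers, float) - center) <= half_width
    if not mask.any():
        raise ValueError(
            f"window [{center - half_width}, {center + half_width}] cm^-1 "
            "contains no grid points"
        )
    return mask


def _check_shared_grid(set_a: SpectrumSet, set_b: SpectrumSet) -> None:
    if set_a.wavenumbers.shape != set_b.wavenumbers.shape or not np.allclose(
        set_a.wavenumbers, set_b.wavenumbers
    ):
        raise ValueError("the two spectrum sets must share a wavenumber grid")


def band_intensity_ratio(
    set_a: SpectrumSet,
    set_b: SpectrumSet,
    center: float,
    half_width: float,
) -> float:
    """Ratio (A over B) of baseline-corrected band heights at a peak.

    Each set's class-mean spectrum is rubber-band corrected over the full
    grid; the band height is the maximum of the corrected mean within
    ``[center - half_width, center + half_width]``.  The ratio indicates
    relative concentration.
    """
    _check_shared_grid(set_a, set_b)
    wn = set_a.wavenumbers
    mask = _window_mask(wn, center, half_width)
    heights = []
    for sset in (set_a, set_b):
        mean = sset.absorbance.mean(axis=0)
        corrected = rubberband_correct_row(wn, mean)
        heights.append(float(corrected[mask].max()))
    if heights[1] <= 1e-12:
        raise ValueError("denominator band height is not positive")
    return heights[0] / heights[1]


def peak_shift(
    set_a: SpectrumSet,
    set_b: SpectrumSet,
    center: float,
    half_width: float,
) -> float:
    """Signed wavenumber shift (A minus B) of a band's maximum.

    Computed on vector-normalised class means; resolution is limited to the
    grid spacing.  A shift indicates molecular structural alteration.
    """
    _check_shared_grid(set_a, set_b)
    wn = set_a.wavenumbers
    mask = _window_mask(wn, center, half_width)
    positions = []
    for sset in (set_a, set_b):
        mean = l2_normalize_rows(sset.absorbance.mean(axis=0))[0]
        window = mean[mask]
        if np.ptp(window) == 0:
            raise ValueError("flat band window; shift is undefined")
        positions.append(float(wn[mask][int(np.argmax(window))]))
    return positions[0] - positions[1]
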