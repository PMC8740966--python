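"""Spectral preprocessing: fingerprint cut, Savitzky-Golay second
derivative, vector normalisation, mean-centring and rubber-band baseline
correction.

The classification chain is fixed as cut -> SG second derivative -> vector
normalise (per spectrum), with mean-centring applied at model-fit time using
training-set statistics only.  The chain is invariant to per-spectrum
multiplicative gain (sample-thickness variation): SG differentiation is
linear and vector normalisation removes the scale.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import savgol_filter

from .spectra_io import SpectrumSet

__all__ = [
    "PreprocessConfig",
    "cut_region",
    "sg_second_derivative",
    "vector_normalize",
    "mean_center",
    "rubberband_baseline",
    "preprocess_chain",
    "savgol_second_derivative_matrix",
    "l2_normalize_rows",
    "rubberband_correct_row",
]

_GRID_RTOL = 1e-6


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``sg_deriv_order`` is fixed at 2 for the standard chain; window and
    polynomial order are instrument-toolbox conventions and are therefore
    explicit, logged configuration rather than hidden defaults.
    """

    region_high: float = 1800.0
    region_low: float = 900.0
    sg_window: int = 9
    sg_polyorder: int = 2
    sg_deriv_order: int = 2
    normalise: str = "vector"   # {"vector", "none"}
    center: str = "mean"        # {"mean", "none"}

    def __post_init__(self) -> None:
        if self.region_high <= self.region_low:
            raise ValueError("region_high must exceed region_low")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and > sg_polyorder")
        if self.sg_polyorder < self.sg_deriv_order:
            raise ValueError("sg_polyorder must be >= sg_deriv_order")
        if self.normalise not in {"vector", "none"}:
            raise ValueError(f"unknown normalise mode {self.normalise!r}")
        if self.center not in {"mean", "none"}:
            raise ValueError(f"unknown center mode {self.center!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        return cls(**d)


def cut_region(sset: SpectrumSet, high: float = 1800.0, low: float = 900.0) -> SpectrumSet:
    """Retain exactly the grid points p with ``low <= p <= high``."""
    if high < low:
        high, low = low, high
    mask = (sset.wavenumbers >= low) & (sset.wavenumbers <= high)
    if not mask.any():
        raise ValueError(
            f"region [{low}, {high}] cm^-1 has no overlap with the grid "
            f"[{sset.wavenumbers.min()}, {sset.wavenumbers.max()}]"
        )
    return sset.with_absorbance(sset.absorbance[:, mask], sset.wavenumbers[mask])


def _check_uniform(grid: np.ndarray) -> None:
    steps = np.diff(grid)
    if len(steps) and not np.allclose(steps, steps[0], rtol=_GRID_RTOL, atol=0):
        raise ValueError("wavenumber grid is not uniformly spaced")


def savgol_second_derivative_matrix(matrix: np.ndarray, window: int, polyorder: int) -> np.ndarray:
    """Row-wise SG second derivative with respect to point index.

    Edges use a one-sided polynomial fit over the terminal window
    (``mode='interp'``); no data are fabricated by padding.  The constant
    scale factor between index- and cm^-1-derivatives is removed downstream
    by vector normalisation.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and > polyorder")
    if polyorder < 2:
        raise ValueError("polyorder must be >= 2 for a second derivative")
    if window > matrix.shape[1]:
        raise ValueError(
            f"SG window ({window}) exceeds grid length ({matrix.shape[1]})"
        )
    return savgol_filter(matrix, window, polyorder, deriv=2, delta=1.0,
                         axis=1, mode="interp")


def sg_second_derivative(sset: SpectrumSet, window: int = 9, polyorder: int = 2) -> SpectrumSet:
    """Savitzky-Golay second differentiation of every spectrum."""
    _check_uniform(sset.wavenumbers)
    return sset.with_absorbance(
        savgol_second_derivative_matrix(sset.absorbance, window, polyorder)
    )


def l2_normalize_rows(matrix: np.ndarray, ids=None) -> np.ndarray:
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    norms = np.linalg.norm(matrix, axis=1)
    if np.any(norms == 0):
        i = int(np.argmin(norms))
        name = ids[i] if ids is not None else f"row {i}"
        raise ValueError(f"cannot vector-normalise zero spectrum {name}")
    return matrix / norms[:, None]


def vector_normalize(sset: SpectrumSet) -> SpectrumSet:
    """Divide every spectrum by its Euclidean norm."""
    return sset.with_absorbance(
        l2_normalize_rows(sset.absorbance, sset.spectrum_ids)
    )


def mean_center(train: np.ndarray, apply_to: np.ndarray | None = None):
    """Centre columns by the *training* means.

    Returns ``(centered_train, centered_apply_to, column_means)``; the
    second element is None when ``apply_to`` is None.  External data are
    always shifted by the training means, never their own — this is the
    test-set leakage guard for the whole pipeline.
    """
    train = np.atleast_2d(np.asarray(train, dtype=float))
    if train.shape[0] == 0:
        raise ValueError("training matrix is empty")
    means = train.mean(axis=0)
    centered_apply = None
    if apply_to is not None:
        apply_to = np.atleast_2d(np.asarray(apply_to, dtype=float))
        if apply_to.shape[1] != train.shape[1]:
            raise ValueError(
                f"column count mismatch: train {train.shape[1]} vs "
                f"apply_to {apply_to.shape[1]}"
            )
        centered_apply = apply_to - means
    return train - means, centered_apply, means


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # Andrew monotone chain, lower hull only; x strictly increasing.
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            cross = (x[b] - x[a]) * (y[i] - y[a]) - (y[b] - y[a]) * (x[i] - x[a])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull)


def rubberband_correct_row(wavenumbers: np.ndarray, row: np.ndarray) -> np.ndarray:
    """Subtract the lower convex hull of one (wavenumber, absorbance) curve."""
    x = np.asarray(wavenumbers, dtype=float)
    y = np.asarray(row, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 grid points for baseline correction")
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    idx = _lower_hull_indices(xs, ys)
    baseline_sorted = np.interp(xs, xs[idx], ys[idx])
    baseline = np.empty_like(baseline_sorted)
    baseline[order] = baseline_sorted
    return y - baseline


def rubberband_baseline(sset: SpectrumSet) -> SpectrumSet:
    """Rubber-band (lower convex hull) baseline correction, per spectrum."""
    corrected = np.vstack([
        rubberband_correct_row(sset.wavenumbers, row) for row in sset.absorbance
    ])
    return sset.with_absorbance(corrected)


def preprocess_chain(sset: SpectrumSet, cfg: PreprocessConfig | None = None) -> SpectrumSet:
    """Apply cut -> SG second derivative -> vector normalise.

    Mean-centring is deliberately not part of this function: it belongs to
    model fitting, where the means must come from training data only.
    """
    cfg = cfg or PreprocessConfig()
    out = cut_region(sset, cfg.region_high, cfg.region_low)
    out = sg_second_derivative(out, cfg.sg_window, cfg.sg_polyorder)
    if cfg.normalise == "vector":
        out = vector_normalize(out)
    return out
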