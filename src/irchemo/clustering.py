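"""Hierarchical cluster analysis of class-mean spectra.

Agglomeration uses Ward's minimum-variance criterion on Euclidean
distances.  Two input modes are provided, differing in where the averaging
sits in the chain:

* fingerprint mode — average spectra by group, then SG second derivative and
  vector normalisation of the group means, then cluster;
* loadings mode — SG + vector normalisation per spectrum, select the columns
  at chosen wavenumbers (typically loading peak positions), average by
  group, then cluster.

Merge heights are on the Euclidean-distance scale (two singletons merge at
their inter-point distance).  Trees export to Newick in ultrametric form:
every leaf sits at depth ``root_height / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .preprocess import (
    PreprocessConfig,
    cut_region,
    l2_normalize_rows,
    savgol_second_derivative_matrix,
)
from .spectra_io import SpectrumSet

__all__ = [
    "HCAResult",
    "class_mean_spectra",
    "hca",
    "hca_fingerprint_mode",
    "hca_loadings_mode",
    "to_newick",
]


@dataclass
class HCAResult:
    """Agglomerative merge history in scipy linkage form.

    ``linkage`` has one row per merge: left node, right node, merge height,
    cluster size.  Node ids < n_leaves are leaves (indexing ``labels``);
    node id ``n_leaves + i`` is the cluster created by merge row ``i``.
    """

    linkage: np.ndarray
    labels: list[str]
    mode: str = "fingerprint"
    selected_wavenumbers: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.linkage.shape != (len(self.labels) - 1, 4):
            raise ValueError("linkage shape inconsistent with leaf count")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValueError("merge heights must be non-decreasing (Ward)")
        if int(self.linkage[-1, 3]) != len(self.labels):
            raise ValueError("final cluster must contain every leaf")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cophenetic_matrix(self) -> np.ndarray:
        return hierarchy.cophenet(self.linkage)

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat cluster id per leaf label at the given cluster count."""
        flat = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def merge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["left", "right", "height", "size"]
        )


def class_mean_spectra(sset: SpectrumSet, group_by: str = "plant_type"):
    """Arithmetic group-mean spectra; labels returned in lexicographic order."""
    labels = sset.labels(group_by)
    groups = sorted({str(v) for v in labels})
    means = np.vstack([
        sset.absorbance[np.asarray(labels).astype(str) == g].mean(axis=0)
        for g in groups
    ])
    return means, groups


def hca(matrix: np.ndarray, labels: list[str], mode: str = "fingerprint",
        selected_wavenumbers: np.ndarray | None = None) -> HCAResult:
    """Ward/Euclidean agglomeration of one row per leaf."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    if len(labels) != matrix.shape[0]:
        raise ValueError("one label per row required")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels")
    linkage = hierarchy.linkage(matrix, method="ward", metric="euclidean")
    return HCAResult(
        linkage=linkage,
        labels=list(labels),
        mode=mode,
        selected_wavenumbers=selected_wavenumbers,
    )


def hca_fingerprint_mode(
    sset: SpectrumSet,
    cfg: PreprocessConfig | None = None,
    group_by: str = "plant_type",
) -> HCAResult:
    """Cluster group means of the fingerprint region.

    Order of operations: region cut -> average by group -> SG second
    derivative of the means -> vector normalise -> Ward/Euclidean HCA.
    """
    cfg = cfg or PreprocessConfig()
    cut = cut_region(sset, cfg.region_high, cfg.region_low)
    means, labels = class_mean_spectra(cut, group_by)
    deriv = savgol_second_derivative_matrix(means, cfg.sg_window, cfg.sg_polyorder)
    normed = l2_normalize_rows(deriv, labels)
    return hca(normed, labels, mode="fingerprint")


def hca_loadings_mode(
    sset: SpectrumSet,
    wavenumbers,
    cfg: PreprocessConfig | None = None,
    group_by: str = "plant_type",
    mode: str = "loadings",
) -> HCAResult:
    """Cluster group means restricted to selected wavenumbers.

    Order of operations: region cut -> SG second derivative and vector
    normalisation per spectrum -> select the columns nearest the requested
    wavenumbers (snap within one grid step, else error) -> average by group
    -> Ward/Euclidean HCA.
    """
    cfg = cfg or PreprocessConfig()
    cut = cut_region(sset, cfg.region_high, cfg.region_low)
    deriv = savgol_second_derivative_matrix(
        cut.absorbance, cfg.sg_window, cfg.sg_polyorder
    )
    normed = l2_normalize_rows(deriv, cut.spectrum_ids)
    grid = cut.wavenumbers
    spacing = float(np.median(np.abs(np.diff(grid))))
    cols, snapped = [], []
    for w in np.asarray(wavenumbers, dtype=float):
        i = int(np.argmin(np.abs(grid - w)))
        if abs(grid[i] - w) > spacing + 1e-9:
            raise ValueError(
                f"wavenumber {w} cm^-1 is farther than one grid step from "
                "any grid point"
            )
        if i not in cols:
            cols.append(i)
    cols.sort()  # grid is descending, so ascending index = descending cm^-1
    snapped = [grid[i] for i in cols]
    selected = cut.with_absorbance(normed[:, cols], np.asarray(snapped))
    means, labels = class_mean_spectra(selected, group_by)
    return hca(means, labels, mode=mode,
               selected_wavenumbers=np.asarray(snapped))


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " \t,;:()[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(result: HCAResult, precision: int = 10) -> str:
    """Render the merge history as an ultrametric Newick string.

    Node heights are halved so that cophenetic distance equals twice the
    leaf depth to the joining node; two leaves merging at height ``h``
    render as ``(A:h/2,B:h/2);``.
    """
    n = result.n_leaves
    heights = {i: 0.0 for i in range(n)}
    for k, (a, b, h, _size) in enumerate(result.linkage):
        heights[n + k] = float(h)

    def render(node: int) -> str:
        if node < n:
            return _quote_label(str(result.labels[node]))
        a, b, h, _ = result.linkage[node - n]
        parts = []
        for child in (int(a), int(b)):
            bl = (heights[node] - heights[child]) / 2.0
            parts.append(f"{render(child)}:{bl:.{precision}g}")
        return "(" + ",".join(parts) + ")"

    return render(2 * n - 2) + ";"
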