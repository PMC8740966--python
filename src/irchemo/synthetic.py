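"""Labelled synthetic absorbance spectra with known ground truth.

Each spectrum is a sum of Gaussian bands (class-specific plus shared,
modulated by leaf-surface gain, location shift and per-class concentration
multipliers), a random polynomial baseline drawn per sample, and additive
Gaussian noise, all multiplied by a per-spectrum log-normal thickness gain.
Generation is bitwise reproducible for a fixed seed.

Three presets mirror the study designs exercised by the pipeline:
``study_scale`` (16 classes, 1580 spectra), ``two_variety`` (a planted
concentration ratio at the 1034 cm^-1 marker band) and ``env_vs_taxon``
(orthogonal taxon and environment band sets for the clustering contrast).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra_io import CANONICAL_TAXA, SpectrumSet

__all__ = [
    "Band",
    "ClassLibrary",
    "SimulationConfig",
    "build_class_library",
    "simulate_spectrum_set",
    "make_two_variety_scenario",
    "make_env_taxon_scenario",
    "make_study_scale_set",
    "PRESETS",
]


@dataclass(frozen=True)
class Band:
    """One Gaussian absorbance band."""

    centre: float      # cm^-1
    amplitude: float   # absorbance units
    width: float       # Gaussian sigma, cm^-1

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("band amplitude must be positive")
        if self.width <= 0:
            raise ValueError("band width must be positive")


@dataclass
class ClassLibrary:
    """Ground-truth band parameters and effect modifiers per class.

    ``surface_gain`` multiplies the amplitudes of the shared bands listed in
    ``surface_band_indices`` on the second leaf surface; ``location_shifts``
    translate the shared bands in ``location_band_indices``; ``concentration``
    maps class -> band index -> amplitude multiplier on that class's own
    bands.
    """

    class_bands: dict[str, list[Band]]
    shared_bands: list[Band] = field(default_factory=list)
    surface_gain: float = 1.0
    surface_band_indices: tuple[int, ...] = ()
    location_shifts: dict[str, float] = field(default_factory=dict)
    location_band_indices: tuple[int, ...] = ()
    concentration: dict[str, dict[int, float]] = field(default_factory=dict)

    @property
    def classes(self) -> list[str]:
        return sorted(self.class_bands)

    def bands_for(self, cls: str, surface_index: int, location: str) -> list[Band]:
        """Effective bands for one (class, surface, location) cell."""
        out: list[Band] = []
        for i, b in enumerate(self.shared_bands):
            amp = b.amplitude
            centre = b.centre
            if surface_index == 1 and i in self.surface_band_indices:
                amp *= self.surface_gain
            if i in self.location_band_indices:
                centre += self.location_shifts.get(location, 0.0)
            out.append(Band(centre, amp, b.width))
        mult = self.concentration.get(cls, {})
        for i, b in enumerate(self.class_bands[cls]):
            out.append(Band(b.centre, b.amplitude * mult.get(i, 1.0), b.width))
        return out


@dataclass
class SimulationConfig:
    grid_high: float = 4000.0
    grid_low: float = 400.0
    spacing: float = 4.0
    n_samples_per_class: int = 5
    replicates_per_surface: int = 10
    noise_sd: float = 0.002
    baseline_degree: int = 2
    baseline_scale: float = 0.02
    thickness_sigma: float = 0.1
    seed: int = 0
    surfaces: tuple[str, str] = ("upper", "lower")
    locations: tuple[str, ...] = ("England", "Shetland", "Japan")
    class_counts: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.replicates_per_surface < 1:
            raise ValueError("replicates_per_surface must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.grid_high <= self.grid_low:
            raise ValueError("grid_high must exceed grid_low")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_high - self.grid_low) / self.spacing)) + 1
        return self.grid_high - self.spacing * np.arange(n)


def build_class_library(
    n_classes: int,
    bands_per_class: int,
    seed: int,
    overlap: float = 0.0,
    min_spacing: float = 25.0,
    centre_range: tuple[float, float] = (920.0, 1780.0),
    amplitude_range: tuple[float, float] = (0.3, 1.0),
    width_range: tuple[float, float] = (8.0, 18.0),
    class_names: list[str] | None = None,
) -> ClassLibrary:
    """Random band library; ``overlap`` is the shared fraction of each
    class's bands (0 = fully disjoint class signatures, 1 = identical).

    Band centres occupy slots at least ``min_spacing`` apart (with a small
    jitter) inside ``centre_range``; an infeasible packing raises.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    if class_names is None:
        class_names = [f"type_{i:02d}" for i in range(n_classes)]
    elif len(class_names) != n_classes:
        raise ValueError("class_names length must equal n_classes")
    rng = np.random.default_rng(seed)
    n_shared = int(round(overlap * bands_per_class))
    n_own = bands_per_class - n_shared
    needed = n_shared + n_classes * n_own
    slots = np.arange(centre_range[0], centre_range[1] + 1e-9, min_spacing)
    if needed > len(slots):
        raise ValueError(
            f"cannot pack {needed} bands at {min_spacing} cm^-1 spacing into "
            f"{centre_range}; reduce bands or spacing"
        )
    centres = rng.permutation(slots)[:needed]
    centres = centres + rng.uniform(-0.1, 0.1, size=needed) * min_spacing

    def draw_band(c: float) -> Band:
        return Band(
            centre=float(c),
            amplitude=float(rng.uniform(*amplitude_range)),
            width=float(rng.uniform(*width_range)),
        )

    shared = [draw_band(c) for c in centres[:n_shared]]
    class_bands = {}
    for k, name in enumerate(class_names):
        own = centres[n_shared + k * n_own: n_shared + (k + 1) * n_own]
        class_bands[name] = [draw_band(c) for c in own]
    return ClassLibrary(class_bands=class_bands, shared_bands=shared)


def _gaussians(grid: np.ndarray, bands: list[Band]) -> np.ndarray:
    signal = np.zeros_like(grid)
    for b in bands:
        signal += b.amplitude * np.exp(-0.5 * ((grid - b.centre) / b.width) ** 2)
    return signal


def simulate_spectrum_set(library: ClassLibrary, cfg: SimulationConfig) -> SpectrumSet:
    """Draw one labelled :class:`SpectrumSet` from a band library.

    Baseline coefficients are drawn once per sample (both surfaces of a leaf
    share them); noise and thickness gain are drawn per spectrum.
    """
    grid = cfg.grid()
    u = np.linspace(0.0, 1.0, len(grid))
    rng = np.random.default_rng(cfg.seed)
    rows, meta = [], []
    for cls in library.classes:
        counts = (cfg.class_counts or {}).get(cls, cfg.n_samples_per_class)
        for s in range(counts):
            location = cfg.locations[s % len(cfg.locations)]
            coeffs = rng.normal(0.0, cfg.baseline_scale, cfg.baseline_degree + 1)
            baseline = np.polyval(coeffs, u)
            year = int(rng.integers(1935, 2001))
            sample_id = f"{cls}_s{s:02d}"
            for si, surface in enumerate(cfg.surfaces):
                signal = _gaussians(grid, library.bands_for(cls, si, location))
                for rep in range(cfg.replicates_per_surface):
                    noise = rng.normal(0.0, cfg.noise_sd, len(grid))
                    gain = float(rng.lognormal(0.0, cfg.thickness_sigma))
                    rows.append(gain * (signal + baseline + noise))
                    meta.append({
                        "spectrum_id": f"{sample_id}_{surface}_{rep:02d}",
                        "sample_id": sample_id,
                        "plant_type": cls,
                        "leaf_surface": surface,
                        "location": location,
                        "collection_year": year,
                    })
    return SpectrumSet(grid, np.vstack(rows), pd.DataFrame(meta))


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

_SHARED_TEMPLATE = [
    Band(1740.0, 0.45, 12.0),
    Band(1640.0, 0.70, 14.0),
    Band(1540.0, 0.35, 12.0),
    Band(1440.0, 0.40, 12.0),
    Band(1340.0, 0.30, 10.0),
    Band(1240.0, 0.35, 12.0),
    Band(1160.0, 0.30, 10.0),
    Band(945.0, 0.25, 10.0),
]


def make_study_scale_set(seed: int = 0, **overrides) -> SpectrumSet:
    """A 1580-spectrum, 16-class set at the study's replication scale.

    79 samples (one class contributes 4, the rest 5) x 2 surfaces x 10
    replicates = 1580 spectra, labelled with the canonical taxon names.
    """
    library = build_class_library(
        n_classes=16, bands_per_class=3, seed=seed, overlap=1 / 3,
        min_spacing=20.0, class_names=list(CANONICAL_TAXA),
    )
    library.surface_gain = 1.2
    library.surface_band_indices = (0,) if library.shared_bands else ()
    counts = {cls: 5 for cls in library.classes}
    counts[library.classes[-1]] = 4
    cfg = SimulationConfig(seed=seed, class_counts=counts, **overrides)
    sset = simulate_spectrum_set(library, cfg)
    sset.attrs["scenario"] = "study_scale"
    return sset


def make_two_variety_scenario(
    ratio: float,
    seed: int = 0,
    n_samples_per_class: int = 8,
    marker_centre: float = 1034.0,
    marker_amplitude: float = 0.5,
    **overrides,
) -> SpectrumSet:
    """Two classes identical except a marker band near 1034 cm^-1 whose
    amplitude differs by ``ratio`` (invasive over dwarf).

    Ground truth is recorded in ``attrs`` (marker centre, planted ratio,
    class labels).
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    marker = Band(marker_centre, marker_amplitude, 10.0)
    library = ClassLibrary(
        class_bands={"var_invasive": [marker], "var_dwarf": [marker]},
        shared_bands=list(_SHARED_TEMPLATE),
        concentration={"var_invasive": {0: ratio}},
    )
    overrides.setdefault("noise_sd", 0.002)
    overrides.setdefault("thickness_sigma", 0.05)
    cfg = SimulationConfig(
        seed=seed, n_samples_per_class=n_samples_per_class, **overrides
    )
    sset = simulate_spectrum_set(library, cfg)
    sset.attrs.update({
        "scenario": "two_variety",
        "marker_centre": marker_centre,
        "true_ratio": ratio,
        "class_a": "var_invasive",
        "class_b": "var_dwarf",
    })
    return sset


def make_env_taxon_scenario(
    seed: int = 0,
    taxon_amplitude: float = 0.5,
    env_amplitude: float = 1.0,
    n_samples_per_class: int = 4,
    **overrides,
) -> SpectrumSet:
    """Four classes crossing two taxon templates with a shared greenhouse
    environment band set.

    Classes ``taxonA_greenhouse`` and ``taxonB_greenhouse`` carry strong
    environment bands on top of their taxon signature, so whole-fingerprint
    clustering groups by environment while clustering restricted to the
    taxon wavenumbers (recorded in ``attrs``) groups by taxon.
    """
    ta = [1700.0, 1500.0, 1300.0]
    tb = [1660.0, 1460.0, 1260.0]
    env = [1100.0, 1040.0, 980.0]
    width = 10.0

    def bands(centres, amp):
        return [Band(c, amp, width) for c in centres]

    class_bands = {
        "taxonA_wild": bands(ta, taxon_amplitude),
        "taxonA_greenhouse": bands(ta, taxon_amplitude) + bands(env, env_amplitude),
        "taxonB_wild": bands(tb, taxon_amplitude),
        "taxonB_greenhouse": bands(tb, taxon_amplitude) + bands(env, env_amplitude),
    }
    library = ClassLibrary(class_bands=class_bands,
                           shared_bands=[Band(1580.0, 0.3, 12.0)])
    overrides.setdefault("noise_sd", 0.001)
    overrides.setdefault("thickness_sigma", 0.05)
    cfg = SimulationConfig(
        seed=seed, n_samples_per_class=n_samples_per_class,
        replicates_per_surface=overrides.pop("replicates_per_surface", 5),
        **overrides,
    )
    sset = simulate_spectrum_set(library, cfg)
    sset.attrs.update({
        "scenario": "env_vs_taxon",
        "taxon_wavenumbers": ta + tb,
        "env_wavenumbers": env,
        "taxon_groups": {
            "taxonA_wild": "A", "taxonA_greenhouse": "A",
            "taxonB_wild": "B", "taxonB_greenhouse": "B",
        },
        "env_groups": {
            "taxonA_wild": "wild", "taxonB_wild": "wild",
            "taxonA_greenhouse": "greenhouse", "taxonB_greenhouse": "greenhouse",
        },
    })
    return sset


PRESETS = {
    "study_scale": make_study_scale_set,
    "two_variety": lambda seed=0, **kw: make_two_variety_scenario(2.0, seed=seed, **kw),
    "env_vs_taxon": make_env_taxon_scenario,
}
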