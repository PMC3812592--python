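"""Parametric grass/clover canopy-reflectance simulator.

Generates plot-level repeated readings on the 350-2500 nm grid with
biomass-linked absorption-feature depths, per-plot multiplicative scatter and
detector-dependent reading noise, so that every pipeline stage can be tested
without field data.  The template makes no radiative-transfer claims; its
dips are placed so each of the five default absorption zones contains exactly
one feature.

Seed handling uses per-plot and per-reading substreams derived from one root
seed, so increasing ``n_plots`` never reshuffles earlier plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from grasspec.continuum import DEFAULT_ZONES
from grasspec.spectra_io import (
    BiomassRecord,
    ReadingSet,
    SpectraError,
    Spectrum,
)

#: Gaussian dip centres and widths (nm) used by the template; the keyed zones
#: are the ones whose amplitudes are biomass-linked.
DIP_SHAPES: dict[str, tuple[float, float]] = {
    "Z1": (490.0, 25.0),
    "Z2": (670.0, 35.0),
    "Z3": (980.0, 30.0),
    "Z4": (1200.0, 40.0),
    "Z5": (1450.0, 45.0),
    "_water1940": (1940.0, 50.0),
}

#: Template amplitudes used when no per-plot depths are supplied.
DEFAULT_DIP_AMPLITUDES: dict[str, float] = {
    "Z1": 0.15,
    "Z2": 0.35,
    "Z3": 0.12,
    "Z4": 0.15,
    "Z5": 0.35,
    "_water1940": 0.55,
}

#: Noisy detector intervals where reading noise is inflated tenfold.
_NOISY_INTERVALS = ((1360.0, 1385.0), (1800.0, 1930.0), (2400.0, 2500.0))


@dataclass(frozen=True)
class ZoneLink:
    """Linear link from a biomass variable to an absorption-feature depth."""

    d0: float
    d1: float
    variable: str  # TAGB | GAGB | pctGAGB

    def depth(self, record: BiomassRecord) -> float:
        return self.d0 + self.d1 * record.response(self.variable)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults emulate 30 plots x 15 readings."""

    n_plots: int = 30
    readings_per_plot: int = 15
    seed: int = 0
    grid_start: float = 350.0
    grid_stop: float = 2500.0
    grid_step: float = 1.0
    tagb_mean: float = 45.05
    tagb_sd: float = 15.40
    tagb_bounds: tuple[float, float] = (5.0, 80.0)
    pct_green_mean: float = 68.34
    pct_green_sd: float = 13.57
    pct_green_bounds: tuple[float, float] = (25.0, 95.0)
    zone_links: Mapping[str, ZoneLink] = field(
        default_factory=lambda: {
            "Z1": ZoneLink(0.10, 0.003, "pctGAGB"),
            "Z2": ZoneLink(0.10, 0.003, "pctGAGB"),
            "Z3": ZoneLink(0.04, 0.002, "TAGB"),
            "Z4": ZoneLink(0.05, 0.004, "TAGB"),
            "Z5": ZoneLink(0.10, 0.002, "TAGB"),
        }
    )
    depth_jitter_sd: float = 0.01
    noise_sd_vnir: float = 0.004
    noise_sd_swir1: float = 0.008
    noise_sd_swir2: float = 0.012
    noisy_band_noise_factor: float = 10.0
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.n_plots < 1 or self.readings_per_plot < 1:
            raise SpectraError("n_plots and readings_per_plot must be >= 1")
        for sd in (
            self.tagb_sd,
            self.pct_green_sd,
            self.depth_jitter_sd,
            self.noise_sd_vnir,
            self.noise_sd_swir1,
            self.noise_sd_swir2,
            self.scatter_slope_sd,
            self.scatter_offset_sd,
        ):
            if sd < 0:
                raise SpectraError("standard deviations must be >= 0")
        if not (350.0 <= self.grid_start < self.grid_stop <= 2500.0):
            raise SpectraError("grid must lie within 350-2500 nm")

    def wavelengths(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)


@dataclass(frozen=True)
class PlotTruth:
    """Ground truth recorded for one simulated plot."""

    plot_id: str
    biomass: BiomassRecord
    depths: dict[str, float]
    scatter_slope: float
    scatter_offset: float


@dataclass(frozen=True)
class SyntheticTruth:
    plots: tuple[PlotTruth, ...]

    def depth_vector(self, zone: str) -> np.ndarray:
        return np.array([p.depths[zone] for p in self.plots])


def _sigmoid(t: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-t))


def base_curve(
    wavelengths: np.ndarray,
    dip_amplitudes: Mapping[str, float] | None = None,
) -> Spectrum:
    """Deterministic grass-canopy reflectance template.

    A 0.05 visible floor with a green-peak bump at 550 nm, a sigmoid red
    edge centred at 715 nm rising to a 0.45 NIR plateau, a gentle linear
    decline beyond 1500 nm, and multiplicative Gaussian absorption dips
    (one per default zone plus the 1940 nm water band).  All values in (0, 1).
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.min() < 350.0 or wl.max() > 2500.0:
        raise SpectraError("grid must lie within 350-2500 nm")
    amps = DEFAULT_DIP_AMPLITUDES if dip_amplitudes is None else dip_amplitudes
    smooth = (
        0.05
        + 0.05 * np.exp(-((wl - 550.0) ** 2) / (2.0 * 30.0**2))
        + 0.40 * _sigmoid((wl - 715.0) / 18.0)
        - 8.0e-5 * np.clip(wl - 1500.0, 0.0, None)
    )
    curve = smooth.copy()
    for key, (center, sd) in DIP_SHAPES.items():
        amp = float(amps.get(key, 0.0))
        if amp != 0.0:
            curve = curve * (1.0 - amp * np.exp(-((wl - center) ** 2) / (2.0 * sd**2)))
    return Spectrum(wl, np.clip(curve, 1e-6, None))


def _noise_sd(wavelengths: np.ndarray, config: SimulationConfig) -> np.ndarray:
    sd = np.where(
        wavelengths <= 1000.0,
        config.noise_sd_vnir,
        np.where(wavelengths <= 1800.0, config.noise_sd_swir1, config.noise_sd_swir2),
    ).astype(float)
    for lo, hi in _NOISY_INTERVALS:
        sd[(wavelengths >= lo) & (wavelengths <= hi)] *= config.noisy_band_noise_factor
    return sd


def _truncnorm_draw(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float]
) -> float:
    lo, hi = bounds
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[ReadingSet], dict[str, BiomassRecord], SyntheticTruth]:
    """Simulate plot reading sets, biomass records and the generating truth."""
    wl = config.wavelengths()
    noise_sd = _noise_sd(wl, config)
    reading_sets: list[ReadingSet] = []
    biomass: dict[str, BiomassRecord] = {}
    truths: list[PlotTruth] = []
    for i in range(config.n_plots):
        rng = np.random.default_rng([config.seed, i])
        tagb = _truncnorm_draw(rng, config.tagb_mean, config.tagb_sd, config.tagb_bounds)
        pct = _truncnorm_draw(
            rng, config.pct_green_mean, config.pct_green_sd, config.pct_green_bounds
        )
        record = BiomassRecord(tagb, tagb * pct / 100.0, pct)
        depths = {}
        for zone, link in config.zone_links.items():
            jitter = rng.normal(0.0, config.depth_jitter_sd) if config.depth_jitter_sd else 0.0
            depths[zone] = float(np.clip(link.depth(record) + jitter, 0.0, 0.95))
        slope = float(rng.normal(1.0, config.scatter_slope_sd))
        offset = float(rng.normal(0.0, config.scatter_offset_sd))
        amps = dict(DEFAULT_DIP_AMPLITUDES)
        amps.update(depths)
        plot_curve = np.clip(
            slope * base_curve(wl, amps).values + offset, 1e-6, 1.2
        )
        readings = []
        for k in range(config.readings_per_plot):
            rng_read = np.random.default_rng([config.seed, i, k])
            noisy = plot_curve + rng_read.normal(0.0, 1.0, wl.size) * noise_sd
            readings.append(Spectrum(wl, np.clip(noisy, 0.0, 1.2)))
        pid = f"plot{i + 1:03d}"
        reading_sets.append(ReadingSet(pid, tuple(readings)))
        biomass[pid] = record
        truths.append(PlotTruth(pid, record, depths, slope, offset))
    return reading_sets, biomass, SyntheticTruth(tuple(truths))


def recovery_benchmark(
    config: SimulationConfig | None = None,
    include_grid: bool = False,
    f_max: int = 10,
    center: str = "mean",
) -> dict:
    """Run the full pipeline on simulated data and report recovery accuracy.

    Reports LOOCV R2/RMSE for TAGB regressed on MBD over Z3+Z4 and for GAGB
    on AOM over Z1+Z3+Z4.  With ``include_grid=True`` the full default model
    grid is run for TAGB and the rank of Z4-bearing inputs is reported.
    """
    from grasspec import pipeline  # deferred: pipeline depends on this module
    from grasspec.continuum import extract_feature_table, feature_matrix
    from grasspec.models import select_plsr_factors
    from grasspec.spectra_io import (
        dataset_from_readings,
        exclude_noisy_bands,
        response_vector,
    )

    cfg = config if config is not None else SimulationConfig(seed=1)
    reading_sets, biomass, truth = simulate_dataset(cfg)
    ds = exclude_noisy_bands(dataset_from_readings(reading_sets, "mean"))
    table = extract_feature_table(ds)
    ids = ds.sample_ids

    report: dict = {"config": cfg, "truth": truth}
    X_tagb = feature_matrix(table, "MBD", ["Z3", "Z4"], ids)
    y_tagb = response_vector(biomass, ids, "TAGB")
    F, cv = select_plsr_factors(X_tagb, y_tagb, f_max=f_max, center=center)
    report["TAGB_MBD_Z3Z4"] = {"F": F, "R2": cv.r2, "RMSE": cv.rmse,
                               "pct_RMSE": cv.pct_rmse}

    X_gagb = feature_matrix(table, "AOM", ["Z1", "Z3", "Z4"], ids)
    y_gagb = response_vector(biomass, ids, "GAGB")
    F_g, cv_g = select_plsr_factors(X_gagb, y_gagb, f_max=f_max, center=center)
    report["GAGB_AOM_Z1Z3Z4"] = {"F": F_g, "R2": cv_g.r2, "RMSE": cv_g.rmse,
                                 "pct_RMSE": cv_g.pct_rmse}

    if include_grid:
        grid_cfg = pipeline.GridConfig(responses=("TAGB",), f_max=f_max, center=center)
        specs = pipeline.build_model_grid(grid_cfg)
        result = pipeline.run_grid(specs, reading_sets, biomass, grid_cfg)
        ranked = pipeline.rank_models(result)
        ok = ranked[~ranked["error"].astype(bool)]
        top = ok.iloc[0]
        report["grid_top"] = top.to_dict()
        report["grid_top_bears_Z4"] = pipeline.row_bears_zone(top, "Z4")
        z4_ranks = [
            rank
            for rank, (_, row) in enumerate(ok.iterrows(), start=1)
            if pipeline.row_bears_zone(row, "Z4")
        ]
        report["best_Z4_rank"] = min(z4_ranks) if z4_ranks else None
    return report
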