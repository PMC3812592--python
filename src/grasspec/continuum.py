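"""Continuum removal over absorption zones and the MBD / AOM indices.

The continuum over a zone is the straight chord joining the reflectance at
the two zone endpoints (snapped to the nearest grid wavelengths at or inside
the printed bounds).  Continuum-removed reflectance (CRR) is the pointwise
ratio spectrum/chord; band depth is 1 - CRR.

MBD is the maximum band depth over the zone.  AOM is MBD times the feature
width, with the width measured between the two half-depth crossings nearest
to the band-depth maximum.  Crossings are located exactly for piecewise
linear reflectance by solving x(l) = (1 - MBD/2) * c(l) on the bracketing
grid interval (x and c both linear there).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from grasspec.spectra_io import SpectralDataset, SpectraError, Spectrum


class ContinuumError(ValueError):
    """Invalid zone/spectrum combination for continuum removal."""


@dataclass(frozen=True)
class AbsorptionZone:
    """A named wavelength interval containing one absorption feature."""

    name: str
    lambda_start: float
    lambda_end: float

    def __post_init__(self) -> None:
        if not self.lambda_start < self.lambda_end:
            raise ContinuumError(
                f"zone {self.name!r}: start must be < end "
                f"({self.lambda_start} >= {self.lambda_end})"
            )

    @property
    def width(self) -> float:
        return self.lambda_end - self.lambda_start


#: The five default absorption zones (nm).
DEFAULT_ZONES: dict[str, AbsorptionZone] = {
    "Z1": AbsorptionZone("Z1", 440.0, 567.0),
    "Z2": AbsorptionZone("Z2", 554.0, 762.0),
    "Z3": AbsorptionZone("Z3", 916.0, 1120.0),
    "Z4": AbsorptionZone("Z4", 1079.0, 1297.0),
    "Z5": AbsorptionZone("Z5", 1265.0, 1676.0),
}

ZONE_NAMES: tuple[str, ...] = tuple(DEFAULT_ZONES)


@dataclass(frozen=True)
class ContinuumRemoved:
    """Continuum-removed reflectance over one zone."""

    zone: AbsorptionZone
    wavelengths: np.ndarray
    crr: np.ndarray
    continuum: np.ndarray

    def __post_init__(self) -> None:
        for name in ("wavelengths", "crr", "continuum"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.wavelengths.size == self.crr.size == self.continuum.size):
            raise ContinuumError("wavelengths, crr and continuum lengths differ")
        if np.any(self.continuum <= 0):
            raise ContinuumError("continuum must be strictly positive")

    @property
    def reflectance(self) -> np.ndarray:
        return self.crr * self.continuum


def _zone_slice(x: Spectrum, z: AbsorptionZone) -> np.ndarray:
    idx = np.nonzero(
        (x.wavelengths_nm >= z.lambda_start) & (x.wavelengths_nm <= z.lambda_end)
    )[0]
    if idx.size < 2:
        raise ContinuumError(
            f"zone {z.name!r} [{z.lambda_start}, {z.lambda_end}] covers fewer "
            "than 2 grid wavelengths"
        )
    return idx


def continuum_line(x: Spectrum, z: AbsorptionZone) -> np.ndarray:
    """Chord joining the spectrum values at the zone's endpoint wavelengths.

    Endpoints are the grid wavelengths nearest inside the zone bounds; the
    line is evaluated at every grid wavelength in the zone.
    """
    idx = _zone_slice(x, z)
    wl = x.wavelengths_nm[idx]
    v = x.values[idx]
    if v[0] <= 0 or v[-1] <= 0:
        raise ContinuumError(
            f"zone {z.name!r}: endpoint reflectance must be positive "
            f"(got {v[0]:.4g}, {v[-1]:.4g})"
        )
    slope = (v[-1] - v[0]) / (wl[-1] - wl[0])
    line = v[0] + slope * (wl - wl[0])
    # exact anchoring at the endpoints regardless of rounding
    line[0], line[-1] = v[0], v[-1]
    return line


def continuum_removed(x: Spectrum, z: AbsorptionZone) -> ContinuumRemoved:
    """Divide the spectrum by its continuum chord over the zone."""
    idx = _zone_slice(x, z)
    cont = continuum_line(x, z)
    if np.any(cont <= 0):
        raise ContinuumError(f"zone {z.name!r}: continuum not strictly positive")
    crr = x.values[idx] / cont
    crr[0] = 1.0
    crr[-1] = 1.0
    return ContinuumRemoved(z, x.wavelengths_nm[idx], crr, cont)


def max_band_depth(cr: ContinuumRemoved) -> float:
    """MBD = max(0, 1 - min CRR); 0 (degenerate) when nothing dips below the chord."""
    return max(0.0, 1.0 - float(cr.crr.min()))


def is_degenerate(cr: ContinuumRemoved) -> bool:
    """True when the spectrum never dips below its continuum."""
    return float(cr.crr.min()) >= 1.0


def _cross_exact(
    wl: np.ndarray, x: np.ndarray, c: np.ndarray, j: int, thr: float
) -> float:
    """Wavelength in [wl[j], wl[j+1]] where x(l) = thr * c(l).

    Exact for reflectance and continuum both linear on the interval.  f
    changes sign on the bracket by construction.
    """
    f0 = x[j] - thr * c[j]
    f1 = x[j + 1] - thr * c[j + 1]
    if f0 == f1:
        return float(wl[j])
    return float(wl[j] + (wl[j + 1] - wl[j]) * f0 / (f0 - f1))


def half_depth_width(cr: ContinuumRemoved) -> tuple[float, float, float]:
    """Feature width at half of MBD.

    Returns ``(width, lambda_left, lambda_right)``.  The crossings are the
    nearest to the band-depth argmin on each side; a side where the depth
    never falls below MBD/2 is bounded by the zone edge.  Width is 0 when
    MBD is 0.
    """
    mbd = max_band_depth(cr)
    wl = cr.wavelengths
    if mbd <= 0.0:
        return 0.0, float(wl[0]), float(wl[0])
    bd = 1.0 - cr.crr
    i0 = int(np.argmin(cr.crr))  # first index attaining the minimum
    thr_crr = 1.0 - mbd / 2.0
    x = cr.reflectance
    c = cr.continuum

    lam_left = float(wl[0])
    for j in range(i0 - 1, -1, -1):
        if bd[j] < mbd / 2.0:
            lam_left = _cross_exact(wl, x, c, j, thr_crr)
            break
    lam_right = float(wl[-1])
    for j in range(i0, wl.size - 1):
        if bd[j + 1] < mbd / 2.0:
            lam_right = _cross_exact(wl, x, c, j, thr_crr)
            break
    return lam_right - lam_left, lam_left, lam_right


def area_over_minimum(cr: ContinuumRemoved) -> float:
    """AOM = MBD x width-at-half-depth; 0 for degenerate features."""
    mbd = max_band_depth(cr)
    if mbd <= 0.0:
        return 0.0
    width, _, _ = half_depth_width(cr)
    return mbd * width


def extract_feature_table(
    ds: SpectralDataset,
    zones: Iterable[AbsorptionZone | str] | None = None,
) -> pd.DataFrame:
    """MBD and AOM for every sample x zone.

    Returns a data frame with columns ``sample_id, zone, MBD, AOM,
    degenerate``, one row per sample and zone, in dataset order.
    """
    zone_objs = _resolve_zones(zones)
    rows = []
    for sid, values in zip(ds.sample_ids, ds.matrix):
        spec = Spectrum(ds.wavelengths_nm, values, kind="transformed")
        for z in zone_objs:
            cr = continuum_removed(spec, z)
            rows.append(
                {
                    "sample_id": sid,
                    "zone": z.name,
                    "MBD": max_band_depth(cr),
                    "AOM": area_over_minimum(cr),
                    "degenerate": is_degenerate(cr),
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "zone", "MBD", "AOM", "degenerate"])


def feature_matrix(
    table: pd.DataFrame, index: str, zones: Sequence[str], sample_ids: Sequence[str]
) -> np.ndarray:
    """Pivot a feature table into a samples x zones predictor matrix."""
    if index not in ("MBD", "AOM"):
        raise ContinuumError(f"unknown index {index!r}")
    pivot = table.pivot(index="sample_id", columns="zone", values=index)
    missing = [z for z in zones if z not in pivot.columns]
    if missing:
        raise SpectraError(f"feature table lacks zones {missing}")
    return pivot.loc[list(sample_ids), list(zones)].to_numpy(dtype=float)


def _resolve_zones(
    zones: Iterable[AbsorptionZone | str] | None,
) -> list[AbsorptionZone]:
    if zones is None:
        return list(DEFAULT_ZONES.values())
    out = []
    for z in zones:
        if isinstance(z, AbsorptionZone):
            out.append(z)
        elif z in DEFAULT_ZONES:
            out.append(DEFAULT_ZONES[z])
        else:
            raise ContinuumError(f"unknown zone {z!r}")
    return out
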