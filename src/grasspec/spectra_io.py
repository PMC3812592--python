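"""Loading, validation, averaging and subsetting of canopy reflectance spectra.

Spectra are handled on arbitrary strictly increasing wavelength grids; band
membership for noise exclusion and subsetting is decided by wavelength value,
never by array index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Wavelength ranges (nm, inclusive) retained after removal of the noisy
#: detector bands (1360-1385 nm, 1800-1930 nm and >2400 nm are dropped).
RETAINED_RANGES: tuple[tuple[float, float], ...] = (
    (350.0, 1359.0),
    (1386.0, 1799.0),
    (1931.0, 2399.0),
)

#: Named spectral subsets (nm, inclusive on both ends).
SUBSET_RANGES: dict[str, tuple[tuple[float, float], ...]] = {
    "VNIR": ((350.0, 1000.0),),
    "VNIR_SWIR1": ((350.0, 1359.0), (1386.0, 1799.0)),
    "VNIR_SWIR1_SWIR2": RETAINED_RANGES,
}

#: Upper bound accepted for reflectance values (panel-calibration artifacts
#: can push reflectance slightly above 1).
REFLECTANCE_MAX = 1.2


class SpectraError(ValueError):
    """Structural or validation error in spectral data."""


@dataclass(frozen=True)
class Spectrum:
    """A single spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nanometres.
    values
        Reflectance (fraction) or transformed values, one per wavelength.
    kind
        ``"reflectance"`` or ``"transformed"``.  Reflectance values must lie
        in ``[0, 1.2]``.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str = "reflectance"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.ndim != 1:
            raise SpectraError("wavelengths and values must be 1-D")
        if wl.size != vals.size:
            raise SpectraError(
                f"length mismatch: {wl.size} wavelengths vs {vals.size} values"
            )
        if wl.size == 0:
            raise SpectraError("empty spectrum")
        if np.any(np.diff(wl) <= 0):
            raise SpectraError("wavelengths must be strictly increasing")
        if self.kind not in ("reflectance", "transformed"):
            raise SpectraError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "reflectance":
            if np.any(vals < 0) or np.any(vals > REFLECTANCE_MAX):
                raise SpectraError(
                    "reflectance values must lie in "
                    f"[0, {REFLECTANCE_MAX}]; got range "
                    f"[{vals.min():.4g}, {vals.max():.4g}]"
                )

    @property
    def n_bands(self) -> int:
        return self.wavelengths_nm.size


@dataclass(frozen=True)
class ReadingSet:
    """Repeated spectral readings of one plot on an identical grid."""

    plot_id: str
    readings: tuple[Spectrum, ...]

    def __post_init__(self) -> None:
        readings = tuple(self.readings)
        object.__setattr__(self, "readings", readings)
        if len(readings) == 0:
            raise SpectraError(f"plot {self.plot_id!r}: empty reading set")
        grid = readings[0].wavelengths_nm
        for r in readings[1:]:
            if r.wavelengths_nm.shape != grid.shape or not np.array_equal(
                r.wavelengths_nm, grid
            ):
                raise SpectraError(
                    f"plot {self.plot_id!r}: readings on mismatched grids"
                )

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.readings[0].wavelengths_nm

    @property
    def n_readings(self) -> int:
        return len(self.readings)


@dataclass(frozen=True)
class SpectralDataset:
    """A sample-by-band matrix on a shared wavelength grid."""

    wavelengths_nm: np.ndarray
    matrix: np.ndarray
    sample_ids: tuple[str, ...]
    averaging: str = "mean"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        mat = np.asarray(self.matrix, dtype=float)
        ids = tuple(str(s) for s in self.sample_ids)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "sample_ids", ids)
        if mat.ndim != 2:
            raise SpectraError("matrix must be 2-D (samples x bands)")
        if mat.shape[1] != wl.size:
            raise SpectraError(
                f"matrix has {mat.shape[1]} columns but grid has {wl.size} bands"
            )
        if mat.shape[0] != len(ids):
            raise SpectraError("one sample_id required per matrix row")
        if len(set(ids)) != len(ids):
            raise SpectraError("duplicate sample_ids")
        if wl.size and np.any(np.diff(wl) <= 0):
            raise SpectraError("wavelengths must be strictly increasing")
        if self.averaging not in ("mean", "median"):
            raise SpectraError(f"unknown averaging {self.averaging!r}")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bands(self) -> int:
        return self.matrix.shape[1]

    def spectrum(self, sample_id: str, kind: str = "reflectance") -> Spectrum:
        """Return one sample row as a :class:`Spectrum`."""
        i = self.sample_ids.index(sample_id)
        return Spectrum(self.wavelengths_nm, self.matrix[i], kind=kind)


@dataclass(frozen=True)
class BiomassRecord:
    """Per-plot biomass response variables.

    TAGB and GAGB are dry aboveground biomass in g/m2 (total and green
    fraction); pctGAGB is the green fraction as a percentage of the total.
    """

    TAGB: float
    GAGB: float
    pctGAGB: float

    _PCT_TOL = 0.5  # absolute tolerance (%) on pctGAGB consistency

    def __post_init__(self) -> None:
        if not (0.0 <= self.GAGB <= self.TAGB):
            raise SpectraError(
                f"GAGB must satisfy 0 <= GAGB <= TAGB; got GAGB={self.GAGB}, "
                f"TAGB={self.TAGB}"
            )
        if not (0.0 <= self.pctGAGB <= 100.0):
            raise SpectraError(f"pctGAGB must lie in [0, 100]; got {self.pctGAGB}")
        if self.TAGB > 0:
            implied = 100.0 * self.GAGB / self.TAGB
            if abs(implied - self.pctGAGB) > self._PCT_TOL:
                raise SpectraError(
                    f"pctGAGB={self.pctGAGB} inconsistent with "
                    f"100*GAGB/TAGB={implied:.3f}"
                )

    def response(self, name: str) -> float:
        if name not in ("TAGB", "GAGB", "pctGAGB"):
            raise SpectraError(f"unknown response {name!r}")
        return getattr(self, name)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def average_readings(readings: ReadingSet, method: str = "mean") -> Spectrum:
    """Collapse a reading set to a single per-wavelength mean or median spectrum."""
    if method not in ("mean", "median"):
        raise SpectraError(f"unknown averaging method {method!r}")
    stack = np.vstack([r.values for r in readings.readings])
    avg = stack.mean(axis=0) if method == "mean" else np.median(stack, axis=0)
    return Spectrum(readings.wavelengths_nm, avg, kind=readings.readings[0].kind)


def _range_mask(wavelengths: np.ndarray, ranges: Iterable[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(wavelengths.size, dtype=bool)
    for lo, hi in ranges:
        mask |= (wavelengths >= lo) & (wavelengths <= hi)
    return mask


def exclude_noisy_bands(ds: SpectralDataset) -> SpectralDataset:
    """Drop the noisy detector bands, keeping only :data:`RETAINED_RANGES`.

    Idempotent; issues a warning (rather than an error) if nothing remains.
    """
    mask = _range_mask(ds.wavelengths_nm, RETAINED_RANGES)
    if not mask.any():
        warnings.warn("no bands remain after noisy-band exclusion", stacklevel=2)
    return SpectralDataset(
        ds.wavelengths_nm[mask], ds.matrix[:, mask], ds.sample_ids, ds.averaging
    )


def subset(ds: SpectralDataset, name: str) -> SpectralDataset:
    """Restrict a (noise-excluded) dataset to a named spectral subset."""
    if name not in SUBSET_RANGES:
        raise SpectraError(
            f"unknown subset {name!r}; expected one of {sorted(SUBSET_RANGES)}"
        )
    mask = _range_mask(ds.wavelengths_nm, SUBSET_RANGES[name])
    return SpectralDataset(
        ds.wavelengths_nm[mask], ds.matrix[:, mask], ds.sample_ids, ds.averaging
    )


def dataset_from_readings(
    reading_sets: Sequence[ReadingSet], method: str = "mean"
) -> SpectralDataset:
    """Average each plot's readings and stack the results into a dataset."""
    if not reading_sets:
        raise SpectraError("no reading sets provided")
    grid = reading_sets[0].wavelengths_nm
    rows, ids = [], []
    for rs in reading_sets:
        if not np.array_equal(rs.wavelengths_nm, grid):
            raise SpectraError(f"plot {rs.plot_id!r} is on a different grid")
        rows.append(average_readings(rs, method).values)
        ids.append(rs.plot_id)
    return SpectralDataset(grid, np.vstack(rows), tuple(ids), averaging=method)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_WL_COL = "wavelength_nm"


def _read_table(path: str | Path) -> pd.DataFrame:
    # sep=None sniffs comma vs tab
    return pd.read_csv(path, sep=None, engine="python")


def load_spectra(path: str | Path) -> list[ReadingSet]:
    """Load reading sets from a delimited text file.

    The file has a ``wavelength_nm`` first column and one column per reading
    named ``<plot_id>__r<k>``.
    """
    df = _read_table(path)
    if df.columns[0] != _WL_COL:
        raise SpectraError(
            f"{path}: first column must be {_WL_COL!r}, got {df.columns[0]!r}"
        )
    wl = df[_WL_COL].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise SpectraError(f"{path}: wavelengths not strictly increasing")
    groups: dict[str, list[Spectrum]] = {}
    for col in df.columns[1:]:
        if "__r" not in col:
            raise SpectraError(
                f"{path}: malformed reading column {col!r} (expected <plot>__r<k>)"
            )
        plot_id = col.rsplit("__r", 1)[0]
        groups.setdefault(plot_id, []).append(
            Spectrum(wl, df[col].to_numpy(dtype=float))
        )
    return [ReadingSet(pid, tuple(specs)) for pid, specs in groups.items()]


def write_spectra(reading_sets: Sequence[ReadingSet], path: str | Path) -> None:
    """Write reading sets in the :func:`load_spectra` layout."""
    if not reading_sets:
        raise SpectraError("no reading sets to write")
    grid = reading_sets[0].wavelengths_nm
    data: dict[str, np.ndarray] = {_WL_COL: grid}
    for rs in reading_sets:
        if not np.array_equal(rs.wavelengths_nm, grid):
            raise SpectraError(f"plot {rs.plot_id!r} is on a different grid")
        for k, reading in enumerate(rs.readings, start=1):
            data[f"{rs.plot_id}__r{k}"] = reading.values
    pd.DataFrame(data).to_csv(path, index=False)


def load_dataset(path: str | Path, averaging: str = "mean") -> SpectralDataset:
    """Load a sample-by-band dataset written by :func:`write_dataset`."""
    df = _read_table(path)
    if df.columns[0] != _WL_COL:
        raise SpectraError(
            f"{path}: first column must be {_WL_COL!r}, got {df.columns[0]!r}"
        )
    wl = df[_WL_COL].to_numpy(dtype=float)
    ids = tuple(df.columns[1:])
    matrix = df[list(ids)].to_numpy(dtype=float).T
    return SpectralDataset(wl, matrix, ids, averaging=averaging)


def write_dataset(ds: SpectralDataset, path: str | Path) -> None:
    """Write a dataset as delimited text (lossless float round trip)."""
    data: dict[str, np.ndarray] = {_WL_COL: ds.wavelengths_nm}
    for i, sid in enumerate(ds.sample_ids):
        data[sid] = ds.matrix[i]
    pd.DataFrame(data).to_csv(path, index=False)


def load_biomass(path: str | Path) -> dict[str, BiomassRecord]:
    """Load a biomass table with columns ``plot_id, TAGB, GAGB, pctGAGB``."""
    df = _read_table(path)
    required = {"plot_id", "TAGB", "GAGB", "pctGAGB"}
    missing = required - set(df.columns)
    if missing:
        raise SpectraError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, BiomassRecord] = {}
    for _, row in df.iterrows():
        pid = str(row["plot_id"])
        if pid in out:
            raise SpectraError(f"{path}: duplicated plot_id {pid!r}")
        out[pid] = BiomassRecord(
            float(row["TAGB"]), float(row["GAGB"]), float(row["pctGAGB"])
        )
    return out


def write_biomass(records: Mapping[str, BiomassRecord], path: str | Path) -> None:
    rows = [
        {"plot_id": pid, "TAGB": r.TAGB, "GAGB": r.GAGB, "pctGAGB": r.pctGAGB}
        for pid, r in records.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def response_vector(
    records: Mapping[str, BiomassRecord], sample_ids: Sequence[str], name: str
) -> np.ndarray:
    """Align a biomass response with a dataset's sample order."""
    missing = [sid for sid in sample_ids if sid not in records]
    if missing:
        raise SpectraError(f"missing biomass records for plots {missing}")
    return np.array([records[sid].response(name) for sid in sample_ids])
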