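"""Chemometric pre-processing transformations applied before modelling.

Each transformation is applied to one spectrum at a time except the three
multiplicative-scatter corrections, which fit every sample against the
dataset mean spectrum and therefore must be re-derived whenever the set of
samples changes (e.g. inside each cross-validation fold).

Transform codes
---------------
BLO           baseline offset (subtract per-spectrum minimum)
DE-TREN1/2/3  polynomial de-trending, order 1..3
MSCA/MSCF/MSCO multiplicative scatter correction (amplification/full/offset)
NAR/NMX/NME/NRA/NUV  normalise by area / max / mean / range / unit vector
NGD-3/5/7/9   Norris gap first derivative, gap 3..9
RAB           reflectance to absorbance, log10(1/R)
SNV           standard normal variate
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly

from grasspec.spectra_io import SpectralDataset, SpectraError, Spectrum

#: The 18 non-continuum-removal transform codes.
TRANSFORM_CODES: tuple[str, ...] = (
    "BLO",
    "DE-TREN1",
    "DE-TREN2",
    "DE-TREN3",
    "MSCA",
    "MSCF",
    "MSCO",
    "NAR",
    "NMX",
    "NME",
    "NRA",
    "NUV",
    "NGD-3",
    "NGD-5",
    "NGD-7",
    "NGD-9",
    "RAB",
    "SNV",
)

_MSC_CODES = {"MSCA": "amplification", "MSCF": "full", "MSCO": "offset"}
_NORM_CODES = {
    "NAR": "area",
    "NMX": "max",
    "NME": "mean",
    "NRA": "range",
    "NUV": "unit_vector",
}


class TransformError(ValueError):
    """Invalid input for a pre-processing transformation."""


# ---------------------------------------------------------------------------
# Per-spectrum transforms
# ---------------------------------------------------------------------------


def baseline_offset(x: Spectrum) -> Spectrum:
    """Subtract the spectrum minimum so the output minimum is exactly 0."""
    return Spectrum(x.wavelengths_nm, x.values - x.values.min(), kind="transformed")


def detrend(x: Spectrum, k: int) -> Spectrum:
    """Remove the least-squares degree-``k`` polynomial trend in wavelength.

    The grid is internally mapped to [-1, 1] for conditioning; the residuals
    are identical to a fit on the raw wavelengths.
    """
    if k not in (1, 2, 3):
        raise TransformError(f"detrend order must be 1, 2 or 3; got {k}")
    if x.n_bands <= k + 1:
        raise TransformError(
            f"detrend order {k} requires more than {k + 1} bands; got {x.n_bands}"
        )
    wl = x.wavelengths_nm
    t = 2.0 * (wl - wl[0]) / (wl[-1] - wl[0]) - 1.0
    coef = npoly.polyfit(t, x.values, deg=k)
    return Spectrum(wl, x.values - npoly.polyval(t, coef), kind="transformed")


def normalize(x: Spectrum, mode: str) -> Spectrum:
    """Scale a spectrum by its area, maximum, mean, range or l2 norm."""
    v = x.values
    if mode == "area":
        denom = np.trapezoid(v, x.wavelengths_nm)
    elif mode == "max":
        denom = v.max()
    elif mode == "mean":
        denom = v.mean()
    elif mode == "range":
        denom = v.max() - v.min()
    elif mode == "unit_vector":
        denom = float(np.linalg.norm(v))
    else:
        raise TransformError(f"unknown normalisation mode {mode!r}")
    if abs(denom) < 1e-300:
        raise TransformError(f"normalisation denominator is zero (mode {mode!r})")
    return Spectrum(x.wavelengths_nm, v / denom, kind="transformed")


def norris_gap_derivative(x: Spectrum, g: int) -> Spectrum:
    """Symmetric gap first derivative; drops ``g`` bands at each edge.

    D(l_i) = (x(l_{i+g}) - x(l_{i-g})) / (l_{i+g} - l_{i-g}); exact for
    quadratics on uniform grids.
    """
    if g not in (3, 5, 7, 9):
        raise TransformError(f"gap size must be 3, 5, 7 or 9; got {g}")
    n = x.n_bands
    if n <= 2 * g:
        raise TransformError(f"gap {g} requires more than {2 * g} bands; got {n}")
    wl, v = x.wavelengths_nm, x.values
    deriv = (v[2 * g :] - v[: n - 2 * g]) / (wl[2 * g :] - wl[: n - 2 * g])
    return Spectrum(wl[g : n - g], deriv, kind="transformed")


def reflectance_to_absorbance(x: Spectrum) -> Spectrum:
    """Apparent absorbance A = log10(1/R); requires strictly positive values."""
    if np.any(x.values <= 0):
        raise TransformError("reflectance-to-absorbance requires values > 0")
    return Spectrum(x.wavelengths_nm, np.log10(1.0 / x.values), kind="transformed")


def snv(x: Spectrum) -> Spectrum:
    """Standard normal variate: centre to zero mean, scale to unit sd (n-1)."""
    if x.n_bands < 2:
        raise TransformError("SNV requires at least 2 bands")
    sd = x.values.std(ddof=1)
    if sd <= 0:
        raise TransformError("SNV undefined for a constant spectrum")
    return Spectrum(
        x.wavelengths_nm, (x.values - x.values.mean()) / sd, kind="transformed"
    )


# ---------------------------------------------------------------------------
# Multiplicative scatter correction (dataset-level)
# ---------------------------------------------------------------------------


def _msc_fit(row: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    """OLS fit of one sample against the reference: row = a + b * ref."""
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom < 1e-300:
        raise TransformError("MSC reference spectrum is constant")
    b = float(ref_c @ (row - row.mean())) / denom
    a = float(row.mean() - b * ref.mean())
    return a, b


def msc(ds: SpectralDataset, mode: str) -> SpectralDataset:
    """Multiplicative scatter correction against the dataset mean spectrum.

    mode ``offset`` subtracts the fitted intercept; ``amplification`` divides
    by the fitted slope; ``full`` applies both.  The intercept is estimated
    in all three modes.
    """
    if mode not in ("offset", "amplification", "full"):
        raise TransformError(f"unknown MSC mode {mode!r}")
    if ds.n_samples < 2:
        raise TransformError("MSC requires at least 2 samples")
    ref = ds.matrix.mean(axis=0)
    corrected = _msc_apply(ds.matrix, ref, mode)
    return SpectralDataset(ds.wavelengths_nm, corrected, ds.sample_ids, ds.averaging)


def _msc_apply(X: np.ndarray, ref: np.ndarray, mode: str) -> np.ndarray:
    out = np.empty_like(X, dtype=float)
    for i, row in enumerate(X):
        a, b = _msc_fit(row, ref)
        if mode != "offset" and abs(b) < 1e-12:
            raise TransformError(f"degenerate MSC slope for sample index {i}")
        if mode == "offset":
            out[i] = row - a
        elif mode == "amplification":
            out[i] = row / b
        else:
            out[i] = (row - a) / b
    return out


# ---------------------------------------------------------------------------
# Code dispatch and fold-safe preprocessing
# ---------------------------------------------------------------------------


def _apply_rowwise(ds: SpectralDataset, fn) -> SpectralDataset:
    specs = [fn(Spectrum(ds.wavelengths_nm, row, kind="transformed")) for row in ds.matrix]
    grid = specs[0].wavelengths_nm
    return SpectralDataset(
        grid, np.vstack([s.values for s in specs]), ds.sample_ids, ds.averaging
    )


def apply_transform(ds: SpectralDataset, code: str) -> SpectralDataset:
    """Apply one Table-coded transformation to a whole dataset."""
    if code not in TRANSFORM_CODES:
        raise TransformError(f"unknown transform code {code!r}")
    if code in _MSC_CODES:
        return msc(ds, _MSC_CODES[code])
    if code in _NORM_CODES:
        return _apply_rowwise(ds, lambda s: normalize(s, _NORM_CODES[code]))
    if code == "BLO":
        return _apply_rowwise(ds, baseline_offset)
    if code.startswith("DE-TREN"):
        k = int(code[-1])
        return _apply_rowwise(ds, lambda s: detrend(s, k))
    if code.startswith("NGD-"):
        g = int(code.split("-")[1])
        return _apply_rowwise(ds, lambda s: norris_gap_derivative(s, g))
    if code == "RAB":
        return _apply_rowwise(ds, reflectance_to_absorbance)
    return _apply_rowwise(ds, snv)  # SNV


def is_dataset_dependent(code: str) -> bool:
    """True when the transform fits parameters across samples (MSC family)."""
    return code in _MSC_CODES


@dataclass
class TransformPreprocessor:
    """Fold-safe wrapper: fit any dataset-level state on training rows only.

    Only the MSC family carries state (the mean reference spectrum); all
    other transforms are per-spectrum and ``fit`` is a no-op for them.
    """

    code: str
    _ref: np.ndarray | None = None

    def fit(self, wavelengths: np.ndarray, X: np.ndarray) -> "TransformPreprocessor":
        if self.code not in TRANSFORM_CODES:
            raise TransformError(f"unknown transform code {self.code!r}")
        if self.code in _MSC_CODES:
            if X.shape[0] < 2:
                raise TransformError("MSC requires at least 2 training samples")
            self._ref = X.mean(axis=0)
        return self

    def transform(
        self, wavelengths: np.ndarray, X: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        if self.code in _MSC_CODES:
            if self._ref is None:
                raise TransformError("MSC preprocessor used before fit")
            return wavelengths, _msc_apply(X, self._ref, _MSC_CODES[self.code])
        ds = SpectralDataset(
            wavelengths, X, tuple(f"s{i}" for i in range(X.shape[0]))
        )
        out = apply_transform(ds, self.code)
        return out.wavelengths_nm, out.matrix
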