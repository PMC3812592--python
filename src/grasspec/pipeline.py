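"""Model-grid enumeration, execution, ranking and zone-combination search.

The default grid contains, per response variable:

* 12 non-transformed models: {PLSR, SVM} x 3 spectral subsets x 2 averagings;
* 124 PLSR models with transformations/indices: 18 transforms x 3 subsets
  x 2 averagings, continuum-removed reflectance over each of the 5 zones x 2,
  the MBD and AOM all-zone index sets x 2, and the untrimmed full spectrum
  x 2;
* 4 OLSR models: {MBD, AOM} x 2 averagings, each internally scanning the
  five zones and reporting the best single-zone fit;

for a total of 140 specs per response, 420 over the three responses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from grasspec import transforms as _transforms
from grasspec.continuum import (
    DEFAULT_ZONES,
    ZONE_NAMES,
    continuum_removed,
    extract_feature_table,
    feature_matrix,
)
from grasspec.models import (
    DEFAULT_C_GRID,
    DEFAULT_EPSILON,
    PARSIMONY_REL,
    CVResult,
    fit_olsr,
    fit_svr,
    loocv,
    select_plsr_factors,
)
from grasspec.spectra_io import (
    BiomassRecord,
    ReadingSet,
    SpectraError,
    SUBSET_RANGES,
    Spectrum,
    dataset_from_readings,
    exclude_noisy_bands,
    response_vector,
    subset,
)
from grasspec.transforms import TRANSFORM_CODES, TransformPreprocessor, is_dataset_dependent

RESPONSES: tuple[str, ...] = ("TAGB", "GAGB", "pctGAGB")
SUBSET_NAMES: tuple[str, ...] = ("VNIR", "VNIR_SWIR1", "VNIR_SWIR1_SWIR2")
AVERAGINGS: tuple[str, ...] = ("mean", "median")
INDEX_NAMES: tuple[str, ...] = ("MBD", "AOM")

RESULT_COLUMNS = [
    "response",
    "method",
    "transform",
    "input",
    "spectra",
    "complexity",
    "R2",
    "RMSE",
    "pctRMSE",
    "zones_used",
    "error",
]


class PipelineError(ValueError):
    """Invalid grid configuration or execution input."""


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the model grid."""

    response: str
    method: str  # PLSR | SVM | OLSR
    input_type: str  # subset | transform | full | crr | index | olsr_index
    averaging: str  # mean | median
    subset: str | None = None
    transform: str | None = None
    zones: tuple[str, ...] = ()
    index: str | None = None

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise PipelineError(f"unknown response {self.response!r}")
        if self.method not in ("PLSR", "SVM", "OLSR"):
            raise PipelineError(f"unknown method {self.method!r}")
        if self.averaging not in AVERAGINGS:
            raise PipelineError(f"unknown averaging {self.averaging!r}")
        if self.input_type not in (
            "subset",
            "transform",
            "full",
            "crr",
            "index",
            "olsr_index",
        ):
            raise PipelineError(f"unknown input_type {self.input_type!r}")
        if self.method == "SVM" and self.input_type != "subset":
            raise PipelineError("SVM is only run on raw spectral subsets")
        if self.method == "OLSR" and self.input_type != "olsr_index":
            raise PipelineError("OLSR is only run on continuum-removal indices")
        if self.input_type in ("subset", "transform") and self.subset not in SUBSET_NAMES:
            raise PipelineError(f"spec requires a valid subset, got {self.subset!r}")
        if self.input_type == "transform" and self.transform not in TRANSFORM_CODES:
            raise PipelineError(f"invalid transform code {self.transform!r}")
        if self.input_type == "crr" and (len(self.zones) != 1 or self.zones[0] not in ZONE_NAMES):
            raise PipelineError("crr spec requires exactly one valid zone")
        if self.input_type in ("index", "olsr_index") and self.index not in INDEX_NAMES:
            raise PipelineError("index spec requires index MBD or AOM")

    @property
    def input_label(self) -> str:
        if self.input_type in ("subset", "transform"):
            return str(self.subset)
        if self.input_type == "full":
            return "full"
        if self.input_type == "crr":
            return self.zones[0]
        if self.input_type == "index":
            return "-".join(self.zones) + f" ({self.index})"
        return f"best-zone ({self.index})"


@dataclass(frozen=True)
class GridConfig:
    """Configuration of the model grid; defaults reproduce the full study grid."""

    responses: tuple[str, ...] = RESPONSES
    transforms: tuple[str, ...] = TRANSFORM_CODES
    subsets: tuple[str, ...] = SUBSET_NAMES
    zones: tuple[str, ...] = ZONE_NAMES
    averagings: tuple[str, ...] = AVERAGINGS
    indices: tuple[str, ...] = INDEX_NAMES
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    epsilon: float = DEFAULT_EPSILON
    f_max: int = 10
    center: str = "mean"


def build_model_grid(config: GridConfig | None = None) -> list[ModelSpec]:
    """Enumerate the model grid; a pure function of the configuration."""
    cfg = config if config is not None else GridConfig()
    specs: list[ModelSpec] = []
    for resp in cfg.responses:
        for method, sub, avg in itertools.product(
            ("PLSR", "SVM"), cfg.subsets, cfg.averagings
        ):
            specs.append(ModelSpec(resp, method, "subset", avg, subset=sub))
        for code, sub, avg in itertools.product(
            cfg.transforms, cfg.subsets, cfg.averagings
        ):
            specs.append(
                ModelSpec(resp, "PLSR", "transform", avg, subset=sub, transform=code)
            )
        for zone, avg in itertools.product(cfg.zones, cfg.averagings):
            specs.append(ModelSpec(resp, "PLSR", "crr", avg, zones=(zone,)))
        for index, avg in itertools.product(cfg.indices, cfg.averagings):
            specs.append(
                ModelSpec(resp, "PLSR", "index", avg, zones=tuple(cfg.zones), index=index)
            )
        for avg in cfg.averagings:
            specs.append(ModelSpec(resp, "PLSR", "full", avg))
        for index, avg in itertools.product(cfg.indices, cfg.averagings):
            specs.append(ModelSpec(resp, "OLSR", "olsr_index", avg, index=index))
    if len(set(specs)) != len(specs):
        raise PipelineError("duplicate specs in grid")
    return specs


# ---------------------------------------------------------------------------
# Grid execution
# ---------------------------------------------------------------------------


class _PreparedData:
    """Per-averaging caches shared by all specs."""

    def __init__(
        self,
        reading_sets: Sequence[ReadingSet],
        averaging: str,
        zones: Sequence[str],
    ) -> None:
        self.full_raw = dataset_from_readings(reading_sets, averaging)
        self.clean = exclude_noisy_bands(self.full_raw)
        self.subsets = {name: subset(self.clean, name) for name in SUBSET_NAMES}
        self.features = extract_feature_table(self.clean, zones)
        self._crr: dict[str, np.ndarray] = {}

    def crr_matrix(self, zone: str) -> np.ndarray:
        if zone not in self._crr:
            z = DEFAULT_ZONES[zone]
            rows = [
                continuum_removed(
                    Spectrum(self.clean.wavelengths_nm, row, kind="transformed"), z
                ).crr
                for row in self.clean.matrix
            ]
            self._crr[zone] = np.vstack(rows)
        return self._crr[zone]


def _run_spec(
    spec: ModelSpec,
    data: _PreparedData,
    y: np.ndarray,
    cfg: GridConfig,
) -> tuple[CVResult, tuple[str, ...], str]:
    """Execute one spec; returns (cv, zones actually used, transform label)."""
    ids = data.clean.sample_ids
    if spec.method == "SVM":
        ds = data.subsets[spec.subset]
        _, cv = fit_svr(ds.matrix, y, cfg.c_grid, cfg.epsilon, cfg.center)
        return cv, (), "none"
    if spec.method == "OLSR":
        best: tuple[CVResult, str] | None = None
        for zone in cfg.zones:
            X = feature_matrix(data.features, spec.index, [zone], ids)
            cv = loocv(fit_olsr, X, y, center=cfg.center, complexity=1.0)
            if best is None or (cv.r2, -cv.rmse) > (best[0].r2, -best[0].rmse):
                best = (cv, zone)
        assert best is not None
        return best[0], (best[1],), spec.index
    # PLSR family
    preprocess = None
    if spec.input_type == "subset":
        ds = data.subsets[spec.subset]
        X, wl = ds.matrix, ds.wavelengths_nm
        zones_used: tuple[str, ...] = ()
        label = "none"
    elif spec.input_type == "transform":
        ds = data.subsets[spec.subset]
        if is_dataset_dependent(spec.transform):
            X, wl = ds.matrix, ds.wavelengths_nm
            preprocess = TransformPreprocessor(spec.transform)
        else:
            out = _transforms.apply_transform(ds, spec.transform)
            X, wl = out.matrix, out.wavelengths_nm
        zones_used, label = (), spec.transform
    elif spec.input_type == "full":
        X, wl = data.full_raw.matrix, data.full_raw.wavelengths_nm
        zones_used, label = (), "none"
    elif spec.input_type == "crr":
        X = data.crr_matrix(spec.zones[0])
        wl = None
        zones_used, label = spec.zones, "CRR"
    else:  # index
        X = feature_matrix(data.features, spec.index, list(spec.zones), ids)
        wl = None
        zones_used, label = spec.zones, spec.index
    _, cv = select_plsr_factors(
        X, y, f_max=cfg.f_max, center=cfg.center, preprocess=preprocess, wavelengths=wl
    )
    return cv, zones_used, label


def run_grid(
    specs: Sequence[ModelSpec],
    reading_sets: Sequence[ReadingSet],
    biomass: Mapping[str, BiomassRecord],
    config: GridConfig | None = None,
) -> pd.DataFrame:
    """Execute every spec; per-spec failures are recorded, not raised.

    Returns one row per spec with the Table-style columns plus ``zones_used``
    (zones the executed model actually consumed; for OLSR the best zone) and
    ``error`` (empty string on success).
    """
    cfg = config if config is not None else GridConfig()
    prepared = {
        avg: _PreparedData(reading_sets, avg, cfg.zones) for avg in cfg.averagings
    }
    responses = {}
    rows = []
    for spec in specs:
        data = prepared[spec.averaging]
        key = (spec.response, spec.averaging)
        if key not in responses:
            responses[key] = response_vector(
                biomass, data.clean.sample_ids, spec.response
            )
        y = responses[key]
        row = {
            "response": spec.response,
            "method": spec.method,
            "transform": "",
            "input": spec.input_label,
            "spectra": spec.averaging,
            "complexity": float("nan"),
            "R2": float("nan"),
            "RMSE": float("nan"),
            "pctRMSE": float("nan"),
            "zones_used": (),
            "error": "",
            "spec": spec,
        }
        try:
            cv, zones_used, label = _run_spec(spec, data, y, cfg)
            row.update(
                transform=label,
                complexity=cv.complexity,
                R2=cv.r2,
                RMSE=cv.rmse,
                pctRMSE=cv.pct_rmse,
                zones_used=zones_used,
            )
            if spec.method == "OLSR":
                row["input"] = f"{zones_used[0]} ({spec.index})"
        except Exception as exc:  # noqa: BLE001 - failures recorded per row
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS + ["spec"])


def is_more_accurate(rmse_a: float, rmse_b: float) -> bool:
    """True when model A's CV RMSE beats model B's by at least 2%."""
    return rmse_a <= (1.0 - PARSIMONY_REL) * rmse_b


def rank_models(result: pd.DataFrame) -> pd.DataFrame:
    """Order rows by R2 descending (ties: RMSE ascending, then input order).

    Failed rows sort last.  Adds ``rank`` and ``better_than_next`` (the >=2%
    RMSE-improvement flag relative to the next-ranked successful row).
    """
    if len(result) == 0:
        raise PipelineError("empty grid result")
    df = result.copy()
    df["_failed"] = df["error"].astype(bool)
    df["_order"] = np.arange(len(df))
    df = df.sort_values(
        by=["_failed", "R2", "RMSE", "_order"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).drop(columns=["_failed", "_order"])
    df = df.reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    flags = []
    for i in range(len(df)):
        if df.loc[i, "error"] or i + 1 >= len(df) or df.loc[i + 1, "error"]:
            flags.append(False)
        else:
            flags.append(is_more_accurate(df.loc[i, "RMSE"], df.loc[i + 1, "RMSE"]))
    df["better_than_next"] = flags
    return df


def _zone_in_ranges(zone: str, ranges: Iterable[tuple[float, float]]) -> bool:
    z = DEFAULT_ZONES[zone]
    return any(lo <= z.lambda_start and z.lambda_end <= hi for lo, hi in ranges)


def row_bears_zone(row: Mapping, zone: str) -> bool:
    """Whether a result row's input covers the named absorption zone.

    Index/CRR inputs bear a zone when it is among the zones actually used;
    continuous-spectrum inputs bear it when the zone's wavelength interval is
    fully inside the input's wavelength ranges.
    """
    spec: ModelSpec = row["spec"]
    if spec.input_type in ("crr", "index", "olsr_index"):
        return zone in tuple(row["zones_used"])
    if spec.input_type == "full":
        return True
    return _zone_in_ranges(zone, SUBSET_RANGES[spec.subset])


def explore_zone_combinations(
    index: str,
    feature_table: pd.DataFrame,
    y: np.ndarray,
    sample_ids: Sequence[str],
    mandatory: str = "Z4",
    f_max: int = 10,
    center: str = "mean",
) -> pd.DataFrame:
    """PLSR over every zone combination containing the mandatory zone.

    All non-empty subsets of the optional zones are unioned with the
    mandatory zone (15 combinations of sizes 2-5 with the default five
    zones); factor selection is applied per combination.
    """
    if index not in INDEX_NAMES:
        raise PipelineError(f"unknown index {index!r}")
    present = set(feature_table["zone"].unique())
    if mandatory not in present:
        raise SpectraError(f"mandatory zone {mandatory!r} absent from feature table")
    optional = [z for z in ZONE_NAMES if z in present and z != mandatory]
    rows = []
    for r in range(1, len(optional) + 1):
        for combo in itertools.combinations(optional, r):
            zones = tuple(z for z in ZONE_NAMES if z in set(combo) | {mandatory})
            X = feature_matrix(feature_table, index, list(zones), sample_ids)
            F, cv = select_plsr_factors(X, y, f_max=f_max, center=center)
            rows.append(
                {
                    "input": "-".join(zones) + f" ({index})",
                    "zones": zones,
                    "F": F,
                    "R2": cv.r2,
                    "RMSE": cv.rmse,
                    "pctRMSE": cv.pct_rmse,
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(by=["R2", "RMSE"], ascending=[False, True]).reset_index(
        drop=True
    )
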