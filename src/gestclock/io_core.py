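"""Tabular I/O for beta matrices, clock tables and sample sheets.

All formats are plain delimited text (comma for ``.csv``, tab for ``.tsv`` /
``.txt``); beta matrices default to CpGs-as-rows on disk (the usual
series-matrix layout) while the in-memory :class:`BetaMatrix` is samples x
CpGs. Readers validate and fail loudly with located messages; they never
silently coerce.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .clocks import ClockModel

log = logging.getLogger("gestclock")

TISSUES = ("cvs", "placenta_fetal", "placenta_decidual", "cord_blood")

#: the birth- and pregnancy-related predictor variables and their coding.
#: Binary codings: child_sex 1 = female, parity 1 = multiparous,
#: delivery_mode 1 = aided (breech/forceps/vacuum/cesarean).
PREDICTOR_TYPES: dict[str, str] = {
    "child_sex": "binary",
    "birth_weight_g": "continuous",
    "birth_length_cm": "continuous",
    "head_circumference_cm": "continuous",
    "maternal_age_years": "continuous",
    "maternal_bmi": "continuous",
    "maternal_smoking": "binary",
    "parity": "binary",
    "delivery_mode": "binary",
    "induced_labor": "binary",
    "maternal_diabetes": "binary",
    "hypertensive_disorder": "binary",
    "maternal_mental_disorders": "binary",
    "maternal_alcohol_use": "binary",
}

#: default predictor set: alcohol use is held out of the main models (it is
#: missing for many samples in practice) and added on request.
DEFAULT_PREDICTORS: tuple[str, ...] = tuple(
    k for k in PREDICTOR_TYPES if k != "maternal_alcohol_use"
)

ANCESTRY_COLS = ("ancestry_c1", "ancestry_c2")
CELL_PREFIX = "cell_"


def _delimiter(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# BetaMatrix


@dataclass
class BetaMatrix:
    """Methylation beta values, in-memory orientation samples x CpGs.

    Missing values are NaN; every non-missing value must lie in [0, 1].
    """

    cpg_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_samples, n_cpgs)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.cpg_ids)):
            raise ValueError(
                f"beta matrix shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.cpg_ids)} CpGs"
            )
        for label, ids in (("CpG", self.cpg_ids), ("sample", self.sample_ids)):
            dup = pd.Index(ids)[pd.Index(ids).duplicated()]
            if len(dup):
                raise ValueError(f"duplicate {label} id: {dup[0]!r}")
        with np.errstate(invalid="ignore"):
            bad = (self.values < 0) | (self.values > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta out of range: value {self.values[i, j]} at CpG "
                f"{self.cpg_ids[j]!r}, sample {self.sample_ids[i]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.cpg_ids)


def read_beta_matrix(path: str | Path,
                     orientation: str = "cpgs_as_rows") -> BetaMatrix:
    """Read a delimited beta matrix; first column holds ids.

    orientation: ``cpgs_as_rows`` (default) or ``samples_as_rows``.
    """
    if orientation not in ("cpgs_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_delimiter(path), index_col=0)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                          & df[col].notna()]
            where = f"row {bad.index[0]!r}" if len(bad) else "unknown row"
            raise ValueError(
                f"non-numeric beta value in column {col!r}, {where} of {path}")
    if orientation == "cpgs_as_rows":
        cpg_ids = [str(i) for i in df.index]
        sample_ids = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float).T
    else:
        sample_ids = [str(i) for i in df.index]
        cpg_ids = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
    return BetaMatrix(cpg_ids=cpg_ids, sample_ids=sample_ids, values=values)


def write_beta_matrix(betas: BetaMatrix, path: str | Path,
                      orientation: str = "cpgs_as_rows") -> None:
    df = betas.to_frame()
    if orientation == "cpgs_as_rows":
        df = df.T
        df.index.name = "cpg"
    else:
        df.index.name = "sample_id"
    df.to_csv(path, sep=_delimiter(path))


# ---------------------------------------------------------------------------
# Clock tables

_INTERCEPT_ROW = "(Intercept)"


def read_clock_table(path: str | Path) -> ClockModel:
    """Read a clock coefficient table.

    Expected layout: a first comment line ``# name=<clock> unit=<weeks|days>``
    followed by a two-column table ``cpg,weight`` containing one reserved
    row with cpg = "(Intercept)".
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    meta: dict[str, str] = {}
    skip = 0
    if first.startswith("#"):
        skip = 1
        for tok in first.lstrip("#").split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
    name = meta.get("name", path.stem)
    unit = meta.get("unit", "weeks")
    df = pd.read_csv(path, sep=_delimiter(path), skiprows=skip)
    if list(df.columns[:2]) != ["cpg", "weight"]:
        raise ValueError(f"clock table {path} must have columns (cpg, weight)")
    dup = df["cpg"][df["cpg"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate CpG in clock table: {dup.iloc[0]!r}")
    if _INTERCEPT_ROW not in set(df["cpg"]):
        raise ValueError(f'clock table {path} is missing an "(Intercept)" row')
    inter = float(df.loc[df["cpg"] == _INTERCEPT_ROW, "weight"].iloc[0])
    rows = df[df["cpg"] != _INTERCEPT_ROW]
    weights = dict(zip(rows["cpg"].astype(str), rows["weight"].astype(float)))
    return ClockModel(name=name, intercept=inter, weights=weights, unit=unit)


def write_clock_table(clock: ClockModel, path: str | Path) -> None:
    sep = _delimiter(path)
    with open(path, "w") as fh:
        fh.write(f"# name={clock.name} unit={clock.unit}\n")
        fh.write(f"cpg{sep}weight\n")
        fh.write(f"{_INTERCEPT_ROW}{sep}{clock.intercept!r}\n")
        for cpg, w in clock.weights.items():
            fh.write(f"{cpg}{sep}{w!r}\n")


# ---------------------------------------------------------------------------
# Phenotype tables


@dataclass
class PhenotypeTable:
    """One row per (individual, tissue) sample with GA, predictors,
    cell-type proportions and two ancestry components."""

    df: pd.DataFrame  # indexed by sample_id
    predictor_types: dict[str, str]

    @property
    def predictors(self) -> list[str]:
        return list(self.predictor_types)

    @property
    def cell_cols(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith(CELL_PREFIX)]

    def subset(self, tissue: str | None = None,
               cohort: str | None = None) -> "PhenotypeTable":
        df = self.df
        if tissue is not None:
            df = df[df["tissue"] == tissue]
        if cohort is not None:
            df = df[df["cohort_id"] == cohort]
        return PhenotypeTable(df.copy(), dict(self.predictor_types))


def _validate_phenotypes(df: pd.DataFrame,
                         predictor_types: Mapping[str, str]) -> pd.DataFrame:
    df = df.copy()
    unknown = set(df["tissue"]) - set(TISSUES)
    if unknown:
        raise ValueError(f"unknown tissue label(s): {sorted(unknown)}")
    if (df["ga_weeks"] <= 0).any():
        bad = df.index[df["ga_weeks"] <= 0][0]
        raise ValueError(f"ga_weeks must be positive (sample {bad!r})")
    for name, kind in predictor_types.items():
        if kind == "binary":
            vals = df[name].dropna()
            bad = vals[~vals.isin([0, 1])]
            if len(bad):
                raise ValueError(
                    f"binary predictor {name!r} must be coded 0/1; got "
                    f"{bad.iloc[0]!r} for sample {bad.index[0]!r}")
    cell_cols = [c for c in df.columns if c.startswith(CELL_PREFIX)]
    if cell_cols:
        props = df[cell_cols].to_numpy(dtype=float)
        if (props < 0).any():
            raise ValueError("cell proportions must be non-negative")
        sums = props.sum(axis=1)
        off = np.abs(sums - 1.0) > 1e-3
        if off.any():
            bad = df.index[off][0]
            raise ValueError(
                f"cell proportions of sample {bad!r} sum to "
                f"{sums[off][0]:.6f}, outside 1 +/- 1e-3")
        df[cell_cols] = props / sums[:, None]
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id: {dup[0]!r}")
    return df


def read_phenotypes(path: str | Path,
                    predictors: Sequence[str] | None = None) -> PhenotypeTable:
    """Read a sample sheet CSV/TSV (one row per sample, sample_id column)."""
    df = pd.read_csv(path, sep=_delimiter(path)).set_index("sample_id")
    df.index = df.index.astype(str)
    names = [p for p in (predictors or PREDICTOR_TYPES) if p in df.columns]
    types = {p: PREDICTOR_TYPES[p] for p in names}
    df = _validate_phenotypes(df, types)
    return PhenotypeTable(df=df, predictor_types=types)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    df = table.df.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep=_delimiter(path))


# ---------------------------------------------------------------------------
# Run configuration and manifests


@dataclass
class RunConfig:
    """Knobs of the selection pipeline plus file paths and filters."""

    seed: int = 0
    B: int = 1000
    alpha_grid: tuple[float, ...] = tuple(np.round(np.arange(0, 1.01, 0.1), 1))
    n_lambda: int = 100
    k_folds: int = 10
    stability_threshold: float = 0.75
    min_coverage: float = 0.5
    tissue: str | None = None
    cohort: str | None = None
    sex: str = "all"  # all | male | female
    include_alcohol: bool = False
    beta_path: str | None = None
    phenotype_path: str | None = None
    clock_path: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not 0 < self.stability_threshold < 1:
            raise ValueError("stability_threshold must lie in (0, 1)")
        if self.sex not in ("all", "male", "female"):
            raise ValueError("sex filter must be all, male or female")

    @property
    def predictor_set(self) -> tuple[str, ...]:
        if self.include_alcohol:
            return tuple(PREDICTOR_TYPES)
        return DEFAULT_PREDICTORS

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "alpha_grid" in data:
            data["alpha_grid"] = tuple(float(a) for a in data["alpha_grid"])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, seed: int, config: Mapping | RunConfig,
                   input_paths: Iterable[str | Path] = (),
                   extra: Mapping | None = None) -> dict:
    """Write a JSON run manifest: seed, config hash, input checksums."""
    cfg = config.to_dict() if isinstance(config, RunConfig) else dict(config)
    blob = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "seed": int(seed),
        "config": cfg,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "inputs": {str(p): file_checksum(p) for p in input_paths},
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("manifest written to %s (seed=%d)", path, seed)
    return manifest
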