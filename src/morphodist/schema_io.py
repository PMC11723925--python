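"""Variable schemas, flake-table I/O, filtering, and the geometric-mean shape transform.

An artefact table is a flat CSV with one row per flake: a grouping column
(cultural phase) plus mixed-scale attribute columns.  Each attribute is
declared by a :class:`Variable` (continuous, ordinal, or nominal with an
ordered level list), and the five calliper measurements describing overall
flake geometry (length, width, thickness, platform width, platform
thickness) carry a ``geometry`` flag so they can be converted into scale-free
shape variables by dividing each by the per-flake geometric mean.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SCALES = ("continuous", "ordinal", "nominal")

#: Cell contents parsed as missing (case-insensitive, after stripping).
MISSING_TOKENS = frozenset({"", "na", "n/a", "nan", "na´s", "na's", "<na>"})


class SchemaError(ValueError):
    """A table does not structurally match its declared schema."""


class ValidationError(ValueError):
    """A cell value violates the declared scale or level set."""


class DomainError(ValueError):
    """A value is outside the mathematical domain of an operation."""


@dataclass(frozen=True)
class Variable:
    """Declaration of one recorded attribute."""

    name: str
    scale: str
    levels: tuple[str, ...] | None = None
    level_labels: tuple[str, ...] | None = None
    geometry: bool = False
    label: str | None = None
    reference_counts: tuple[int, ...] | None = None
    reference_na: int | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise SchemaError(f"{self.name}: unknown scale {self.scale!r}")
        if self.scale == "continuous":
            if self.levels is not None:
                raise SchemaError(f"{self.name}: continuous variables take no levels")
        else:
            if not self.levels:
                raise SchemaError(f"{self.name}: {self.scale} variable needs levels")
            if len(set(self.levels)) != len(self.levels):
                raise SchemaError(f"{self.name}: duplicate levels")
            if len(self.levels) < 2:
                raise SchemaError(f"{self.name}: needs at least 2 levels")
        if self.geometry and self.scale != "continuous":
            raise SchemaError(f"{self.name}: geometry flag requires continuous scale")
        if self.level_labels is not None and self.levels is not None:
            if len(self.level_labels) != len(self.levels):
                raise SchemaError(f"{self.name}: level_labels length mismatch")

    @property
    def is_categorical(self) -> bool:
        return self.scale in ("ordinal", "nominal")

    def level_of_label(self, label: str) -> str | None:
        if self.level_labels is None or self.levels is None:
            return None
        try:
            return self.levels[self.level_labels.index(label)]
        except ValueError:
            return None


@dataclass(frozen=True)
class Schema:
    """An ordered collection of variable declarations plus the grouping column."""

    variables: tuple[Variable, ...]
    group_column: str = "GROUP"
    group_levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in schema")
        if self.group_column in names:
            raise SchemaError("group column collides with a variable name")

    # -- lookups ---------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    def of_scale(self, *scales: str) -> list[Variable]:
        return [v for v in self.variables if v.scale in scales]

    @property
    def continuous_names(self) -> list[str]:
        return [v.name for v in self.of_scale("continuous")]

    @property
    def ordinal_names(self) -> list[str]:
        return [v.name for v in self.of_scale("ordinal")]

    @property
    def nominal_names(self) -> list[str]:
        return [v.name for v in self.of_scale("nominal")]

    @property
    def geometry_names(self) -> list[str]:
        return [v.name for v in self.variables if v.geometry]

    def drop(self, *names: str) -> "Schema":
        """Schema without the named variables (for sensitivity variants)."""
        keep = tuple(v for v in self.variables if v.name not in names)
        return replace(self, variables=keep)

    # -- construction ----------------------------------------------------
    @classmethod
    def from_dict(cls, doc: dict) -> "Schema":
        vars_: list[Variable] = []
        for item in doc["variables"]:
            vars_.append(
                Variable(
                    name=str(item["name"]),
                    scale=str(item["scale"]),
                    levels=tuple(str(x) for x in item["levels"]) if item.get("levels") else None,
                    level_labels=tuple(str(x) for x in item["level_labels"])
                    if item.get("level_labels")
                    else None,
                    geometry=bool(item.get("geometry", False)),
                    label=item.get("label"),
                    reference_counts=tuple(int(x) for x in item["reference_counts"])
                    if item.get("reference_counts")
                    else None,
                    reference_na=int(item["reference_na"]) if "reference_na" in item else None,
                )
            )
        return cls(
            variables=tuple(vars_),
            group_column=str(doc.get("group_column", "GROUP")),
            group_levels=tuple(str(x) for x in doc["group_levels"])
            if doc.get("group_levels")
            else None,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Schema":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def sibhudu(cls) -> "Schema":
        """The packaged default: the 16-attribute Sibhudu flake recording protocol."""
        ref = resources.files("morphodist.data").joinpath("sibhudu_schema.yaml")
        return cls.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


@dataclass
class FlakeTable:
    """Artefact records with mixed-scale values, group labels, and missingness.

    ``data`` holds one column per schema variable (continuous as float64,
    ordinal/nominal as pandas Categorical over the declared levels); ``group``
    is an aligned Series of phase labels (may contain missing values until
    filtered).
    """

    data: pd.DataFrame
    group: pd.Series
    schema: Schema

    def __post_init__(self) -> None:
        if list(self.data.columns) != self.schema.names:
            raise SchemaError("table columns do not match schema order")
        if len(self.group) != len(self.data):
            raise SchemaError("group labels and records differ in length")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def missing_counts(self) -> pd.Series:
        """Number of missing attribute cells per record."""
        return self.data.isna().sum(axis=1)

    def group_counts(self) -> pd.Series:
        return self.group.value_counts(sort=False, dropna=False)

    def copy(self) -> "FlakeTable":
        return FlakeTable(self.data.copy(), self.group.copy(), self.schema)

    def take(self, index) -> "FlakeTable":
        return FlakeTable(
            self.data.loc[index].reset_index(drop=True),
            self.group.loc[index].reset_index(drop=True),
            self.schema,
        )

    def to_frame(self) -> pd.DataFrame:
        """Group column plus attributes, suitable for CSV round-tripping."""
        out = self.data.copy()
        out.insert(0, self.schema.group_column, self.group)
        return out

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class FilterConfig:
    """Record-retention rules: missingness cap and group-label requirement."""

    max_missing_fraction: float = 0.20
    require_group: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# parsing


def _is_missing_token(cell: str) -> bool:
    return cell.strip().lower() in MISSING_TOKENS


def _normalise_code(cell: str) -> str:
    """Map '1.0' -> '1' so numerically-typed category codes survive CSV round trips."""
    s = cell.strip()
    try:
        f = float(s)
    except ValueError:
        return s
    if f == int(f):
        return str(int(f))
    return s


def read_table(
    path: str | Path,
    schema: Schema | None = None,
    group_column: str | None = None,
) -> FlakeTable:
    """Read and validate a delimited artefact table against a schema.

    Empty and NA-token cells become missing; unparseable continuous cells
    become missing; a categorical value outside the declared level set raises
    :class:`ValidationError` with the offending row.
    """
    schema = schema or Schema.sibhudu()
    group_column = group_column or schema.group_column
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in schema.names + [group_column] if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"input file lacks required column(s): {', '.join(missing_cols)}")

    data: dict[str, object] = {}
    for var in schema.variables:
        col = raw[var.name].astype(str)
        miss = col.map(_is_missing_token)
        if var.scale == "continuous":
            parsed = pd.to_numeric(col.where(~miss), errors="coerce")
            data[var.name] = parsed.astype(float)
        else:
            vals = col.where(~miss).map(lambda s: _normalise_code(s) if isinstance(s, str) else s)
            # accept labels as synonyms for level codes
            if var.level_labels is not None:
                label_map = {lab: lev for lab, lev in zip(var.level_labels, var.levels)}
                vals = vals.map(lambda s: label_map.get(s, s) if isinstance(s, str) else s)
            bad = vals.dropna()[~vals.dropna().isin(var.levels)]
            if len(bad):
                row = int(bad.index[0])
                raise ValidationError(
                    f"column {var.name}: value {bad.iloc[0]!r} at row {row} is not "
                    f"among declared levels {list(var.levels)}"
                )
            data[var.name] = pd.Categorical(
                vals, categories=var.levels, ordered=(var.scale == "ordinal")
            )

    gcol = raw[group_column].astype(str)
    gmiss = gcol.map(_is_missing_token)
    group = gcol.where(~gmiss).map(lambda s: _normalise_code(s) if isinstance(s, str) else s)
    group.name = schema.group_column
    return FlakeTable(pd.DataFrame(data, columns=schema.names), group, schema)


def table_from_frame(frame: pd.DataFrame, schema: Schema) -> FlakeTable:
    """Build a validated FlakeTable from an in-memory DataFrame (same rules as read_table)."""
    import io

    buf = io.StringIO()
    frame.to_csv(buf, index=False)
    buf.seek(0)
    return read_table(buf, schema)


# ---------------------------------------------------------------------------
# filtering


def max_missing_count(n_vars: int, fraction: float) -> int:
    """Largest number of missing variables admissible under a proportional cap.

    Uses floor: a 20% cap over 16 variables admits at most 3 missing.
    """
    if n_vars < 1:
        raise ValueError("n_vars must be >= 1")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    return math.floor(fraction * n_vars)


def filter_flakes(table: FlakeTable, cfg: FilterConfig | None = None) -> FlakeTable:
    """Retain records with a group label and at most the admissible number of missing cells."""
    cfg = cfg or FilterConfig()
    cap = max_missing_count(len(table.schema), cfg.max_missing_fraction)
    keep = table.missing_counts <= cap
    if cfg.require_group:
        keep &= table.group.notna()
    out = table.take(table.data.index[keep])
    counts = out.group.value_counts(sort=False)
    logger.info(
        "filter_flakes: kept %d of %d records (missing cap %d of %d); per-group %s",
        out.n, table.n, cap, len(table.schema), counts.to_dict(),
    )
    if out.n == 0:
        warnings.warn("filter_flakes produced an empty table", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# shape transform


def to_shape_variables(table: FlakeTable, mode: str = "available") -> FlakeTable:
    """Convert the five geometry measurements into scale-free shape variables.

    Each geometry value is divided by the per-record geometric mean of the
    geometry measurements.  ``mode='available'`` (default) uses the geometric
    mean of whichever geometry cells are observed in that record, so broken
    flakes with partial measurements remain size-corrected; ``mode='strict'``
    transforms only records with all five measurements and leaves the rest
    untouched.  Non-positive measurements are a domain error.
    """
    if mode not in ("available", "strict"):
        raise ValueError("mode must be 'available' or 'strict'")
    geo = table.schema.geometry_names
    if not geo:
        return table.copy()
    vals = table.data[geo].to_numpy(dtype=float)
    obs = ~np.isnan(vals)
    if np.any(vals[obs] <= 0):
        bad = np.argwhere(np.where(obs, vals <= 0, False))
        raise DomainError(
            f"non-positive geometry measurement at row {int(bad[0, 0])}, "
            f"column {geo[int(bad[0, 1])]}: geometric mean undefined"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        logs = np.where(obs, np.log(vals, where=obs, out=np.full_like(vals, np.nan)), np.nan)
    n_obs = obs.sum(axis=1)
    if mode == "strict":
        rows = n_obs == len(geo)
    else:
        rows = n_obs > 0
    gm = np.exp(np.nansum(np.where(rows[:, None], logs, np.nan), axis=1) / np.where(rows, n_obs, 1))
    out = vals.copy()
    out[rows] = vals[rows] / gm[rows, None]
    new = table.copy()
    for j, name in enumerate(geo):
        new.data[name] = out[:, j]
    return new


# ---------------------------------------------------------------------------
# summaries


def summarize(table: FlakeTable) -> pd.DataFrame:
    """Per-variable summary in the style of a recording-protocol table.

    Continuous variables report Min/1st Qu./Median/Mean/3rd Qu./Max and the
    NA count; ordinal and nominal variables report per-level counts and the
    NA count.  Returned long-format with columns
    ``variable, scale, statistic, value``.
    """
    rows: list[dict] = []
    for var in table.schema.variables:
        col = table.data[var.name]
        na = int(col.isna().sum())
        if var.scale == "continuous":
            x = col.dropna().astype(float)
            if len(x):
                stats = {
                    "Min.": float(x.min()),
                    "1st Qu.": float(x.quantile(0.25)),
                    "Median": float(x.median()),
                    "Mean": float(x.mean()),
                    "3rd Qu.": float(x.quantile(0.75)),
                    "Max.": float(x.max()),
                }
            else:
                stats = {k: float("nan") for k in ("Min.", "1st Qu.", "Median", "Mean", "3rd Qu.", "Max.")}
            for k, v in stats.items():
                rows.append({"variable": var.name, "scale": var.scale, "statistic": k, "value": v})
        else:
            counts = col.value_counts(sort=False)
            for lev in var.levels:  # type: ignore[union-attr]
                rows.append(
                    {
                        "variable": var.name,
                        "scale": var.scale,
                        "statistic": f"level {lev}",
                        "value": int(counts.get(lev, 0)),
                    }
                )
        rows.append({"variable": var.name, "scale": var.scale, "statistic": "NA's", "value": na})
    return pd.DataFrame(rows, columns=["variable", "scale", "statistic", "value"])
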