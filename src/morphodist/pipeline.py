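"""End-to-end orchestration: filter -> shape transform -> correlations ->
resemblance -> permutation tests, with sensitivity variants and exports.

Variants re-run the whole analysis under a modified condition:

- ``main``               full filter (20% missingness cap), size-corrected
- ``complete_cases``     missingness cap 0 (complete flakes only)
- ``no_size_correction`` skip the geometric-mean shape transform
- ``exclude_raw_material``  drop the raw-material attribute
- ``dolerite_only``      restrict to dolerite flakes
- ``group_by_raw_material`` group by raw material instead of phase (the
  raw-material attribute is removed from the variable set, since it would be
  perfectly confounded with the grouping)
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .flexdist import AnalysisConfig, DistanceSummary, OrdinationSummary, run_flexdist
from .hetcor import HetCorMatrix, hetero_corr_matrix
from .perm import dist_to_group_centroid, pairwise_tests
from .schema_io import FilterConfig, FlakeTable, Schema, filter_flakes, read_table, summarize, to_shape_variables
from .simulate import SimulationConfig, simulate_assemblage

logger = logging.getLogger(__name__)

VARIANTS = (
    "main",
    "complete_cases",
    "no_size_correction",
    "exclude_raw_material",
    "dolerite_only",
    "group_by_raw_material",
)

RAW_MATERIAL_VAR = "RMA"
DOLERITE_LABEL = "Dolerite"


@dataclass
class RunConfig:
    """Configuration of one orchestrated analysis run."""

    input_path: str | Path | None = None
    sim: SimulationConfig | None = None
    schema: Schema | None = None
    variant: str = "main"
    max_missing_fraction: float = 0.20
    n_iterations: int = 1000
    n_perm: int = 1000
    ci_level: float = 0.95
    seed: int = 1
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.input_path is None and self.sim is None:
            raise ValueError("provide input_path or a simulation config")

    @classmethod
    def fast(cls, **kw) -> "RunConfig":
        """Reduced-iteration profile for smoke tests and CI."""
        kw.setdefault("n_iterations", 50)
        kw.setdefault("n_perm", 199)
        return cls(**kw)


@dataclass
class RunResult:
    """All products of one variant run."""

    config: RunConfig
    table: FlakeTable
    summary: pd.DataFrame
    hetcor: HetCorMatrix
    distances: DistanceSummary
    ordination: OrdinationSummary
    tests: pd.DataFrame
    dispersion: pd.DataFrame
    group_counts: dict[str, int]
    timings: dict[str, float] = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kw):
            try:
                return fn(*args, **kw)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def _load(cfg: RunConfig, schema: Schema) -> FlakeTable:
    if cfg.input_path is not None:
        return read_table(cfg.input_path, schema)
    table, _ = simulate_assemblage(cfg.sim)
    return table


def run_variant(cfg: RunConfig) -> RunResult:
    """Execute one full analysis variant and (optionally) export everything."""
    schema = cfg.schema or (cfg.sim.schema if cfg.sim is not None else Schema.sibhudu())
    timings: dict[str, float] = {}

    def tick(name, fn, *args, **kw):
        t0 = time.perf_counter()
        out = _stage(name)(fn)(*args, **kw)
        timings[name] = round(time.perf_counter() - t0, 3)
        return out

    table = tick("load", _load, cfg, schema)

    max_missing = cfg.max_missing_fraction
    if cfg.variant == "complete_cases":
        max_missing = 0.0
    if cfg.variant == "dolerite_only":
        var = schema[RAW_MATERIAL_VAR]
        lev = var.level_of_label(DOLERITE_LABEL) or var.levels[0]  # type: ignore[index]
        keep = table.data[RAW_MATERIAL_VAR] == lev
        table = table.take(table.data.index[keep])
    if cfg.variant in ("exclude_raw_material", "group_by_raw_material"):
        if cfg.variant == "group_by_raw_material":
            new_group = table.data[RAW_MATERIAL_VAR].astype(str)
            new_group = new_group.where(table.data[RAW_MATERIAL_VAR].notna())
            table = FlakeTable(
                table.data.drop(columns=[RAW_MATERIAL_VAR]),
                new_group.rename(schema.group_column),
                schema.drop(RAW_MATERIAL_VAR),
            )
        else:
            table = FlakeTable(
                table.data.drop(columns=[RAW_MATERIAL_VAR]),
                table.group,
                schema.drop(RAW_MATERIAL_VAR),
            )
        schema = table.schema

    table = tick("filter", filter_flakes, table, FilterConfig(max_missing_fraction=max_missing))
    group_counts = {str(k): int(v) for k, v in table.group.value_counts(sort=False).items()
                    if v > 0}
    if cfg.variant != "no_size_correction":
        table = tick("shape_transform", to_shape_variables, table)
    summary = tick("summarize", summarize, table)
    het = tick("hetcor", hetero_corr_matrix, table, schema)
    acfg = AnalysisConfig(n_iterations=cfg.n_iterations, ci_level=cfg.ci_level, seed=cfg.seed)
    distances, ordination = tick("flexdist", run_flexdist, table, schema, acfg)
    tests = tick(
        "pairwise_tests", pairwise_tests,
        distances.median, table.group.to_numpy(), cfg.n_perm, cfg.seed,
    )
    prof = tick("dispersion", dist_to_group_centroid, distances.median, table.group.to_numpy())
    dispersion = prof.distances.merge(
        prof.group_summary[["group", "median", "lower", "upper"]], on="group",
        suffixes=("", "_group"),
    )

    result = RunResult(
        config=cfg, table=table, summary=summary, hetcor=het,
        distances=distances, ordination=ordination, tests=tests,
        dispersion=dispersion, group_counts=group_counts, timings=timings,
    )
    if cfg.out_dir is not None:
        export_bundle(result, Path(cfg.out_dir))
    return result


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def export_bundle(result: RunResult, out_dir: Path) -> dict:
    """Write all analysis products as CSV/JSON plus a run manifest."""
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    result.table.to_csv(out_dir / "filtered_table.csv")
    result.summary.to_csv(out_dir / "summary.csv", index=False)
    result.hetcor.matrix.to_csv(out_dir / "hetcor_matrix.csv")
    result.hetcor.to_long().to_csv(out_dir / "hetcor_long.csv", index=False)
    result.distances.to_long().to_csv(out_dir / "distances_long.csv", index=False)
    result.ordination.object_centroids.to_csv(out_dir / "object_centroids.csv", index=False)
    result.ordination.object_ellipses.to_csv(out_dir / "object_ellipses.csv", index=False)
    result.ordination.group_centroids.to_csv(out_dir / "group_centroids.csv", index=False)
    result.ordination.group_ellipses.to_csv(out_dir / "group_ellipses.csv", index=False)
    pd.DataFrame(
        {"pc": np.arange(1, len(result.ordination.variance_pct) + 1),
         "variance_pct": result.ordination.variance_pct}
    ).to_csv(out_dir / "eigenvalues.csv", index=False)
    result.ordination.arrows.to_csv(out_dir / "arrows.csv", index=False)
    result.tests.to_csv(out_dir / "tests.csv", index=False)
    result.dispersion.to_csv(out_dir / "dispersion.csv", index=False)

    manifest = {
        "package": "morphodist",
        "version": __version__,
        "python": platform.python_version(),
        "variant": cfg.variant,
        "seed": cfg.seed,
        "n_iterations": cfg.n_iterations,
        "n_perm": cfg.n_perm,
        "ci_level": cfg.ci_level,
        "max_missing_fraction": cfg.max_missing_fraction,
        "input": str(cfg.input_path) if cfg.input_path else "simulated",
        "n_records": result.table.n,
        "group_counts": result.group_counts,
        "timings_s": result.timings,
        "exports": {p.name: _digest(p) for p in sorted(out_dir.glob("*.csv"))},
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
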