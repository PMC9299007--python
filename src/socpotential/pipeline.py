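"""Reproducible end-to-end pipeline: harmonize -> classify -> budget -> upscale.

The pipeline ties the stages together behind one function,
:func:`run_pipeline`, which writes a self-describing output directory
(effects, strata, shares, budgets, potentials, scenarios) plus a run
manifest recording the configuration snapshot, input digests, seed,
software version and per-stage row counts.  Outputs are assembled fully in
memory and written only when every stage has succeeded, so a failing stage
leaves no partial output tree.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import StageError
from .manure_budget import budget_table
from .meta_harmonize import (
    CLIMATES,
    INTERVENTION_MEASURE,
    MEASURES,
    METRICS,
    RECORD_COLUMNS,
    VARIATION_KINDS,
    build_effect_table,
    load_table2_effects,
)
from .strata import (
    CELL_COLUMNS,
    RESIDUE_CLASSES,
    ROTATION_CLASSES,
    TILLAGE_CLASSES,
    classify_cells,
    eligible_area,
    summarize_shares,
)
from .synthetic_data import (
    EffectGeneratorConfig,
    GeneratorConfig,
    ManureGeneratorConfig,
    generate_cells,
    generate_effect_records,
    generate_manure_records,
)
from .upscale import (
    combine_max_complementarity,
    combine_rank_weighted,
    global_potentials,
    load_table3_potentials,
    monte_carlo_potential,
)

logger = logging.getLogger(__name__)

#: CSV float formatting used for byte-identical reruns
FLOAT_FORMAT = "%.6g"

DEFAULT_CONFIG: dict = {
    "generator": {},  # GeneratorConfig overrides
    "effect_generator": {},  # EffectGeneratorConfig overrides
    "manure_generator": {},  # ManureGeneratorConfig overrides
    "upscale": {"n_mc": 1000, "all_bounds": "draws"},
    "inputs": {},  # cells / manure / records / effects CSV paths
}


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML config file over the documented defaults."""
    config = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if section not in config:
                raise StageError("config", f"unknown config section {section!r}")
            config[section].update(values or {})
    return config


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written alongside every pipeline output tree."""

    version: str
    seed: int | None
    config: dict
    input_digests: dict
    row_counts: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _scenario_dict(result) -> dict:
    return {
        "rule": result.rule,
        "total_mton": round(result.total, 6),
        "low_mton": round(result.low, 6),
        "high_mton": round(result.high, 6),
        "ranks": list(result.ranks),
        "weights": {m: round(w, 6) for m, w in result.weights.items()},
    }


def run_pipeline(
    out_dir: str | Path,
    config: dict | str | Path | None = None,
    seed: int | None = 0,
    synthetic: bool = False,
    fixtures: str | None = None,
) -> Path:
    """Execute the full pipeline and write the output directory.

    Parameters
    ----------
    config:
        Dict (or YAML path) with sections generator / effect_generator /
        manure_generator / upscale / inputs; see :data:`DEFAULT_CONFIG`.
    synthetic:
        Generate all inputs with the synthetic-data module instead of
        reading the CSV paths in ``config["inputs"]``.
    fixtures:
        "table2": use the packaged pooled effect table instead of
        harmonizing records; "table3": skip straight to scenario
        combination from the packaged potential table.
    """
    if not isinstance(config, dict) and config is not None:
        config = load_config(config)
    elif config is None:
        config = load_config(None)
    else:
        merged = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
        for k, v in config.items():
            if k not in merged:
                raise StageError("config", f"unknown config section {k!r}")
            merged[k].update(v or {})
        config = merged
    if fixtures not in (None, "table2", "table3"):
        raise StageError("config", f"unknown fixtures option {fixtures!r}")

    outputs: dict[str, str] = {}
    row_counts: dict[str, int] = {}
    digests: dict[str, str] = {}

    def csv(df: pd.DataFrame) -> str:
        return df.to_csv(index=False, float_format=FLOAT_FORMAT)

    if fixtures == "table3":
        potentials = load_table3_potentials()
    else:
        # ---- stage: inputs -------------------------------------------------
        try:
            if synthetic:
                gen = GeneratorConfig(seed=seed or 0, **config["generator"])
                cells = generate_cells(gen)
                manure = generate_manure_records(
                    ManureGeneratorConfig(seed=seed or 0, **config["manure_generator"])
                )
                digests["cells"] = "synthetic"
                digests["manure"] = "synthetic"
            else:
                paths = config["inputs"]
                for key in ("cells", "manure"):
                    if key not in paths:
                        raise StageError("inputs", f"missing input path {key!r}")
                report = validate_inputs(
                    {k: paths[k] for k in ("cells", "manure", "records") if k in paths}
                )
                if report:
                    raise StageError("inputs", f"schema violations: {report[:5]}")
                cells = pd.read_csv(paths["cells"])
                manure = pd.read_csv(paths["manure"])
                digests["cells"] = _digest(paths["cells"])
                digests["manure"] = _digest(paths["manure"])
        except StageError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError("inputs", str(exc)) from exc

        # ---- stage: harmonize ----------------------------------------------
        try:
            if fixtures == "table2":
                effects = load_table2_effects()
                digests["effects"] = "fixture:table2"
            elif synthetic:
                records, truth = generate_effect_records(
                    EffectGeneratorConfig(seed=seed or 0, **config["effect_generator"])
                )
                effects = build_effect_table(records)
                outputs["effect_truth.csv"] = csv(truth)
            else:
                paths = config["inputs"]
                if "effects" in paths:
                    effects = pd.read_csv(paths["effects"])
                    digests["effects"] = _digest(paths["effects"])
                elif "records" in paths:
                    records = pd.read_csv(paths["records"])
                    digests["records"] = _digest(paths["records"])
                    effects = build_effect_table(records)
                else:
                    raise StageError("harmonize", "need inputs.effects or inputs.records")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("harmonize", str(exc)) from exc
        outputs["effects.csv"] = csv(effects)
        row_counts["effects"] = len(effects)

        # ---- stage: classify -----------------------------------------------
        try:
            strata = classify_cells(cells, by=("region_id",))
            shares = summarize_shares(strata)
        except Exception as exc:
            raise StageError("classify", str(exc)) from exc
        outputs["strata.csv"] = csv(strata)
        outputs["shares.json"] = json.dumps(shares, indent=2, sort_keys=True)
        row_counts["cells"] = len(cells)
        row_counts["strata"] = len(strata)

        # ---- stage: budget -------------------------------------------------
        try:
            budgets = budget_table(manure)
        except Exception as exc:
            raise StageError("budget", str(exc)) from exc
        outputs["budgets.csv"] = csv(budgets)
        row_counts["budgets"] = len(budgets)

        # ---- stage: upscale ------------------------------------------------
        try:
            n_mc = int(config["upscale"].get("n_mc", 1000))
            all_bounds = config["upscale"].get("all_bounds", "draws")
            ss = np.random.SeedSequence(seed or 0)
            streams = {m: np.random.default_rng(s) for m, s in
                       zip([*MEASURES, "M2cor"], ss.spawn(len(MEASURES) + 1))}
            tables = []
            m2_area = None
            for m in MEASURES:
                area = eligible_area(strata, m, by=("region_id", "climate"))
                if m == "M2":
                    m2_area = area
                if area.empty:
                    zone_rows = [(m, c, 0.0, 0.0, 0.0) for c in [*CLIMATES, "all"]]
                    tables.append(
                        pd.DataFrame(
                            zone_rows,
                            columns=["measure", "climate", "mean_mton", "q01_mton", "q99_mton"],
                        )
                    )
                    continue
                tables.append(
                    monte_carlo_potential(
                        area, effects, n_mc=n_mc, seed=streams[m],
                        all_bounds=all_bounds, measure=m,
                    )
                )
            tables.append(
                monte_carlo_potential(
                    m2_area, effects, n_mc=n_mc, seed=streams["M2cor"],
                    cap_budget=budgets, all_bounds=all_bounds, measure="M2cor",
                )
            )
            potentials = pd.concat(tables, ignore_index=True)
        except Exception as exc:
            raise StageError("upscale", str(exc)) from exc

    outputs["potentials.csv"] = csv(potentials)
    row_counts["potentials"] = len(potentials)

    # ---- stage: scenarios ----------------------------------------------
    try:
        gp = global_potentials(potentials)
        scenarios = {
            "max_complementarity": _scenario_dict(combine_max_complementarity(gp)),
            "rank_weighted": _scenario_dict(combine_rank_weighted(gp)),
        }
    except Exception as exc:
        raise StageError("scenarios", str(exc)) from exc
    outputs["scenarios.json"] = json.dumps(scenarios, indent=2, sort_keys=True)

    manifest = RunManifest(
        version=__version__,
        seed=seed,
        config={k: dict(v) for k, v in config.items()},
        input_digests=digests,
        row_counts=row_counts,
    )
    outputs["manifest.json"] = manifest.to_json()

    # all stages succeeded: write the tree in one pass
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, content in outputs.items():
        (out / name).write_text(content)
    logger.info("pipeline wrote %d files to %s", len(outputs), out)
    return out


# --------------------------------------------------------------------------
# input validation


def _check(violations, file, row, column, ok, message):
    if not ok:
        violations.append(
            {"file": str(file), "row": None if row is None else int(row),
             "column": column, "message": message}
        )


def _validate_enum(violations, path, df, column, allowed, allow_na=False):
    for idx, val in df[column].items():
        if pd.isna(val):
            if not allow_na:
                _check(violations, path, idx, column, False, "missing value")
            continue
        _check(
            violations, path, idx, column, val in allowed,
            f"invalid value {val!r}; allowed: {sorted(allowed)}",
        )


def _validate_cells(violations, path, df):
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        _check(violations, path, None, ",".join(missing), False, "missing required columns")
        return
    _validate_enum(violations, path, df, "climate", set(CLIMATES))
    _validate_enum(violations, path, df, "tillage", set(TILLAGE_CLASSES))
    _validate_enum(violations, path, df, "rotation", set(ROTATION_CLASSES))
    _validate_enum(violations, path, df, "residue_fate", set(RESIDUE_CLASSES))
    for col in ("area_ha", "n_fert_rate", "n_manure_rate"):
        vals = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[vals.isna()]:
            _check(violations, path, idx, col, False, "not a number")
        for idx in df.index[vals < 0]:
            _check(violations, path, idx, col, False, "negative value")


def _validate_manure(violations, path, df):
    cols = ["region_id", "n_excreted", "n_applied_cropland", "n_applied_grassland"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        _check(violations, path, None, ",".join(missing), False, "missing required columns")
        return
    for col in cols[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[vals.isna()]:
            _check(violations, path, idx, col, False, "not a number")
        for idx in df.index[vals < 0]:
            _check(violations, path, idx, col, False, "negative value")


def _validate_records(violations, path, df):
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        _check(violations, path, None, ",".join(missing), False, "missing required columns")
        return
    _validate_enum(violations, path, df, "intervention", set(INTERVENTION_MEASURE))
    _validate_enum(violations, path, df, "climate", set(CLIMATES))
    _validate_enum(violations, path, df, "metric", set(METRICS))
    _validate_enum(violations, path, df, "variation_kind", set(VARIATION_KINDS), allow_na=True)
    depth = pd.to_numeric(df["depth_m"], errors="coerce")
    for idx in df.index[~(depth > 0)]:
        _check(violations, path, idx, "depth_m", False, "must be positive")
    dur = pd.to_numeric(df["duration_yr"], errors="coerce")
    is_total = df["metric"].isin(["stock_total", "conc_total"])
    for idx in df.index[is_total & ~(dur > 0)]:
        _check(violations, path, idx, "duration_yr", False, "must be positive for total metrics")


def validate_inputs(paths: dict[str, str | Path]) -> list[dict]:
    """Column-level schema checks for the pipeline's CSV inputs.

    ``paths`` maps the input kind ("cells", "manure", "records") to a CSV
    path.  Violations are collected — not fail-fast — and returned as a
    list of dicts with file, row, column and message; an empty list means
    the inputs are valid.
    """
    validators = {"cells": _validate_cells, "manure": _validate_manure, "records": _validate_records}
    violations: list[dict] = []
    for kind, path in paths.items():
        if kind not in validators:
            raise ValueError(f"unknown input kind {kind!r}; expected {sorted(validators)}")
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            _check(violations, path, None, None, False, f"unreadable CSV: {exc}")
            continue
        validators[kind](violations, path, df)
    return violations
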