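"""End-to-end orchestration: ingest → aggregate → code → fit → optimize →
network search → sensitivity → comparison, as one seeded, reproducible run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ann, compare, datamodel, desirability, rsm
from .datamodel import RESPONSE_COLUMNS

__all__ = ["RunConfig", "run_pipeline", "load_config"]

#: Responses where smaller is better (IC50: stronger antioxidant capacity).
MINIMIZE_RESPONSES = ("abts_ic50", "dpph_ic50")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    Input paths default to the packaged study tables.  ANN settings
    default to the study's: a 70/15/15 split, 20 candidate networks with
    3-5 hidden neurons, 5 retained; all desirability weights are 1.
    """

    output_dir: str = "strawpoly_run"
    seed: int = 0
    guariba_table: str | None = None
    valparaiso_table: str | None = None
    class_table: str | None = None
    antioxidant_table: str | None = None
    responses_table: str | None = None  # pre-aggregated alternative to the four tables
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    n_candidates: int = 20
    n_retain: int = 5
    hidden_sizes: tuple[int, ...] = (3, 4, 5)
    hidden_activations: tuple[str, ...] = ("tanh", "logistic", "exponential", "identity")
    max_iter: int = 500
    tol: float = 1e-6
    grid_infection_step: float = 0.5
    desirability_weights: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        d["hidden_sizes"] = list(self.hidden_sizes)
        d["hidden_activations"] = list(self.hidden_activations)
        return d


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("split_fractions", "hidden_sizes", "hidden_activations"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("ingest")
def _ingest(config: RunConfig):
    conditions, ic50 = datamodel.load_conditions(config.antioxidant_table)
    if config.responses_table is not None:
        table = datamodel.read_responses_tidy(config.responses_table)
        table = table.loc[[c.sample_id for c in conditions]]
        return conditions, table
    class_map = datamodel.load_class_map(config.class_table)
    measurements = []
    for path in (
        config.guariba_table or datamodel.fixture_path("table2_guariba.csv"),
        config.valparaiso_table or datamodel.fixture_path("table3_valparaiso.csv"),
    ):
        measurements.extend(datamodel.load_compound_table(path, class_map))
    table = datamodel.aggregate_classes(measurements, class_map, ic50=ic50)
    table = table.loc[[c.sample_id for c in conditions]]
    return conditions, table


@_stage("fit-rsm")
def _fit_rsm(conditions, table, coding):
    coded = coding.code_all(conditions)
    models = {}
    for resp in RESPONSE_COLUMNS:
        y = table[resp].to_numpy(dtype=float)
        ok = np.isfinite(y)
        X = rsm.build_design_matrix(coded[ok])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models[resp] = rsm.fit_polynomial(X, y[ok], response=resp)
    return coded, models


@_stage("optimize")
def _optimize(config: RunConfig, conditions, table, coding, models):
    specs = {}
    for resp in RESPONSE_COLUMNS:
        vals = table[resp].dropna()
        w = float(config.desirability_weights.get(resp, 1.0))
        direction = "minimize" if resp in MINIMIZE_RESPONSES else "maximize"
        specs[resp] = desirability.DesirabilitySpec(
            y_min=float(vals.min()), y_max=float(vals.max()),
            weight=w, direction=direction,
        )
    coded = coding.code_all(conditions)
    grid = [sorted(set(np.round(coded[:, j], 12))) for j in range(5)]
    lo, hi = coding.infection_range
    if hi > lo:
        levels = np.arange(lo, hi + 1e-9, config.grid_infection_step)
        grid[3] = sorted(set(np.round(2 * (levels - lo) / (hi - lo) - 1, 12)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return desirability.optimize(models, specs, grid)


@_stage("train-ann")
def _train_ann(config: RunConfig, conditions, table):
    features, column_map = ann.expand_inputs(conditions)
    # class responses are complete; IC50 gaps are median-filled for the
    # multi-output network (the comparison masks them back out)
    Y = table[list(RESPONSE_COLUMNS)].copy()
    Y = Y.fillna(Y.median())
    split = ann.split_data(len(conditions), config.split_fractions, seed=config.seed)
    candidates = ann.default_candidates(
        n_inputs=features.shape[1], n_outputs=Y.shape[1],
        n_candidates=config.n_candidates, hidden_sizes=config.hidden_sizes,
        hidden_activations=config.hidden_activations,
    )
    retained = ann.model_search(
        candidates, features, Y.to_numpy(), split, seed=config.seed,
        n_retain=config.n_retain, max_iter=config.max_iter, tol=config.tol,
    )
    return features, column_map, split, retained


@_stage("sensitivity")
def _sensitivity(retained, column_map):
    best = retained[0][0]
    cols = {}
    for j, resp in enumerate(RESPONSE_COLUMNS):
        cols[resp] = ann.garson_importance(best, column_map, output=j)
    return pd.DataFrame(cols)


@_stage("compare")
def _compare(models, retained, coded, features, table, split):
    networks = [
        (f"{m.architecture.name} #{k + 1}", m) for k, (m, _s) in enumerate(retained)
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return compare.build_report(
            models, networks, coded, features, table[list(RESPONSE_COLUMNS)], split
        )


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all artifacts; returns the manifest.

    The manifest records the config, seeds, package versions and a sha256
    per artifact, so byte-identical reruns are verifiable.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    conditions, table = _ingest(config)
    datamodel.write_responses_tidy(table, out / "responses.csv")

    (out / "condition_schema.json").write_text(
        json.dumps(datamodel.condition_schema(), indent=1, sort_keys=True)
    )

    coding = rsm.FactorCoding.from_conditions(conditions)
    coded, models = _fit_rsm(conditions, table, coding)
    for resp, model in models.items():
        model.to_json(out / f"rsm_{resp}.json")
        # surface over the two strongest linear effects, other factors at 0
        i, j = sorted(np.argsort(-np.abs(model.beta[1:6]))[:2])
        grid = rsm.surface_grid(model, (int(i), int(j)), resolution=25)
        grid.to_csv(out / f"surface_{resp}.csv", index=False, float_format="%.12g")

    result = _optimize(config, conditions, table, coding, models)
    (out / "optimum.json").write_text(json.dumps(result.to_dict(), indent=1, sort_keys=True))
    opt_rows = [
        {"response": r, "predicted": result.predictions[r],
         "ci_low": None if result.intervals[r] is None else result.intervals[r][0],
         "ci_high": None if result.intervals[r] is None else result.intervals[r][1],
         "desirability": result.per_response_d[r],
         "composite_desirability": result.composite_d}
        for r in sorted(result.predictions)
    ]
    pd.DataFrame(opt_rows).to_csv(out / "optimum.csv", index=False, float_format="%.12g")

    features, column_map, split, retained = _train_ann(config, conditions, table)
    for k, (model, score) in enumerate(retained):
        model.to_json(out / f"mlp_{k + 1}.json")

    sens = _sensitivity(retained, column_map)
    sens.to_csv(out / "sensitivity.csv", float_format="%.12g")

    report = _compare(models, retained, coded, features, table, split)
    report.to_csv(out / "comparison.csv", index=False, float_format="%.12g")

    from . import __version__ as _pkg_version

    artifacts = sorted(p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "strawpoly_version": _pkg_version,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "n_samples": len(conditions),
        "responses": list(RESPONSE_COLUMNS),
        "retained_networks": [
            {"name": m.architecture.name, "validation_r": s, "seed": m.seed}
            for m, s in retained
        ],
        "optimum": result.to_dict(),
        "artifacts": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
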