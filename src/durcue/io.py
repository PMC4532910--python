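"""Trial-table readers/writers, run configuration, and the pipeline driver.

Durations are stored in milliseconds in files and converted to natural-log
space at a single boundary inside the library, so the CSVs stay
human-readable.  Responses are the strings ``second_longer`` /
``second_shorter``; numeric ``1``/``0`` are accepted as aliases on read and
an empty field means no response (schedule-only files).
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison, observer, psychometric, schedules
from .schedules import (COMPARISON_DURATIONS_MS, REFERENCE_MS, Schedule,
                        TRIAL_COLUMNS)

_RESPONSE_ALIASES = {
    "second_longer": "second_longer", "second_shorter": "second_shorter",
    "1": "second_longer", "0": "second_shorter",
    "1.0": "second_longer", "0.0": "second_shorter",
}


def write_trials(schedule, path) -> None:
    """Write a schedule or trial DataFrame to CSV (schema of TRIAL_COLUMNS)."""
    frame = schedule.trials if isinstance(schedule, Schedule) else schedule
    out = frame[TRIAL_COLUMNS].copy()
    out.to_csv(path, index=False)


def read_trials(path, strict: bool = False) -> Schedule:
    """Read a trial CSV into a :class:`Schedule`.

    In strict mode, rows whose comparison duration is off the 26-level grid
    or whose reference is not 600 ms are rejected with their row numbers.
    """
    frame = pd.read_csv(path, dtype={"response": "string"})
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    resp = frame["response"].str.strip()
    bad = resp.notna() & ~resp.isin(_RESPONSE_ALIASES)
    if bad.any():
        raise ValueError(f"{path}: unrecognised responses in rows "
                         f"{frame.index[bad].tolist()}")
    frame["response"] = resp.map(_RESPONSE_ALIASES).astype(object)
    frame["response"] = frame["response"].where(frame["response"].notna(), None)
    if strict:
        grid = set(float(d) for d in COMPARISON_DURATIONS_MS)
        off = ~frame["comp_duration_ms"].astype(float).isin(grid)
        off |= frame["ref_duration_ms"].astype(float) != float(REFERENCE_MS)
        if off.any():
            raise ValueError(
                f"{path}: rows off the duration grid: "
                f"{frame.index[off].tolist()}")
    exp = str(frame["experiment_id"].iloc[0]) if len(frame) else "unknown"
    return Schedule(frame, exp, seed=None)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run; round-trips losslessly
    through YAML/JSON."""

    experiment_id: str
    schedule_seed: int
    observer_seed: int
    generating_model: dict
    generating_params: dict
    models: str | list = "all"
    folds: int = 12
    restarts: int = 10
    fold_restarts: int | None = None
    maxiter: int = 100
    fold_maxiter: int | None = None
    quad_order: int = 7
    out_dir: str = "results/run"

    def __post_init__(self):
        for name in ("schedule_seed", "observer_seed"):
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"config is missing required seed {name!r}")
            setattr(self, name, int(v))
        if self.experiment_id not in schedules.BUILDERS:
            raise ValueError(f"unknown experiment_id {self.experiment_id!r}")

    def model_specs(self) -> list[observer.ModelSpec]:
        if self.models == "all":
            return comparison.enumerate_models()
        return [observer.ModelSpec(**m) for m in self.models]

    def generating(self):
        model = observer.ModelSpec(**self.generating_model)
        params = observer.ObserverParams(**self.generating_params)
        return model, params

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text))
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> fit psychometric -> cross-validate models -> compare.

    Writes the simulated trials, per-model CV results, a comparison table and
    a manifest (versions, seeds, timings) under ``config.out_dir``; any stage
    failure is recorded in the manifest as partial completion.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    bundle: dict = {"manifest": manifest}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # record partial completion
            manifest["stages"][name] = {"status": "failed", "error": str(exc),
                                        "seconds": time.perf_counter() - t0}
            _write_manifest(out, manifest)
            raise
        manifest["stages"][name] = {"status": "ok",
                                    "seconds": round(time.perf_counter() - t0, 3)}
        return result

    def simulate():
        sched = schedules.BUILDERS[config.experiment_id](config.schedule_seed)
        model, params = config.generating()
        responded = schedules.simulate_responses(sched, model, params,
                                                 config.observer_seed)
        write_trials(responded, out / "trials.csv")
        return responded

    responded = stage("simulate", simulate)

    def psycho():
        fit = psychometric.fit_psychometric(responded.trials,
                                            seed=config.observer_seed)
        (out / "psychometric.json").write_text(
            json.dumps(fit.to_dict(), indent=2))
        return fit

    bundle["psychometric"] = stage("fit_psychometric", psycho)

    def cv():
        support = observer.PriorSupport.from_schedule(responded)
        folds = comparison.make_folds(responded.trials, config.folds,
                                      config.schedule_seed)
        results = []
        for spec in config.model_specs():
            res = comparison.cross_validate(
                responded.trials, spec, support, n_folds=config.folds,
                seed=config.observer_seed, restarts=config.restarts,
                fold_restarts=config.fold_restarts, maxiter=config.maxiter,
                fold_maxiter=config.fold_maxiter,
                quad_order=config.quad_order, folds=folds)
            results.append(res)
        payload = [{"model": r.model.name,
                    "fold_loglik": [float(v) for v in r.fold_loglik],
                    "total_cvll": r.total_cvll} for r in results]
        (out / "cv_results.json").write_text(json.dumps(payload, indent=2))
        return results

    bundle["cv_results"] = stage("cross_validate", cv)

    def compare():
        table = comparison.compare_models(bundle["cv_results"])
        table.to_csv(out / "comparison.csv", index=False)
        return table

    bundle["comparison"] = stage("compare", compare)
    _write_manifest(out, manifest)
    return bundle


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
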