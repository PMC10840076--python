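"""End-to-end study pipeline.

Generates (or ingests) a cohort, splits it 80/20 stratified by sex, derives
the sex-specific height exponent on the training partition via the
height-independency criterion, and evaluates the new against the
conventional formula on the held-out partition: screening accuracy for
excess body fat, category reclassification, and all-cause-mortality Cox
model comparison.  Everything downstream of the split treats
training-derived quantities (exponent, cutoffs, category thresholds) as
frozen inputs, so there is no test-set leakage by construction.

One top-level seed deterministically spawns per-stage seeds; two runs with
identical config produce byte-identical report bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anthropometry import DEFAULT_SCHEME, derive_measures
from .cohort import (GeneratorParams, generate_cohort, generate_mortality,
                     read_cohort, split_train_test, write_cohort)
from .power_scan import (BennExponentSelector, PowerGrid,
                         criterion_table_to_frame, build_criterion_table)
from .screening import build_screening_table, screening_table_to_frame
from .survival import compare_formulas_survival

__all__ = ["RunConfig", "run_full_analysis", "write_report", "read_cohort",
           "write_cohort"]

log = logging.getLogger("bennscale")


@dataclass
class RunConfig:
    """Configuration of a full synthetic or file-based run."""

    mode: str = "synthetic"              # "synthetic" | "file"
    cohort_path: str | None = None       # required for mode="file"
    params_path: str | None = None       # optional generator params YAML
    n_per_sex: int = 20_000
    seed: int = 1
    test_fraction: float = 0.2
    grid_min: float = -5.0
    grid_max: float = 5.0
    grid_step: float = 0.01
    criterion: str = "height"
    out_dir: str | None = None

    def grid(self) -> PowerGrid:
        return PowerGrid(self.grid_min, self.grid_max, self.grid_step)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage %s: done in %.1fs", name, dt)
            else:
                log.error("stage %s: FAILED after %.1fs: %s", name, dt, exc)
            return False
    return _Timer()


def _spawn_seeds(seed: int, k: int) -> list[int]:
    """Deterministic per-stage integer seeds below 2^31 from one top seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(k) % (2**31)]


def _assemble_cohort(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    if config.mode == "file":
        if not config.cohort_path:
            raise ValueError("mode='file' requires cohort_path")
        cohort = read_cohort(config.cohort_path)
        return cohort, {"source": str(config.cohort_path)}
    seeds = _spawn_seeds(config.seed, 3)
    parts, prov = [], {}
    for sex, s in zip(("F", "M"), seeds[:2]):
        params = GeneratorParams.defaults_for(sex, n=config.n_per_sex, seed=s)
        part = generate_mortality(generate_cohort(params), params)
        parts.append(part)
        prov[sex] = {"seed": s, "p_true": params.p_true, "n": params.n}
    cohort = pd.concat(parts, ignore_index=True)
    return cohort, prov


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole study flow; returns the report bundle (JSON-ready dict)."""
    seeds = _spawn_seeds(config.seed, 4)
    grid = config.grid()
    with _stage("cohort"):
        cohort, provenance = _assemble_cohort(config)
        log.info("cohort: %d records (%s)", len(cohort),
                 dict(cohort["sex"].value_counts()))
    with _stage("split"):
        train, test = split_train_test(cohort, config.test_fraction, seeds[3])

    bundle: dict = {
        "manifest": {
            "package": "bennscale",
            "version": __version__,
            "seed": config.seed,
            "stage_seeds": seeds,
            "grid": {"p_min": grid.p_min, "p_max": grid.p_max,
                     "step": grid.step},
            "criterion": config.criterion,
            "test_fraction": config.test_fraction,
            "provenance": provenance,
            "n_train": len(train),
            "n_test": len(test),
        }
    }
    for sex in ("F", "M"):
        tr = derive_measures(train[train["sex"] == sex].reset_index(drop=True))
        te = derive_measures(test[test["sex"] == sex].reset_index(drop=True))
        if len(tr) == 0:
            continue
        section: dict = {"n_train": len(tr), "n_test": len(te)}
        with _stage(f"criterion_table[{sex}]"):
            table = build_criterion_table(tr, grid)
            section["criterion_table"] = [
                {"criterion": row.criterion, "power": row.power,
                 "correlations": row.correlations}
                for row in table]
        with _stage(f"select[{sex}]"):
            selector = BennExponentSelector(criterion=config.criterion,
                                            grid=grid).fit(tr)
            section["new_formula"] = {
                "name": f"BMI_new_{sex}", "power": selector.power_,
                "r_at_optimum": selector.optimum_.r_at_optimum,
                "sign_change_bracketed": selector.optimum_.sign_change_bracketed,
            }
        formulas = {"BMI_old": 2.0, f"BMI_new_{sex}": selector.power_}
        with _stage(f"screening[{sex}]"):
            results, reclass = build_screening_table(tr, te, formulas,
                                                     DEFAULT_SCHEME)
            section["screening"] = [vars(r) for r in results]
            section["reclassification"] = vars(reclass) if reclass else None
        with _stage(f"survival[{sex}]"):
            fits, delta_aic = compare_formulas_survival(te, formulas)
            section["survival"] = {
                "fits": [
                    {"formula": f.formula, "aic": f.aic,
                     "log_partial_likelihood": f.log_partial_likelihood,
                     "n": f.n, "events": f.events,
                     "hr_by_fifth": {str(k): list(v)
                                     for k, v in f.hr_by_fifth.items()},
                     "coef": f.coef, "se": f.se}
                    for f in fits],
                "delta_aic_new_minus_old": delta_aic,
            }
        bundle[sex] = section
    if config.out_dir:
        write_report(bundle, config.out_dir)
    return bundle


def write_report(bundle: dict, out_dir) -> None:
    """Write the JSON contract plus human-readable delimited-text tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for sex in ("F", "M"):
        if sex not in bundle:
            continue
        section = bundle[sex]
        pd.DataFrame([
            {"criterion": r["criterion"], "power": r["power"],
             **{f"r_{m}": v for m, v in r["correlations"].items()}}
            for r in section["criterion_table"]
        ]).to_csv(out / f"criterion_table_{sex}.csv", index=False)
        pd.DataFrame(section["screening"]).to_csv(
            out / f"screening_table_{sex}.csv", index=False)
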