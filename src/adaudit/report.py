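"""End-to-end pipeline orchestration and report bundle.

Stage order follows the audit workflow: coding (load or simulate), GPS
imputation, boundary exclusion, nutrition scoring, policy classification,
statistics. Every run emits a manifest recording seeds, a config hash and
row counts at each stage, so bundles are reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import compliance as comp
from . import geo, model, npm, stats
from .synth import GeneratorConfig, generate_audit

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "simulate_command"]


class RunConfig(BaseModel):
    """Pipeline configuration: either audit-table paths or a generator."""

    input_dir: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    manual_coordinates: dict[str, tuple[float, float]] = Field(default_factory=dict)
    buffers_m: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0)
    analysis_buffer_m: float = 0.0
    fibre_basis: str = "AOAC"
    seed: int = 0
    out_dir: str = "adaudit_out"

    @model_validator(mode="after")
    def _one_source(self) -> "RunConfig":
        if (self.input_dir is None) == (self.generator is None):
            raise ValueError("supply exactly one of input_dir or generator config")
        return self

    def config_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json(exclude={"out_dir"}).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    dataset: model.AuditDataset
    filtered: model.AuditDataset
    outcomes: dict
    npm_frame: pd.DataFrame
    verdicts: dict
    tables: dict[str, pd.DataFrame]
    tests: dict[str, stats.ChiSqResult]
    sensitivity: dict[float, dict[str, pd.DataFrame]]
    manifest: dict = field(default_factory=dict)


def _stage_counts(ds: model.AuditDataset) -> dict[str, int]:
    return model.count_hierarchy(ds) | {
        "n_images": len(ds.images),
        "n_neighbourhoods": len(ds.neighbourhoods),
    }


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Run coding -> GPS -> exclusion -> NPM -> compliance -> statistics."""
    manifest: dict = {"seed": config.seed, "config_hash": config.config_hash(), "stages": {}}

    # stage 1: dataset
    if config.generator is not None:
        ds = generate_audit(config.generator)
        manifest["source"] = "generator"
    else:
        ds = model.load_audit(config.input_dir)
        manifest["source"] = config.input_dir
    manifest["stages"]["coding"] = _stage_counts(ds)

    # stage 2: coordinate imputation
    imputed = geo.impute_coordinates(ds.images.values(), config.manual_coordinates)
    ds = ds.model_copy(update={"images": {i.image_id: i for i in imputed}})
    unresolved = [i.image_id for i in imputed if i.lon is None]
    manifest["stages"]["gps"] = {
        "n_images": len(imputed),
        "n_unresolved": len(unresolved),
    }

    # stage 3: boundary exclusion
    policy = geo.BufferPolicy(buffers_m=tuple(sorted(set(config.buffers_m) | {0.0})))
    polys = {a: nb.geometry for a, nb in ds.neighbourhoods.items()}
    located = [a for a in ds.assets.values() if a.lon is not None]
    outcomes = geo.filter_within_boundary(located, polys, policy)
    filtered = geo.apply_filter(ds, outcomes, config.analysis_buffer_m)
    manifest["stages"]["geo"] = {
        "records_in": len(ds.assets),
        "records_retained": len(filtered.assets),
        "records_excluded": len(ds.assets) - len(filtered.assets),
        "analysis_buffer_m": config.analysis_buffer_m,
    }

    # stage 4: NPM scoring
    npm_frame = npm.score_products_frame(filtered.products.values())
    n_assessable = int(npm_frame["assessable"].sum()) if len(npm_frame) else 0
    manifest["stages"]["npm"] = {
        "n_products": len(npm_frame),
        "n_assessable": n_assessable,
        "n_hfss": int(npm_frame.loc[npm_frame["assessable"], "is_hfss"].sum())
        if n_assessable
        else 0,
    }

    # stage 5: compliance classification
    verdicts = comp.classify_dataset(filtered, npm_frame)
    manifest["stages"]["compliance"] = {
        "n_food_drink_adverts": len(verdicts),
        "n_non_compliant": sum(
            1 for v in verdicts.values() if v.status == comp.STATUS_NON_COMPLIANT
        ),
    }

    # stage 6: statistics and sensitivity
    tables = stats.exposure_tables(filtered, verdicts)
    tests = stats.run_exposure_tests(filtered, verdicts)
    sensitivity = geo.buffer_sensitivity(ds, policy, verdicts=None)
    manifest["stages"]["stats"] = {
        name: {
            "statistic": round(t.statistic, 6) if t.statistic == t.statistic else None,
            "df": t.df,
            "p_value": round(t.p_value, 6) if t.p_value == t.p_value else None,
            "valid": t.valid,
        }
        for name, t in tests.items()
    }

    result = PipelineResult(
        dataset=ds, filtered=filtered, outcomes=outcomes, npm_frame=npm_frame,
        verdicts=verdicts, tables=tables, tests=tests, sensitivity=sensitivity,
        manifest=manifest,
    )
    if write:
        _write_bundle(result, config)
    return result


def _write_bundle(res: PipelineResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model.write_audit(res.dataset, out / "dataset")
    geo.outcomes_to_frame(res.outcomes).to_csv(out / "filter_outcomes.csv", index=False)
    res.npm_frame.to_csv(out / "products_npm.csv", index=False)
    comp.verdicts_to_frame(res.verdicts).to_csv(out / "advert_verdicts.csv", index=False)
    for name, tbl in res.tables.items():
        tbl.to_csv(out / f"table_{name}.csv")
    test_rows = [
        {
            "test": name,
            "statistic": t.statistic,
            "df": t.df,
            "p_value": t.p_value,
            "valid": t.valid,
            "significant_at_95": t.significant_at_95,
        }
        for name, t in res.tests.items()
    ]
    pd.DataFrame(test_rows).to_csv(out / "chisq_results.csv", index=False)
    sens_rows = []
    for b, tabs in res.sensitivity.items():
        row = {"buffer_m": b, "n_assets": int(tabs["assets_by_quintile"]["n_assets"].sum())}
        for q in stats.QUINTILES:
            row[f"assets_q{q}"] = int(tabs["assets_by_quintile"].loc[q, "n_assets"])
        sens_rows.append(row)
    pd.DataFrame(sens_rows).to_csv(out / "buffer_sensitivity.csv", index=False)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(res.manifest, fh, indent=2, sort_keys=True)


def simulate_command(generator: GeneratorConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a synthetic audit and write its CSV/GeoJSON tables."""
    ds = generate_audit(generator)
    return model.write_audit(ds, out_dir)
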