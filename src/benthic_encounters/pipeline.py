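"""Pipeline orchestration: generate -> fit -> meta -> simulate.

Each stage reads and writes schema-validated CSV artifacts, and every
output is recorded in a JSON manifest with its row count, content hash,
input hashes and the seed that produced it, so a re-run with unchanged
inputs and seed can be recognised (and skipped) by hash comparison.
All randomness flows from one master seed through named substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abm, functional_response as fr, meta_analysis as ma
from .allometry import default_strategy_scalings
from .synthetic_data import GeneratorConfig, generate_meta_dataset
from .trials import TRIALS_COLUMNS, frame_to_trials, trials_to_frame

__all__ = ["PipelineConfig", "run_pipeline", "validate_table", "SCHEMAS"]

log = logging.getLogger("benthic_encounters.pipeline")

STAGES = ("generate", "fit", "meta", "simulate")


# ---------------------------------------------------------------------------
# Schema validation
# ---------------------------------------------------------------------------

#: Per-column (kind, min, max) checks; kind "num"/"int"/"str"/"bool".
SCHEMAS: dict[str, dict] = {
    "trials": {
        "columns": {
            "pair_id": ("str", None, None), "N0": ("int", 0, None),
            "eaten": ("int", 0, None), "T": ("num", 0, None),
            "arena": ("num", 0, None), "arena_dim": ("int", 2, 3),
            "consumer_mass_g": ("num", 0, None),
            "resource_mass_g": ("num", 0, None),
            "temp_C": ("num", -5, 50), "strategy": ("str", None, None),
            "taxon_group": ("str", None, None),
        },
        "rules": [("eaten_le_N0", lambda df: df["eaten"] <= df["N0"]),
                  ("positive_mass",
                   lambda df: (df["consumer_mass_g"] > 0)
                   & (df["resource_mass_g"] > 0))],
    },
    "truth": {
        "columns": {
            "pair_id": ("str", None, None), "strategy": ("str", None, None),
            "taxon_group": ("str", None, None),
            "consumer_mass_g": ("num", 0, None),
            "resource_mass_g": ("num", 0, None), "temp_C": ("num", -5, 50),
            "b": ("num", 0, None), "h": ("num", 0, None),
            "q": ("num", 0, None),
        },
        "rules": [],
    },
    "fitted": {
        "columns": {
            "pair_id": ("str", None, None), "variant": ("str", None, None),
            "b": ("num", 0, None), "h": ("num", 0, None),
            "q": ("num", 0, None), "loglik": ("num", None, None),
            "AICc": ("num", None, None),
        },
        "rules": [],
    },
    "meta": {
        "columns": {
            "pair_id": ("str", None, None),
            "log_consumer_mass": ("num", None, None),
            "log_resource_mass": ("num", None, None),
            "log_temperature": ("num", None, None),
            "strategy": ("str", None, None),
            "taxon_group": ("str", None, None),
        },
        "rules": [],
    },
    "encounters": {
        "columns": {
            "strategy": ("str", None, None),
            "consumer_mass_g": ("num", 0, None),
            "replicate": ("int", 0, None),
            "unitary_rate": ("num", 0, None),
            "biomass_rate": ("num", 0, None),
        },
        "rules": [],
    },
    "quantiles": {
        "columns": {
            "strategy": ("str", None, None),
            "consumer_mass_g": ("num", 0, None),
            "unitary_median": ("num", 0, None),
            "unitary_q025": ("num", 0, None),
            "unitary_q975": ("num", 0, None),
            "biomass_median": ("num", 0, None),
            "biomass_q025": ("num", 0, None),
            "biomass_q975": ("num", 0, None),
        },
        "rules": [("quantile_order",
                   lambda df: (df["unitary_q025"] <= df["unitary_q975"])
                   & (df["biomass_q025"] <= df["biomass_q975"]))],
    },
}


def validate_table(path, schema_name: str) -> list[dict]:
    """Validate a CSV artifact against a registered schema.

    Returns a list of violations, each ``{"rule": id, "column": name,
    "rows": [...]}``; an empty list means the table is valid.
    """
    if schema_name not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_name!r}; "
                       f"registered: {sorted(SCHEMAS)}")
    schema = SCHEMAS[schema_name]
    df = pd.read_csv(path)
    violations: list[dict] = []
    for col, (kind, lo, hi) in schema["columns"].items():
        if col not in df.columns:
            violations.append({"rule": "missing_column", "column": col,
                               "rows": []})
            continue
        series = df[col]
        if kind in ("num", "int"):
            vals = pd.to_numeric(series, errors="coerce")
            bad = vals.isna() & series.notna()
            if bad.any():
                violations.append({"rule": "non_numeric", "column": col,
                                   "rows": df.index[bad].tolist()})
            if lo is not None:
                neg = vals < lo
                if neg.any():
                    violations.append({"rule": f"below_min_{lo}",
                                       "column": col,
                                       "rows": df.index[neg.fillna(False)].tolist()})
            if hi is not None:
                over = vals > hi
                if over.any():
                    violations.append({"rule": f"above_max_{hi}",
                                       "column": col,
                                       "rows": df.index[over.fillna(False)].tolist()})
    for rule_id, predicate in schema["rules"]:
        try:
            ok = predicate(df)
        except KeyError:
            continue
        bad_rows = df.index[~ok.fillna(False)].tolist()
        if bad_rows:
            violations.append({"rule": rule_id, "column": None,
                               "rows": bad_rows})
    return violations


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Stage toggles, output directory, master seed and stage parameters."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    generate: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "stages" in payload:
            payload["stages"] = tuple(payload["stages"])
        return cls(**payload)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _record(manifest: list, stage: str, path: Path, seed: int,
            inputs: list[Path]) -> None:
    df_rows = sum(1 for _ in open(path)) - 1
    manifest.append({
        "stage": stage, "path": str(path), "rows": df_rows,
        "sha256": _sha256(path), "seed": seed,
        "input_hashes": {str(p): _sha256(p) for p in inputs},
    })


def _stage_seed(master: int, stage: str) -> int:
    # stable per-stage substream seed below 2**31
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_pipeline(config: PipelineConfig) -> list[dict]:
    """Execute the enabled stages in dependency order.

    Returns the manifest: one entry per artifact with path, row count,
    content hash, input hashes and seed.  Artifacts consumed by later
    stages are schema-validated before use; a violation aborts with
    row/column diagnostics.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    prior = _load_manifest(out)

    trials_csv = out / "trials.csv"
    truth_csv = out / "truth.csv"
    fits_csv = out / "fits.csv"

    if "generate" in config.stages:
        t0 = time.time()
        seed = _stage_seed(config.seed, "generate")
        gen_cfg = GeneratorConfig(seed=seed, **config.generate)
        trial_sets, truth = generate_meta_dataset(gen_cfg)
        trials_to_frame(trial_sets).to_csv(trials_csv, index=False)
        truth.to_csv(truth_csv, index=False)
        _record(manifest, "generate", trials_csv, seed, [])
        _record(manifest, "generate", truth_csv, seed, [])
        log.info("generate: %d pairs in %.1fs", len(trial_sets),
                 time.time() - t0)

    if "fit" in config.stages:
        t0 = time.time()
        seed = _stage_seed(config.seed, "fit")
        _require_valid(trials_csv, "trials")
        if _unchanged(prior, "fit", fits_csv, [trials_csv], seed):
            log.info("fit: inputs and seed unchanged, skipping")
            manifest.extend(e for e in prior if e["stage"] == "fit")
        else:
            trial_sets = frame_to_trials(pd.read_csv(trials_csv))
            convention = config.fit.get("convention", "q")
            selected = []
            for ts in trial_sets:
                fits = fr.fit_all_variants(ts, exponent_convention=convention,
                                           compute_se=False)
                selected.append(fr.select_response(fits, ts))
            fr.fits_to_frame(selected).to_csv(fits_csv, index=False)
            _record(manifest, "fit", fits_csv, seed, [trials_csv])
            q_groups = {}
            for f, ts in zip(selected, trial_sets):
                q_groups.setdefault(ts.strategy, []).append(f.params.q)
            qboot = fr.bootstrap_mean_q(
                {k: np.array(v) for k, v in q_groups.items()},
                n_boot=int(config.fit.get("n_boot", 2000)), seed=seed)
            qboot_csv = out / "q_bootstrap.csv"
            qboot.to_csv(qboot_csv, index=False)
            _record(manifest, "fit", qboot_csv, seed, [fits_csv])
        log.info("fit: done in %.1fs", time.time() - t0)

    if "meta" in config.stages:
        t0 = time.time()
        seed = _stage_seed(config.seed, "meta")
        _require_valid(trials_csv, "trials")
        _require_valid(fits_csv, "fitted")
        trial_sets = frame_to_trials(pd.read_csv(trials_csv))
        fits_df = pd.read_csv(fits_csv)
        selected = _fits_from_frame(fits_df, trial_sets)
        records, _ = ma.build_meta_table(selected, trial_sets)
        records_csv = out / "meta_records.csv"
        records.to_csv(records_csv, index=False)
        _record(manifest, "meta", records_csv, seed, [fits_csv, trials_csv])
        response = config.meta.get("response", "capture")
        best, table = ma.select_structure(records, response)
        table_csv = out / "aicc_table.csv"
        table.to_csv(table_csv, index=False)
        _record(manifest, "meta", table_csv, seed, [records_csv])
        bands = ma.bootstrap_predictions(
            best, records, n_boot=int(config.meta.get("n_boot", 100)),
            seed=seed)
        bands_csv = out / "prediction_bands.csv"
        bands.to_csv(bands_csv, index=False)
        _record(manifest, "meta", bands_csv, seed, [records_csv])
        log.info("meta: best structure %s in %.1fs", best.structure.label(),
                 time.time() - t0)

    if "simulate" in config.stages:
        t0 = time.time()
        seed = _stage_seed(config.seed, "simulate")
        sim = config.simulate
        strategies = sim.get("strategies", list(abm._FOCAL_STRATEGIES))
        mass_grid = sim.get("mass_grid", [0.1, 1.0, 10.0])
        replicates = int(sim.get("replicates", 100))
        arena = abm.ArenaConfig(n_steps=int(sim.get("n_steps", 2000)),
                                max_resources=int(sim.get("max_resources", 500)))
        tidy_rows, quantile_frames = [], []
        scalings = default_strategy_scalings()
        for si, strategy in enumerate(strategies):
            for mi, mass in enumerate(mass_grid):
                for rep in range(replicates):
                    rng = np.random.default_rng(np.random.SeedSequence(
                        entropy=seed, spawn_key=(si, mi, rep)))
                    lg = abm.run_replicate(arena, mass, strategy, rng,
                                           scalings=scalings)
                    tidy_rows.append({
                        "strategy": strategy, "consumer_mass_g": mass,
                        "replicate": rep, "unitary_rate": lg.unitary_rate,
                        "biomass_rate": lg.biomass_rate})
            q = abm.sweep_consumer_mass(strategy, mass_grid, replicates,
                                        arena, seed=seed, scalings=scalings)
            quantile_frames.append(q)
        enc_csv = out / "encounters.csv"
        pd.DataFrame(tidy_rows).to_csv(enc_csv, index=False)
        _record(manifest, "simulate", enc_csv, seed, [])
        quant = pd.concat(quantile_frames, ignore_index=True).rename(
            columns={"consumer_mass_g": "consumer_mass_g"})
        quant_csv = out / "encounter_quantiles.csv"
        quant.to_csv(quant_csv, index=False)
        _record(manifest, "simulate", quant_csv, seed, [enc_csv])
        log.info("simulate: done in %.1fs", time.time() - t0)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _fits_from_frame(fits_df: pd.DataFrame, trial_sets) -> list:
    """Rebuild FittedResponse objects (derived rates included) from CSV."""
    by_pair = {t.pair_id: t for t in trial_sets}
    out = []
    for _, row in fits_df.iterrows():
        t = by_pair.get(row["pair_id"])
        if t is None:
            continue
        params = fr.HollingParams(b=float(row["b"]), h=float(row["h"]),
                                  q=float(row["q"]))
        fit = fr.FittedResponse(
            params=params, variant=str(row["variant"]),
            loglik=float(row["loglik"]), k=int(row.get("k", 2)),
            n=int(row.get("n", t.n)), AICc=float(row["AICc"]),
            converged=bool(row.get("converged", True)),
            flag=str(row.get("flag", "") or ""), pair_id=str(row["pair_id"]))
        fr._attach_derived(fit, t)
        out.append(fit)
    return out


def _require_valid(path: Path, schema: str) -> None:
    if not path.exists():
        raise FileNotFoundError(f"required input {path} is missing")
    violations = validate_table(path, schema)
    if violations:
        raise ValueError(f"schema '{schema}' violations in {path}: "
                         f"{violations[:5]}")


def _load_manifest(out: Path) -> list[dict]:
    p = out / "manifest.json"
    if p.exists():
        try:
            return json.load(open(p))
        except json.JSONDecodeError:
            return []
    return []


def _unchanged(prior: list[dict], stage: str, output: Path,
               inputs: list[Path], seed: int) -> bool:
    """True when a prior manifest entry proves this stage is a no-op."""
    for entry in prior:
        if entry["stage"] != stage or entry["path"] != str(output):
            continue
        if entry["seed"] != seed or not output.exists():
            return False
        if entry["sha256"] != _sha256(output):
            return False
        for p in inputs:
            recorded = entry["input_hashes"].get(str(p))
            if recorded is None or not p.exists() or recorded != _sha256(p):
                return False
        return True
    return False
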