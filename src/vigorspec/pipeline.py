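"""End-to-end orchestration: simulate -> preprocess -> split -> grid search -> validate.

A single :class:`RunConfig` (optionally loaded from YAML) drives the whole
pipeline.  Stage seeds are derived from the master seed by stable hashing of
the stage name, so adding a stage never shifts another stage's randomness.
All tabular outputs are plain CSV; reports are JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify, preprocess, synthetic_data
from .classify import GridSpec, SplitSpec, default_grid
from .preprocess import DEFAULT_SAM_THRESHOLD
from .synthetic_data import BandSpec, GeneratorConfig

__all__ = [
    "RunConfig",
    "RunManifest",
    "stage_seed",
    "load_config",
    "validate_config",
    "run_all",
    "write_heatmap",
    "write_filter_report",
    "write_averaged",
    "load_averaged",
]

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Full pipeline configuration."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    grids: tuple[GridSpec, ...] = field(
        default_factory=lambda: tuple(default_grid(a) for a in classify.ALGORITHMS)
    )
    sam_threshold: float = DEFAULT_SAM_THRESHOLD
    pca_in_fold: bool = False
    seed: int = 0
    outdir: str | None = None
    log_level: str = "INFO"


@dataclass
class RunManifest:
    """What a run produced: stage seeds and every file written."""

    stage_seeds: dict[str, int]
    outputs: dict[str, str]
    started: str
    finished: str
    version: str = "0.1.0"


# ---------------------------------------------------------------------------
# Config file handling
# ---------------------------------------------------------------------------

_GENERATOR_KEYS = {f.name for f in dataclasses.fields(GeneratorConfig)}
_TOP_KEYS = {"generator", "split", "grids", "sam_threshold", "pca_in_fold",
             "seed", "outdir", "log_level"}


def load_config(path: str | Path | None = None) -> RunConfig:
    """Parse a YAML config file into a RunConfig; an empty file yields all defaults.

    Unknown keys are rejected so typos cannot silently fall back to defaults.
    """
    raw: Mapping = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        raw = loaded or {}
    if not isinstance(raw, Mapping):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    gen_raw = dict(raw.get("generator") or {})
    unknown = set(gen_raw) - _GENERATOR_KEYS
    if unknown:
        raise ValueError(f"unknown generator keys: {sorted(unknown)}")
    if "composition" in gen_raw:
        gen_raw["composition"] = tuple(
            (str(c), str(v), int(n)) for c, v, n in gen_raw["composition"]
        )
    if "bands" in gen_raw:
        gen_raw["bands"] = tuple(
            BandSpec(str(name), *map(float, spec)) for name, spec in gen_raw["bands"].items()
        )
    generator = GeneratorConfig(**gen_raw)

    split_raw = dict(raw.get("split") or {})
    unknown = set(split_raw) - {"n_validation", "n_hv", "n_lv", "seed"}
    if unknown:
        raise ValueError(f"unknown split keys: {sorted(unknown)}")
    split = SplitSpec(**split_raw)

    grids_raw = raw.get("grids")
    if grids_raw is None:
        grids = tuple(default_grid(a) for a in classify.ALGORITHMS)
    else:
        grids = tuple(
            GridSpec(
                algorithm=str(g["algorithm"]).lower(),
                pc_grid=tuple(int(p) for p in g.get("pc_grid", range(1, 21))),
                hyper_grid=tuple(g["hyper_grid"]) if "hyper_grid" in g else (),
            )
            for g in grids_raw
        )

    return RunConfig(
        generator=generator,
        split=split,
        grids=grids,
        sam_threshold=float(raw.get("sam_threshold", DEFAULT_SAM_THRESHOLD)),
        pca_in_fold=bool(raw.get("pca_in_fold", False)),
        seed=int(raw.get("seed", 0)),
        outdir=raw.get("outdir"),
        log_level=str(raw.get("log_level", "INFO")),
    )


def validate_config(config: RunConfig) -> list[str]:
    """Collect every reason the config is not runnable (empty list = runnable)."""
    issues: list[str] = []
    try:
        config.generator.validate()
    except ValueError as exc:
        issues.append(str(exc))
    if not 0.0 < config.sam_threshold <= 1.0:
        issues.append(f"sam_threshold must be in (0, 1], got {config.sam_threshold}")
    totals = {"HV": 0, "LV": 0}
    for _, vigor, n in config.generator.composition:
        if vigor in totals:
            totals[vigor] += n
    needed = {"HV": config.split.n_hv, "LV": config.split.n_lv}
    for label, n in totals.items():
        if n <= needed[label]:
            issues.append(
                f"composition has {n} {label} samples; the split needs more than {needed[label]}"
            )
    if config.generator.replicates_per_sample < 2:
        issues.append("replicates_per_sample must be >= 2 for the SAM filter")
    seen = set()
    for grid in config.grids:
        if grid.algorithm in seen:
            issues.append(f"duplicate grid for algorithm {grid.algorithm}")
        seen.add(grid.algorithm)
        n_train = sum(totals.values()) - config.split.n_validation
        if max(grid.pc_grid) > n_train - 1:
            issues.append(
                f"{grid.algorithm} pc_grid exceeds the training-set rank ({n_train - 1})"
            )
    return issues


# ---------------------------------------------------------------------------
# Artifact writers
# ---------------------------------------------------------------------------

def write_heatmap(gsmap: classify.GridSearchMap, path: str | Path) -> None:
    gsmap.to_frame().to_csv(path, float_format="%.4f")


def write_filter_report(reports: Sequence[preprocess.FilterReport], path: str | Path) -> None:
    pd.DataFrame(
        [{"sample_id": r.sample_id, "band": r.band, "n_input": r.n_input,
          "n_discarded": r.n_discarded,
          "discarded_indices": ";".join(map(str, r.discarded_indices))}
         for r in reports]
    ).to_csv(path, index=False)


def write_averaged(samples: Sequence[preprocess.AveragedSample], path: str | Path) -> None:
    """Averaged-sample matrix: metadata columns then one column per wavelength."""
    frame = pd.DataFrame(
        np.stack([s.intensities for s in samples]),
        columns=[f"{w:.6g}" for w in samples[0].wavelengths],
    )
    frame.insert(0, "sample_id", [s.sample_id for s in samples])
    frame.insert(1, "cultivar", [s.cultivar for s in samples])
    frame.insert(2, "vigor", [s.vigor for s in samples])
    frame.to_csv(path, index=False, float_format="%.6g")


def load_averaged(path: str | Path, band: str) -> list[preprocess.AveragedSample]:
    frame = pd.read_csv(path)
    meta = ["sample_id", "cultivar", "vigor"]
    wavelengths = np.array([float(c) for c in frame.columns if c not in meta])
    return [
        preprocess.AveragedSample(
            sample_id=str(row["sample_id"]), cultivar=str(row["cultivar"]),
            vigor=str(row["vigor"]), band=band, wavelengths=wavelengths,
            intensities=row.drop(meta).to_numpy(dtype=float),
        )
        for _, row in frame.iterrows()
    ]


def _round_floats(obj):
    if isinstance(obj, float):
        return round(obj, 6)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# The full pipeline
# ---------------------------------------------------------------------------

def run_all(config: RunConfig, outdir: str | Path | None = None) -> RunManifest:
    """Execute the whole pipeline and write all artifacts to ``outdir``."""
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    outdir = Path(outdir if outdir is not None else (config.outdir or "."))
    outdir.mkdir(parents=True, exist_ok=True)
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid configuration: " + "; ".join(issues))

    seeds = {name: stage_seed(config.seed, name)
             for name in ("simulate", "outliers", "split")}
    outputs: dict[str, str] = {}

    logger.info("simulate: generating synthetic dataset (seed %d)", seeds["simulate"])
    gen = dataclasses.replace(config.generator, seed=seeds["simulate"])
    samples = synthetic_data.generate_dataset(gen)
    samples, corrupted = synthetic_data.inject_outliers(
        samples, gen.outlier_fraction, np.random.default_rng(seeds["outliers"])
    )
    logger.info("simulate: %d samples, %d corrupted replicates", len(samples), len(corrupted))

    logger.info("preprocess: SNV + SAM filter (threshold %.2f) + averaging", config.sam_threshold)
    averaged, reports = preprocess.preprocess_dataset(samples, config.sam_threshold)
    del samples
    frac = preprocess.discarded_fraction(reports)
    logger.info("preprocess: discarded %.2f%% of replicates", 100 * frac)
    path = outdir / "filter_report.csv"
    write_filter_report(reports, path)
    outputs["filter_report"] = path.name

    bands = sorted(averaged)
    split_spec = dataclasses.replace(config.split, seed=seeds["split"])
    train0, val0 = classify.split_dataset(averaged[bands[0]], split_spec)
    train_ids = {s.sample_id for s in train0}

    report: dict = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_samples": len(averaged[bands[0]]),
        "n_corrupted_replicates": len(corrupted),
        "discarded_fraction": frac,
        "validation_ids": sorted(s.sample_id for s in val0),
        "bands": {},
    }

    for band in bands:
        band_samples = averaged[band]
        path = outdir / f"averaged_{band}.csv"
        write_averaged(band_samples, path)
        outputs[f"averaged_{band}"] = path.name
        train = [s for s in band_samples if s.sample_id in train_ids]
        val = [s for s in band_samples if s.sample_id not in train_ids]
        X, y, _ = classify.sample_matrix(train)
        band_report: dict = {}
        for grid in config.grids:
            logger.info("train: %s / %s grid search (%d x %d cells)", grid.algorithm,
                        band, len(grid.pc_grid), len(grid.hyper_grid))
            gsmap = classify.grid_search(X, y, grid, band=band, pca_in_fold=config.pca_in_fold)
            path = outdir / f"heatmap_{grid.algorithm}_{band}.csv"
            write_heatmap(gsmap, path)
            outputs[f"heatmap_{grid.algorithm}_{band}"] = path.name
            n_pcs, hyper = gsmap.chosen
            model = classify.train_classifier(train, grid.algorithm, n_pcs, hyper)
            validation = classify.external_validate(model, val)
            logger.info("validate: %s / %s -> %.3f external accuracy",
                        grid.algorithm, band, validation.accuracy)
            band_report[grid.algorithm] = {
                "chosen_n_pcs": int(n_pcs),
                "chosen_hyperparameter": hyper,
                "loo_cv_accuracy": gsmap.best_accuracy,
                "external_accuracy": validation.accuracy,
                "confusion": validation.confusion.tolist(),
                "confusion_labels": list(validation.labels),
            }
        report["bands"][band] = band_report

    path = outdir / "report.json"
    path.write_text(json.dumps(_round_floats(report), indent=2, ensure_ascii=False) + "\n")
    outputs["report"] = path.name

    manifest = RunManifest(
        stage_seeds=seeds, outputs=outputs, started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    path = outdir / "run_manifest.json"
    path.write_text(json.dumps(dataclasses.asdict(manifest), indent=2) + "\n")
    return manifest
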