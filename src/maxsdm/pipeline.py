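"""End-to-end orchestration: config, staged execution, report assembly.

A run proceeds clean → thin → prune → tune → cross-validated fit →
projection per scenario → classification → area / percent-change →
centroid track → two-species overlap, writing every artifact plus a
manifest (input digests, seed, version) so a rerun with the same config is
reproducible.  All randomness flows from one root seed split per stage via
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    DEFAULT_FC_GRID,
    DEFAULT_RM_GRID,
    draw_background,
    kfold_cv,
    tune,
)
from .grids import EnvStack, read_raster, write_raster
from .maxent import SuitabilityMap, predict, predict_map
from .occurrences import clean_coordinates, extract_values, load_occurrences, thin_to_grid
from .predictors import SelectionPolicy, pearson_matrix, prune_collinear, sample_stack_cells
from .ranges import (
    area_report,
    binary_suitable,
    centroid_track,
    change_map,
    classify,
    overlap,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_stack_dir"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a pipeline run needs; loadable from a YAML document."""

    occurrences: dict[str, str]                  # species -> CSV path
    current_stack: str                           # directory of .asc layers
    scenario_stacks: dict[str, str] = field(default_factory=dict)
    out_dir: str = "maxsdm_out"
    policy: SelectionPolicy = field(default_factory=SelectionPolicy)
    rm_grid: tuple = DEFAULT_RM_GRID
    fc_grid: tuple = DEFAULT_FC_GRID
    k_folds: int = 10
    n_background: int = 10_000
    thresholds: tuple[float, float, float] = (0.2, 0.4, 0.6)
    binary_threshold: float = 0.2
    transform: str = "cloglog"
    hinge_knots: int = 20
    threshold_knots: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        policy = doc.pop("policy", None)
        cfg = cls(
            occurrences=doc.pop("occurrences"),
            current_stack=doc.pop("current_stack"),
            scenario_stacks=doc.pop("scenario_stacks", {}),
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in doc.items()
            },
        )
        if policy:
            cfg.policy = SelectionPolicy(
                threshold=policy.get("threshold", 0.8),
                priority=list(policy.get("priority", [])),
                always_keep=set(policy.get("always_keep", ["elev", "slope"])),
                always_drop=set(policy.get("always_drop", ["aspect"])),
            )
        return cfg


def load_stack_dir(path) -> EnvStack:
    """Read every .asc layer in a directory into one harmonized stack."""
    files = sorted(p for p in os.listdir(path) if p.endswith(".asc"))
    if not files:
        raise ValueError(f"{path}: no .asc layers found")
    layers = [read_raster(os.path.join(path, f)) for f in files]
    stack = EnvStack(layers[0].grid)
    for layer in layers:
        stack.add(layer)
    return stack.harmonize_mask()


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write_map(smap: SuitabilityMap, path, name: str) -> None:
    from .grids import Layer

    write_raster(Layer(smap.grid, smap.values, name), path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full study; returns the manifest dictionary.

    Any stage failure raises :class:`PipelineError` naming the stage.
    Outputs already written before the failure remain on disk and are
    listed in the manifest with ``"partial": true``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {},
        "outputs": [],
        "partial": True,
    }
    root = np.random.SeedSequence(config.seed)
    seeds = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("prune", "tune", "cv", "background"), root.spawn(4)
        )
    }

    def emit(rel: str) -> Path:
        manifest["outputs"].append(rel)
        return out / rel

    stage = "load_stacks"
    try:
        current = load_stack_dir(config.current_stack)
        manifest["inputs"]["current_stack"] = config.current_stack
        scenarios = {
            label: load_stack_dir(p) for label, p in config.scenario_stacks.items()
        }
        if not scenarios:
            logger.warning("no scenario stacks configured: current-only run")

        stage = "prune"
        samples = sample_stack_cells(
            current, 10_000, seed=int(seeds["prune"].integers(2**31))
        )
        corr = pearson_matrix(samples)
        policy = config.policy
        if not policy.priority:
            policy.priority = [
                v for v in current.names
                if v not in policy.always_keep | policy.always_drop
            ]
        retained = prune_collinear(corr, policy)
        corr.to_frame().to_csv(emit("correlation_matrix.csv"))
        emit("retained_variables.txt").write_text("\n".join(retained) + "\n")
        stack = current.subset(retained)
        scen_stacks = {l: s.subset(retained) for l, s in scenarios.items()}

        species_masks: dict[str, dict[str, np.ndarray]] = {}
        for species, occ_path in config.occurrences.items():
            stage = f"{species}:occurrences"
            manifest["inputs"][species] = {
                "path": occ_path, "sha256": _digest(occ_path),
            }
            sdir = out / species
            sdir.mkdir(exist_ok=True)
            occ = load_occurrences(occ_path, species=species)
            occ = clean_coordinates(occ, stack)
            occ = thin_to_grid(occ, stack.grid)
            occ.to_csv(emit(f"{species}/occurrences_clean.csv"))
            occ.drop_log_frame().to_csv(
                emit(f"{species}/drop_log.csv"), index=False
            )
            presence = extract_values(occ, stack)

            stage = f"{species}:tune"
            bg = draw_background(
                stack, config.n_background,
                np.random.default_rng(int(seeds["background"].integers(2**31))),
            )
            train_bg = pd.concat([bg, presence], ignore_index=True)
            report = tune(
                presence, train_bg,
                rm_values=config.rm_grid, fc_values=config.fc_grid,
                hinge_knots=config.hinge_knots,
                threshold_knots=config.threshold_knots,
                seed=config.seed,
            )
            rm, fc = report.best
            report.to_frame().to_csv(emit(f"{species}/tuning.csv"), index=False)
            logger.info("%s: selected RM=%s FC=%s", species, rm, fc)

            stage = f"{species}:cv_fit"
            aucs, current_map, models = kfold_cv(
                presence, stack, rm, fc,
                k=config.k_folds, n_background=config.n_background,
                seed=int(seeds["cv"].integers(2**31)),
                transform=config.transform,
                hinge_knots=config.hinge_knots,
                threshold_knots=config.threshold_knots,
            )
            pd.DataFrame({"fold": range(1, len(aucs) + 1), "auc": aucs}).to_csv(
                emit(f"{species}/cv_aucs.csv"), index=False
            )
            models[0].save(emit(f"{species}/model_fold1.json"))
            _write_map(
                current_map, emit(f"{species}/suitability_current.asc"),
                "suitability",
            )

            stage = f"{species}:project"
            scen_maps: dict[str, SuitabilityMap] = {}
            for label, sstack in scen_stacks.items():
                grid = sstack.grid
                valid = sstack.mask
                rows, cols = np.nonzero(valid)
                tbl = pd.DataFrame(
                    sstack.table(rows, cols), columns=sstack.names
                )[presence.columns]
                vals = np.mean(
                    [predict(m, tbl, config.transform) for m in models], axis=0
                )
                arr = np.full(grid.shape, grid.nodata)
                arr[rows, cols] = vals
                smap = SuitabilityMap(grid, arr, config.transform)
                scen_maps[label] = smap
                _write_map(
                    smap, emit(f"{species}/suitability_{label}.asc"), "suitability"
                )

            stage = f"{species}:ranges"
            cmap_now = classify(current_map, config.thresholds)
            base_rep = area_report(cmap_now)
            rows_out = [
                {"scenario": "current",
                 **{f"{c}_1e4km2": round(base_rep.areas[c], 2)
                    for c in ("extreme", "moderate", "low", "total")}}
            ]
            mask_now, _ = binary_suitable(current_map, config.binary_threshold)
            masks = {"current": mask_now}
            for label, smap in scen_maps.items():
                cm = classify(smap, config.thresholds)
                rep = area_report(cm, baseline=base_rep)
                row = {"scenario": label}
                for c in ("extreme", "moderate", "low", "total"):
                    row[f"{c}_1e4km2"] = round(rep.areas[c], 2)
                    ch = rep.change_pct.get(c)
                    row[f"{c}_change_pct"] = (
                        round(ch, 2) if ch is not None else None
                    )
                rows_out.append(row)
                m, _ = binary_suitable(smap, config.binary_threshold)
                masks[label] = m
                codes = change_map(mask_now, m, valid=smap.mask)
                from .grids import Layer

                write_raster(
                    Layer(smap.grid, codes.astype(float), "change"),
                    emit(f"{species}/change_{label}.asc"),
                )
            pd.DataFrame(rows_out).to_csv(
                emit(f"{species}/areas.csv"), index=False
            )

            track = centroid_track(list(masks.items()), stack.grid)
            track.to_frame().to_csv(
                emit(f"{species}/centroids.csv"), index=False
            )
            species_masks[species] = masks

        stage = "overlap"
        if len(species_masks) == 2:
            (sp_a, masks_a), (sp_b, masks_b) = species_masks.items()
            rows_out = []
            for label in masks_a:
                if label not in masks_b:
                    continue
                rep = overlap(masks_a[label], masks_b[label], stack.grid)
                rows_out.append(
                    {"scenario": label, **rep.to_frame().iloc[0].to_dict()}
                )
            pd.DataFrame(rows_out).to_csv(emit("overlap.csv"), index=False)

        manifest["partial"] = False
    except Exception as exc:  # noqa: BLE001 - annotate with the stage name
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise PipelineError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
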