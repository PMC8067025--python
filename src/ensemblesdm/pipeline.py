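"""End-to-end runs from one YAML configuration: seeding, artifacts, reports.

A run configuration carries the grid, the file paths (or the synthetic
generator switch), and every stage's parameters, defaulting to the study's
printed constants: 30 m cells, 682 m thinning distance and home-range
radius, VIF cutoff 5, 10-fold CV repeated 50 times, gate AUC >= 0.80 and
TSS >= 0.60, 5% importance retention, 50 mortality background points.

A single global seed deterministically derives every stage seed as
``SeedSequence([global_seed, stage_index])``; changing the global seed
changes every stochastic output, while two runs with identical
configurations are byte-identical (timestamps excluded). Every artifact is
listed in the report manifest with its SHA-256 hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import algorithms as alg
from .ensemble import EnsembleSDM, EnsembleSDMResults, \
    SelectionConfig
from .evaluation import CvConfig, GateConfig
from .grids import (GridSpec, LayerKind, OccurrenceSet, PointLabel,
                    RasterStack, StudyRegion, clip_stack, read_stack,
                    write_ascii_grid)
from .mortality import (MORTALITY_BACKGROUND_N, compare_runs,
                        run_mortality_pipeline)
from .preprocess import (BackgroundConfig, ThinningConfig, VifConfig,
                         sample_background, spatial_thin, vif_report)
from .synthetic import GeneratorConfig, generate_landscape, sample_points

log = logging.getLogger("ensemblesdm")

# stage indices for seed derivation (stable across releases)
_STAGES = {"generate": 0, "thin": 1, "background": 2, "selection": 3,
           "models": 4, "carcass": 5, "mortality_background": 6,
           "mortality_selection": 7, "mortality_models": 8}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the single global seed."""
    ss = np.random.SeedSequence([int(global_seed), _STAGES[stage]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


class ConfigError(ValueError):
    """A run configuration failed schema validation."""


@dataclass
class RunConfig:
    """Validated configuration for the habitat and mortality runs."""

    seed: int = 0
    out_dir: str = "runs/out"
    synthetic: bool = True
    grid: GridSpec = field(default_factory=GridSpec)
    stack_paths: list[str] = field(default_factory=list)
    layer_kinds: dict[str, str] = field(default_factory=dict)
    presence_csv: str | None = None
    carcass_csv: str | None = None
    region_geojson: str | None = None
    thin: bool = False
    thinning: ThinningConfig = field(default_factory=ThinningConfig)
    vif: VifConfig = field(default_factory=VifConfig)
    n_background: int | None = None     # habitat run; None -> 10x presences
    cv: CvConfig = field(default_factory=CvConfig)
    gate: GateConfig = field(default_factory=GateConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    algorithms: list[str] = field(
        default_factory=lambda: list(alg.ALGORITHM_NAMES))
    hyper: dict = field(default_factory=dict)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(raw)
        try:
            if "grid" in kwargs:
                g = dict(kwargs["grid"])
                if "origin" in g:
                    g["origin"] = tuple(g["origin"])
                kwargs["grid"] = GridSpec(**g)
            for key, klass in (("thinning", ThinningConfig),
                               ("vif", VifConfig), ("cv", CvConfig),
                               ("gate", GateConfig),
                               ("selection", SelectionConfig)):
                if key in kwargs and isinstance(kwargs[key], dict):
                    kwargs[key] = klass(**kwargs[key])
            if "generator" in kwargs and isinstance(kwargs["generator"], dict):
                kwargs["generator"] = GeneratorConfig(**kwargs["generator"])
            cfg = cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        for a in cfg.algorithms:
            if a.upper() not in alg.ALGORITHM_NAMES:
                raise ConfigError(f"unknown algorithm {a!r}")
        if not cfg.synthetic and not cfg.stack_paths:
            raise ConfigError("stack_paths required when synthetic is false")
        if not cfg.synthetic and cfg.presence_csv is None:
            raise ConfigError("presence_csv required when synthetic is false")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic:
        gen = GeneratorConfig(
            grid=cfg.grid,
            smoothing_sigma=cfg.generator.smoothing_sigma,
            true_betas=cfg.generator.true_betas,
            beta0=cfg.generator.beta0,
            n_presence=cfg.generator.n_presence,
            n_carcass=cfg.generator.n_carcass,
            collinear_copies=cfg.generator.collinear_copies,
            window=cfg.generator.window,
            seed=stage_seed(cfg.seed, "generate"))
        stack, truth = generate_landscape(gen)
        presences = sample_points(truth, gen.n_presence, PointLabel.PRESENCE,
                                  seed=stage_seed(cfg.seed, "thin"))
        return stack, truth, presences
    stack = read_stack(cfg.stack_paths, cfg.grid,
                       kinds={k: LayerKind(v)
                              for k, v in cfg.layer_kinds.items()})
    presences = OccurrenceSet.from_csv(cfg.presence_csv,
                                       label=PointLabel.PRESENCE)
    return stack, None, presences


def _write_results(results: EnsembleSDMResults, stack: RasterStack,
                   out: Path, prefix: str, cfg: RunConfig) -> dict:
    artifacts: dict[str, str] = {}

    def _save(name: str, writer) -> None:
        path = out / name
        writer(path)
        artifacts[name] = _sha256(path)

    _save(f"{prefix}_cv_report.csv",
          lambda p: results.cv_report.to_csv(p, cfg.gate))
    if results.importance is not None:
        _save(f"{prefix}_importance.csv",
              lambda p: results.importance.to_csv(p))
    _save(f"{prefix}_audit.jsonl", lambda p: p.write_text(
        "\n".join(json.dumps(a, sort_keys=True) for a in results.audit_log)
        + "\n"))
    if not results.gate_failed:
        suit = results.predict_stack(stack, name=f"{prefix}_suitability")
        _save(f"{prefix}_suitability.asc",
              lambda p: write_ascii_grid(suit, p))
        binary = results.binary_map(stack)
        _save(f"{prefix}_binary.asc", lambda p: write_ascii_grid(binary, p))
    return artifacts


def _report_block(results: EnsembleSDMResults, cfg: RunConfig) -> dict:
    block = {
        "variables": results.variables,
        "vif_excluded": results.vif_excluded,
        "admitted": results.admitted,
        "gate_failed": results.gate_failed,
        "cv": results.cv_report.with_verdicts(cfg.gate)
                     .to_dict(orient="records"),
    }
    if not results.gate_failed:
        block.update({
            "ensemble_auc": results.ensemble_auc,
            "ensemble_tss": results.ensemble_tss,
            "threshold": results.threshold,
            "importance_relative_pct":
                results.importance["relative_pct"].round(6).to_dict(),
        })
    return block


def run_habitat(cfg: RunConfig) -> tuple[EnsembleSDMResults, dict]:
    """Thin -> extract -> VIF -> forward selection -> gate -> ensemble."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack, truth, presences = _load_inputs(cfg)
    log.info("habitat run: %d presence points, %d layers",
             len(presences), len(stack))
    if cfg.thin:
        thin_cfg = ThinningConfig(
            min_distance=cfg.thinning.min_distance,
            n_repeats=cfg.thinning.n_repeats,
            seed=stage_seed(cfg.seed, "thin"))
        before = len(presences)
        presences = spatial_thin(presences, thin_cfg)
        log.info("thinning: %d -> %d points", before, len(presences))
    region = (StudyRegion.from_geojson(cfg.region_geojson)
              if cfg.region_geojson else None)
    n_bg = cfg.n_background or 10 * len(presences)
    background = sample_background(
        BackgroundConfig(n_points=n_bg, region=region,
                         seed=stage_seed(cfg.seed, "background")),
        stack.grid, stack.combined_mask())
    model = EnsembleSDM.from_stack(
        stack, presences, background,
        vif=cfg.vif,
        selection=SelectionConfig(
            importance_min_pct=cfg.selection.importance_min_pct,
            max_iterations=cfg.selection.max_iterations,
            shape_screen=cfg.selection.shape_screen,
            seed=stage_seed(cfg.seed, "selection")),
        cv=CvConfig(k=cfg.cv.k, n_repeats=cfg.cv.n_repeats,
                    seed=stage_seed(cfg.seed, "models"),
                    stratified=cfg.cv.stratified),
        gate=cfg.gate, algorithms=cfg.algorithms, hyper=cfg.hyper,
        seed=stage_seed(cfg.seed, "models"))
    results = model.fit()
    presences.to_csv(out / "habitat_presences.csv")
    background.to_csv(out / "habitat_background.csv")
    artifacts = {
        "habitat_presences.csv": _sha256(out / "habitat_presences.csv"),
        "habitat_background.csv": _sha256(out / "habitat_background.csv"),
    }
    vrep = vif_report(model.train.X[model.candidates], cfg.vif)
    vrep.to_csv(out / "habitat_vif.csv", index=False)
    artifacts["habitat_vif.csv"] = _sha256(out / "habitat_vif.csv")
    artifacts.update(_write_results(results, stack, out, "habitat", cfg))
    report = {
        "run": "habitat", "seed": cfg.seed,
        "n_presences": len(presences), "n_background": n_bg,
        "habitat": _report_block(results, cfg),
        "manifest": artifacts,
    }
    (out / "habitat_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    return results, report


def run_mortality(cfg: RunConfig,
                  habitat: EnsembleSDMResults | None = None
                  ) -> tuple[EnsembleSDMResults, dict]:
    """The carcass-site run, plus the comparison when a habitat result is given."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack, truth, _ = _load_inputs(cfg)
    if cfg.synthetic:
        from .benchmarks import _northern_region

        region = _northern_region(stack.grid)
        carcasses = sample_points(
            truth, cfg.generator.n_carcass, PointLabel.CARCASS,
            seed=stage_seed(cfg.seed, "carcass"), aspect_bias=True,
            aspect_layer=stack["aspect"], region=region)
    else:
        if cfg.carcass_csv is None or cfg.region_geojson is None:
            raise ConfigError("carcass_csv and region_geojson required for "
                              "a non-synthetic mortality run")
        carcasses = OccurrenceSet.from_csv(cfg.carcass_csv,
                                           label=PointLabel.CARCASS)
        region = StudyRegion.from_geojson(cfg.region_geojson)
    log.info("mortality run: %d carcass points, %d backgrounds",
             len(carcasses), MORTALITY_BACKGROUND_N)
    results = run_mortality_pipeline(
        carcasses, stack, region,
        seed=stage_seed(cfg.seed, "mortality_background"),
        vif=cfg.vif,
        selection=SelectionConfig(
            importance_min_pct=cfg.selection.importance_min_pct,
            max_iterations=cfg.selection.max_iterations,
            shape_screen=cfg.selection.shape_screen,
            seed=stage_seed(cfg.seed, "mortality_selection")),
        cv=CvConfig(k=cfg.cv.k, n_repeats=cfg.cv.n_repeats,
                    seed=stage_seed(cfg.seed, "mortality_models"),
                    stratified=cfg.cv.stratified),
        gate=cfg.gate, algorithms=cfg.algorithms, hyper=cfg.hyper)
    clipped = clip_stack(stack, region)
    artifacts = _write_results(results, clipped, out, "mortality", cfg)
    report = {
        "run": "mortality", "seed": cfg.seed,
        "n_carcasses": len(carcasses),
        "n_background": MORTALITY_BACKGROUND_N,
        "mortality": _report_block(results, cfg),
        "manifest": artifacts,
    }
    if habitat is not None and not habitat.gate_failed \
            and not results.gate_failed:
        comp = compare_runs(habitat, results, stack, region=region)
        report["comparison"] = comp.to_dict()
        (out / "comparison.json").write_text(
            json.dumps(comp.to_dict(), indent=2, sort_keys=True))
    (out / "mortality_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    return results, report
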