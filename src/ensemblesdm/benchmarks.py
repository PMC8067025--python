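"""End-to-end benchmark scenarios on the synthetic landscape.

These scenarios exercise the full pipeline at sizes chosen for a single CPU
(see docs/methods.md): the default 200 x 200 landscape with 150 presences and
500 habitat background points, cross-validation with 4 folds x 1 repeat
inside selection, and lightened tree counts for the tree learners. The
generator's scientific conditions (grid, coefficient directions and
magnitudes, presence/carcass counts, the fixed 50 mortality backgrounds)
are the package defaults and are not varied here.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import box

from . import algorithms as alg
from .ensemble import EnsembleSDM, SelectionConfig
from .evaluation import CvConfig, GateConfig
from .grids import PointLabel, StudyRegion
from .mortality import compare_runs, run_mortality_pipeline
from .preprocess import BackgroundConfig, sample_background, vif_stepwise
from .synthetic import GeneratorConfig, generate_landscape, sample_points

#: lightened hyperparameters used by every benchmark run (runtime choice)
BENCH_HYPER = {
    "RF": {"n_trees": 250},
    "BRT": {"max_trees": 300},
    "CART": {"cv_folds": 3, "max_alphas": 10},
}

#: habitat background count: ~2x presences, matching the mortality run's
#: class balance so the two committees' score calibrations are comparable
N_HABITAT_BACKGROUND = 300


def _derive_seed(base: int, *idx: int) -> int:
    ss = np.random.SeedSequence([int(base), *map(int, idx)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _habitat_model(stack, truth, seed: int, cv: CvConfig) -> EnsembleSDM:
    pres = sample_points(truth, truth.config.n_presence, PointLabel.PRESENCE,
                         seed=_derive_seed(seed, 1))
    bg = sample_background(
        BackgroundConfig(n_points=N_HABITAT_BACKGROUND,
                         seed=_derive_seed(seed, 2)),
        stack.grid, stack.combined_mask())
    return EnsembleSDM.from_stack(
        stack, pres, bg,
        selection=SelectionConfig(seed=_derive_seed(seed, 3)),
        cv=cv, gate=GateConfig(), hyper=BENCH_HYPER,
        seed=_derive_seed(seed, 4))


def run_recovery(seed: int, cv: CvConfig | None = None) -> dict:
    """One seeded parameter-recovery run of the habitat pipeline.

    Generates the default landscape, fits the full ensemble model, and
    reports whether VIF removed one member of each collinear pair, whether
    forward selection recovered the informative variables, how many noise
    variables slipped in, and the ensemble's CV AUC.
    """
    cv = cv or CvConfig(k=4, n_repeats=1, seed=_derive_seed(seed, 0))
    cfg = GeneratorConfig(seed=seed)
    stack, truth = generate_landscape(cfg)
    model = _habitat_model(stack, truth, seed, cv)

    retained, excluded = vif_stepwise(model.train.X[model.candidates],
                                      model.vif)
    pairs_broken = all(
        (copy in excluded) or (src in excluded)
        for copy, (src, _) in cfg.collinear_copies.items())
    max_vif_ok = True
    if len(retained) >= 2:
        from .preprocess import compute_vif
        max_vif_ok = max(compute_vif(model.train.X[retained]).values()) \
            < model.vif.cutoff

    results = model.fit()
    informative = set(truth.informative)
    selected = set(results.variables)
    return {
        "seed": seed,
        "selected": sorted(selected),
        "recovered_all": informative <= selected,
        "false_inclusions": len(selected - informative),
        "vif_pairs_broken": pairs_broken,
        "vif_max_ok": max_vif_ok,
        "gate_failed": results.gate_failed,
        "ensemble_auc": results.ensemble_auc,
        "ensemble_tss": results.ensemble_tss,
        "results": results,
    }


def recovery_benchmark(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Parameter recovery across seeds (the headline in-silico check)."""
    runs = [run_recovery(_derive_seed(base_seed, 100, i))
            for i in range(n_seeds)]
    aucs = [r["ensemble_auc"] for r in runs if r["ensemble_auc"] is not None]
    return {
        "n_seeds": n_seeds,
        "recovery_rate": float(np.mean([r["recovered_all"] for r in runs])),
        "false_inclusions_mean": float(np.mean([r["false_inclusions"]
                                                for r in runs])),
        "vif_copy_removal_rate": float(np.mean([r["vif_pairs_broken"]
                                                for r in runs])),
        "ensemble_auc_mean": float(np.mean(aucs)) if aucs else float("nan"),
        "gate_failure_rate": float(np.mean([r["gate_failed"] for r in runs])),
        "runs": runs,
    }


def _northern_region(grid) -> StudyRegion:
    # upper half of the landscape, the high-density polygon analogue
    x0, y0 = grid.origin
    width = grid.n_cols * grid.cell_size
    height = grid.n_rows * grid.cell_size
    poly = box(x0, y0 - height / 2, x0 + width, y0)
    return StudyRegion(poly, name="northern")


def coincidence_benchmark(seed: int = 0) -> dict:
    """Habitat vs carcass-site runs on one landscape.

    Carcasses are sampled from the habitat truth (with the south-east aspect
    preference), so the two ensembles should select overlapping variables and
    predict overlapping binary maps; a null run with uniformly placed
    carcasses should fail the gate or hover near AUC 0.5.
    """
    cv = CvConfig(k=4, n_repeats=1, seed=_derive_seed(seed, 0))
    cfg = GeneratorConfig(seed=seed)
    stack, truth = generate_landscape(cfg)
    region = _northern_region(stack.grid)

    habitat = _habitat_model(stack, truth, seed, cv).fit()

    # carcasses drawn from the habitat truth itself (the coincidence
    # hypothesis); the south-east aspect preference is exercised separately
    carc = sample_points(truth, cfg.n_carcass, PointLabel.CARCASS,
                         seed=_derive_seed(seed, 5), region=region)
    from .ensemble import GateFailureError
    # the mortality table is tiny (24 carcasses + 50 backgrounds), so extra
    # CV repeats are cheap and stabilise the max-TSS threshold
    mort_cv = CvConfig(k=4, n_repeats=5, seed=_derive_seed(seed, 0))
    try:
        mortality = run_mortality_pipeline(
            carc, stack, region, seed=_derive_seed(seed, 6),
            selection=SelectionConfig(seed=_derive_seed(seed, 7)),
            cv=mort_cv, hyper=BENCH_HYPER)
        mortality_failed = mortality.gate_failed
    except GateFailureError:
        mortality, mortality_failed = None, True

    out = {"seed": seed, "habitat": habitat, "mortality": mortality}
    if habitat.gate_failed or mortality_failed:
        out.update({"comparison": None, "jaccard": float("nan"),
                    "shared_fraction": float("nan")})
    else:
        comp = compare_runs(habitat, mortality, stack, region=region)
        out.update({"comparison": comp, "jaccard": comp.jaccard,
                    "shared_fraction": comp.shared_fraction})

    # null scenario: carcasses unrelated to habitat
    null_truth_vals = np.full(stack.grid.shape, 0.5)
    from .grids import RasterLayer
    from .synthetic import TruthRecord
    flat = TruthRecord(
        suitability=RasterLayer("flat", stack.grid, null_truth_vals,
                                mask=stack.combined_mask()),
        informative=[], betas={}, beta0=0.0, config=cfg)
    null_carc = sample_points(flat, cfg.n_carcass, PointLabel.CARCASS,
                              seed=_derive_seed(seed, 8), region=region)
    try:
        null_res = run_mortality_pipeline(
            null_carc, stack, region, seed=_derive_seed(seed, 9),
            selection=SelectionConfig(seed=_derive_seed(seed, 10)),
            cv=cv, hyper=BENCH_HYPER)
        null_failed = null_res.gate_failed
        null_auc = (null_res.ensemble_auc if not null_failed
                    else float(null_res.cv_report.table["auc_mean"].max()))
    except (ValueError, RuntimeError):
        null_failed, null_auc = True, float("nan")
    out["null_gate_failed"] = bool(null_failed)
    out["null_auc"] = float(null_auc)
    return out


def coincidence_suite(n_seeds: int = 4, base_seed: int = 0) -> dict:
    """Coincidence scenario over several seeds; medians as robust summaries."""
    runs = [coincidence_benchmark(_derive_seed(base_seed, 200, i))
            for i in range(n_seeds)]
    jac = [r["jaccard"] for r in runs]
    cov = []
    for r in runs:
        if r["mortality"] is not None and not r["habitat"].gate_failed:
            hv = set(r["habitat"].variables)
            mv = set(r["mortality"].variables)
            cov.append(len(hv & mv) / len(hv))
        else:
            cov.append(float("nan"))
    null_aucs = [r["null_auc"] for r in runs if not np.isnan(r["null_auc"])]
    rho = [r["comparison"].suitability_correlation
           if r.get("comparison") is not None else float("nan")
           for r in runs]
    return {
        "n_seeds": n_seeds,
        "jaccard_median": float(np.nanmedian(jac)),
        "jaccard_all": jac,
        "rank_correlation_median": float(np.nanmedian(rho)),
        "rank_correlation_all": rho,
        "habitat_coverage_median": float(np.nanmedian(cov)),
        "habitat_coverage_all": cov,
        "null_flagged_rate": float(np.mean([r["null_gate_failed"]
                                            or abs(r["null_auc"] - 0.5) < 0.1
                                            for r in runs])),
        "null_auc_mean": float(np.mean(null_aucs)) if null_aucs
        else float("nan"),
        "runs": runs,
    }
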