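"""End-to-end orchestration: segment -> dose -> DVH -> features -> outcome ->
univariate screen -> model, with one master seed feeding every stage.

Configuration is a plain mapping (or a YAML file with the same keys); all
defaults are embedded and echoed into the report for provenance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ldrio
from .dvh import DVH_AXIS, compute_dvh
from .featurization import assemble_feature_table, assemble_indicators, scale_and_prune
from .geometry import build_grid, enumerate_zone_names, label_voxels
from .dosimetry import compute_dose_grid
from .model import HyperParams, SplitScheme, importance_by_removal, pso_tune, sbs_select
from .outcome import label_toxicity
from .synthetic import GeneratorConfig, generate_cohort
from .uva import univariate_table

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "input_dir": None,  # read contours.json/seeds.csv/cohort.csv here; None -> simulate
    "simulate": {"n_patients": 85},  # GeneratorConfig overrides
    "spacing_mm": 1.0,
    "prescription_gy": 110.0,
    "repeats": 1000,
    "selection_repeats": None,  # S&S repeats during SBS scoring; None -> repeats
    "test_fraction": 0.2,
    "r_threshold": 0.9,
    "seed": 0,
    "pso": {"enabled": True, "particles": 8, "iters": 5, "repeats": 32},
    "horizon_months": 12.0,
    "tolerance_points": 2,
}


def load_config(path: str | Path | None = None, **overrides) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k].update(v)
            else:
                cfg[k] = v
    cfg.update(overrides)
    return cfg


def _derive_seeds(master: int) -> dict[str, int]:
    """Named per-stage seeds, all below 2**31, from one master seed."""
    ss = np.random.SeedSequence(master)
    names = ["simulate", "splits", "selection", "pso", "final"]
    children = ss.spawn(len(names))
    return {
        n: int(c.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for n, c in zip(names, children)
    }


def _cohort_from_inputs(cfg: dict, seeds: dict[str, int]):
    """Either simulate a cohort or load one from the input directory; returns
    (ids, zone_curves, zone_empty, indicators, records)."""
    if cfg["input_dir"] is None:
        sim = {k: v for k, v in (cfg.get("simulate") or {}).items()}
        gen = GeneratorConfig(
            master_seed=seeds["simulate"],
            prescription_gy=cfg["prescription_gy"],
            voxel_mm=cfg["spacing_mm"],
            **sim,
        )
        cohort = generate_cohort(gen)
        return (
            cohort.patient_ids,
            cohort.zone_curves,
            cohort.zone_empty,
            cohort.indicators,
            cohort.records,
        )

    indir = Path(cfg["input_dir"])
    anatomies = ldrio.read_contours(indir / "contours.json")
    implants = ldrio.read_seeds(indir / "seeds.csv")
    table, records = ldrio.read_cohort_csv(indir / "cohort.csv")
    ids = [r.patient_id for r in records]
    zone_names = enumerate_zone_names()
    curves = {z: np.zeros((len(ids), len(DVH_AXIS))) for z in zone_names}
    empty = {z: np.zeros(len(ids), dtype=bool) for z in zone_names}
    rows = []
    meta = table.set_index(table["patient_id"].astype(str))
    for i, pid in enumerate(ids):
        anatomy = anatomies[pid]
        grid = build_grid(anatomy, cfg["spacing_mm"])
        zones = label_voxels(anatomy, grid)
        dose = compute_dose_grid(implants[pid], grid, cfg["prescription_gy"])
        for z in zone_names:
            c = compute_dvh(dose, zones.zone_masks[z], z, pid)
            curves[z][i] = c.volume_fraction
            empty[z][i] = c.empty
        clinical = {
            "patient_id": pid,
            "needles": int(meta.loc[pid, "needles"]),
            "seeds": int(meta.loc[pid, "seeds"]),
            "baseline_ipss": int(meta.loc[pid, "baseline_ipss"]),
        }
        rows.append(assemble_indicators(dose, zones, clinical))
    indicators = pd.DataFrame(rows, index=ids)
    return ids, curves, empty, indicators, records


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run every stage and write the report bundle to ``out_dir``.

    Outputs: ``features.csv`` (scaled, pruned), ``pruned_features.json``,
    ``scaling.json``, ``uva.csv``, ``model_report.json``, ``roc.csv`` and
    ``importance.csv``. Returns the report as a dict.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else load_config(None, **config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _derive_seeds(cfg["seed"])

    ids, curves, empty, indicators, records = _cohort_from_inputs(cfg, seeds)
    labels = np.array(
        [
            label_toxicity(r, cfg["horizon_months"], cfg["tolerance_points"])
            for r in records
        ]
    )

    table, models = assemble_feature_table(curves, indicators, empty)
    n_raw = len(table.feature_names)
    pruned = scale_and_prune(table, cfg["r_threshold"])
    pruned.values.to_csv(out / "features.csv")
    (out / "pruned_features.json").write_text(
        json.dumps({"dropped": pruned.pruned_to_keeper, "kept": pruned.feature_names})
    )
    (out / "scaling.json").write_text(
        json.dumps({k: list(v) for k, v in pruned.scaling_params.items()})
    )

    uva = univariate_table(pruned.values, labels)
    uva.to_csv(out / "uva.csv", index=False)

    scheme = SplitScheme(
        n_repeats=cfg["repeats"],
        test_fraction=cfg["test_fraction"],
        master_seed=seeds["splits"],
    )
    sel_repeats = cfg["selection_repeats"] or cfg["repeats"]
    sel_scheme = replace(scheme, n_repeats=sel_repeats, master_seed=seeds["selection"])

    pso_cfg = cfg["pso"]
    if pso_cfg.get("enabled", True):
        hyper = pso_tune(
            pruned.values,
            labels,
            scheme=replace(scheme, n_repeats=pso_cfg["repeats"], master_seed=seeds["pso"]),
            n_particles=pso_cfg["particles"],
            n_iters=pso_cfg["iters"],
            seed=seeds["pso"],
        )
    else:
        hyper = HyperParams()

    trace = sbs_select(
        pruned.values, labels, scheme=scheme, hyper=hyper, selection_scheme=sel_scheme
    )
    importance = importance_by_removal(
        trace.final_features, pruned.values, labels, scheme=scheme, hyper=hyper
    )
    importance.to_csv(out / "importance.csv", index=False)
    perf = trace.final_performance
    pd.DataFrame({"fpr": perf.fpr_grid, "mean_tpr": perf.mean_tpr}).to_csv(
        out / "roc.csv", index=False
    )

    report = {
        "config": cfg,
        "stage_seeds": seeds,
        "n_patients": len(ids),
        "prevalence": float(labels.mean()),
        "n_features_raw": n_raw,
        "n_features_pruned": len(pruned.feature_names),
        "n_zones_with_pca": len(models),
        "hyperparams": {"C": hyper.C, "gamma": hyper.gamma},
        "stop_level": trace.stop_level,
        "sbs_iterations": [
            {"removed": name, "mean_auc": auc} for name, auc in trace.iterations
        ],
        "final_features": trace.final_features,
        "performance": {
            "mean_auc": perf.mean_auc,
            "accuracy": perf.accuracy,
            "sensitivity": perf.sensitivity,
            "specificity": perf.specificity,
        },
        "importance": importance.to_dict(orient="records"),
        "uva_significant": uva.loc[uva["significant"] == True, "feature"].tolist(),  # noqa: E712
    }
    (out / "model_report.json").write_text(json.dumps(report, indent=2))
    return report
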