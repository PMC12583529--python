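"""End-to-end study driver.

``run_study`` executes, for each requested model, the three experiments —
competition sweep, feedback-configuration grid, and asymmetric-ratio sweep —
and writes tidy CSVs, JSON reports, optional figures and a manifest
sufficient to reproduce every number bit-identically.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np

from . import __version__
from .io import write_json, write_sweep_csv
from .models import MODEL_NAMES
from .sweeps import (
    SWEEP_SIM_SETTINGS,
    competition_sweep,
    evaluate_point,
    feedback_grid_sweep,
    ratio_sweep,
)
from .tunability import extra_domain_curve, tunability_report

__all__ = ["default_config", "run_study"]

logger = logging.getLogger(__name__)


def default_config() -> dict:
    """Baseline study configuration (scaled for a desk-size run).

    Grids: 11-point competition sweep on k ∈ [0, 1], 21 × 21 feedback grid
    on (pos, neg) ∈ [0, 1]², ratio sweep with 10 log-spaced ratios in
    [1, 20] at base strength 0.1.  Every entry can be overridden globally
    or per model via the ``models.<name>`` block.
    """
    return {
        "seed": 0,
        "models": {name: {} for name in MODEL_NAMES},
        "k_grid": np.linspace(0.0, 1.0, 11).tolist(),
        "feedback_grid_points": 21,
        "feedback_max": 1.0,
        "ratio_grid": np.logspace(0.0, np.log10(20.0), 10).tolist(),
        "ratio_base_strength": 0.1,
        "ratio_dominant": "positive",
        "ratio_subgrid_points": 15,
        "n_bins": 50,
    }


def _model_config(config: dict, name: str) -> dict:
    merged = {k: v for k, v in config.items() if k != "models"}
    merged.update(config.get("models", {}).get(name, {}) or {})
    return merged


def run_study(config: dict | None = None, out_dir: str | Path = "study_out") -> dict:
    """Run the configured experiments; returns the manifest dictionary.

    Partial failures are recorded per model in the manifest; the function
    raises only on configuration errors, never on individual sweep points.
    """
    cfg = default_config()
    if config:
        cfg.update(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "config": json.loads(json.dumps(cfg)),
        "sim_settings": SWEEP_SIM_SETTINGS,
        "models": {},
    }

    for name in cfg["models"]:
        mc = _model_config(cfg, name)
        seed = int(mc["seed"])
        entry: dict = {"outputs": {}, "errors": []}
        try:
            comp = competition_sweep(name, mc["k_grid"], seed=seed)
            path = write_sweep_csv(comp, out / f"{name}_competition.csv")
            entry["outputs"]["competition"] = path.name

            npts = int(mc["feedback_grid_points"])
            grid_axis = np.linspace(0.0, float(mc["feedback_max"]), npts)
            grid = feedback_grid_sweep(name, grid_axis, grid_axis, seed=seed)
            path = write_sweep_csv(grid, out / f"{name}_feedback_grid.csv")
            entry["outputs"]["feedback_grid"] = path.name

            baseline = evaluate_point(
                name,
                *_default_ks(name),
                0.0,
                0.0,
                seed,
            )
            obs = grid.observables[0]
            if not baseline.failed and baseline.summaries[obs].is_oscillatory:
                report = tunability_report(grid, baseline.summaries[obs], obs)
                write_json(report, out / f"{name}_tunability.json")
                entry["outputs"]["tunability"] = f"{name}_tunability.json"
            else:
                entry["errors"].append(
                    "baseline (pos=0, neg=0) not oscillatory; "
                    "tunability reference undefined"
                )

            rs = ratio_sweep(
                name,
                mc["ratio_dominant"],
                mc["ratio_grid"],
                base_strength=float(mc["ratio_base_strength"]),
                seed=seed,
                n_sub=int(mc["ratio_subgrid_points"]),
            )
            path = write_sweep_csv(rs, out / f"{name}_ratio.csv")
            entry["outputs"]["ratio"] = path.name
            curve = extra_domain_curve(rs, n_bins=int(mc["n_bins"]))
            curve.to_csv(
                out / f"{name}_extra_domain.csv", index=False, float_format="%.17g"
            )
            entry["outputs"]["extra_domain"] = f"{name}_extra_domain.csv"
        except Exception as exc:
            logger.exception("study failed for model %s", name)
            entry["errors"].append(f"{type(exc).__name__}: {exc}")
        manifest["models"][name] = entry

    write_json(manifest, out / "manifest.json")
    return manifest


def _default_ks(name: str) -> tuple[float, float]:
    from .models import make_model

    p = make_model(name).default_params
    return p["k1"], p["k2"]
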