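"""Parameter-sweep orchestration.

Three experiment shapes, applied to any model:

* :func:`competition_sweep` — vary the mutual-inhibition strength k1 = k2 = k
  with the auxiliary feedback off, tracing the amplitude/frequency trade-off
  of the competitive pair.
* :func:`feedback_grid_sweep` — Cartesian grid over (pos, neg) feedback
  strengths at fixed competition, from which the positive-only, negative-only
  and hybrid configurations are recovered as slices.
* :func:`ratio_sweep` — asymmetric-feedback experiment: for each
  dominant-to-recessive strength ratio r, evaluate the admissible (pos, neg)
  envelope [0, min(r·base, cap)] × [0, base], whose occupied
  amplitude-frequency states feed the extra-domain statistic.

Every grid point gets a deterministic seed derived from the global seed and
the point's coordinates, so results are independent of evaluation order;
failed integrations are recorded with their reason, never dropped.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import (
    OscillationSummary,
    PhaseRelation,
    phase_relation,
    summarize_oscillation,
)
from .integrate import integrate
from .models import ModelSpec, make_model

__all__ = [
    "SweepRecord",
    "SweepResult",
    "SWEEP_SIM_SETTINGS",
    "evaluate_point",
    "competition_sweep",
    "feedback_grid_sweep",
    "ratio_sweep",
]

logger = logging.getLogger(__name__)

# Reduced-cost integration settings used inside sweeps: horizons cover a few
# tens of periods past the transient at each model's default configuration,
# with tolerances loose enough for sweep-scale throughput (validated against
# the tight defaults by the step-halving consistency test).
SWEEP_SIM_SETTINGS: dict[str, dict] = {
    "cell_cycle": {"horizon": 500.0, "rtol": 1e-6, "atol": 1e-9},
    "fitzhugh_nagumo": {"horizon": 700.0, "rtol": 1e-6, "atol": 1e-9},
    "goodwin": {"horizon": 500.0, "rtol": 1e-6, "atol": 1e-9},
    "repressilator": {"horizon": 1300.0, "rtol": 1e-6, "atol": 1e-9},
    "predator_prey": {"horizon": 1500.0, "rtol": 1e-6, "atol": 1e-9},
    # LSODA: metastable configurations near the stability boundary make
    # explicit RK grind; the stiff switcher fails them fast instead
    "van_der_pol": {"horizon": 600.0, "rtol": 1e-6, "atol": 1e-9,
                    "method": "LSODA", "divergence_bound": 1e3},
    "neuromechanical": {"horizon": 40.0, "rtol": 1e-6, "atol": 1e-9, "method": "LSODA"},
}


@dataclass(frozen=True)
class SweepRecord:
    """Outcome at one parameter point (possibly a failed integration)."""

    k1: float
    k2: float
    pos: float
    neg: float
    ratio: float  # nan outside ratio sweeps
    seed: int
    summaries: dict[str, OscillationSummary] = field(default_factory=dict)
    phase: PhaseRelation | None = None
    failed: bool = False
    failure_reason: str | None = None

    @property
    def antiphase(self) -> bool:
        return self.phase is not None and self.phase.classification == "antiphase"


@dataclass
class SweepResult:
    """All records of one sweep plus its axes and configuration label."""

    model_name: str
    axes: dict[str, np.ndarray]
    records: list[SweepRecord]
    config_label: str  # positive_only | negative_only | hybrid | none | mixed
    observables: tuple[str, str]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (point, observable)."""
        rows = []
        for rec in self.records:
            base = {
                "model": self.model_name,
                "k1": rec.k1,
                "k2": rec.k2,
                "pos": rec.pos,
                "neg": rec.neg,
                "ratio": rec.ratio,
                "seed": rec.seed,
                "failed": rec.failed,
                "failure_reason": rec.failure_reason or "",
                "correlation": rec.phase.correlation if rec.phase else np.nan,
                "phase_class": rec.phase.classification if rec.phase else "",
            }
            if rec.summaries:
                for obs, s in rec.summaries.items():
                    rows.append(
                        base
                        | {
                            "observable": obs,
                            "amplitude": s.amplitude,
                            "frequency": s.frequency,
                            "is_oscillatory": s.is_oscillatory,
                            "peak_count": s.peak_count,
                            "period_cv": s.period_cv,
                            "flags": ";".join(s.flags),
                        }
                    )
            else:
                rows.append(
                    base
                    | {
                        "observable": "",
                        "amplitude": np.nan,
                        "frequency": np.nan,
                        "is_oscillatory": False,
                        "peak_count": 0,
                        "period_cv": np.nan,
                        "flags": "",
                    }
                )
        return pd.DataFrame(rows)


def point_seed(global_seed: int, model_name: str, k1: float, k2: float,
               pos: float, neg: float) -> int:
    """Deterministic per-point seed, independent of evaluation order.

    Derived from a SHA-256 digest of the point coordinates so parallel or
    reordered execution cannot change any result; kept below 2**31.
    """
    key = f"{global_seed}|{model_name}|{k1!r}|{k2!r}|{pos!r}|{neg!r}"
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def evaluate_point(
    model_name: str,
    k1: float,
    k2: float,
    pos: float,
    neg: float,
    global_seed: int,
    *,
    ratio: float = float("nan"),
    overrides: dict | None = None,
    sim: dict | None = None,
) -> SweepRecord:
    """Integrate one (k1, k2, pos, neg) configuration and summarize it."""
    seed = point_seed(global_seed, model_name, k1, k2, pos, neg)
    opts = dict(SWEEP_SIM_SETTINGS.get(model_name, {}))
    if sim:
        opts.update(sim)
    full_overrides = dict(overrides or {})
    full_overrides.update({"k1": k1, "k2": k2, "pos": pos, "neg": neg})
    try:
        model = make_model(model_name, full_overrides)
        traj = integrate(model, seed=seed, **opts)
        i, j = model.competitive_pair
        summaries = {
            model.state_names[idx]: summarize_oscillation(traj, idx)
            for idx in (i, j)
        }
        phase = phase_relation(traj)
    except Exception as exc:  # failures are data, not crashes
        return SweepRecord(
            k1, k2, pos, neg, ratio, seed,
            failed=True, failure_reason=f"{type(exc).__name__}: {exc}",
        )
    return SweepRecord(k1, k2, pos, neg, ratio, seed, summaries, phase)


def _dedup(grid) -> np.ndarray:
    values = np.asarray(list(grid), dtype=float)
    uniq = np.unique(values)
    if len(uniq) < len(values):
        warnings.warn("duplicate grid values removed", stacklevel=3)
    return uniq


def competition_sweep(
    model: ModelSpec | str,
    k_grid,
    seed: int = 0,
    *,
    sim: dict | None = None,
) -> SweepResult:
    """Sweep k1 = k2 = k with the auxiliary feedback off (pos = neg = 0)."""
    name, overrides = _model_name_and_overrides(model)
    k_values = _dedup(k_grid)
    records = [
        evaluate_point(name, k, k, 0.0, 0.0, seed, overrides=overrides, sim=sim)
        for k in k_values
    ]
    return SweepResult(
        model_name=name,
        axes={"k": k_values},
        records=records,
        config_label="none",
        observables=_observables(name),
    )


def feedback_grid_sweep(
    model: ModelSpec | str,
    pos_grid,
    neg_grid,
    k1: float | None = None,
    k2: float | None = None,
    seed: int = 0,
    *,
    sim: dict | None = None,
    check_baseline: bool = True,
) -> SweepResult:
    """Full Cartesian (pos, neg) grid at fixed competition strength.

    The positive-only, negative-only and no-feedback configurations are the
    neg = 0 row, pos = 0 column, and origin of the returned grid.
    """
    name, overrides = _model_name_and_overrides(model)
    defaults = make_model(name).default_params
    if k1 is None:
        k1 = defaults["k1"]
    if k2 is None:
        k2 = defaults["k2"]
    pos_values = _dedup(pos_grid)
    neg_values = _dedup(neg_grid)

    if check_baseline:
        base = evaluate_point(name, k1, k2, 0.0, 0.0, seed,
                              overrides=overrides, sim=sim)
        if not base.antiphase:
            warnings.warn(
                f"baseline (pos=0, neg=0) of {name} at k1={k1}, k2={k2} is "
                "not antiphase; feedback-configuration comparisons assume an "
                "antiphase competitive core",
                stacklevel=2,
            )

    records = []
    for pos in pos_values:
        for neg in neg_values:
            records.append(
                evaluate_point(name, k1, k2, pos, neg, seed,
                               overrides=overrides, sim=sim)
            )
    if np.all(pos_values == 0.0) and np.all(neg_values == 0.0):
        label = "none"
    elif np.all(neg_values == 0.0):
        label = "positive_only"
    elif np.all(pos_values == 0.0):
        label = "negative_only"
    else:
        label = "hybrid"
    return SweepResult(
        model_name=name,
        axes={"pos": pos_values, "neg": neg_values},
        records=records,
        config_label=label,
        observables=_observables(name),
    )


def ratio_sweep(
    model: ModelSpec | str,
    dominant: str,
    ratio_grid,
    base_strength: float,
    k1: float | None = None,
    k2: float | None = None,
    seed: int = 0,
    *,
    n_sub: int = 21,
    cap: float = 1.0,
    semantics: str = "envelope",
    sim: dict | None = None,
    cache: dict | None = None,
) -> SweepResult:
    """Asymmetric-feedback sweep over dominant/recessive strength ratios.

    ``semantics="envelope"`` (default): each ratio r admits the (pos, neg)
    region [0, min(r·base, cap)] × [0, base] (dominant axis first), sampled
    on an ``n_sub`` × ``n_sub`` grid; the accessible-state statistic needs
    the whole region, not a single point.  ``semantics="line"`` evaluates
    only the single point (dominant = min(r·base, cap), recessive = base).

    Points shared between ratios (same exact (pos, neg)) are integrated
    once and reused; each record is tagged with its ratio.  Passing a
    ``cache`` dict lets related sweeps (e.g. both dominance directions of
    the same model) share evaluated points; per-point seeds depend only on
    the coordinates, so reuse cannot change any value.
    """
    if dominant not in ("positive", "negative"):
        raise ValueError("dominant must be 'positive' or 'negative'")
    if semantics not in ("envelope", "line"):
        raise ValueError("semantics must be 'envelope' or 'line'")
    if base_strength <= 0:
        raise ValueError(
            "base_strength must be > 0 (zero degenerates to single feedback)"
        )
    ratios = _dedup(ratio_grid)
    if np.any(ratios < 1):
        raise ValueError("ratio_grid values must be >= 1")

    name, overrides = _model_name_and_overrides(model)
    defaults = make_model(name).default_params
    if k1 is None:
        k1 = defaults["k1"]
    if k2 is None:
        k2 = defaults["k2"]

    if cache is None:
        cache = {}

    def point(pos: float, neg: float, r: float) -> SweepRecord:
        key = (pos, neg)
        if key not in cache:
            cache[key] = evaluate_point(
                name, k1, k2, pos, neg, seed,
                ratio=r, overrides=overrides, sim=sim,
            )
        rec = cache[key]
        if rec.ratio != r:
            rec = SweepRecord(
                rec.k1, rec.k2, rec.pos, rec.neg, r, rec.seed,
                rec.summaries, rec.phase, rec.failed, rec.failure_reason,
            )
        return rec

    records = []
    for r in ratios:
        dom_max = min(r * base_strength, cap)
        if semantics == "line":
            pos, neg = (
                (dom_max, base_strength)
                if dominant == "positive"
                else (base_strength, dom_max)
            )
            records.append(point(pos, neg, r))
            continue
        dom_values = np.linspace(0.0, dom_max, n_sub)
        rec_values = np.linspace(0.0, base_strength, n_sub)
        for d in dom_values:
            for rv in rec_values:
                pos, neg = (d, rv) if dominant == "positive" else (rv, d)
                records.append(point(pos, neg, r))
    return SweepResult(
        model_name=name,
        axes={"ratio": ratios},
        records=records,
        config_label="hybrid",
        observables=_observables(name),
    )


def _model_name_and_overrides(model: ModelSpec | str):
    if isinstance(model, str):
        return model, {}
    # carry non-control overrides of a prebuilt spec into per-point models
    defaults = make_model(model.name).default_params
    overrides = {
        key: model.params[key]
        for key in model.params
        if key not in ("k1", "k2", "pos", "neg")
        and model.params[key] != defaults[key]
    }
    return model.name, overrides


def _observables(name: str) -> tuple[str, str]:
    m = make_model(name)
    i, j = m.competitive_pair
    return (m.state_names[i], m.state_names[j])
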