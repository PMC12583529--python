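"""Headline tunability statistics.

Two quantities summarize a sweep:

* normalized tunability, (max − min)/reference, of amplitude and frequency
  over a feedback sweep, with the reference taken from the no-feedback
  baseline (pos = neg = 0);
* the extra-domain percentage (N_h − N_s)/N_h × 100, where N_h and N_s count
  occupied bins of a shared discretized amplitude-frequency plane under
  hybrid and single feedback respectively.

Only records that are both oscillatory and antiphase enter either statistic;
non-oscillatory or phase-drifting corners of a sweep would otherwise
contribute spurious states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .features import OscillationSummary
from .sweeps import SweepRecord, SweepResult

__all__ = [
    "TunabilityEntry",
    "TunabilityReport",
    "StateOccupancy",
    "oscillatory_points",
    "tunability",
    "accessible_states",
    "extra_domain_percentage",
]

logger = logging.getLogger(__name__)

DEFAULT_BINS = 50
EDGE_MARGIN = 0.02


@dataclass(frozen=True)
class TunabilityEntry:
    """Extrema and normalized ranges of one configuration's sweep."""

    config: str
    freq_min: float
    freq_max: float
    amp_min: float
    amp_max: float
    tunability_freq: float
    tunability_amp: float
    n_points: int


@dataclass(frozen=True)
class TunabilityReport:
    """Per-configuration tunability for one model and observable."""

    model_name: str
    observable: str
    reference_freq: float
    reference_amp: float
    entries: dict[str, TunabilityEntry]

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "observable": self.observable,
            "reference_freq": self.reference_freq,
            "reference_amp": self.reference_amp,
            "configurations": {
                name: vars(e).copy() for name, e in self.entries.items()
            },
        }


@dataclass(frozen=True)
class StateOccupancy:
    """Occupied bins of a shared (frequency, amplitude) grid per configuration."""

    bin_edges_freq: np.ndarray
    bin_edges_amp: np.ndarray
    occupied: dict[str, np.ndarray]  # config -> boolean (nf, na) matrix

    def count(self, config: str) -> int:
        return int(self.occupied[config].sum())

    @property
    def counts(self) -> dict[str, int]:
        return {cfg: self.count(cfg) for cfg in self.occupied}


def _usable(rec: SweepRecord, observable: str) -> bool:
    if rec.failed or rec.phase is None:
        return False
    s = rec.summaries.get(observable)
    return s is not None and s.is_oscillatory and rec.antiphase


def oscillatory_points(
    sweep: SweepResult | list[SweepRecord],
    observable: str,
    *,
    require_antiphase: bool = True,
) -> np.ndarray:
    """(n, 2) array of (frequency, amplitude) for usable records."""
    records = sweep.records if isinstance(sweep, SweepResult) else sweep
    pts = []
    for rec in records:
        if rec.failed or rec.phase is None:
            continue
        s = rec.summaries.get(observable)
        if s is None or not s.is_oscillatory:
            continue
        if require_antiphase and not rec.antiphase:
            continue
        pts.append((s.frequency, s.amplitude))
    if not pts:
        return np.empty((0, 2))
    return np.asarray(pts)


def tunability(
    sweep: SweepResult | list[SweepRecord],
    baseline: OscillationSummary,
    observable: str,
    config: str = "hybrid",
) -> TunabilityEntry:
    """Normalized tunability entry for one configuration's records.

    ``baseline`` is the no-feedback (pos = 0, neg = 0) summary providing the
    reference amplitude and frequency; it must be oscillatory with positive
    amplitude, otherwise the normalization is undefined.
    """
    if not baseline.is_oscillatory or baseline.amplitude <= 0 or baseline.frequency <= 0:
        raise ValueError(
            "baseline is not oscillatory; the tunability reference "
            "(pos = 0, neg = 0) is undefined"
        )
    pts = oscillatory_points(sweep, observable)
    if len(pts) == 0:
        raise ValueError(
            "no oscillatory antiphase records to compute tunability from"
        )
    f, a = pts[:, 0], pts[:, 1]
    return TunabilityEntry(
        config=config,
        freq_min=float(f.min()),
        freq_max=float(f.max()),
        amp_min=float(a.min()),
        amp_max=float(a.max()),
        tunability_freq=float((f.max() - f.min()) / baseline.frequency),
        tunability_amp=float((a.max() - a.min()) / baseline.amplitude),
        n_points=len(pts),
    )


def shared_edges(
    point_sets: dict[str, np.ndarray],
    n_bins: int = DEFAULT_BINS,
    margin: float = EDGE_MARGIN,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform bin edges spanning the pooled cloud, padded by ``margin``."""
    pooled = np.concatenate(
        [p for p in point_sets.values() if len(p)] or [np.zeros((1, 2))]
    )
    edges = []
    for col in (0, 1):
        lo, hi = float(pooled[:, col].min()), float(pooled[:, col].max())
        span = hi - lo
        pad = margin * span if span > 0 else max(abs(hi), 1.0) * margin
        edges.append(np.linspace(lo - pad, hi + pad, n_bins + 1))
    return edges[0], edges[1]


def accessible_states(
    point_sets: dict[str, np.ndarray],
    n_bins: int = DEFAULT_BINS,
    *,
    edges: tuple[np.ndarray, np.ndarray] | None = None,
) -> StateOccupancy:
    """Bin each configuration's (frequency, amplitude) points on shared edges.

    ``point_sets`` maps a configuration label (e.g. ``hybrid``,
    ``positive_only``) to an (n, 2) array of (frequency, amplitude) points,
    typically from :func:`oscillatory_points`.  Empty point sets yield zero
    occupancy, which is valid.
    """
    if edges is None:
        fe, ae = shared_edges(point_sets, n_bins)
    else:
        fe, ae = edges
    occupied = {}
    for cfg, pts in point_sets.items():
        grid = np.zeros((len(fe) - 1, len(ae) - 1), dtype=bool)
        if len(pts):
            hist, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=(fe, ae))
            grid = hist > 0
        occupied[cfg] = grid
    return StateOccupancy(fe, ae, occupied)


def extra_domain_percentage(
    occ: StateOccupancy,
    hybrid: str = "hybrid",
    singles: tuple[str, ...] = ("positive_only", "negative_only"),
) -> float:
    """(N_h − N_s)/N_h × 100 on a shared binning.

    N_h counts bins occupied under hybrid feedback; N_s counts bins occupied
    by either single-feedback configuration (their union), regardless of
    overlap with the hybrid set.  A negative value therefore flags
    single-feedback states lying outside the hybrid envelope; these are
    logged as anomalies rather than clipped.
    """
    n_h = occ.count(hybrid)
    if n_h == 0:
        raise ValueError("N_h = 0: extra-domain percentage is undefined")
    single_union = np.zeros_like(occ.occupied[hybrid])
    for cfg in singles:
        if cfg in occ.occupied:
            single_union |= occ.occupied[cfg]
    n_s = int(single_union.sum())
    value = (n_h - n_s) / n_h * 100.0
    if value < 0:
        logger.warning(
            "single-feedback occupancy (%d bins) exceeds hybrid occupancy "
            "(%d bins); single-feedback states fall outside the hybrid envelope",
            n_s, n_h,
        )
    return value


def extra_domain_curve(
    sweep: SweepResult,
    observable: str | None = None,
    n_bins: int = DEFAULT_BINS,
) -> "pd.DataFrame":
    """Extra-domain percentage as a function of the feedback-strength ratio.

    For each ratio in a :func:`osctune.sweeps.ratio_sweep` result, the hybrid
    point set is that ratio's full admissible (pos, neg) envelope and the
    single-feedback sets are its neg = 0 and pos = 0 slices.  Bin edges are
    shared across the *entire* sweep (all ratios and configurations pooled),
    so percentages along the curve are directly comparable: a tiny symmetric
    envelope occupies few bins of the common grid and yields a near-zero
    percentage, while a widening asymmetric envelope fills bins no
    single-feedback slice reaches.

    Returns a DataFrame with columns ``ratio``, ``extra_domain_pct``,
    ``n_hybrid``, ``n_single``.
    """
    import pandas as pd

    if observable is None:
        observable = sweep.observables[0]
    by_ratio: dict[float, dict[str, np.ndarray]] = {}
    all_points = []
    for r in sweep.axes["ratio"]:
        recs = [rec for rec in sweep.records if rec.ratio == r]
        sets = {
            "hybrid": oscillatory_points(recs, observable),
            "positive_only": oscillatory_points(
                [rec for rec in recs if rec.neg == 0.0], observable
            ),
            "negative_only": oscillatory_points(
                [rec for rec in recs if rec.pos == 0.0], observable
            ),
        }
        by_ratio[float(r)] = sets
        all_points.extend(p for p in sets.values() if len(p))
    pooled = {"all": np.concatenate(all_points) if all_points else np.empty((0, 2))}
    edges = shared_edges(pooled, n_bins)

    rows = []
    for r, sets in by_ratio.items():
        occ = accessible_states(sets, n_bins, edges=edges)
        n_h = occ.count("hybrid")
        single = occ.occupied["positive_only"] | occ.occupied["negative_only"]
        n_s = int(single.sum())
        pct = (n_h - n_s) / n_h * 100.0 if n_h > 0 else np.nan
        rows.append(
            {"ratio": r, "extra_domain_pct": pct, "n_hybrid": n_h, "n_single": n_s}
        )
    return pd.DataFrame(rows)


def single_config_slices(
    grid_sweep: SweepResult,
) -> dict[str, list[SweepRecord]]:
    """Extract configuration slices from a full (pos, neg) grid sweep.

    Returns the ``positive_only`` (neg = 0), ``negative_only`` (pos = 0) and
    ``hybrid`` (all points) record subsets.
    """
    recs = grid_sweep.records
    return {
        "positive_only": [r for r in recs if r.neg == 0.0],
        "negative_only": [r for r in recs if r.pos == 0.0],
        "hybrid": list(recs),
    }


def tunability_report(
    grid_sweep: SweepResult,
    baseline: OscillationSummary,
    observable: str | None = None,
) -> TunabilityReport:
    """Per-configuration tunability from one full (pos, neg) grid sweep.

    The positive-only, negative-only and hybrid configurations are the
    grid's neg = 0 row, pos = 0 column, and full grid; the baseline summary
    supplies the reference amplitude and frequency.
    """
    if observable is None:
        observable = grid_sweep.observables[0]
    entries = {}
    for cfg, recs in single_config_slices(grid_sweep).items():
        try:
            entries[cfg] = tunability(recs, baseline, observable, config=cfg)
        except ValueError as exc:
            logger.warning("tunability undefined for %s: %s", cfg, exc)
    return TunabilityReport(
        model_name=grid_sweep.model_name,
        observable=observable,
        reference_freq=baseline.frequency,
        reference_amp=baseline.amplitude,
        entries=entries,
    )
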