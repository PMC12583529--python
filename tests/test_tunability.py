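"""Tunability statistics: arithmetic oracles, binning, edge cases."""

import numpy as np
import pytest

from osctune.features import OscillationSummary, PhaseRelation
from osctune.sweeps import SweepRecord
from osctune.tunability import (
    StateOccupancy,
    accessible_states,
    extra_domain_percentage,
    oscillatory_points,
    shared_edges,
    tunability,
)


def _summary(freq, amp, observable="x", oscillatory=True):
    return OscillationSummary(
        observable=observable,
        amplitude=amp,
        frequency=freq,
        is_oscillatory=oscillatory,
        peak_count=20,
        period_cv=0.01,
    )


def _record(freq, amp, pos=0.1, neg=0.1, antiphase=True):
    corr = -0.95 if antiphase else 0.1
    cls = "antiphase" if antiphase else "uncorrelated"
    return SweepRecord(
        k1=1.0, k2=1.0, pos=pos, neg=neg, ratio=float("nan"), seed=0,
        summaries={"x": _summary(freq, amp)},
        phase=PhaseRelation(("x", "y"), corr, cls),
    )


class TestTunability:
    def test_zero_range(self):
        recs = [_record(0.5, 1.0) for _ in range(3)]
        entry = tunability(recs, _summary(0.5, 1.0), "x")
        assert entry.tunability_freq == 0.0

    def test_printed_formula_arithmetic(self):
        recs = [_record(0.4, 1.0), _record(0.9, 2.0)]
        entry = tunability(recs, _summary(0.5, 1.0), "x")
        assert entry.tunability_freq == pytest.approx((0.9 - 0.4) / 0.5)
        assert entry.tunability_amp == pytest.approx((2.0 - 1.0) / 1.0)

    def test_non_oscillatory_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            tunability([_record(0.5, 1.0)], _summary(0.0, 0.0, oscillatory=False), "x")

    def test_empty_filtered_sweep_rejected(self):
        recs = [_record(0.5, 1.0, antiphase=False)]
        with pytest.raises(ValueError, match="no oscillatory"):
            tunability(recs, _summary(0.5, 1.0), "x")

    def test_non_antiphase_records_excluded(self):
        recs = [_record(0.4, 1.0), _record(5.0, 9.0, antiphase=False)]
        entry = tunability(recs, _summary(0.5, 1.0), "x")
        assert entry.freq_max == 0.4
        assert entry.n_points == 1


class TestOccupancy:
    def test_brute_force_binning_oracle(self, rng):
        """Occupancy equals exhaustive per-point bin assignment."""
        pts = rng.uniform(0.0, 1.0, size=(60, 2))
        sets = {"hybrid": pts}
        occ = accessible_states(sets, n_bins=10)
        fe, ae = occ.bin_edges_freq, occ.bin_edges_amp
        manual = np.zeros((10, 10), dtype=bool)
        for f, a in pts:
            i = min(np.searchsorted(fe, f, side="right") - 1, 9)
            j = min(np.searchsorted(ae, a, side="right") - 1, 9)
            manual[i, j] = True
        assert np.array_equal(occ.occupied["hybrid"], manual)

    def test_empty_point_set_is_valid(self):
        occ = accessible_states(
            {"hybrid": np.array([[0.5, 1.0]]), "positive_only": np.empty((0, 2))}
        )
        assert occ.count("hybrid") == 1
        assert occ.count("positive_only") == 0

    def test_shared_edges_cover_all_sets(self, rng):
        sets = {
            "a": rng.uniform(0, 1, size=(10, 2)),
            "b": rng.uniform(2, 3, size=(10, 2)),
        }
        fe, ae = shared_edges(sets, n_bins=20)
        pooled = np.concatenate(list(sets.values()))
        assert fe[0] < pooled[:, 0].min() and fe[-1] > pooled[:, 0].max()
        assert ae[0] < pooled[:, 1].min() and ae[-1] > pooled[:, 1].max()

    def test_monotone_coverage_with_fixed_edges(self, rng):
        pts = rng.uniform(0.0, 1.0, size=(30, 2))
        extra = rng.uniform(0.0, 1.0, size=(10, 2))
        edges = shared_edges({"all": np.vstack([pts, extra])}, n_bins=15)
        occ_small = accessible_states({"hybrid": pts}, edges=edges)
        occ_big = accessible_states(
            {"hybrid": np.vstack([pts, extra])}, edges=edges
        )
        assert occ_big.count("hybrid") >= occ_small.count("hybrid")


class TestExtraDomain:
    def _occ(self, n_h, n_s):
        fe = np.linspace(0, 1, 21)
        hyb = np.zeros((20, 20), dtype=bool)
        hyb.flat[:n_h] = True
        single = np.zeros((20, 20), dtype=bool)
        single.flat[:n_s] = True
        return StateOccupancy(fe, fe, {"hybrid": hyb, "positive_only": single,
                                       "negative_only": single})

    def test_printed_formula(self):
        assert extra_domain_percentage(self._occ(200, 50)) == pytest.approx(75.0)

    def test_identical_sets_give_zero(self):
        assert extra_domain_percentage(self._occ(37, 37)) == pytest.approx(0.0)

    def test_empty_single_gives_hundred(self):
        assert extra_domain_percentage(self._occ(37, 0)) == pytest.approx(100.0)

    def test_undefined_for_empty_hybrid(self):
        with pytest.raises(ValueError):
            extra_domain_percentage(self._occ(0, 5))

    def test_single_outside_hybrid_can_go_negative(self):
        fe = np.linspace(0, 1, 11)
        hyb = np.zeros((10, 10), dtype=bool)
        hyb[0, 0] = True
        single = np.zeros((10, 10), dtype=bool)
        single[5:, 5:] = True  # disjoint from hybrid
        occ = StateOccupancy(fe, fe, {"hybrid": hyb, "positive_only": single,
                                      "negative_only": np.zeros_like(single)})
        assert extra_domain_percentage(occ) < 0


def test_oscillatory_points_filters():
    recs = [
        _record(0.5, 1.0),
        _record(0.6, 1.1, antiphase=False),
        SweepRecord(1, 1, 0, 0, float("nan"), 0, failed=True,
                    failure_reason="x"),
    ]
    pts = oscillatory_points(recs, "x")
    assert pts.shape == (1, 2)
    pts_all = oscillatory_points(recs, "x", require_antiphase=False)
    assert pts_all.shape == (2, 2)
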