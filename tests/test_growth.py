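"""Growth-parameter extraction: closed-form oracles, invariances, and
wild-type normalization."""

import numpy as np
import pandas as pd
import pytest
from trnascreen.growth import (
    GrowthCurve,
    curves_from_frames,
    extract_growth_params,
    fit_library,
    normalize_to_wildtype,
    preprocess_curve,
    read_plate_table,
)
from trnascreen.simulate import SimConfig, logistic_od


def _logistic_curve(r=0.40, K=1.2, od0=0.02, lag=2.0, t_max=36.0, dt=0.5, noise=None,
                    seed=0):
    t = np.arange(0.0, t_max + dt / 2, dt)
    od = logistic_od(t, K, r, od0, lag)
    if noise:
        od = np.maximum(od + np.random.default_rng(seed).normal(0, noise, len(t)), 0)
    return GrowthCurve("A01", t, od)


class TestReadPlateTable:
    def test_full_plate_bookkeeping(self, tmp_path, noiseless_config):
        from trnascreen.simulate import default_assignments, simulate_plate

        cfg = noiseless_config
        assignments = default_assignments(cfg, [])
        reads, pmap = simulate_plate(cfg, assignments, seed=0)
        reads_p, map_p = tmp_path / "r.csv", tmp_path / "m.csv"
        reads.to_csv(reads_p, index=False)
        pmap.to_csv(map_p, index=False)
        curves, blank = read_plate_table(reads_p, map_p)
        # 4 WT wells tracked as curves; 2 blanks routed to blank estimate
        assert len(curves) == 4
        assert all(len(c.od) == cfg.n_points for c in curves.values())
        assert blank == pytest.approx(cfg.blank_od)

    def test_missing_od_column_is_named(self, tmp_path):
        (tmp_path / "r.csv").write_text("time_h,well\n0,A01\n")
        (tmp_path / "m.csv").write_text("well,strain,bio_rep\nA01,WT,1\n")
        with pytest.raises(ValueError, match="'od'"):
            read_plate_table(tmp_path / "r.csv", tmp_path / "m.csv")

    def test_unmapped_well_rejected(self):
        reads = pd.DataFrame({"time_h": [0.0, 0.5], "well": "Z99", "od": 0.1})
        pmap = pd.DataFrame({"well": ["A01"], "strain": ["WT"], "bio_rep": [1]})
        with pytest.raises(ValueError, match="Z99"):
            curves_from_frames(reads, pmap)

    def test_mapped_but_unread_well_flagged_missing(self):
        t = np.arange(8) * 0.5
        reads = pd.DataFrame({"time_h": t, "well": "A01", "od": 0.1})
        pmap = pd.DataFrame(
            {"well": ["A01", "B01"], "strain": ["s1", "s2"], "bio_rep": [1, 1]}
        )
        curves, _ = curves_from_frames(reads, pmap)
        assert "missing" in curves[("s2", 1, "B01")].flags
        p = extract_growth_params(curves[("s2", 1, "B01")])
        assert np.isnan(p.rate) and np.isnan(p.yield_)

    def test_duplicate_reading_rejected(self):
        reads = pd.DataFrame(
            {"time_h": [0.0, 0.0, 0.5], "well": "A01", "od": [0.1, 0.1, 0.2]}
        )
        pmap = pd.DataFrame({"well": ["A01"], "strain": ["WT"], "bio_rep": [1]})
        with pytest.raises(ValueError, match="duplicate"):
            curves_from_frames(reads, pmap)


class TestPreprocess:
    def test_window_one_zero_blank_is_identity(self):
        c = _logistic_curve()
        out = preprocess_curve(c, blank=0.0, smooth_window=1)
        np.testing.assert_array_equal(out.od, c.od)

    def test_constant_at_blank_flags_no_growth(self):
        t = np.arange(10) * 0.5
        c = GrowthCurve("A01", t, np.full(10, 0.08))
        out = preprocess_curve(c, blank=0.08)
        assert "no_growth" in out.flags
        assert np.all(out.od == 0)

    def test_median_removes_single_spike(self):
        # spike on the stationary plateau, where the neighbouring values
        # the median substitutes differ by less than the read noise
        clean = _logistic_curve()
        spiked = clean.od.copy()
        spiked[65] += 0.5
        out = preprocess_curve(GrowthCurve("A01", clean.times, spiked), 0.0, 3)
        assert np.max(np.abs(out.od - clean.od)) < 0.005

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            preprocess_curve(_logistic_curve(), 0.0, smooth_window=4)


class TestExtractGrowthParams:
    def test_noiseless_logistic_within_one_percent(self):
        p = extract_growth_params(_logistic_curve(r=0.40, K=1.2, od0=0.02))
        assert 0.392 <= p.rate <= 0.408
        assert 1.188 <= p.yield_ <= 1.212
        assert not p.lethal and not p.truncated

    def test_pure_exponential_rate_and_truncation(self):
        t = np.arange(0.0, 24.5, 0.5)
        od = 0.02 * np.exp(0.3 * t)
        p = extract_growth_params(GrowthCurve("A01", t, od))
        assert p.rate == pytest.approx(0.3, rel=0.01)
        assert p.yield_ == pytest.approx(od.max())
        assert p.truncated

    def test_flat_curve_called_lethal(self):
        t = np.arange(20) * 0.5
        p = extract_growth_params(GrowthCurve("A01", t, np.full(20, 0.01)))
        assert p.lethal and p.rate == 0.0 and p.yield_ == 0.0

    @pytest.mark.parametrize("scale", [0.5, 2.0, 3.7])
    def test_rate_invariant_yield_equivariant_under_od_scaling(self, scale):
        base = extract_growth_params(_logistic_curve())
        c = _logistic_curve()
        scaled = extract_growth_params(GrowthCurve("A01", c.times, c.od * scale))
        # small departures allowed: the detection and log floors are
        # absolute OD values and do not rescale with the data
        assert scaled.rate == pytest.approx(base.rate, rel=5e-3)
        assert scaled.yield_ == pytest.approx(base.yield_ * scale, rel=1e-3)

    @pytest.mark.parametrize("shift", [-1.0, 5.0])
    def test_time_shift_leaves_parameters_unchanged(self, shift):
        base = extract_growth_params(_logistic_curve())
        c = _logistic_curve()
        shifted = extract_growth_params(GrowthCurve("A01", c.times + shift, c.od))
        assert shifted.rate == pytest.approx(base.rate, rel=1e-9)
        assert shifted.yield_ == pytest.approx(base.yield_, rel=1e-9)

    @pytest.mark.parametrize("mult", [0.8, 0.9, 1.2])
    def test_planted_multiplier_recovered_within_one_percent(self, mult):
        # near-noiseless simulated curve: extractor recovers m * baseline
        wt = extract_growth_params(_logistic_curve(noise=1e-6))
        mut = extract_growth_params(
            _logistic_curve(r=0.40 * mult, K=1.2 * mult, noise=1e-6, seed=1)
        )
        assert mut.rate / wt.rate == pytest.approx(mult, rel=0.01)
        assert mut.yield_ / wt.yield_ == pytest.approx(mult, rel=0.01)


class TestNormalizeToWildtype:
    def _params(self, entries):
        from trnascreen.growth import GrowthParams

        return {
            (strain, 1, f"A{i:02d}"): GrowthParams(rate=r, yield_=y)
            for i, (strain, r, y) in enumerate(entries)
        }

    def test_strain_at_wt_mean_scores_one(self):
        params = self._params(
            [("WT", 0.38, 1.1), ("WT", 0.42, 1.3), ("s1", 0.40, 1.2)]
        )
        pmap = pd.DataFrame({"well": ["A00", "A01", "A02"],
                             "strain": ["WT", "WT", "s1"], "bio_rep": [1, 1, 1]})
        rel = normalize_to_wildtype(params, pmap)
        row = rel[rel["strain"] == "s1"].iloc[0]
        assert row["rel_rate"] == pytest.approx(1.0)
        assert row["rel_yield"] == pytest.approx(1.0)

    def test_wildtype_rel_values_average_to_one(self):
        params = self._params([("WT", 0.35, 1.0), ("WT", 0.45, 1.4), ("WT", 0.40, 1.2)])
        pmap = pd.DataFrame({"well": ["A00", "A01", "A02"], "strain": "WT",
                             "bio_rep": 1})
        rel = normalize_to_wildtype(params, pmap)
        assert rel[rel["strain"] == "WT"]["rel_rate"].mean() == pytest.approx(1.0)
        assert rel[rel["strain"] == "WT"]["rel_yield"].mean() == pytest.approx(1.0)

    def test_plate_without_wildtype_rejected(self):
        params = self._params([("s1", 0.4, 1.2)])
        pmap = pd.DataFrame({"well": ["A00"], "strain": ["s1"], "bio_rep": [1]})
        with pytest.raises(ValueError, match="wild-type"):
            normalize_to_wildtype(params, pmap)

    def test_all_wildtype_lethal_rejected(self):
        from trnascreen.growth import GrowthParams

        params = {("WT", 1, "A00"): GrowthParams(0.0, 0.0, lethal=True),
                  ("s1", 1, "A01"): GrowthParams(0.4, 1.2)}
        pmap = pd.DataFrame({"well": ["A00", "A01"], "strain": ["WT", "s1"],
                             "bio_rep": [1, 1]})
        with pytest.raises(ValueError, match="lethal"):
            normalize_to_wildtype(params, pmap)


class TestLibraryRecovery:
    def test_planted_yield_multiplier_recovered(self, small_screen):
        cfg, truth, plates = small_screen
        rel = fit_library(plates)
        merged = (
            rel[rel["strain"] != "WT"]
            .groupby("strain")[["rel_rate", "rel_yield"]]
            .mean()
            .join(truth.effects.set_index("strain"))
        )
        planted = merged[(merged["effect_yield"] == 0.8) & ~merged["lethal"]]
        assert len(planted) > 0
        assert planted["rel_yield"].mean() == pytest.approx(0.8, abs=0.02)

    def test_lethal_strains_flagged_not_scored(self, small_screen):
        cfg, truth, plates = small_screen
        rel = fit_library(plates)
        dead = truth.effects[truth.effects["lethal"]]["strain"]
        sub = rel[rel["strain"].isin(dead)]
        assert len(sub) > 0
        assert sub["lethal"].all()
        assert (sub["rel_yield"] == 0).all()
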