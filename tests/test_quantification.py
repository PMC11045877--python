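"""Relative BiAD ratios, per-cell aggregation, allelic and control normalisation."""

import numpy as np
import pytest

import biadquant as bq
from biadquant.errors import ExclusionError
from biadquant.io import CellImage, ChannelRole
from biadquant.quantification import ALLELE_XA, ALLELE_XI
from biadquant.segmentation import NucleusRegion, SpotRegion

from conftest import quantify_sim

M, B = ChannelRole.MARKER, ChannelRole.BIAD


def make_spot(marker_mean, biad_mean, spot_id=1, area=10):
    mask = np.zeros((4, 4), dtype=bool)
    mask[0, 0] = True
    return SpotRegion(mask=mask, centroid=(0.0, 0.0), area=area, spot_id=spot_id,
                      mean_intensity={M: marker_mean, B: biad_mean})


def make_nucleus(marker_mean, biad_mean):
    return NucleusRegion(mask=np.ones((4, 4), dtype=bool), area=16,
                         mean_intensity={M: marker_mean, B: biad_mean})


class TestBackgroundSubtract:
    @pytest.mark.parametrize("spot,nuc,expected", [
        (500, 200, 300), (200, 200, 0), (150, 200, -50),
    ])
    def test_subtraction_preserves_sign(self, spot, nuc, expected):
        assert bq.background_subtract(spot, nuc) == expected


class TestSpotRelativeBiad:
    def test_ratio(self):
        q = bq.spot_relative_biad(make_spot(500, 190), make_nucleus(200, 40))
        assert q.corrected_marker == 300 and q.corrected_biad == 150
        assert q.relative_biad == 0.5

    def test_null_detector_gives_zero(self):
        q = bq.spot_relative_biad(make_spot(500, 40), make_nucleus(200, 40))
        assert q.relative_biad == 0.0

    def test_negative_biad_preserved(self):
        q = bq.spot_relative_biad(make_spot(500, 10), make_nucleus(200, 40))
        assert q.relative_biad == pytest.approx(-0.1)

    def test_degenerate_marker_marked_invalid(self):
        q = bq.spot_relative_biad(make_spot(200, 100), make_nucleus(200, 40), eps=1e-6)
        assert not q.valid and np.isnan(q.relative_biad)

    def test_missing_biad_channel_is_configuration_error(self):
        spot = make_spot(500, 190)
        del spot.mean_intensity[B]
        with pytest.raises(bq.ConfigurationError):
            bq.spot_relative_biad(spot, make_nucleus(200, 40))

    def test_end_to_end_pixel_oracle_on_noiseless_render(self, noiseless_cell,
                                                         noiseless_config):
        """Top-hat spots (MARKER +200, BIAD +100 over base 100/40): ratio 0.5 exactly."""
        cq = quantify_sim(noiseless_cell, noiseless_config)
        assert cq.spot_count == len(noiseless_cell.loci)
        for s in cq.spots:
            assert s.relative_biad == pytest.approx(0.5, rel=1e-12)


class TestCellMean:
    def _quants(self, ratios):
        return [bq.SpotQuant(i + 1, 300.0, 300.0 * r, r, area=20)
                for i, r in enumerate(ratios)]

    @pytest.mark.parametrize("ratios,expected", [
        ([0.4, 0.6], 0.5),
        ([0.7], 0.7),
        ([0.2, -0.1, 0.5], 0.2),
    ])
    def test_mean_over_spots(self, ratios, expected):
        cq = bq.cell_mean_biad(self._quants(ratios), "c", "WT")
        assert cq.mean_relative_biad == pytest.approx(expected)
        assert cq.spot_count == len(ratios)

    def test_invalid_spots_excluded_from_mean(self):
        quants = self._quants([0.4, 0.6])
        quants.append(bq.SpotQuant(3, 0.0, 5.0, float("nan"), area=4, valid=False))
        cq = bq.cell_mean_biad(quants, "c", "WT")
        assert cq.mean_relative_biad == pytest.approx(0.5)
        assert cq.spot_count == 2

    def test_zero_valid_spots_excluded_with_reason(self):
        bad = [bq.SpotQuant(1, 0.0, 5.0, float("nan"), area=4, valid=False)]
        with pytest.raises(ExclusionError) as err:
            bq.cell_mean_biad(bad, "c", "WT")
        assert err.value.reason == "no_valid_spots"


class TestClassifyAlleles:
    def _spot_with_mask(self, pixels):
        mask = np.zeros((10, 10), dtype=bool)
        for p in pixels:
            mask[p] = True
        return SpotRegion(mask=mask, centroid=(0, 0), area=len(pixels), spot_id=1,
                          mean_intensity={})

    def test_overlap_tiers(self):
        stain = np.zeros((10, 10), dtype=bool)
        stain[:, :5] = True
        full = self._spot_with_mask([(0, 0), (0, 1)])          # overlap 1.0
        none = self._spot_with_mask([(0, 7), (0, 8)])          # overlap 0.0
        half = self._spot_with_mask([(0, 4), (0, 5)])          # overlap exactly 0.5
        labels = bq.classify_alleles([full, none, half], stain)
        assert labels == [ALLELE_XI, ALLELE_XA, ALLELE_XI]  # boundary is inclusive


class TestNormalizeToXa:
    def _cell(self, xi_ratios, xa_ratios):
        spots = [bq.SpotQuant(i + 1, 300, 300 * r, r, area=20, allele=ALLELE_XI)
                 for i, r in enumerate(xi_ratios)]
        spots += [bq.SpotQuant(len(spots) + i + 1, 300, 300 * r, r, area=20,
                               allele=ALLELE_XA) for i, r in enumerate(xa_ratios)]
        return bq.CellQuant("c", "WT", float(np.mean(xi_ratios + xa_ratios)),
                            len(spots), spots=spots)

    def test_ratio_to_mean_xa(self):
        out = bq.normalize_to_xa(self._cell([0.8], [0.4, 0.4]))
        vals = {s.allele: [] for s in out.spots}
        for s in out.spots:
            vals[s.allele].append(s.xa_normalized)
        assert vals[ALLELE_XI] == [pytest.approx(2.0)]
        assert vals[ALLELE_XA] == [pytest.approx(1.0), pytest.approx(1.0)]

    def test_no_enrichment_null(self):
        out = bq.normalize_to_xa(self._cell([0.3], [0.3, 0.3]))
        assert all(s.xa_normalized == pytest.approx(1.0) for s in out.spots)

    def test_xa_anchor_property(self):
        out = bq.normalize_to_xa(self._cell([0.9, 1.1], [0.2, 0.5, 0.35]))
        xa = [s.xa_normalized for s in out.spots if s.allele == ALLELE_XA]
        assert np.mean(xa) == pytest.approx(1.0, abs=1e-12)

    def test_missing_allele_classes_excluded(self):
        with pytest.raises(ExclusionError) as err:
            bq.normalize_to_xa(self._cell([0.8], []))
        assert err.value.reason == "no_xa_spot"
        with pytest.raises(ExclusionError) as err:
            bq.normalize_to_xa(self._cell([], [0.4]))
        assert err.value.reason == "no_xi_spot"

    def test_degenerate_xa_mean_excluded(self):
        with pytest.raises(ExclusionError) as err:
            bq.normalize_to_xa(self._cell([0.8], [0.0, 0.0]))
        assert err.value.reason == "degenerate_xa_mean"

    def test_simulated_enrichment_recovered_exactly_at_small_contamination(self):
        """Noiseless Xi render with 2x BiAD enrichment recovers ~2.0 via Xa anchor."""
        cfg = bq.SimulationConfig(
            n_loci=3, n_xi=1, biad_enrichment=2.0, biad_gain=0.25,
            noise=bq.NoiseConfig.off(), seed=21,
        )
        sim = bq.simulate_cell(cfg)
        cq = quantify_sim(sim, cfg, options=bq.QuantifyOptions(allelic=True))
        out = bq.normalize_to_xa(cq)
        xi = [s.xa_normalized for s in out.spots if s.allele == ALLELE_XI]
        # nuclear-mean spot contamination (<3% of nucleus area) bounds the bias
        assert xi[0] == pytest.approx(2.0, rel=0.05)


class TestNormalizeToControl:
    def _table(self, rows):
        return bq.ExperimentTable(rows=[
            bq.CellQuant(f"c{i}", cond, val, 1, treatment=arm)
            for i, (cond, arm, val) in enumerate(rows)
        ])

    def test_ratio_to_control_mean(self):
        rows = [("WT", "mock", 0.6)] + [("R44Q", "mock", v) for v in (0.2, 0.2, 0.2)]
        out = bq.normalize_to_control(self._table(rows), "R44Q")
        wt = [r.control_normalized for r in out.rows if r.condition == "WT"]
        assert wt == [pytest.approx(3.0)]

    def test_control_anchor_per_arm(self):
        rows = [("R44Q", "mock", v) for v in (0.1, 0.2, 0.3)] + \
               [("R44Q", "drug", v) for v in (0.4, 0.5, 0.6)]
        out = bq.normalize_to_control(self._table(rows), "R44Q")
        for arm in ("mock", "drug"):
            vals = [r.control_normalized for r in out.rows
                    if r.treatment == arm and r.condition == "R44Q"]
            assert np.mean(vals) == pytest.approx(1.0, abs=1e-12)

    def test_two_arms_match_grouped_mean_oracle(self, rng):
        rows = []
        for arm in ("mock", "drug"):
            for v in rng.random(5):
                rows.append(("WT", arm, float(v)))
            for v in rng.random(4) + 0.1:
                rows.append(("R44Q", arm, float(v)))
        table = self._table(rows)
        out = bq.normalize_to_control(table, "R44Q")
        # loop oracle
        expected = {}
        for arm in ("mock", "drug"):
            ctrl = [v for c, a, v in rows if a == arm and c == "R44Q"]
            m = sum(ctrl) / len(ctrl)
            for i, (c, a, v) in enumerate(rows):
                if a == arm:
                    expected[f"c{i}"] = v / m
        for r in out.rows:
            assert r.control_normalized == pytest.approx(expected[r.cell_id], rel=1e-12)

    def test_too_few_control_cells_rejected(self):
        rows = [("WT", "mock", 0.6), ("R44Q", "mock", 0.2)]
        with pytest.raises(bq.ConfigurationError):
            bq.normalize_to_control(self._table(rows), "R44Q")

    def test_degenerate_control_refused(self):
        rows = [("R44Q", "mock", 0.0)] * 3 + [("WT", "mock", 0.5)]
        table = bq.ExperimentTable(rows=[
            bq.CellQuant(f"c{i}", cond, val, 1, treatment=arm)
            for i, (cond, arm, val) in enumerate(rows)
        ])
        with pytest.raises(ExclusionError) as err:
            bq.normalize_to_control(table, "R44Q")
        assert err.value.reason == "degenerate_control"


class TestSpotQcSummary:
    def test_histogram(self):
        rows = [bq.CellQuant(f"c{i}", "WT", 0.5, n,
                             spots=[bq.SpotQuant(j + 1, 300, 150, 0.5, area=25)
                                    for j in range(n)])
                for i, n in enumerate([2, 3, 4])]
        out = bq.spot_qc_summary(bq.ExperimentTable(rows=rows))
        rec = out.set_index("condition").loc["WT"]
        assert (rec["count_2"], rec["count_3"], rec["count_4"]) == (1, 1, 1)
        assert rec["count_0"] == 0 and rec["mean_spot_area"] == 25.0

    def test_determinism_across_identical_conditions(self):
        def rows(cond):
            return [bq.CellQuant(f"{cond}{i}", cond, 0.5, 2,
                                 spots=[bq.SpotQuant(1, 300, 150, 0.5, area=20),
                                        bq.SpotQuant(2, 300, 150, 0.5, area=30)])
                    for i in range(3)]
        out = bq.spot_qc_summary(bq.ExperimentTable(rows=rows("A") + rows("B")))
        a = out[out.condition == "A"].drop(columns="condition").reset_index(drop=True)
        b = out[out.condition == "B"].drop(columns="condition").reset_index(drop=True)
        assert a.equals(b)

    def test_modal_spot_count_matches_polyploidy(self):
        """n_loci=3 simulations: modal detected spot count is 3."""
        cfg = bq.SimulationConfig(n_loci=3, noise=bq.NoiseConfig.off(), seed=9)
        counts = []
        from biadquant.simulate import simulate_experiment
        from biadquant.pipeline import run_quantify

        cells, sheet, _ = simulate_experiment({"WT": cfg}, 40, seed=9)
        table, _ = run_quantify([(cid, s.image) for cid, s in cells], sheet)
        out = bq.spot_qc_summary(table)
        rec = out.set_index("condition").loc["WT"]
        hist = {k: rec[f"count_{k}"] for k in range(7)}
        assert max(hist, key=hist.get) == 3


class TestRatioInvariances:
    def test_gain_and_offset_invariance(self, noiseless_cell, noiseless_config):
        base = quantify_sim(noiseless_cell, noiseless_config)
        img = noiseless_cell.image
        from biadquant.simulate import suggested_thresholds
        nt, st = suggested_thresholds(noiseless_config)

        # common multiplicative gain on both channels: ratios unchanged
        g = 2.5
        scaled = CellImage(channels={r: p * g for r, p in img.channels.items()})
        thr = bq.ThresholdPair(nt * g, st * g)
        cq = bq.quantify_cell(scaled, thr, condition="sim")
        for s0, s1 in zip(base.spots, cq.spots):
            assert s1.relative_biad == pytest.approx(s0.relative_biad, rel=1e-12)

        # uniform additive offset on either channel: background subtraction cancels it
        shifted = CellImage(channels={
            M: img.channels[M] + 17.0, B: img.channels[B] + 31.0})
        thr = bq.ThresholdPair(nt + 17.0, st + 17.0)
        cq = bq.quantify_cell(shifted, thr, condition="sim")
        for s0, s1 in zip(base.spots, cq.spots):
            assert s1.relative_biad == pytest.approx(s0.relative_biad, rel=1e-9)

    def test_biad_only_gain_scales_ratio_linearly(self, noiseless_cell, noiseless_config):
        base = quantify_sim(noiseless_cell, noiseless_config)
        img = noiseless_cell.image
        from biadquant.simulate import suggested_thresholds
        thr = bq.ThresholdPair(*suggested_thresholds(noiseless_config))
        g = 3.0
        scaled = CellImage(channels={M: img.channels[M], B: img.channels[B] * g})
        cq = bq.quantify_cell(scaled, thr, condition="sim")
        for s0, s1 in zip(base.spots, cq.spots):
            assert s1.relative_biad == pytest.approx(g * s0.relative_biad, rel=1e-12)

    def test_copy_number_invariance(self):
        """Doubling copy number doubles corrected marker but leaves the ratio fixed."""
        ratios, markers = [], []
        for cn in (80, 160, 320):
            cfg = bq.SimulationConfig(copy_number=cn, biad_gain=0.5,
                                      noise=bq.NoiseConfig.off(), seed=13)
            sim = bq.simulate_cell(cfg)
            cq = quantify_sim(sim, cfg)
            ratios.append(cq.mean_relative_biad)
            markers.append(np.mean([s.corrected_marker for s in cq.spots]))
        assert all(r == pytest.approx(0.5, rel=1e-10) for r in ratios)
        assert markers[0] < markers[1] < markers[2]
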