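"""Atom% estimator, natural-abundance calibration, enrichment classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symbiotrace.isotope_quant import (
    NaturalAbundanceCalibration,
    QuantError,
    ROIQuant,
    activity_summary,
    atom_percent,
    calibrate_natural_abundance,
    classify_enrichment,
    quantify_rois,
)
from symbiotrace.segmentation import extract_rois, segment_cell, segment_compartments
from symbiotrace.synthetic_data import (
    SimConfig,
    simulate_control_counts,
    simulate_population,
)


class TestAtomPercent:
    def test_zero_heavy_counts(self):
        assert atom_percent(0, 1000).atom_pct == 0.0

    def test_natural_abundance_scale(self):
        # 377 heavy in 100_000 total: the magnitude of unlabeled 15N controls
        ap = atom_percent(377, 99623)
        assert ap.atom_pct == pytest.approx(0.377, rel=1e-12)

    def test_symmetric_counts_and_binomial_se(self):
        ap = atom_percent(500, 500)
        assert ap.atom_pct == 50.0
        assert ap.se_pct == pytest.approx(100 * math.sqrt(0.25 / 1000), rel=1e-12)

    def test_zero_total_flagged_undefined_not_raised(self):
        ap = atom_percent(0, 0)
        assert not ap.defined
        assert math.isnan(ap.atom_pct)

    def test_negative_counts_rejected(self):
        with pytest.raises(QuantError):
            atom_percent(-1, 5)

    @given(
        heavy=st.integers(1, 10**6),
        light=st.integers(1, 10**6),
        k=st.integers(2, 100),
    )
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance(self, heavy, light, k):
        """Scaling both counts by k preserves atom% and shrinks SE by sqrt(k)."""
        a = atom_percent(heavy, light)
        b = atom_percent(k * heavy, k * light)
        assert b.atom_pct == pytest.approx(a.atom_pct, rel=1e-9)
        assert b.se_pct == pytest.approx(a.se_pct / math.sqrt(k), rel=1e-9)

    @given(heavy=st.integers(0, 10**6), light=st.integers(0, 10**6))
    @settings(max_examples=100, derandomize=True)
    def test_bounds(self, heavy, light):
        ap = atom_percent(heavy, light)
        if ap.defined:
            assert 0.0 <= ap.atom_pct <= 100.0
            assert ap.se_pct >= 0.0


class TestQuantifyRois:
    def test_single_pixel_roi_equals_atom_percent(self, segmented_cell):
        image, truth, mask = segmented_cell
        from symbiotrace.sims_io import ROI

        r, c = 64, 64  # a host pixel near the center
        roi = ROI(truth.cell_id, "host_N", 0,
                  (np.array([r]), np.array([c])), image.pixel_size)
        q = quantify_rois(image, [roi])[0]
        ap = atom_percent(int(image.data["C15N"][r, c]), int(image.data["C14N"][r, c]))
        assert q.atom15N_pct == pytest.approx(ap.atom_pct, abs=1e-12)

    def test_diazoplast_estimate_within_3se_of_truth(self, segmented_cell):
        image, truth, mask = segmented_cell
        rois = extract_rois(mask, image.pixel_size, cell_id=truth.cell_id)
        quants = quantify_rois(image, rois)
        true_pct = 100 * truth.atom_frac_15N["diazoplast"]
        for q in quants:
            if q.compartment == "diazoplast":
                assert abs(q.atom15N_pct - true_pct) < 3 * q.se15N_pct

    def test_storage_has_largest_c2_density(self, segmented_cell):
        image, truth, mask = segmented_cell
        rois = extract_rois(mask, image.pixel_size, cell_id=truth.cell_id)
        quants = quantify_rois(image, rois)
        dens = {}
        for q in quants:
            c2 = q.counts["C2"] + q.counts["C13C"]
            dens.setdefault(q.compartment, []).append(c2 / q.area_px)
        assert min(dens["host_minusN"]) > max(dens["host_N"] + dens["diazoplast"])

    def test_missing_channels_leave_isotope_unavailable(self, segmented_cell):
        image, truth, mask = segmented_cell
        from symbiotrace.sims_io import IonCountImage

        n_only = IonCountImage(
            {ch: image.data[ch] for ch in ("C14N", "C15N")}, image.pixel_size
        )
        rois = extract_rois(mask, image.pixel_size, cell_id=truth.cell_id)
        q = quantify_rois(n_only, rois)[0]
        assert q.defined("15N") and not q.defined("13C")


def _control_quants(n=30, atom_fraction=0.00377, total=1e6, seed=0, isotope="15N"):
    heavy_ch, light_ch = ("C15N", "C14N") if isotope == "15N" else ("C13C", "C2")
    df = simulate_control_counts(n, atom_fraction, total, seed=seed)
    out = []
    for r in df.itertuples():
        ap = atom_percent(int(r.heavy), int(r.light))
        q = ROIQuant("ctrl", int(r.roi_id), "host_N", 1,
                     counts={heavy_ch: int(r.heavy), light_ch: int(r.light)})
        if isotope == "15N":
            q.atom15N_pct, q.se15N_pct = ap.atom_pct, ap.se_pct
        else:
            q.atom13C_pct, q.se13C_pct = ap.atom_pct, ap.se_pct
        out.append(q)
    return out


class TestCalibration:
    def test_constant_controls_give_zero_sd_threshold(self):
        quants = []
        for i in range(5):
            q = ROIQuant("c", i, "host_N", 1)
            q.atom15N_pct = 0.377
            quants.append(q)
        cal = calibrate_natural_abundance(quants, "15N")
        assert cal.threshold_pct == pytest.approx(0.377)

    def test_threshold_is_mean_plus_three_sd(self):
        cal = NaturalAbundanceCalibration("15N", 0.377, 0.012, 10)
        assert cal.threshold_pct == pytest.approx(0.413)

    def test_recovers_control_baseline(self):
        cal = calibrate_natural_abundance(_control_quants(seed=3), "15N")
        pooled_se = 0.0194 / math.sqrt(30)  # per-ROI binomial SE at 1e6 counts
        assert abs(cal.mean_pct - 0.377) < 3 * pooled_se

    def test_requires_three_controls(self):
        with pytest.raises(QuantError):
            calibrate_natural_abundance(_control_quants(n=2), "15N")

    def test_ratio_of_sums_close_to_calibration_mean(self):
        quants = _control_quants(seed=4)
        cal = calibrate_natural_abundance(quants, "15N")
        heavy = sum(q.counts["C15N"] for q in quants)
        light = sum(q.counts["C14N"] for q in quants)
        pooled = atom_percent(heavy, light)
        assert abs(pooled.atom_pct - cal.mean_pct) < 3 * pooled.se_pct


class TestClassification:
    cal = NaturalAbundanceCalibration("15N", 0.377, 0.012, 10)

    def test_at_threshold_not_enriched(self):
        q = ROIQuant("c", 0, "diazoplast", 1)
        q.atom15N_pct = self.cal.threshold_pct
        assert classify_enrichment(q, self.cal) is False

    def test_clearly_enriched(self):
        q = ROIQuant("c", 0, "diazoplast", 1)
        q.atom15N_pct = 1.2
        assert classify_enrichment(q, self.cal) is True

    def test_undefined_atom_percent_unclassified(self):
        q = ROIQuant("c", 0, "diazoplast", 1)
        assert classify_enrichment(q, self.cal) is None

    def test_monotone_in_atom_percent(self):
        calls = []
        for pct in np.linspace(0.3, 1.0, 30):
            q = ROIQuant("c", 0, "diazoplast", 1)
            q.atom15N_pct = float(pct)
            calls.append(classify_enrichment(q, self.cal))
        assert calls == sorted(calls)  # False before True, single switch

    def test_inactive_cells_rarely_misclassified(self):
        """Unlabeled controls stay below the mean+3SD threshold in >=99% of draws."""
        quants = _control_quants(n=200, seed=5)
        cal = calibrate_natural_abundance(_control_quants(n=30, seed=6), "15N")
        calls = [classify_enrichment(q, cal) for q in quants]
        assert sum(calls) / len(calls) <= 0.01


class TestActivitySummary:
    def _summarize(self, frac_active, n_cells, seed):
        cfg = SimConfig(frac_active=frac_active, seed=seed)
        from symbiotrace.pipeline import analyze_population
        from symbiotrace.segmentation import SegmentationParams
        from symbiotrace.synthetic_data import simulate_control_population

        pop = simulate_population(cfg, n_cells)
        ctrl = simulate_control_population(SimConfig(seed=seed + 1), 10)
        res = analyze_population(pop, ctrl, SegmentationParams())
        return pop, activity_summary(res["quants"], res["cal15"], res["cal13"])

    def test_all_inactive_population_gives_zero_fraction(self):
        pop, summary = self._summarize(0.0, 8, seed=21)
        assert summary.frac_active_15N == 0.0

    def test_recovers_realized_active_fraction(self):
        pop, summary = self._summarize(0.7, 40, seed=22)
        realized = sum(t.active for _, t in pop) / len(pop)
        lo, hi = summary.ci_active_15N
        assert lo <= realized <= hi
        # classification tracks ground truth cell-by-cell up to ~1 flip
        assert abs(summary.frac_active_15N - realized) <= 1 / len(pop)

    def test_both_quadrant_is_modal_under_dual_labeling(self):
        pop, summary = self._summarize(0.7, 40, seed=23)
        co = summary.co_table
        assert co.loc[True, True] == co.values.max()

    def test_no_diazoplast_anywhere_raises(self):
        q = ROIQuant("c", 0, "host_N", 1)
        q.atom15N_pct = 0.4
        cal = NaturalAbundanceCalibration("15N", 0.377, 0.012, 10)
        with pytest.raises(QuantError):
            activity_summary([q], cal)
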