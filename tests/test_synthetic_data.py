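"""Generator correctness: geometry, Poisson count model, population structure."""

import math

import numpy as np
import pytest
from skimage.measure import label as cc_label

from symbiotrace.sims_io import CLASS_BACKGROUND, CLASS_DIAZOPLAST, CLASS_HOST_MINUS_N, CLASS_HOST_N
from symbiotrace.synthetic_data import (
    GeometryError,
    SimConfig,
    make_cell_geometry,
    simulate_bulk_irms,
    simulate_cell_records,
    simulate_diel_ara,
    simulate_ion_image,
    simulate_population,
    simulate_qpcr,
)


class TestGeometry:
    def test_degenerate_geometry_has_only_host_and_background(self):
        cfg = SimConfig(n_diazoplasts=0, vacuole_fraction=0.0, seed=1)
        truth = make_cell_geometry(cfg)
        assert set(np.unique(truth.labels)) == {CLASS_BACKGROUND, CLASS_HOST_N}

    def test_diazoplast_count_matches_config(self, config):
        truth = make_cell_geometry(config)
        _, n = cc_label(truth.labels == CLASS_DIAZOPLAST, return_num=True)
        assert n == config.n_diazoplasts == 4

    def test_volume_ratio_matches_closed_form(self, config):
        # 4 spheres r=1.55 µm inside a 10 x 5 µm prolate spheroid:
        # 4 r^3 / (a b^2) = 4 * 1.55^3 / 250 ≈ 0.0596
        truth = make_cell_geometry(config)
        expected = 4 * 1.55**3 / (10.0 * 5.0**2)
        ratio = truth.volumes_um3["diazoplast"] / truth.volumes_um3["host_total"]
        assert ratio == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.06, abs=0.005)

    def test_labels_partition_the_grid(self, config):
        truth = make_cell_geometry(config)
        counts = {c: int((truth.labels == c).sum()) for c in np.unique(truth.labels)}
        assert sum(counts.values()) == truth.labels.size

    def test_infeasible_geometry_raises(self):
        cfg = SimConfig(n_diazoplasts=4, diazoplast_radius=4.0, seed=0)
        with pytest.raises(GeometryError):
            make_cell_geometry(cfg)

    def test_geometry_deterministic_under_seed(self, config):
        a = make_cell_geometry(config, 3)
        b = make_cell_geometry(config, 3)
        assert np.array_equal(a.labels, b.labels)


class TestIonImage:
    def test_zero_density_gives_all_zero_image(self, config):
        cfg = SimConfig(
            count_density={k: {"CN": 0.0, "C2": 0.0} for k in
                           ("diazoplast", "host_N", "host_minusN", "background")},
            seed=2,
        )
        truth = make_cell_geometry(cfg)
        img = simulate_ion_image(truth, cfg)
        assert all(arr.sum() == 0 for arr in img.data.values())

    def test_pooled_isotope_ratio_converges_to_truth(self, config):
        # law of large numbers: pooled C15N/(C14N+C15N) over all diazoplast
        # pixels lies within 3 binomial SEs of the true atom fraction
        truth = make_cell_geometry(config)
        img = simulate_ion_image(truth, config, rng=np.random.default_rng(5))
        d = truth.labels == CLASS_DIAZOPLAST
        heavy = img.data["C15N"][d].sum()
        total = heavy + img.data["C14N"][d].sum()
        p_true = truth.atom_frac_15N["diazoplast"]
        se = math.sqrt(p_true * (1 - p_true) / total)
        assert abs(heavy / total - p_true) < 3 * se

    def test_storage_compartment_low_cn_high_c2(self, config):
        truth = make_cell_geometry(config)
        img = simulate_ion_image(truth, config, rng=np.random.default_rng(6))
        cn = img.data["C14N"] + img.data["C15N"]
        c2 = img.data["C2"] + img.data["C13C"]
        storage = truth.labels == CLASS_HOST_MINUS_N
        host = truth.labels == CLASS_HOST_N
        bg = truth.labels == CLASS_BACKGROUND
        assert cn[storage].mean() < 0.2 * cn[host].mean()
        assert c2[storage].mean() > 2 * c2[host].mean()
        assert c2[storage].mean() > 10 * c2[bg].mean()

    def test_pooled_counts_converge_to_density(self, config):
        truth = make_cell_geometry(config)
        img = simulate_ion_image(truth, config, rng=np.random.default_rng(7))
        for comp, code in (("diazoplast", CLASS_DIAZOPLAST), ("host_N", CLASS_HOST_N)):
            m = truth.labels == code
            total = (img.data["C14N"][m] + img.data["C15N"][m]).sum()
            expected = config.count_density[comp]["CN"] * m.sum()
            assert abs(total - expected) / expected < 3 / math.sqrt(expected)


class TestPopulation:
    def test_all_inactive_when_frac_active_zero(self):
        cfg = SimConfig(frac_active=0.0, seed=3)
        pop = simulate_population(cfg, 5)
        for _, truth in pop:
            assert not truth.active
            assert truth.atom_frac_15N["diazoplast"] == pytest.approx(cfg.baseline_15N)

    def test_realized_active_fraction_within_binomial_bounds(self):
        cfg = SimConfig(frac_active=0.7, seed=4)
        pop = simulate_population(cfg, 200)
        k = sum(t.active for _, t in pop)
        se = math.sqrt(0.7 * 0.3 / 200)
        assert abs(k / 200 - 0.7) < 1.96 * se + 1e-12

    def test_host_excess_is_host_ratio_times_diazoplast_excess(self, config):
        pop = simulate_population(config, 20)
        for _, t in pop:
            if t.active:
                assert t.excess_15N_host == pytest.approx(
                    config.host_ratio * t.excess_15N_diazoplast, rel=1e-12
                )

    def test_population_bit_identical_under_seed(self, config):
        a = simulate_population(config, 3)
        b = simulate_population(config, 3)
        for (ia, ta), (ib, tb) in zip(a, b):
            assert np.array_equal(ta.labels, tb.labels)
            for ch in ia.channels:
                assert np.array_equal(ia.data[ch], ib.data[ch])


class TestAssaySimulators:
    def test_noise_free_irms_returns_true_delta(self):
        vals = simulate_bulk_irms(-19.0, 0.0, 5, seed=1)
        assert np.allclose(vals, -19.0)

    def test_irms_sample_mean_near_truth(self):
        vals = simulate_bulk_irms(-19.0, 2.0, 100, seed=2)
        assert abs(vals.mean() - (-19.0)) < 3 * 2.0 / math.sqrt(100)

    def test_irms_rejects_negative_noise(self):
        with pytest.raises(ValueError):
            simulate_bulk_irms(0.0, -1.0, 3)

    def test_diel_treated_mean_scales_with_factor(self):
        control, treated = simulate_diel_ara(
            [10, 12, 11, 9], treatment_factor=0.4, noise_cv=0.0, n_replicates=3, seed=5
        )
        assert treated.data["rate"].mean() == pytest.approx(
            0.4 * control.data["rate"].mean()
        )

    def test_diel_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            simulate_diel_ara([1.0, -1.0])

    def test_qpcr_noise_free_delta_cq_matches_log_fold(self):
        df = simulate_qpcr(10.0, efficiency=2.0, noise_sd=0.0, n=2, seed=6)
        day = df[df.condition == "day"]
        night = df[df.condition == "night"]
        dcq = night["Cq_target"].mean() - day["Cq_target"].mean()
        assert dcq == pytest.approx(-math.log2(10.0), abs=1e-9)

    def test_qpcr_rejects_nonpositive_fold(self):
        with pytest.raises(ValueError):
            simulate_qpcr(0.0)


class TestRecords:
    def test_cell_records_noise_free_are_exactly_proportional(self):
        df = simulate_cell_records(20, host_ratio=0.9, rel_noise=0.0, seed=7)
        assert np.allclose(df.x_h, 0.9 * df.x_d)
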