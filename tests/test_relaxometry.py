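"""EPG forward model, dictionary matching, fat T2, and Dixon separation."""

import numpy as np
import pytest
from _oracles import oracle_epg_train

from myodyn import relaxometry as rx
from myodyn import synthetic

PROTOCOL = rx.MeseProtocol()
SHORT = rx.MeseProtocol(echo_times=tuple(10.9 * (i + 1) for i in range(5)))


class TestSliceProfile:
    def test_single_bin_is_ideal(self):
        assert rx.slice_profile(1) == [(1.0, 1.0)]

    def test_weights_sum_to_one(self):
        for n in (3, 17, 51):
            assert sum(w for _, w in rx.slice_profile(n)) == pytest.approx(1)

    def test_profile_monotone_from_center(self):
        scales = [s for s, _ in rx.slice_profile(51)]
        assert scales[0] == pytest.approx(1.0)
        assert all(a >= b for a, b in zip(scales, scales[1:]))
        assert scales[-1] < scales[0]


class TestEpgForward:
    def test_ideal_refocusing_matches_exponential(self):
        """180-degree single-bin train must equal exp(-TE/T2) to 1e-10;
        first echo for T2 = 35 ms is exp(-10.9/35) = 0.7324."""
        e = rx.epg_mese_forward(35.0, 1400.0, PROTOCOL, 1.0, n_bins=1)
        expected = np.exp(-np.asarray(PROTOCOL.echo_times) / 35.0)
        np.testing.assert_allclose(e, expected, atol=1e-10)
        assert e[0] == pytest.approx(np.exp(-10.9 / 35.0), abs=1e-10)

    def test_infinite_t2_all_echoes_equal(self):
        e = rx.epg_mese_forward(1e12, 1e15, PROTOCOL, 1.0, n_bins=1)
        np.testing.assert_allclose(e, e[0], rtol=1e-6)

    def test_reduced_refocusing_matches_independent_oracle(self):
        mine = rx.epg_mese_forward(35.0, 1400.0, SHORT, 0.66, n_bins=1)
        orc = oracle_epg_train(np.pi / 2, np.pi * 0.66, 5, 10.9,
                               1400.0, 35.0)
        np.testing.assert_allclose(mine, orc, atol=1e-12)

    def test_reduced_refocusing_slows_apparent_decay(self):
        """Stimulated-echo pathways at 120 deg store magnetization along z,
        so the tail decays slower than pure T2."""
        e = rx.epg_mese_forward(35.0, 1400.0, PROTOCOL, 0.66, n_bins=1)
        ref = np.exp(-np.asarray(PROTOCOL.echo_times) / 35.0)
        assert e[-1] / e[1] > ref[-1] / ref[1]

    def test_t2_longer_than_t1_warns(self):
        with pytest.warns(RuntimeWarning, match="T2 exceeds T1"):
            rx.epg_mese_forward(500.0, 100.0, SHORT, 1.0, n_bins=1)

    def test_vectorized_matches_scalar(self):
        grid = np.array([20.0, 35.0, 60.0])
        vec = rx.epg_mese_forward(grid, 1400.0, SHORT, 0.8)
        for j, t2 in enumerate(grid):
            np.testing.assert_allclose(
                vec[:, j], rx.epg_mese_forward(t2, 1400.0, SHORT, 0.8))


class TestDualCompartment:
    def test_pure_water_and_pure_fat_limits(self):
        p = PROTOCOL
        w = (1 - np.exp(-p.tr / p.t1_water)) * rx.epg_mese_forward(
            35.0, p.t1_water, p)
        f = (1 - np.exp(-p.tr / p.t1_fat)) * rx.epg_mese_forward(
            150.0, p.t1_fat, p)
        np.testing.assert_allclose(
            rx.dual_compartment_signal(0.0, 35.0, 150.0, p), w)
        np.testing.assert_allclose(
            rx.dual_compartment_signal(1.0, 35.0, 150.0, p), f)

    def test_degenerate_compartments_reduce_to_single(self):
        p = rx.MeseProtocol(t1_water=1000.0, t1_fat=1000.0)
        s = rx.dual_compartment_signal(0.5, 40.0, 40.0, p)
        single = (1 - np.exp(-p.tr / 1000.0)) * rx.epg_mese_forward(
            40.0, 1000.0, p)
        np.testing.assert_allclose(s, single, rtol=1e-12)

    def test_ff_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rx.dual_compartment_signal(1.2, 35.0, 150.0, PROTOCOL)


@pytest.fixture(scope="module")
def dictionary():
    return rx.build_dictionary(PROTOCOL, fat_t2=150.0)


class TestDictionary:
    def test_rows_unit_norm_and_grid_unique(self, dictionary):
        norms = np.linalg.norm(dictionary.signals, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)
        pairs = set(zip(dictionary.wt2.tolist(), dictionary.ff.tolist()))
        assert len(pairs) == dictionary.signals.shape[0]

    def test_dictionary_entry_matches_itself(self, dictionary):
        sig = rx.dual_compartment_signal(0.04, 35.0, 150.0, PROTOCOL)
        wt2, ff, sim = rx.match_dictionary(sig, dictionary)
        assert (wt2, ff) == (35.0, 0.04)
        assert sim == pytest.approx(1.0, abs=1e-9)

    def test_matching_scale_invariant(self, dictionary):
        sig = rx.dual_compartment_signal(0.10, 42.0, 150.0, PROTOCOL)
        a = rx.match_dictionary(sig, dictionary)
        b = rx.match_dictionary(5.0 * sig, dictionary)
        assert (a[0], a[1]) == (b[0], b[1])
        assert a[2] == pytest.approx(b[2], abs=1e-12)

    def test_zero_voxel_flagged(self, dictionary):
        wt2, ff, sim = rx.match_dictionary(np.zeros(17), dictionary)
        assert np.isnan(wt2) and np.isnan(ff)

    def test_noisy_recovery_median_unbiased(self, dictionary):
        """Rician noise at SNR 50 (first-echo referenced): the median
        recovered wT2 over 100 seeded draws stays within 1 ms of truth."""
        sig = rx.dual_compartment_signal(0.04, 35.0, 150.0, PROTOCOL)
        sd = sig[0] / 50.0
        rec = []
        for i in range(100):
            noisy = synthetic.simulate_mese_signal(
                0.04, 35.0, 150.0, noise_sd=sd, seed=5000 + i)
            w, _, _ = rx.match_dictionary(noisy, dictionary, noise_sd=sd)
            rec.append(w)
        assert abs(np.median(rec) - 35.0) <= 1.0


class TestFatT2:
    def test_on_grid_self_consistency(self):
        sig = np.tile(rx.epg_mese_forward(150.0, PROTOCOL.t1_fat, PROTOCOL),
                      (12, 1))
        assert rx.estimate_fat_t2(sig, PROTOCOL) == 150.0

    def test_off_grid_rounds_to_nearest(self):
        sig = np.tile(rx.epg_mese_forward(152.7, PROTOCOL.t1_fat, PROTOCOL),
                      (12, 1))
        assert rx.estimate_fat_t2(sig, PROTOCOL) == 153.0

    def test_too_few_voxels_advises_default(self):
        sig = np.ones((3, 17))
        with pytest.raises(ValueError, match="155"):
            rx.estimate_fat_t2(sig, PROTOCOL)


class TestWt2Map:
    def test_two_region_phantom_recovered(self, small_phantom):
        stack = synthetic.simulate_mese_volume(
            small_phantom,
            wt2_by_label={1: 35.0, 2: 50.0, 3: 35.0, 4: 35.0},
            ff_by_label={1: 0.04, 2: 0.04, 3: 0.04, 4: 0.90},
            fat_t2=150.0,
        )
        wt2, ff, sim, report = rx.fit_wt2_map(
            stack, small_phantom.label_volume,
            wt2_range=(20.0, 60.0, 0.2), ff_range=(0.0, 1.0, 0.01),
            fat_t2=150.0,
        )
        lab = small_phantom.label_volume
        assert np.nanmean(wt2[lab == 1]) == pytest.approx(35.0, abs=0.2)
        assert np.nanmean(wt2[lab == 2]) == pytest.approx(50.0, abs=0.2)
        assert np.nanmean(ff[lab == 1]) == pytest.approx(0.04, abs=0.01)
        assert report["voxels_fitted"] > 0

    def test_subcutaneous_calibration_used(self, small_phantom):
        # pure-fat subcutis: calibration recovers the generating fat T2
        stack = synthetic.simulate_mese_volume(
            small_phantom, ff_by_label={1: 0.04, 2: 0.04, 3: 0.04, 4: 1.0},
            fat_t2=150.0)
        _, _, _, report = rx.fit_wt2_map(
            stack, small_phantom.label_volume,
            wt2_range=(30.0, 40.0, 0.5), ff_range=(0.0, 1.0, 0.02),
        )
        assert report["fat_t2_ms"] == pytest.approx(150.0, abs=1.0)

    def test_subcutaneous_water_admixture_biases_calibration_low(
            self, small_phantom):
        """Realistic subcutis (~90% fat) contains short-T2 water, so the
        pure-fat calibration lands somewhat below the generating fat T2."""
        stack = synthetic.simulate_mese_volume(small_phantom, fat_t2=150.0)
        _, _, _, report = rx.fit_wt2_map(
            stack, small_phantom.label_volume,
            wt2_range=(30.0, 40.0, 0.5), ff_range=(0.0, 1.0, 0.02),
        )
        assert 125.0 <= report["fat_t2_ms"] <= 150.0

    def test_empty_mask_warns(self):
        stack = np.zeros((4, 4, 4, 17))
        with pytest.warns(RuntimeWarning, match="no voxels"):
            wt2, ff, sim, rep = rx.fit_wt2_map(
                stack, np.zeros((4, 4, 4), dtype=int), fat_t2=150.0,
                wt2_range=(30.0, 40.0, 1.0), ff_range=(0.0, 1.0, 0.1))
        assert np.isnan(wt2).all()

    def test_missing_subcutaneous_and_no_default_rejected(self):
        stack = np.ones((4, 4, 4, 17))
        labels = np.ones((4, 4, 4), dtype=int)  # soleus only
        with pytest.raises(ValueError, match="fat_t2"):
            rx.fit_wt2_map(stack, labels)


class TestDixon:
    def test_pure_water_zero_ff(self):
        sig = synthetic.simulate_dixon_volume(np.zeros((5, 5, 1)),
                                              psi_hz=0.0)
        ff, psi = rx.dixon_fat_fraction(sig)
        np.testing.assert_allclose(ff, 0.0, atol=1e-4)
        np.testing.assert_allclose(psi, 0.0, atol=0.1)

    @pytest.mark.parametrize("ff_true", [0.0, 0.05, 0.2, 0.4, 0.8, 1.0])
    def test_noise_free_recovery(self, ff_true):
        sig = synthetic.simulate_dixon_volume(np.full((4, 4, 1), ff_true),
                                              psi_hz=30.0)
        ff, psi = rx.dixon_fat_fraction(sig)
        assert np.abs(ff - ff_true).max() <= 0.01
        assert np.abs(psi - 30.0).max() <= 1.0

    def test_two_compartment_swap_corrected_by_region_growing(self):
        vol = np.zeros((10, 10, 1))
        vol[5:] = 0.85
        sig = synthetic.simulate_dixon_volume(vol, psi_hz=-40.0)
        ff, psi = rx.dixon_fat_fraction(sig)
        assert np.abs(ff - vol).max() <= 0.01
        assert np.abs(psi + 40.0).max() <= 1.0

    def test_magnitude_only_falls_back_with_warning(self):
        sig = synthetic.simulate_dixon_volume(np.full((3, 3, 1), 0.2))
        with pytest.warns(RuntimeWarning, match="magnitude"):
            ff, _ = rx.dixon_fat_fraction(np.abs(sig))
        assert np.abs(ff - 0.2).max() < 0.05

    def test_echo_count_validated(self):
        with pytest.raises(ValueError, match="echo count"):
            rx.dixon_fat_fraction(np.zeros((2, 2, 1, 4), dtype=complex))


class TestDixonProtocol:
    def test_fat_peak_amplitudes_normalized(self):
        p = rx.DixonProtocol()
        assert sum(a for _, a in p.fat_peaks) == pytest.approx(1.0)

    def test_minimum_echo_count(self):
        with pytest.raises(ValueError):
            rx.DixonProtocol(echo_times=(1.0, 2.0))
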