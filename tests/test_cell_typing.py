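import numpy as np
import pytest

from spikemap import (
    classify_ei,
    dip_test_isi,
    fano_factor,
    interpolate_waveform,
    measure_kinetics,
    spatial_crosscorrelogram,
)
from spikemap.cell_typing import WaveformKinetics
from spikemap._dip import dip_statistic

FS = 18000.0


def gaussian_trough(sigma_ms=0.1, peak_delay_ms=None, peak_ratio=0.0, span_ms=5.0):
    """Sampled inverted-Gaussian trough (optionally with a later positive peak)."""
    t = np.arange(-span_ms, span_ms + 1e-9, 1000.0 / FS)
    wf = -np.exp(-0.5 * (t / sigma_ms) ** 2)
    if peak_delay_ms is not None:
        wf += peak_ratio * np.exp(-0.5 * ((t - peak_delay_ms) / (peak_delay_ms / 2)) ** 2)
    return wf


class TestInterpolation:
    def test_exact_at_original_samples(self, rng):
        wf = rng.normal(size=50)
        t_ms, out = interpolate_waveform(wf, FS, 90000.0)
        orig_t = np.arange(50) * 1000.0 / FS
        for ti, vi in zip(orig_t, wf):
            j = np.argmin(np.abs(t_ms - ti))
            assert t_ms[j] == pytest.approx(ti, abs=1e-9)
            assert out[j] == pytest.approx(vi, abs=1e-9)

    def test_query_grid_is_5x_finer(self):
        t_ms, _ = interpolate_waveform(np.zeros(19), FS, 90000.0)
        assert np.diff(t_ms)[0] == pytest.approx(1000.0 / 90000.0)

    def test_sine_trough_located_to_one_query_sample(self):
        """1 kHz sine sampled at 18 kHz: spline trough within one 90 kHz sample
        of the analytic minimum at 3/4 period."""
        t = np.arange(0, 1.2e-3, 1 / FS)  # one trough at 0.75 ms in window
        wf = np.sin(2 * np.pi * 1000.0 * t)
        t_ms, out = interpolate_waveform(wf, FS, 90000.0)
        t_min = t_ms[np.argmin(out)]
        assert abs(t_min - 0.75) <= 1000.0 / 90000.0

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            interpolate_waveform(np.zeros(3), FS)


class TestKinetics:
    def test_fw_of_inverted_gaussian_closed_form(self):
        """FWHM of a Gaussian trough = 2 sqrt(2 ln 2) sigma."""
        wf = gaussian_trough(sigma_ms=0.1)
        t_ms, out = interpolate_waveform(wf, FS, 90000.0)
        kin = measure_kinetics(t_ms, out)
        assert kin.fw_ms == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 0.1, abs=0.012)

    def test_pp_matches_dense_grid_extrema(self):
        """Trough-to-peak of the summed biphasic shape equals the distance
        between its true extrema (dense-grid oracle on the analytic form)."""
        wf = gaussian_trough(sigma_ms=0.2, peak_delay_ms=0.5, peak_ratio=0.3)
        t_ms, out = interpolate_waveform(wf, FS, 90000.0)
        kin = measure_kinetics(t_ms, out)
        td = np.arange(-5.0, 5.0, 1e-4)
        dense = -np.exp(-0.5 * (td / 0.2) ** 2) + 0.3 * np.exp(
            -0.5 * ((td - 0.5) / 0.25) ** 2
        )
        i_tr = np.argmin(dense)
        pp_true = td[i_tr + np.argmax(dense[i_tr:])] - td[i_tr]
        assert kin.pp_ms == pytest.approx(pp_true, abs=2000.0 / 90000.0)

    def test_invariant_to_scale_and_offset(self):
        wf = gaussian_trough(sigma_ms=0.15, peak_delay_ms=0.6, peak_ratio=0.3)
        t_ms, out = interpolate_waveform(wf, FS, 90000.0)
        k0 = measure_kinetics(t_ms, out)
        k1 = measure_kinetics(t_ms, 7.5 * out + 3.0)
        assert k1.fw_ms == pytest.approx(k0.fw_ms, abs=1e-9)
        assert k1.pp_ms == pytest.approx(k0.pp_ms, abs=1e-9)

    def test_narrow_templates_faster_than_broad(self):
        """Every narrow/broad template pair orders FW and PP correctly."""
        from spikemap import make_spike_template

        for seed in range(30):
            r = np.random.default_rng(seed)
            nar, _ = make_spike_template("narrow", FS, r, amplitude_uv=100.0)
            bro, _ = make_spike_template("broad", FS, r, amplitude_uv=100.0)
            kins = []
            for wf in (nar, bro):
                t_ms, out = interpolate_waveform(wf, FS, 90000.0)
                kins.append(measure_kinetics(t_ms, out))
            assert kins[0].fw_ms < kins[1].fw_ms
            assert kins[0].pp_ms < kins[1].pp_ms

    def test_no_post_trough_peak_flags_unit(self):
        wf = gaussian_trough(sigma_ms=0.2)  # purely negative, no rebound
        t_ms, out = interpolate_waveform(wf, FS, 90000.0)
        kin = measure_kinetics(t_ms, out)
        assert not kin.valid and np.isnan(kin.pp_ms)


class TestClassifyEI:
    @staticmethod
    def _population(rng, n=200, narrow_frac=0.1):
        kins, truth = [], []
        for uid in range(n):
            if rng.random() < narrow_frac:
                fw, pp, lab = rng.uniform(0.25, 0.45), rng.uniform(0.3, 0.6), "I"
            else:
                fw, pp, lab = rng.uniform(0.7, 1.4), rng.uniform(0.8, 1.5), "E"
            kins.append(WaveformKinetics(uid, fw, pp, 0.0, pp))
            truth.append(lab)
        return kins, truth

    def test_fast_cluster_labeled_inhibitory(self, rng):
        kins, truth = self._population(rng)
        res = classify_ei(kins, k=2, seed=0)
        acc = np.mean([r.label == t for r, t in zip(res, truth)])
        assert acc >= 0.95
        assert sum(1 for r in res if r.label == "I") > 0

    def test_exactly_one_cluster_is_inhibitory(self, rng):
        kins, _ = self._population(rng)
        res = classify_ei(kins, k="auto", seed=0)
        i_clusters = {r.cluster for r in res if r.label == "I"}
        assert len(i_clusters) == 1

    def test_single_unit_raises(self):
        with pytest.raises(ValueError):
            classify_ei([WaveformKinetics(0, 0.5, 0.5, 0.0, 0.5)])

    def test_invariant_to_unit_order(self, rng):
        kins, _ = self._population(rng, n=60)
        res_a = {r.unit_id: r.label for r in classify_ei(kins, seed=0)}
        res_b = {r.unit_id: r.label for r in classify_ei(kins[::-1], seed=0)}
        assert res_a == res_b

    def test_invariant_to_affine_rescaling(self, rng):
        kins, _ = self._population(rng, n=80)
        scaled = [
            WaveformKinetics(k.unit_id, 1000 * k.fw_ms + 5, 1000 * k.pp_ms + 5, 0, 0)
            for k in kins
        ]
        res_a = {r.unit_id: r.label for r in classify_ei(kins, seed=0)}
        res_b = {r.unit_id: r.label for r in classify_ei(scaled, seed=0)}
        assert res_a == res_b


class TestFano:
    def test_constant_counts_give_zero(self):
        # 2 spikes in every 1 s bin over 4 s
        times = np.concatenate([k + np.array([0.2, 0.7]) for k in range(4)])
        ff = fano_factor(times, duration_s=4.0, bin_durations_ms=(1000.0,))
        assert ff[1000.0] == 0.0

    def test_unbiased_variance_formula(self):
        # counts [0, 4]: var(ddof=1) = 8, mean = 2 -> FF = 4
        times = np.array([1.1, 1.2, 1.3, 1.4])
        ff = fano_factor(times, duration_s=2.0, bin_durations_ms=(1000.0,))
        assert ff[1000.0] == pytest.approx(4.0)

    def test_poisson_calibration_mean_over_seeds(self):
        """Homogeneous Poisson (5 Hz, 600 s): mean FF across 20 seeds in
        [0.9, 1.1] at every default bin duration."""
        from spikemap.cell_typing import DEFAULT_FANO_BINS_MS

        acc = {T: [] for T in DEFAULT_FANO_BINS_MS}
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = r.poisson(5 * 600)
            times = np.sort(r.uniform(0, 600, n))
            ff = fano_factor(times, 600.0)
            for T, v in ff.items():
                acc[T].append(v)
        for T, vals in acc.items():
            assert 0.9 <= np.mean(vals) <= 1.1

    def test_periodic_train_ff_falls_with_bin_size(self):
        times = np.arange(0, 600, 0.2)  # perfectly periodic, 5 Hz
        ff = fano_factor(times, 600.0)
        assert ff[1000.0] < 0.01


class TestSpatialCorrelation:
    def test_identical_trains_correlate_fully(self, rng):
        t = np.sort(rng.uniform(0, 100, 500))
        trains = {0: t, 1: t.copy()}
        pos = {0: (0.0, 0.0), 1: (42.0, 0.0)}
        centers, mean_r, n = spatial_crosscorrelogram(trains, pos, 100.0)
        assert mean_r[n > 0][0] == pytest.approx(1.0)

    def test_independent_populations_near_zero(self):
        r = np.random.default_rng(3)
        trains = {i: np.sort(r.uniform(0, 200, 600)) for i in range(16)}
        pos = {i: (42.0 * (i % 4), 42.0 * (i // 4)) for i in range(16)}
        centers, mean_r, n = spatial_crosscorrelogram(trains, pos, 200.0)
        assert n.sum() >= 100
        assert np.all(np.abs(mean_r[n > 0]) < 0.05)

    def test_shared_drive_correlation_decays_with_distance(self):
        """Units driven by a common rate modulation shared with spatially
        decaying strength show non-increasing mean correlation vs distance."""
        r = np.random.default_rng(5)
        dur, bin_s = 400.0, 0.1
        n_bins = int(dur / bin_s)
        drive = r.gamma(2.0, 1.0, size=n_bins)
        xs = np.arange(8) * 42.0
        trains, pos = {}, {}
        for i, x in enumerate(xs):
            w = np.exp(-x / 60.0)
            lam = 5.0 * (w * drive / drive.mean() + (1 - w))
            counts = r.poisson(lam * bin_s)
            t = np.concatenate(
                [k * bin_s + r.uniform(0, bin_s, c) for k, c in enumerate(counts)]
            )
            trains[i] = np.sort(t)
            pos[i] = (x, 0.0)
        centers, mean_r, n = spatial_crosscorrelogram(trains, pos, 100.0)
        valid = mean_r[n > 0]
        # allow small sampling jitter between consecutive distance bins
        assert np.all(np.diff(valid) < 0.05)
        assert valid[0] > valid[-1]


class TestDip:
    def test_two_point_masses_reach_upper_bound(self):
        x = np.array([0.0] * 50 + [1.0] * 50)
        assert dip_statistic(x) == pytest.approx(0.25)

    def test_evenly_spaced_attains_lower_bound(self):
        n = 40
        assert dip_statistic(np.arange(n)) == pytest.approx(1 / (2 * n))

    def test_exponential_isis_read_as_unimodal(self):
        ok = 0
        for seed in range(25):
            r = np.random.default_rng(seed)
            times = np.cumsum(r.exponential(0.2, size=500))
            _, p, burst = dip_test_isi(times, n_boot=200, seed=seed)
            ok += p > 0.05
        assert ok / 25 >= 0.9

    def test_bimodal_isis_flag_bursting(self):
        ok = 0
        for seed in range(25):
            r = np.random.default_rng(seed)
            isis = np.concatenate([
                r.normal(0.005, 0.001, 250).clip(1e-4),
                r.normal(0.2, 0.02, 250).clip(1e-4),
            ])
            times = np.cumsum(r.permutation(isis))
            _, p, burst = dip_test_isi(times, n_boot=200, seed=seed)
            ok += burst
        assert ok / 25 >= 0.9

    def test_three_isis_raise(self):
        with pytest.raises(ValueError):
            dip_test_isi(np.array([0.0, 0.1, 0.2, 0.3]))
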