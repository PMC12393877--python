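import numpy as np
import pytest

from spikemap import (
    StimulusProtocol,
    compare_psth_conditions,
    compute_psth,
    evoked_zscore,
    summarize_classification,
)
from spikemap.cell_typing import CellTypeResult
from spikemap.opto_validation import ResponseSummary


@pytest.fixture
def protocol():
    return StimulusProtocol(
        epochs=[("baseline", 0.0, 120.0), ("opto-on", 120.0, 240.0), ("opto-off", 240.0, 360.0)],
        light_pulse_times_s=list(np.arange(120.0, 240.0, 10.0)),
        pulse_duration_ms=100.0,
    )


class TestProtocol:
    def test_overlapping_epochs_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol(epochs=[("a", 0, 10), ("b", 5, 15)])

    def test_yaml_round_trip(self, tmp_path, protocol):
        p = tmp_path / "protocol.yaml"
        protocol.to_yaml(p)
        back = StimulusProtocol.from_yaml(p)
        assert back.epochs == protocol.epochs
        assert back.light_pulse_times_s == protocol.light_pulse_times_s


class TestPSTH:
    def test_no_spikes_gives_zero_psth(self, protocol):
        edges, psth = compute_psth({0: np.empty(0)}, protocol)
        assert (psth[0] == 0).all()

    def test_single_locked_spike_lands_in_its_bin(self, protocol):
        pulses = np.asarray(protocol.light_pulse_times_s)
        trains = {0: pulses + 0.0125}  # one spike mid-bin after every pulse
        edges, psth = compute_psth(trains, protocol, bin_ms=5.0, window_s=(-0.1, 0.1))
        k = np.searchsorted(edges, 0.0125, side="right") - 1
        assert psth[0][k] == pytest.approx(1 / 0.005)
        assert psth[0].sum() == pytest.approx(psth[0][k])

    def test_integral_equals_mean_spikes_per_trial(self, protocol, rng):
        t = np.sort(rng.uniform(0, 360, 2000))
        edges, psth = compute_psth({0: t}, protocol, bin_ms=50.0, window_s=(-1, 3))
        pulses = np.asarray(protocol.light_pulse_times_s)
        per_trial = np.mean([
            ((t >= p + edges[0]) & (t < p + edges[-1] + 0.05)).sum() for p in pulses
        ])
        assert psth[0].sum() * 0.05 == pytest.approx(per_trial, rel=1e-9)

    def test_rate_step_recovered(self, protocol):
        """Poisson rate stepping 2 -> 10 Hz at pulse onset shows a plateau
        near 10 Hz after the step."""
        r = np.random.default_rng(0)
        pulses = np.asarray(protocol.light_pulse_times_s)
        t = []
        for p in pulses:
            t.append(p - 1 + np.sort(r.uniform(0, 1, r.poisson(2))))
            t.append(p + np.sort(r.uniform(0, 3, r.poisson(30))))
        trains = {0: np.sort(np.concatenate(t))}
        edges, psth = compute_psth(trains, protocol, bin_ms=250.0, window_s=(-1, 3))
        plateau = psth[0][edges >= 0].mean()
        n_tot = 12 * 30
        ci = 1.96 * np.sqrt(n_tot) / (12 * 3)
        assert plateau == pytest.approx(10.0, abs=ci)


class TestZScore:
    def test_response_equal_to_baseline_mean_gives_zero_z(self, protocol):
        # baseline bins alternate 1 and 3 spikes (mean 2 Hz, SD > 0);
        # the opto-on epoch fires at exactly 2 Hz
        base = np.concatenate(
            [k + (np.array([0.5]) if k % 2 == 0 else np.array([0.2, 0.5, 0.8]))
             for k in range(120)]
        )
        on = 120.0 + np.arange(0.25, 120.0, 0.5)
        r = evoked_zscore(np.concatenate([base, on]), protocol)
        assert r.z == pytest.approx(0.0, abs=1e-9)
        assert not r.responder

    def test_zero_baseline_sd_is_sentinel(self, protocol):
        r = evoked_zscore(np.arange(0.25, 360.0, 0.5), protocol)
        assert r.baseline_sd_hz == 0.0 or np.isfinite(r.z)
        silent = evoked_zscore(np.array([300.0, 301.0]), protocol)
        assert np.isnan(silent.z) and not silent.responder

    def test_gained_units_cross_threshold(self, protocol):
        r = np.random.default_rng(1)
        base = np.sort(r.uniform(0, 120, r.poisson(2 * 120)))
        on = 120 + np.sort(r.uniform(0, 120, r.poisson(10 * 120)))
        res = evoked_zscore(np.concatenate([base, on]), protocol)
        assert res.z > 3 and res.responder

    def test_z_invariant_to_time_rescaling(self, protocol):
        r = np.random.default_rng(2)
        t = np.sort(r.uniform(0, 360, 1500))
        res1 = evoked_zscore(t, protocol)
        scale = 3.0
        proto2 = StimulusProtocol(
            epochs=[(l, a * scale, b * scale) for l, a, b in protocol.epochs],
            light_pulse_times_s=[p * scale for p in protocol.light_pulse_times_s],
        )
        res2 = evoked_zscore(t * scale, proto2, baseline_bin_s=scale)
        assert res2.z == pytest.approx(res1.z, rel=1e-9)


class TestRankSum:
    def test_identical_samples_not_significant(self):
        x = np.arange(50, dtype=float)
        stat, p = compare_psth_conditions(x, x.copy())
        assert p >= 0.99

    def test_power_on_shifted_gaussians(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            _, p = compare_psth_conditions(r.normal(0, 1, 100), r.normal(2, 1, 100))
            hits += p < 0.05
        assert hits >= 99

    def test_tiny_samples_raise(self):
        with pytest.raises(ValueError):
            compare_psth_conditions([1.0], [2.0])


class TestSummary:
    @staticmethod
    def _make(n_i, n_e, i_resp=0, e_resp=0):
        labels, responses = [], []
        uid = 0
        for n, lab, n_resp in ((n_i, "I", i_resp), (n_e, "E", e_resp)):
            for j in range(n):
                labels.append(CellTypeResult(uid, lab, 0 if lab == "I" else 1))
                responses.append(
                    ResponseSummary(uid, 1.0, 0.5, 2.0, 4.0 if j < n_resp else 0.0, j < n_resp)
                )
                uid += 1
        return responses, labels

    def test_printed_population_fractions(self):
        """430 inhibitory of 8189 total units -> 5.25% I, 94.75% E."""
        responses, labels = self._make(430, 7759)
        df = summarize_classification(responses, labels)
        assert df.loc["I", "pct_of_total"] == pytest.approx(5.25, abs=0.005)
        assert df.loc["E", "pct_of_total"] == pytest.approx(94.75, abs=0.005)
        assert df["n"].sum() == 8189

    def test_all_non_responders_zero_everywhere(self):
        responses, labels = self._make(5, 20)
        df = summarize_classification(responses, labels)
        assert (df["pct_responder"] == 0).all()

    def test_responder_fraction_per_label(self):
        responses, labels = self._make(10, 40, i_resp=6, e_resp=2)
        df = summarize_classification(responses, labels)
        assert df.loc["I", "pct_responder"] == pytest.approx(60.0)
        assert df.loc["E", "pct_responder"] == pytest.approx(5.0)

    def test_mismatched_ids_raise(self):
        responses, labels = self._make(2, 2)
        with pytest.raises(ValueError):
            summarize_classification(responses[:-1], labels)
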