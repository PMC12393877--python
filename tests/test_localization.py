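import numpy as np
import pytest

from spikemap import (
    ArrayGeometry,
    center_of_mass,
    deduplicate_units,
    fit_amplitude_decay,
    select_soma_channel,
)
from spikemap.localization import SomaLocation, consolidate_far_field
from spikemap.unit_isolation import PutativeUnit


@pytest.fixture
def geom():
    return ArrayGeometry(8, 8, 42.0)


def _wf(trough):
    w = np.zeros(31)
    w[15] = trough
    return w


class TestSomaChannel:
    def test_deepest_trough_wins(self, geom):
        wfs = {10: _wf(-80.0), 11: _wf(-120.0), 12: _wf(-60.0)}
        assert select_soma_channel(wfs, geom, radius_um=250.0) == 11

    def test_single_channel_unit(self, geom):
        assert select_soma_channel({5: _wf(-50.0)}, geom) == 5

    def test_empty_map_raises(self, geom):
        with pytest.raises(ValueError):
            select_soma_channel({}, geom)


class TestCenterOfMass:
    def test_central_and_uniform_mass_give_zero_offset(self):
        a = np.zeros((3, 3)); a[1, 1] = 1.0
        assert center_of_mass(a, 42.0) == (0.0, 0.0)
        assert center_of_mass(np.ones((3, 3)), 42.0) == (0.0, 0.0)

    def test_corner_mass_printed_formula_value(self):
        a = np.zeros((3, 3)); a[0, 0] = 1.0
        dr, dc = center_of_mass(a, 42.0)
        assert (dr, dc) == (-42.0, -42.0)

    def test_matches_brute_force_double_loop(self):
        """Vectorized COM agrees with the explicit i,j summation to 1e-12."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = rng.uniform(0, 100, size=(3, 3))
            dr, dc = center_of_mass(a, 42.0)
            num_r = num_c = den = 0.0
            for i in range(1, 4):
                for j in range(1, 4):
                    num_r += i * a[i - 1, j - 1]
                    num_c += j * a[i - 1, j - 1]
                    den += a[i - 1, j - 1]
            assert dr == pytest.approx((num_r / den - 2) * 42.0, abs=1e-12)
            assert dc == pytest.approx((num_c / den - 2) * 42.0, abs=1e-12)

    def test_translation_covariance(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 10, size=(3, 2))
        a = np.zeros((3, 3)); a[:, :2] = base
        b = np.zeros((3, 3)); b[:, 1:] = base
        dr_a, dc_a = center_of_mass(a, 42.0)
        dr_b, dc_b = center_of_mass(b, 42.0)
        assert dc_b - dc_a == pytest.approx(42.0, abs=1e-9)
        assert dr_b - dr_a == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_matrix_raises(self):
        with pytest.raises(ValueError):
            center_of_mass(np.zeros((3, 3)), 42.0)


class TestAmplitudeDecay:
    def test_decreasing_profile_kept(self, geom):
        home = geom.channel_at(4, 4)
        troughs = {}
        for d_col, amp in [(0, -200.0), (1, -100.0), (2, -50.0), (3, -20.0)]:
            troughs[geom.channel_at(4, 4 + d_col)] = amp
        prof = fit_amplitude_decay(troughs, home, geom)
        assert prof.slope < 0 and not prof.increasing

    def test_increasing_profile_flagged(self, geom):
        home = geom.channel_at(4, 4)
        troughs = {geom.channel_at(4, 4 + k): -(20.0 + 50.0 * k) for k in range(4)}
        prof = fit_amplitude_decay(troughs, home, geom)
        assert prof.increasing

    def test_linear_profile_recovers_slope_exactly(self, geom):
        """|trough| = 200 - 0.5 * d gives OLS slope -0.5 to 1e-6."""
        home = geom.channel_at(0, 0)
        troughs = {
            geom.channel_at(0, k): -(200.0 - 0.5 * (k * 42.0)) for k in range(6)
        }
        prof = fit_amplitude_decay(troughs, home, geom)
        assert prof.slope == pytest.approx(-0.5, abs=1e-6)
        assert prof.intercept == pytest.approx(200.0, abs=1e-4)

    def test_fewer_than_three_points_skips_fit(self, geom):
        home = geom.channel_at(0, 0)
        assert fit_amplitude_decay({home: -100.0}, home, geom) is None


def _unit(uid, ch, times, trough=-100.0):
    wf = np.zeros(31); wf[15] = trough
    return PutativeUnit(
        unit_id=uid, channel=ch, times_s=np.asarray(times), mean_waveform=wf,
        snr=10.0, rate_hz=len(times) / 100.0, n_spikes=len(times),
    )


def _loc(uid, ch, geom):
    r, c = geom.channel_map[ch]
    return SomaLocation(uid, ch, int(r), int(c), (0.0, 0.0))


class TestDedup:
    def test_distant_pairs_always_kept(self, geom, rng):
        times = np.sort(rng.uniform(0, 100, 200))
        u1, u2 = _unit(0, geom.channel_at(0, 0), times), _unit(1, geom.channel_at(7, 7), times)
        locs = {0: _loc(0, u1.channel, geom), 1: _loc(1, u2.channel, geom)}
        deduplicate_units([u1, u2], locs, geom, radius_um=250.0)
        assert "duplicate" not in u1.flags and "duplicate" not in u2.flags

    def test_mirrored_train_on_neighbor_flagged_smaller_amp(self, geom, rng):
        times = np.sort(rng.uniform(0, 100, 300))
        u1 = _unit(0, geom.channel_at(3, 3), times, trough=-150.0)
        u2 = _unit(1, geom.channel_at(3, 4), times, trough=-60.0)
        locs = {0: _loc(0, u1.channel, geom), 1: _loc(1, u2.channel, geom)}
        pairs = deduplicate_units([u1, u2], locs, geom)
        assert "duplicate" in u2.flags and "duplicate" not in u1.flags
        assert pairs and pairs[0][:2] == (0, 1)

    def test_never_flags_both_members(self, geom, rng):
        times = np.sort(rng.uniform(0, 100, 300))
        units = [
            _unit(k, geom.channel_at(3, 3 + k), times, trough=-100.0 - k)
            for k in range(3)
        ]
        locs = {u.unit_id: _loc(u.unit_id, u.channel, geom) for u in units}
        deduplicate_units(units, locs, geom)
        assert any("duplicate" not in u.flags for u in units)

    def test_independent_poisson_trains_survive(self, geom):
        kept = 0
        n_seeds = 50
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            u1 = _unit(0, geom.channel_at(3, 3), np.sort(r.uniform(0, 100, 300)))
            u2 = _unit(1, geom.channel_at(3, 4), np.sort(r.uniform(0, 100, 300)))
            locs = {0: _loc(0, u1.channel, geom), 1: _loc(1, u2.channel, geom)}
            deduplicate_units([u1, u2], locs, geom)
            kept += "duplicate" not in u1.flags and "duplicate" not in u2.flags
        assert kept / n_seeds >= 0.95


class TestConsolidate:
    def test_far_field_image_flagged_when_soma_unit_exists(self, geom, rng):
        times = np.sort(rng.uniform(0, 100, 100))
        somatic = _unit(0, geom.channel_at(3, 3), times)
        image = _unit(1, geom.channel_at(3, 4), times[::2])
        locs = {
            0: _loc(0, somatic.channel, geom),
            1: _loc(1, somatic.channel, geom),  # image's soma is the other channel
        }
        flagged = consolidate_far_field([somatic, image], locs)
        assert flagged == [1]
        assert "duplicate" in image.flags and "duplicate" not in somatic.flags

    def test_sole_representation_kept(self, geom, rng):
        image = _unit(0, geom.channel_at(3, 4), np.sort(rng.uniform(0, 100, 100)))
        locs = {0: _loc(0, geom.channel_at(3, 3), geom)}  # soma channel has no unit
        assert consolidate_far_field([image], locs) == []
        assert "duplicate" not in image.flags
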