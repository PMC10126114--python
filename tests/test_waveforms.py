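"""One- and multi-channel waveform feature extraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eapclust.errors import DegenerateInputError, FeatureUndefinedError
from eapclust.synthetic import EapGenParams, ProbeGeometry, gen_multichannel_eap
from eapclust.waveforms import (
    MultichannelWaveform,
    extract_multichannel_features,
    extract_one_channel_features,
    symmetry_index,
)

FS_30K = 30000.0
DT_MS = 1000.0 / FS_30K


def _single_channel(trace, fs=FS_30K):
    return MultichannelWaveform(
        samples=np.asarray(trace)[None, :], sampling_rate=fs, channel_depths=[0.0]
    )


class TestOneChannelFeatures:
    def test_tpw_is_trough_to_following_peak_time(self):
        # trough at sample 1 (1 ms at 1 kHz), following local max at sample 4
        w = _single_channel([0, -40, -20, 10, 30, 20, 10, 5, 0, 0], fs=1000.0)
        f = extract_one_channel_features(w)
        assert f.tpw == pytest.approx(3.0)
        assert f.amplitude == 40.0

    def test_rep_uses_linear_interpolation_to_half_peak(self):
        # peak 40 at 1.5 ms; first crossing of 20 at 1.8 ms exactly
        fs = 10000.0  # 0.1 ms bins
        trace = np.zeros(40)
        trace[10] = -50.0
        trace[15] = 40.0
        trace[16] = 40.0 - 20.0 / 3
        trace[17] = 40.0 - 40.0 / 3
        trace[18] = 20.0  # exactly half at 1.8 ms
        trace[19:] = 0.0
        # fill rising edge to keep the peak the max after trough
        trace[11:15] = [-30, -10, 10, 30]
        f = extract_one_channel_features(_single_channel(trace, fs))
        assert f.rep == pytest.approx(0.3, abs=1e-9)

    def test_narrow_unit_has_smaller_tpw_than_wide(self):
        narrow = gen_multichannel_eap(EapGenParams(tpw=0.25, rep=0.2), seed=0)
        wide = gen_multichannel_eap(EapGenParams(tpw=0.65, rep=0.55), seed=0)
        f_n = extract_one_channel_features(narrow)
        f_w = extract_one_channel_features(wide)
        assert f_n.tpw < f_w.tpw
        assert f_n.rep < f_w.rep

    def test_flat_waveform_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            extract_one_channel_features(_single_channel(np.zeros(50)))

    def test_monotone_rise_after_trough_has_no_peak(self):
        trace = np.concatenate([[0, -10.0], np.linspace(-9, 30, 20)])
        with pytest.raises(FeatureUndefinedError):
            extract_one_channel_features(_single_channel(trace))

    @given(scale=st.floats(0.1, 50), offset=st.floats(-30, 30))
    @settings(max_examples=25, deadline=None)
    def test_tpw_rep_invariant_under_amplitude_scaling(self, scale, offset):
        w = gen_multichannel_eap(EapGenParams(tpw=0.5, rep=0.3), seed=3)
        base = extract_one_channel_features(w)
        w2 = MultichannelWaveform(
            w.samples * scale, w.sampling_rate, w.channel_depths
        )
        f2 = extract_one_channel_features(w2)
        assert f2.tpw == base.tpw
        assert f2.rep == pytest.approx(base.rep, abs=1e-9)
        # latency features tolerate a constant voltage offset
        w3 = MultichannelWaveform(
            w.samples + offset, w.sampling_rate, w.channel_depths
        )
        f3 = extract_one_channel_features(w3)
        assert f3.tpw == base.tpw


class TestSymmetryIndex:
    @pytest.mark.parametrize(
        "below, above, expected",
        [
            (-0.5, 0.5, 0.0),
            (1.0, 1.0, math.sqrt(2.0)),
            (0.0, 0.2, 0.2 / math.sqrt(2.0)),
        ],
    )
    def test_hand_values(self, below, above, expected):
        assert symmetry_index(below, above) == pytest.approx(expected, abs=1e-9)

    @given(a=st.floats(-1, 1), b=st.floats(-1, 1))
    @settings(max_examples=50, deadline=None)
    def test_exchange_and_sign_flip_invariance(self, a, b):
        si = symmetry_index(a, b)
        assert symmetry_index(b, a) == pytest.approx(si)
        assert symmetry_index(-a, -b) == pytest.approx(si)


def _synthetic_multichannel(latencies_ms, amps, depths, fs=FS_30K):
    """Build a waveform bank with prescribed per-channel trough latencies."""
    n = int(6.0 / (1000.0 / fs))
    t = np.arange(n) * (1000.0 / fs)
    chans = []
    for lat, amp in zip(latencies_ms, amps):
        t0 = 2.0 + lat
        tr = -amp * np.exp(-0.5 * ((t - t0) / 0.1) ** 2)
        tr += 0.4 * amp * np.exp(-0.5 * ((t - t0 - 0.5) / 0.15) ** 2)
        chans.append(tr)
    return MultichannelWaveform(np.array(chans), fs, np.asarray(depths))


class TestMultiChannelFeatures:
    def test_exact_linear_symmetric_latencies(self):
        depths = np.arange(-200, 201, 20.0)
        lat = 0.005 * np.abs(depths)  # 0.005 ms/um outward both ways
        amps = 100.0 * np.exp(-np.abs(depths) / 400.0)  # all above threshold
        w = _synthetic_multichannel(lat, amps, depths)
        f = extract_multichannel_features(w)
        assert f.inv_v_below == pytest.approx(-0.005, rel=1e-6)
        assert f.inv_v_above == pytest.approx(0.005, rel=1e-6)
        assert f.symmetry_index == pytest.approx(0.0, abs=1e-9)

    def test_spread_follows_contiguous_12pct_rule(self):
        # amplitudes (5, 20, 100, 30, 6) on 20 um pitch; threshold 12 ->
        # channels 2-4 contiguous -> extent 40 um
        depths = np.array([-40.0, -20.0, 0.0, 20.0, 40.0])
        amps = np.array([5.0, 20.0, 100.0, 30.0, 6.0])
        w = _synthetic_multichannel(np.zeros(5), amps, depths)
        f = extract_multichannel_features(w)
        assert f.spread == pytest.approx(40.0)

    def test_instantaneous_propagation_gives_zero_finite_slopes(self):
        depths = np.arange(-200, 201, 20.0)
        amps = 80.0 * np.exp(-np.abs(depths) / 400.0)
        w = _synthetic_multichannel(np.zeros(depths.size), amps, depths)
        f = extract_multichannel_features(w)
        assert f.inv_v_below == 0.0
        assert f.inv_v_above == 0.0
        assert np.isfinite(f.symmetry_index)

    def test_low_amplitude_channels_excluded_from_fits(self):
        depths = np.arange(-200, 201, 20.0)
        amps = np.where(np.abs(depths) > 100, 5.0, 100.0 - 0.05 * np.abs(depths))
        lat = 0.002 * np.abs(depths)
        w = _synthetic_multichannel(lat, amps, depths)
        f = extract_multichannel_features(w)
        assert f.n_channels_below == 6  # d in {-100..0}
        assert f.n_channels_above == 6


class TestGeneratorRoundTrip:
    @pytest.mark.parametrize("tpw, rep", [(0.5, 0.3), (0.25, 0.2), (0.65, 0.55)])
    def test_tpw_rep_recovered_within_one_sample(self, tpw, rep):
        w = gen_multichannel_eap(EapGenParams(tpw=tpw, rep=rep, noise_sd=0.0), seed=0)
        f = extract_one_channel_features(w)
        assert f.tpw == pytest.approx(tpw, abs=DT_MS + 1e-9)
        assert f.rep == pytest.approx(rep, abs=DT_MS + 1e-9)

    def test_slopes_recovered_exactly_on_sample_commensurate_grid(self):
        # 0.005 ms/um at 20 um pitch is exactly 3 samples per row at 30 kHz
        p = EapGenParams(inv_v_above=0.005, inv_v_below=-0.005, noise_sd=0.0)
        f = extract_multichannel_features(gen_multichannel_eap(p, seed=0))
        assert f.inv_v_below == pytest.approx(-0.005, rel=1e-9)
        assert f.inv_v_above == pytest.approx(0.005, rel=1e-9)

    def test_latencies_quantized_to_sampling_interval(self):
        p = EapGenParams(inv_v_above=0.003, inv_v_below=-0.003, noise_sd=0.0)
        w = gen_multichannel_eap(p, seed=0)
        pc = w.peak_channel()
        ref = np.argmin(w.samples[pc])
        troughs = np.argmin(w.samples, axis=1)
        lat = (troughs - ref) * w.dt_ms
        assert np.allclose(lat / w.dt_ms, np.round(lat / w.dt_ms))

    @pytest.mark.parametrize("v", [0.0, 0.005 / 3, 0.005, 0.01])
    def test_fitted_inverse_velocity_monotone_in_generated(self, v):
        # noiseless, sample-commensurate slopes: equality (monotone a fortiori)
        p = EapGenParams(inv_v_above=v, inv_v_below=-v, noise_sd=0.0)
        f = extract_multichannel_features(gen_multichannel_eap(p, seed=0))
        assert f.inv_v_above == pytest.approx(v, abs=1e-9)


def test_probe_geometry_invariants():
    g = ProbeGeometry()
    d = g.channel_depths
    assert np.allclose(np.diff(d), g.vertical_spacing)
    assert d.size >= 21
    with pytest.raises(Exception):
        ProbeGeometry(n_rows=15)
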