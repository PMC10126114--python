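"""Synthetic-data generators: determinism, ground-truth recovery, statistics."""

import numpy as np
import pytest
from scipy import stats as sstats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from eapclust.errors import BoundaryError, ParameterError
from eapclust.synthetic import (
    EapGenParams,
    OptoGenParams,
    PhaseLockGenParams,
    PopulationComponent,
    ProbeGeometry,
    SpikeTrainGenParams,
    gen_lfp_with_locked_spikes,
    gen_morphology,
    gen_multichannel_eap,
    gen_optotagging_session,
    gen_spike_train,
    gen_unit_population,
)
from eapclust.morphology import bifurcation_summary
from eapclust.spiketrains import detect_optotagged
from eapclust.waveforms import extract_multichannel_features


class TestDeterminism:
    def test_eap_generator_bit_identical_given_seed(self):
        p = EapGenParams(noise_sd=4.0)
        a = gen_multichannel_eap(p, seed=42)
        b = gen_multichannel_eap(p, seed=42)
        assert np.array_equal(a.samples, b.samples)
        c = gen_multichannel_eap(p, seed=43)
        assert not np.array_equal(a.samples, c.samples)

    def test_spike_train_and_lfp_deterministic(self):
        sp = SpikeTrainGenParams(rate=5, duration=20, seed=7)
        assert np.array_equal(gen_spike_train(sp), gen_spike_train(sp))
        lp = PhaseLockGenParams(seed=7)
        l1, s1 = gen_lfp_with_locked_spikes(lp)
        l2, s2 = gen_lfp_with_locked_spikes(lp)
        assert np.array_equal(l1, l2) and np.array_equal(s1, s2)


class TestEapGeneration:
    def test_soma_channel_near_edge_rejected(self):
        with pytest.raises(BoundaryError):
            gen_multichannel_eap(EapGenParams(soma_channel=5), ProbeGeometry())

    def test_amplitude_decays_with_distance(self):
        p = EapGenParams(
            decay_length=80.0, noise_sd=0.0, inv_v_above=0.0, inv_v_below=0.0
        )
        w = gen_multichannel_eap(p, seed=0)
        amps = np.max(np.abs(w.samples), axis=1)
        pc = int(np.argmax(amps))
        assert amps[pc] == amps.max()
        d = np.abs(w.channel_depths - w.channel_depths[pc])
        expected = amps[pc] * np.exp(-d / 80.0)
        assert np.allclose(amps, expected, rtol=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            EapGenParams(tpw=-0.1)
        with pytest.raises(ParameterError):
            EapGenParams(inv_v_below=0.002)  # wrong sign
        with pytest.raises(ParameterError):
            PopulationComponent(mean=EapGenParams(), sd={"tpw": -1.0})


class TestUnitPopulation:
    def test_component_counts_within_binomial_ci(self):
        # two components with the study weights; 99% CI of Binomial(1204, .233)
        comps = [
            PopulationComponent(mean=EapGenParams(tpw=0.25), weight=0.233),
            PopulationComponent(mean=EapGenParams(tpw=0.65), weight=0.767),
        ]
        _, labels = gen_unit_population(comps, 1204, seed=5)
        n0 = int(np.sum(labels == 0))
        lo, hi = sstats.binom.ppf([0.005, 0.995], 1204, 0.233)
        assert lo <= n0 <= hi

    def test_single_component_all_labels_identical(self):
        comps = [PopulationComponent(mean=EapGenParams(), weight=1.0)]
        _, labels = gen_unit_population(comps, 50, seed=1)
        assert np.all(labels == 0)

    def test_three_separated_components_perfectly_recoverable(self):
        # K-means at K=3 on the fitted propagation features: ARI = 1
        comps = [
            PopulationComponent(
                mean=EapGenParams(inv_v_below=-0.001, inv_v_above=0.001, noise_sd=0),
                sd={"inv_v_below": 1e-4, "inv_v_above": 1e-4},
                weight=1 / 3,
            ),
            PopulationComponent(
                mean=EapGenParams(inv_v_below=-0.006, inv_v_above=0.001, noise_sd=0),
                sd={"inv_v_below": 1e-4, "inv_v_above": 1e-4},
                weight=1 / 3,
            ),
            PopulationComponent(
                mean=EapGenParams(inv_v_below=-0.001, inv_v_above=0.006, noise_sd=0),
                sd={"inv_v_below": 1e-4, "inv_v_above": 1e-4},
                weight=1 / 3,
            ),
        ]
        wfs, labels = gen_unit_population(comps, 90, seed=3)
        X = np.array(
            [
                [f.inv_v_below, f.inv_v_above]
                for f in (extract_multichannel_features(w) for w in wfs)
            ]
        )
        pred = KMeans(3, n_init=20, random_state=0).fit_predict(X)
        assert adjusted_rand_score(labels, pred) == 1.0


class TestSpikeTrainGeneration:
    def test_poisson_cv_near_one(self):
        st = gen_spike_train(SpikeTrainGenParams(rate=10, duration=1000, seed=0))
        isis = np.diff(st)
        cv = isis.std(ddof=1) / isis.mean()
        assert 0.9 <= cv <= 1.1

    def test_high_shape_gamma_is_clocklike(self):
        st = gen_spike_train(
            SpikeTrainGenParams(
                model="gamma-renewal", rate=10, duration=1000, gamma_shape=1000, seed=0
            )
        )
        isis = np.diff(st)
        assert isis.std(ddof=1) / isis.mean() < 0.1

    def test_times_sorted_within_duration(self):
        st = gen_spike_train(SpikeTrainGenParams(rate=1, duration=3, seed=2))
        assert np.all(np.diff(st) > 0)
        assert st.size == 0 or (st[0] >= 0 and st[-1] <= 3)


class TestPhaseLockGeneration:
    def test_kappa_recovered_by_ml_fit_on_drawn_phases(self):
        p = PhaseLockGenParams(kappa_true=4, n_spikes=10000, seed=9)
        _, spikes = gen_lfp_with_locked_spikes(p)
        # oracle: phases reconstructed from the pure oscillation's phase
        phases = (spikes * p.band_center % 1.0) * 2 * np.pi
        kappa, _, _ = sstats.vonmises.fit(phases, fscale=1)
        assert abs(kappa - 4) / 4 < 0.05

    def test_trough_locked_spikes_read_out_at_180(self):
        p = PhaseLockGenParams(
            kappa_true=50, preferred_phase_true=180.0, n_spikes=2000, seed=1
        )
        _, spikes = gen_lfp_with_locked_spikes(p)
        phases = (spikes * p.band_center % 1.0) * 360.0
        mean = np.degrees(np.angle(np.mean(np.exp(1j * np.radians(phases))))) % 360
        assert abs(mean - 180.0) < 5.0

    def test_aliasing_band_rejected(self):
        with pytest.raises(ParameterError):
            PhaseLockGenParams(band_center=700.0, lfp_rate=1250.0)


class TestOptotaggingGeneration:
    def test_strong_response_detected(self):
        sess, _ = gen_optotagging_session(
            OptoGenParams(baseline_rate=5, response_rate=100, n_trials=200, seed=0)
        )
        assert detect_optotagged(sess).tagged

    def test_no_rate_change_not_tagged(self):
        sess, _ = gen_optotagging_session(
            OptoGenParams(baseline_rate=20, response_rate=20, n_trials=200, seed=0)
        )
        assert not detect_optotagged(sess).tagged

    def test_silent_unit_empty_raster(self):
        sess, _ = gen_optotagging_session(
            OptoGenParams(baseline_rate=0, response_rate=0, n_trials=200, seed=0)
        )
        assert sum(len(t) for t in sess.trials) == 0
        assert not detect_optotagged(sess).tagged


class TestMorphologyGeneration:
    def test_symmetric_bifurcations_give_opposite_sums(self):
        tree = gen_morphology([(50.0, 2), (-50.0, 2)], seed=0)
        s = bifurcation_summary(tree)
        assert s.above_sum == pytest.approx(-s.below_sum)
        assert s.above_sum == pytest.approx(1.0)

    def test_all_above_soma_zero_below_sum(self):
        tree = gen_morphology([(40.0, 1), (90.0, 2)], seed=0)
        s = bifurcation_summary(tree)
        assert s.below_sum == 0.0
        assert s.above_sum > 0

    def test_far_node_excluded(self):
        tree = gen_morphology([(250.0, 2), (50.0, 1)], seed=0)
        s = bifurcation_summary(tree)
        assert s.n_excluded == 1
        assert max(abs(w) for w in s.w_um) <= 200.0
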