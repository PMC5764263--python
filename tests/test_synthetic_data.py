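import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegdcm import synthetic_data as sd
from eegdcm.errors import InvalidConfigError, ShapeError, StabilityError


class TestGenerateParadigm:
    def test_default_block_count(self):
        assert sd.generate_paradigm().n_blocks == 20

    def test_zero_blocks_is_empty(self):
        p = sd.generate_paradigm(n_blocks=0)
        assert p.blocks == ()
        assert len(p.events()) == 0

    def test_trial_onset_spacing(self):
        p = sd.generate_paradigm(seed=3)
        for b in p.blocks:
            diffs = np.diff(b.trial_onsets)
            assert np.allclose(diffs, 1.3)

    def test_trial_counts_in_range(self):
        p = sd.generate_paradigm(seed=5)
        counts = {len(b.trial_onsets) for b in p.blocks}
        assert counts <= {3, 4, 5}
        assert all(len(b.trial_onsets) >= 3 for b in p.blocks)

    def test_onsets_strictly_increasing(self):
        p = sd.generate_paradigm(seed=7)
        all_onsets = []
        for b in p.blocks:
            all_onsets.extend([b.cue_onset, *b.trial_onsets, b.probe_onset])
        assert np.all(np.diff(all_onsets) > 0)

    def test_probe_after_last_dot(self):
        p = sd.generate_paradigm(seed=9)
        for b in p.blocks:
            assert b.probe_onset > b.trial_onsets[-1] + b.dot_duration

    def test_cue_duration_default(self):
        assert sd.generate_paradigm().blocks[0].cue_duration == 4.0

    def test_deterministic(self):
        assert sd.generate_paradigm(seed=42) == sd.generate_paradigm(seed=42)

    def test_negative_duration_rejected(self):
        with pytest.raises(InvalidConfigError):
            sd.generate_paradigm(timing=sd.TimingConfig(cue_duration=-1.0))

    def test_too_few_trials_rejected(self):
        with pytest.raises(InvalidConfigError):
            sd.generate_paradigm(trial_count_range=(2, 3))

    def test_out_of_set_trial_count_rejected(self):
        with pytest.raises(InvalidConfigError):
            sd.generate_paradigm(trial_count_range=(3, 6))

    @given(st.integers(min_value=0, max_value=30), st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_block_count_matches_request(self, n, seed):
        assert sd.generate_paradigm(n_blocks=n, seed=seed).n_blocks == n


class TestNetworkDynamics:
    def test_zero_input_zero_output(self):
        net = sd.default_network()
        u = np.zeros(100)
        x = sd.simulate_network_dynamics(net, u, {"task": u}, dt=0.01)
        assert np.all(x == 0)

    def test_modulation_inert_when_input_off(self):
        net = sd.default_network()
        rng = np.random.default_rng(0)
        u = rng.random(200)
        off = np.zeros(200)
        x1 = sd.simulate_network_dynamics(net, u, {"task": off}, dt=0.01)
        net0 = sd.GroundTruthNetwork(
            A=net.A, B={"task": np.zeros((4, 4))}, C=net.C, input_region=net.input_region
        )
        x2 = sd.simulate_network_dynamics(net0, u, {"task": off}, dt=0.01)
        np.testing.assert_allclose(x1, x2)

    def test_step_input_closed_form(self):
        # dx/dt = -x + u with unit step: x(t) = 1 - exp(-t)
        A = -np.eye(4)
        A[0, 1] = 0.0
        net = sd.GroundTruthNetwork(
            A=A, B={}, C=np.array([1.0, 0, 0, 0]), input_region="PMC"
        )
        dt = 1e-3
        n = 2000
        u = np.ones(n)
        x = sd.simulate_network_dynamics(net, u, {}, dt=dt)
        t = np.arange(n) * dt
        np.testing.assert_allclose(x[0], 1 - np.exp(-t), atol=1e-6)

    def test_euler_convergence_order(self):
        net = sd.default_network()
        dt = 0.02
        n = 200
        rng = np.random.default_rng(3)
        u = rng.random(n)
        mod = (rng.random(n) > 0.5).astype(float)
        exact = sd.simulate_network_dynamics(net, u, {"task": mod}, dt)
        e1 = sd.simulate_network_dynamics(net, u, {"task": mod}, dt, method="euler")
        u2, mod2 = np.repeat(u, 2), np.repeat(mod, 2)
        e2 = sd.simulate_network_dynamics(net, u2, {"task": mod2}, dt / 2, method="euler")[:, ::2]
        err1 = np.max(np.abs(e1 - exact))
        err2 = np.max(np.abs(e2 - exact))
        assert err2 < 0.75 * err1  # first-order: halving dt ~halves the error

    def test_unstable_a_raises(self):
        A = np.eye(4) * 0.1
        with pytest.raises(StabilityError):
            net = sd.GroundTruthNetwork(
                A=A, B={}, C=np.array([1.0, 0, 0, 0]), input_region="PMC"
            )
            sd.simulate_network_dynamics(net, np.zeros(10), {}, dt=0.01)

    def test_dlpfc_m1_exclusion_enforced(self):
        A = -np.eye(4)
        A[2, 3] = 0.2  # M1 <- DLPFC forbidden
        net = sd.GroundTruthNetwork(
            A=A, B={}, C=np.array([1.0, 0, 0, 0]), input_region="PMC"
        )
        with pytest.raises(ShapeError):
            net.validate()


class TestLeadFieldProjection:
    def test_identity_gain_zero_noise(self, rng):
        srcs = rng.standard_normal((4, 50))
        pos = sd.default_roiset().center_array()
        lf = sd.LeadField(
            gain=np.eye(4), channel_labels=("a", "b", "c", "d"), source_positions=pos
        )
        rec = sd.project_to_scalp(srcs, lf, None, fs=100.0)
        np.testing.assert_array_equal(rec.data, srcs)

    def test_default_montage_32_channels(self, rng):
        pos = sd.default_source_positions(n_distractors=2, seed=0)
        lf = sd.gaussian_leadfield(pos)
        rec = sd.project_to_scalp(rng.standard_normal((6, 40)), lf, None, fs=100.0)
        assert rec.data.shape[0] == 32

    def test_noise_variance_scaling(self):
        pos = sd.default_source_positions(n_distractors=0, seed=0)
        lf = sd.gaussian_leadfield(pos)
        n = 100_000
        srcs = np.zeros((4, n))
        v = []
        for sd_noise in (1.0, 2.0):
            rec = sd.project_to_scalp(
                srcs, lf, {"sensor_noise_sd": sd_noise}, fs=500.0, seed=9
            )
            v.append(rec.data[0].var())
        assert abs(v[1] / v[0] - 4.0) < 0.4

    def test_dimension_mismatch(self, rng):
        pos = sd.default_source_positions(n_distractors=0, seed=0)
        lf = sd.gaussian_leadfield(pos)
        with pytest.raises(ShapeError):
            sd.project_to_scalp(rng.standard_normal((7, 10)), lf, None, fs=100.0)

    def test_seed_reproducibility(self, rng):
        pos = sd.default_source_positions(n_distractors=0, seed=0)
        lf = sd.gaussian_leadfield(pos)
        srcs = rng.standard_normal((4, 100))
        a = sd.project_to_scalp(srcs, lf, {"pink_noise_sd": 1.0}, fs=100.0, seed=5)
        b = sd.project_to_scalp(srcs, lf, {"pink_noise_sd": 1.0}, fs=100.0, seed=5)
        np.testing.assert_array_equal(a.data, b.data)


class TestResponses:
    def test_all_correct(self):
        p = sd.generate_paradigm()
        log = sd.generate_responses(p, p_correct=1.0, seed=0)
        assert log.n_blocks == 20
        assert all(r == "correct" for _, r in log.entries)

    def test_all_incorrect(self):
        log = sd.generate_responses(sd.generate_paradigm(), p_correct=0.0, seed=0)
        assert all(r == "incorrect" for _, r in log.entries)

    def test_binomial_rate(self):
        p = sd.generate_paradigm(n_blocks=10_000, seed=1)
        log = sd.generate_responses(p, p_correct=0.9, seed=2)
        sd3 = 3 * np.sqrt(0.9 * 0.1 / 10_000)
        assert abs(log.accuracy - 0.9) < sd3

    def test_invalid_probability(self):
        with pytest.raises(InvalidConfigError):
            sd.generate_responses(sd.generate_paradigm(), p_correct=1.5)

    def test_default_rates_by_session(self):
        for kind, rate in (("ME", 0.904), ("MI", 0.845)):
            assert sd.DEFAULT_P_CORRECT[kind] == rate


class TestArtifacts:
    def test_noop_is_bit_exact(self, small_session):
        rec = small_session.recording
        out = sd.inject_artifacts(rec, blink_rate=0.0, spike_spec=None, seed=0)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_spike_logged_at_requested_time(self, small_session):
        rec = small_session.recording
        out = sd.inject_artifacts(
            rec,
            spike_spec=[{"time_s": 2.0, "channel": "C3", "amplitude_uv": 150.0}],
            seed=0,
        )
        assert out.artifacts["spike_times"] == [2.0]
        i = rec.channel_labels.index("C3")
        s = int(2.0 * rec.fs)
        assert np.max(out.data[i, s : s + 20] - rec.data[i, s : s + 20]) >= 149

    def test_blink_count_poisson_bound(self):
        cfg = sd.SimulationConfig(n_blocks=2, fs_raw=256.0, n_distractors=0)
        session = sd.simulate_session(cfg, seed=3)
        rec = session.recording
        # stretch to 400 s by tiling to test the Poisson rate bound cheaply
        long = sd.SimulatedRecording(
            data=np.zeros((32, int(400 * 256))),
            fs=256.0,
            events=rec.events,
            channel_labels=rec.channel_labels,
        )
        out = sd.inject_artifacts(long, blink_rate=0.25, seed=17)
        assert abs(len(out.artifacts["blink_times"]) - 100) <= 3 * np.sqrt(100)

    def test_blinks_are_frontal_weighted(self):
        rec = sd.SimulatedRecording(
            data=np.zeros((32, 2560)),
            fs=256.0,
            events=None,
            channel_labels=sd.montage.CHANNELS_32,
        )
        out = sd.inject_artifacts(rec, blink_rate=0.5, blink_amplitude_uv=80, seed=2)
        amp = np.abs(out.data).max(axis=1)
        fp1 = rec.channel_labels.index("Fp1")
        oz = rec.channel_labels.index("Oz")
        assert amp[fp1] > 5 * amp[oz]


class TestSession:
    def test_event_conservation(self, small_session):
        ev = small_session.recording.events
        dots = ev[ev["label"] == "dot"]
        expected = sum(len(b.trial_onsets) for b in small_session.paradigm.blocks)
        assert len(dots) == expected
        assert dots["onset_sample"].is_unique

    def test_determinism(self):
        cfg = sd.SimulationConfig(n_blocks=2, fs_raw=256.0, n_distractors=2)
        a = sd.simulate_session(cfg, seed=99)
        b = sd.simulate_session(cfg, seed=99)
        assert a.paradigm == b.paradigm
        assert a.responses == b.responses
        np.testing.assert_array_equal(a.recording.data, b.recording.data)

    def test_session_kind_sets_input_region(self):
        for kind, region in (("ME", "PMC"), ("MI", "SMA")):
            cfg = sd.SimulationConfig(session_kind=kind, n_blocks=1, fs_raw=256.0)
            s = sd.simulate_session(cfg, seed=0)
            assert s.network.input_region == region

    def test_edf_roundtrip(self, small_session, tmp_path):
        sd.write_session(
            small_session, tmp_path / "s.edf", tmp_path / "s_events.tsv"
        )
        from eegdcm.edfio import read_edf

        edf = read_edf(tmp_path / "s.edf")
        assert edf.fs == small_session.recording.fs
        assert list(edf.channel_labels) == list(small_session.recording.channel_labels)
        assert edf.data.shape == small_session.recording.data.shape
        # 16-bit quantization error bounded by the per-channel range
        span = np.abs(small_session.recording.data).max(axis=1)
        err = np.abs(edf.data - small_session.recording.data).max(axis=1)
        assert np.all(err <= 2 * span / 65535 + 1e-6)
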