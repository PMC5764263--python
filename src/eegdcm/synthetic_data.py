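"""Synthetic finger-tapping EEG sessions.

Generates the block/trial task paradigm, ground-truth 4-node network dynamics,
scalp-projected recordings with noise and stereotyped artifacts, and per-block
behavioural responses, so the whole downstream pipeline is testable without
any recorded data.

Defaults follow the study design this emulates: 20 blocks per session, a
4.0-s cue, 3-5 dot trials per block at 1.3-s intervals (dot 0.8 s, fixation
0.5 s), an end-of-block button probe, a 32-channel 10-20 montage, and
mu (8-12 Hz) / beta (13-20 Hz) event-related desynchronization at
sensorimotor sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _integrator, montage
from .edfio import write_edf
from .errors import InvalidConfigError, ShapeError, StabilityError
from .source_recon import ROISet, default_roiset

NODES = ("PMC", "SMA", "M1", "DLPFC")
NODE_INDEX = {lb: i for i, lb in enumerate(NODES)}

DEFAULT_P_CORRECT = {"ME": 0.904, "MI": 0.845}


# ---------------------------------------------------------------------------
# task paradigm
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimingConfig:
    cue_duration: float = 4.0
    inter_trial_interval: float = 1.3
    dot_duration: float = 0.8
    fixation_duration: float = 0.5
    probe_delay: float = 0.5  # gap after the would-be next dot slot
    probe_duration: float = 1.0
    inter_block_interval: float = 2.0

    def validate(self):
        for name in (
            "cue_duration",
            "inter_trial_interval",
            "dot_duration",
            "fixation_duration",
            "probe_duration",
            "inter_block_interval",
        ):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if self.probe_delay < 0:
            raise InvalidConfigError("probe_delay must be >= 0")
        if self.dot_duration + self.fixation_duration > self.inter_trial_interval:
            raise InvalidConfigError("dot + fixation must fit inside the trial interval")


@dataclass(frozen=True)
class Block:
    cue_onset: float
    cue_duration: float
    starting_finger: int
    trial_onsets: tuple[float, ...]
    dot_duration: float
    fixation_duration: float
    probe_onset: float


@dataclass(frozen=True)
class TaskParadigm:
    session_kind: str
    blocks: tuple[Block, ...]

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def first_dot_onsets(self) -> np.ndarray:
        return np.array([b.trial_onsets[0] for b in self.blocks])

    @property
    def duration(self) -> float:
        if not self.blocks:
            return 0.0
        last = self.blocks[-1]
        return last.probe_onset + 2.0

    def events(self) -> pd.DataFrame:
        rows = []
        for bi, b in enumerate(self.blocks):
            rows.append((b.cue_onset, b.cue_duration, "cue", bi))
            for t in b.trial_onsets:
                rows.append((t, b.dot_duration, "dot", bi))
            rows.append((b.probe_onset, 0.0, "probe", bi))
        return pd.DataFrame(rows, columns=["onset", "duration", "trial_type", "block_index"])


def generate_paradigm(
    session_kind: str = "ME",
    n_blocks: int = 20,
    trial_count_range=(3, 4, 5),
    timing: TimingConfig | None = None,
    seed: int = 0,
) -> TaskParadigm:
    """Build a timed block/trial paradigm; identical seeds give identical output."""
    if session_kind not in ("ME", "MI"):
        raise InvalidConfigError("session_kind must be 'ME' or 'MI'")
    if n_blocks < 0:
        raise InvalidConfigError("n_blocks must be >= 0")
    counts = tuple(sorted(set(int(c) for c in trial_count_range)))
    if not counts or min(counts) < 3:
        raise InvalidConfigError("every block needs at least 3 trials")
    if not set(counts) <= {3, 4, 5}:
        raise InvalidConfigError("trial counts must lie in {3, 4, 5}")
    timing = timing or TimingConfig()
    timing.validate()

    rng = np.random.default_rng(seed)
    blocks = []
    t = 0.0
    for _ in range(n_blocks):
        n_trials = int(rng.choice(counts))
        finger = int(rng.integers(1, 5))
        cue_onset = t
        first = cue_onset + timing.cue_duration
        onsets = tuple(first + i * timing.inter_trial_interval for i in range(n_trials))
        probe = onsets[-1] + timing.inter_trial_interval + timing.probe_delay
        blocks.append(
            Block(
                cue_onset=cue_onset,
                cue_duration=timing.cue_duration,
                starting_finger=finger,
                trial_onsets=onsets,
                dot_duration=timing.dot_duration,
                fixation_duration=timing.fixation_duration,
                probe_onset=probe,
            )
        )
        t = probe + timing.probe_duration + timing.inter_block_interval
    return TaskParadigm(session_kind=session_kind, blocks=tuple(blocks))


# ---------------------------------------------------------------------------
# ground-truth network and dynamics
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthNetwork:
    """Bilinear A/B/C structure over (PMC, SMA, M1, DLPFC); row=target, col=source."""

    A: np.ndarray
    B: dict  # condition name -> 4x4 modulatory gain matrix
    C: np.ndarray
    input_region: str
    nodes: tuple[str, ...] = NODES

    def validate(self):
        A = np.asarray(self.A, float)
        if A.shape != (4, 4):
            raise ShapeError("A must be 4x4")
        m1, dl = NODE_INDEX["M1"], NODE_INDEX["DLPFC"]
        mats = [A] + [np.asarray(b, float) for b in self.B.values()]
        for M in mats:
            if M[m1, dl] != 0 or M[dl, m1] != 0:
                raise ShapeError("DLPFC<->M1 couplings must be exactly zero")
        if np.any(np.diag(A) >= 0):
            raise StabilityError("diagonal of A must be strictly negative")
        if np.any(np.real(np.linalg.eigvals(A)) >= 0):
            raise StabilityError("A has an eigenvalue with non-negative real part")
        if self.input_region not in ("PMC", "SMA"):
            raise InvalidConfigError("input_region must be PMC or SMA")
        c = np.asarray(self.C, float)
        mask = np.zeros(4, bool)
        mask[NODE_INDEX[self.input_region]] = True
        if np.any(c[~mask] != 0) or c[mask][0] == 0:
            raise ShapeError("C must be nonzero only at the input region")


def default_network(input_region: str = "PMC", modulation: float = 0.3) -> GroundTruthNetwork:
    """A stable default: fixed self-decay, weak intrinsic couplings, task
    modulation on the motor core plus the DLPFC return loop of the input region."""
    A = -np.eye(4)
    pairs = [
        ("PMC", "SMA"), ("SMA", "PMC"),
        ("PMC", "M1"), ("M1", "PMC"),
        ("SMA", "M1"), ("M1", "SMA"),
        ("PMC", "DLPFC"), ("DLPFC", "PMC"),
        ("SMA", "DLPFC"), ("DLPFC", "SMA"),
    ]
    for tgt, src in pairs:
        A[NODE_INDEX[tgt], NODE_INDEX[src]] = 0.15
    B = np.zeros((4, 4))
    for tgt, src in [("SMA", "PMC"), ("M1", "PMC"), ("M1", "SMA")]:
        B[NODE_INDEX[tgt], NODE_INDEX[src]] = modulation
    B[NODE_INDEX["DLPFC"], NODE_INDEX[input_region]] = modulation
    C = np.zeros(4)
    C[NODE_INDEX[input_region]] = 1.0
    net = GroundTruthNetwork(A=A, B={"task": B}, C=C, input_region=input_region)
    net.validate()
    return net


def simulate_network_dynamics(
    net: GroundTruthNetwork,
    driving_input: np.ndarray,
    modulatory_inputs: dict | None,
    dt: float,
    method: str = "zoh",
) -> np.ndarray:
    """Integrate dx/dt = (A + sum_j u_j B_j) x + C u_drive from x(0)=0 -> (4, n)."""
    if dt <= 0:
        raise InvalidConfigError("dt must be positive")
    net.validate()
    modulatory_inputs = modulatory_inputs or {}
    names = sorted(set(net.B) & set(modulatory_inputs))
    B_list = [np.asarray(net.B[nm], float) for nm in names]
    u_mods = [np.asarray(modulatory_inputs[nm], float) for nm in names]
    n = len(np.asarray(driving_input))
    for u in u_mods:
        if len(u) != n:
            raise ShapeError("modulatory inputs must share the driving-input grid")
    return _integrator.trajectory(net.A, B_list, net.C, driving_input, u_mods, dt, method=method)


def paradigm_inputs(paradigm: TaskParadigm, fs: float, duration: float | None = None):
    """Driving input (boxcar over each dot) and task modulatory boxcar
    (dot onset to dot onset + dot duration), sampled at ``fs``."""
    duration = duration if duration is not None else paradigm.duration
    n = int(round(duration * fs))
    drive = np.zeros(n)
    mod = np.zeros(n)
    for b in paradigm.blocks:
        for t in b.trial_onsets:
            i0 = int(round(t * fs))
            i1 = min(int(round((t + b.dot_duration) * fs)), n)
            drive[i0:i1] = 1.0
            mod[i0:i1] = 1.0
    return drive, mod


# ---------------------------------------------------------------------------
# lead field and scalp projection
# ---------------------------------------------------------------------------

@dataclass
class LeadField:
    gain: np.ndarray  # (n_channels, n_sources), uV per source unit
    channel_labels: tuple[str, ...]
    source_positions: np.ndarray  # (n_sources, 3) mm

    def validate(self):
        g = np.asarray(self.gain, float)
        if g.shape[0] != len(self.channel_labels):
            raise ShapeError("one gain row per channel required")
        if g.shape[1] != len(self.source_positions):
            raise ShapeError("one gain column per source required")
        if not np.all(np.isfinite(g)):
            raise ShapeError("lead-field entries must be finite")
        if np.any(np.all(g == 0, axis=1)):
            raise ShapeError("lead field has an all-zero channel row")


def gaussian_leadfield(
    source_positions: np.ndarray,
    channel_labels=None,
    spread_mm: float = 45.0,
) -> LeadField:
    """Gaussian spatial-spread gain from sources to spherical-scalp electrodes."""
    labels = tuple(channel_labels) if channel_labels is not None else montage.CHANNELS_32
    pos = montage.positions(labels)
    src = np.asarray(source_positions, float)
    d2 = np.sum((pos[:, None, :] - src[None, :, :]) ** 2, axis=2)
    gain = np.exp(-d2 / (2 * spread_mm**2))
    lf = LeadField(gain=gain, channel_labels=labels, source_positions=src)
    lf.validate()
    return lf


def default_source_positions(
    roiset: ROISet | None = None, n_distractors: int = 20, seed: int = 0
) -> np.ndarray:
    """ROI centres first, then uniformly scattered distractor sources."""
    roiset = roiset or default_roiset()
    rng = np.random.default_rng(seed)
    pts = [roiset.center_array()]
    n = 0
    while n < n_distractors:
        cand = rng.uniform(-75, 75, size=3)
        if np.linalg.norm(cand) < 75:
            pts.append(cand[None])
            n += 1
    return np.vstack(pts)


@dataclass
class SimulatedRecording:
    data: np.ndarray  # (n_channels, n_samples) uV
    fs: float
    events: pd.DataFrame  # onset_sample, label, block_index
    channel_labels: tuple[str, ...]
    artifacts: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def _pink_noise(rng, shape, fs):
    """1/f-amplitude noise, unit standard deviation per row."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f[0] = f[1] if len(f) > 1 else 1.0
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def project_to_scalp(
    sources: np.ndarray,
    leadfield: LeadField,
    noise_model: dict | None,
    fs: float,
    seed: int = 0,
    events: pd.DataFrame | None = None,
) -> SimulatedRecording:
    """data = gain @ sources + pink background + white sensor noise."""
    leadfield.validate()
    S = np.asarray(sources, float)
    if S.shape[0] != leadfield.gain.shape[1]:
        raise ShapeError(
            f"lead field expects {leadfield.gain.shape[1]} sources, got {S.shape[0]}"
        )
    noise_model = noise_model or {}
    pink_sd = float(noise_model.get("pink_noise_sd", 0.0))
    white_sd = float(noise_model.get("sensor_noise_sd", 0.0))
    rng = np.random.default_rng(seed)
    data = leadfield.gain @ S
    if pink_sd > 0:
        data = data + pink_sd * _pink_noise(rng, data.shape, fs)
    if white_sd > 0:
        data = data + white_sd * rng.standard_normal(data.shape)
    if events is None:
        events = pd.DataFrame(columns=["onset_sample", "label", "block_index"])
    return SimulatedRecording(
        data=data, fs=fs, events=events, channel_labels=leadfield.channel_labels
    )


# ---------------------------------------------------------------------------
# behaviour and artifacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseLog:
    entries: tuple  # of (block_index, "correct" | "incorrect")

    @property
    def n_blocks(self) -> int:
        return len(self.entries)

    @property
    def accuracy(self) -> float:
        if not self.entries:
            return float("nan")
        return sum(1 for _, r in self.entries if r == "correct") / len(self.entries)

    def response_of(self, block_index: int) -> str:
        return dict(self.entries)[block_index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["block_index", "response"])


def generate_responses(
    paradigm: TaskParadigm, p_correct: float | None = None, seed: int = 0
) -> ResponseLog:
    """I.i.d. Bernoulli per block; default rates 0.904 (ME) / 0.845 (MI)."""
    if p_correct is None:
        p_correct = DEFAULT_P_CORRECT[paradigm.session_kind]
    if not 0.0 <= p_correct <= 1.0:
        raise InvalidConfigError("p_correct must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    draws = rng.random(paradigm.n_blocks) < p_correct
    entries = tuple(
        (i, "correct" if ok else "incorrect") for i, ok in enumerate(draws)
    )
    return ResponseLog(entries=entries)


def blink_template(fs: float, duration: float = 0.4) -> np.ndarray:
    """Fixed biphasic 400-ms waveform (Hann-windowed full sine cycle)."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    return np.hanning(n) * np.sin(2 * np.pi * t / duration)


def blink_channel_weights(channel_labels) -> np.ndarray:
    """Frontal-proximity weights (peak 1 at the channel nearest the eyes)."""
    origin = np.array([0.0, 95.0, -25.0])
    pos = montage.positions(channel_labels)
    d2 = np.sum((pos - origin) ** 2, axis=1)
    w = np.exp(-d2 / (2 * 45.0**2))
    return w / w.max()


def inject_artifacts(
    recording: SimulatedRecording,
    blink_rate: float = 0.0,
    blink_amplitude_uv: float = 80.0,
    spike_spec=None,
    seed: int = 0,
) -> SimulatedRecording:
    """Add frontal-weighted blink transients (Poisson process) and listed
    amplitude spikes; injected times are recorded in ``artifacts``."""
    if blink_rate < 0:
        raise InvalidConfigError("blink_rate must be >= 0")
    rng = np.random.default_rng(seed)
    data = recording.data.copy()
    fs = recording.fs
    n = data.shape[1]
    duration = n / fs

    blink_times = []
    if blink_rate > 0:
        n_blinks = rng.poisson(blink_rate * duration)
        starts = np.sort(rng.uniform(0, max(duration - 0.4, 0), size=n_blinks))
        tpl = blink_template(fs)
        w = blink_channel_weights(recording.channel_labels)
        for t0 in starts:
            i0 = int(round(t0 * fs))
            seg = tpl[: n - i0]
            data[:, i0 : i0 + len(seg)] += blink_amplitude_uv * w[:, None] * seg[None, :]
            blink_times.append(float(t0))

    spike_times = []
    for sp in spike_spec or []:
        i0 = int(round(sp["time_s"] * fs))
        width = int(round(sp.get("width_s", 0.01) * fs)) or 1
        ch = sp.get("channel")
        rows = slice(None) if ch is None else recording.channel_labels.index(ch)
        data[rows, i0 : i0 + width] += sp["amplitude_uv"]
        spike_times.append(float(sp["time_s"]))

    arts = dict(recording.artifacts)
    arts["blink_times"] = arts.get("blink_times", []) + blink_times
    arts["spike_times"] = arts.get("spike_times", []) + spike_times
    return replace(recording, data=data, artifacts=arts)


# ---------------------------------------------------------------------------
# end-to-end session simulator
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    session_kind: str = "ME"
    n_blocks: int = 20
    trial_count_range: tuple = (3, 4, 5)
    timing: TimingConfig = field(default_factory=TimingConfig)
    fs_raw: float = 1024.0
    n_distractors: int = 20
    input_region: str | None = None  # default: PMC for ME, SMA for MI
    modulation: float = 0.3
    dynamics_amplitude_uv: float = 4.0
    mu_freq: float = 10.0
    beta_freq: float = 18.0
    mu_amplitude_uv: float = 3.0
    beta_amplitude_uv: float = 1.5
    erd_depth_mu: float = 0.5
    erd_depth_beta: float = 0.3
    erd_trial_growth: float = 0.0  # fractional depth increase per trial index
    distractor_amplitude_uv: float = 1.0
    pink_noise_sd: float = 0.5
    sensor_noise_sd: float = 0.5
    blink_rate: float = 0.0
    blink_amplitude_uv: float = 60.0
    p_correct: float | None = None

    def resolved_input_region(self) -> str:
        if self.input_region:
            return self.input_region
        return "PMC" if self.session_kind == "ME" else "SMA"


@dataclass
class SessionData:
    config: SimulationConfig
    paradigm: TaskParadigm
    network: GroundTruthNetwork
    leadfield: LeadField
    recording: SimulatedRecording
    responses: ResponseLog
    roi_sources: np.ndarray  # (4, n_samples) ground-truth ROI signals


def _erd_envelope(paradigm, fs, n, depth, growth):
    env = np.ones(n)
    for b in paradigm.blocks:
        for ti, t in enumerate(b.trial_onsets):
            d = min(depth * (1.0 + growth * ti), 0.95)
            i0 = int(round(t * fs))
            i1 = min(int(round((t + b.dot_duration + b.fixation_duration) * fs)), n)
            env[i0:i1] = np.minimum(env[i0:i1], 1.0 - d)
    return env


def _recording_events(paradigm: TaskParadigm, fs: float) -> pd.DataFrame:
    ev = paradigm.events()
    return pd.DataFrame(
        {
            "onset_sample": np.round(ev["onset"] * fs).astype(int),
            "label": ev["trial_type"],
            "block_index": ev["block_index"],
        }
    )


def simulate_session(config: SimulationConfig | None = None, seed: int = 0) -> SessionData:
    """Generate one complete synthetic session (paradigm through recording)."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    paradigm = generate_paradigm(
        config.session_kind,
        config.n_blocks,
        config.trial_count_range,
        config.timing,
        seed=int(rng.integers(2**31)),
    )
    fs = config.fs_raw
    duration = paradigm.duration
    n = int(round(duration * fs))
    net = default_network(config.resolved_input_region(), config.modulation)

    drive, mod = paradigm_inputs(paradigm, fs, duration)
    states = simulate_network_dynamics(net, drive, {"task": mod}, 1.0 / fs)

    t = np.arange(n) / fs
    mu_env = _erd_envelope(paradigm, fs, n, config.erd_depth_mu, config.erd_trial_growth)
    beta_env = _erd_envelope(paradigm, fs, n, config.erd_depth_beta, config.erd_trial_growth)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    mu_osc = np.sin(2 * np.pi * config.mu_freq * t + phases[0])
    beta_osc = np.sin(2 * np.pi * config.beta_freq * t + phases[1])

    roi_sources = config.dynamics_amplitude_uv * states
    # sensorimotor rhythm with task-locked suppression rides on M1 (strong)
    # and PMC/SMA (weaker)
    for lb, w in (("M1", 1.0), ("PMC", 0.4), ("SMA", 0.4)):
        i = NODE_INDEX[lb]
        roi_sources[i] = roi_sources[i] + w * (
            config.mu_amplitude_uv * mu_env * mu_osc
            + config.beta_amplitude_uv * beta_env * beta_osc
        )

    src_pos = default_source_positions(
        n_distractors=config.n_distractors, seed=int(rng.integers(2**31))
    )
    lf = gaussian_leadfield(src_pos)
    distractors = config.distractor_amplitude_uv * _pink_noise(
        rng, (config.n_distractors, n), fs
    ) if config.n_distractors else np.zeros((0, n))
    sources = np.vstack([roi_sources, distractors])

    events = _recording_events(paradigm, fs)
    rec = project_to_scalp(
        sources,
        lf,
        {"pink_noise_sd": config.pink_noise_sd, "sensor_noise_sd": config.sensor_noise_sd},
        fs,
        seed=int(rng.integers(2**31)),
        events=events,
    )
    if config.blink_rate > 0:
        rec = inject_artifacts(
            rec,
            blink_rate=config.blink_rate,
            blink_amplitude_uv=config.blink_amplitude_uv,
            seed=int(rng.integers(2**31)),
        )
    responses = generate_responses(paradigm, config.p_correct, seed=int(rng.integers(2**31)))
    return SessionData(
        config=config,
        paradigm=paradigm,
        network=net,
        leadfield=lf,
        recording=rec,
        responses=responses,
        roi_sources=roi_sources,
    )


def write_session(session: SessionData, edf_path, events_path) -> None:
    """Persist a session as 16-bit EDF plus a BIDS-style events TSV."""
    rec = session.recording
    write_edf(edf_path, rec.data, rec.fs, list(rec.channel_labels))
    ev = session.paradigm.events().copy()
    resp = dict(session.responses.entries)
    ev["response"] = [resp.get(bi, "n/a") for bi in ev["block_index"]]
    ev.to_csv(events_path, sep="\t", index=False)
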