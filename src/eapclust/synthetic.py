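"""Synthetic data generators with known ground truth.

Every input modality of the analysis pipeline can be generated here:
multi-channel EAP waveforms with controlled width/repolarization and
direction-dependent linear trough propagation, mixture populations of such
waveforms, Poisson/gamma-renewal spike trains, band-limited LFP traces with
von Mises phase-locked spiking, optotagging trial rasters, and SWC
morphologies with bifurcations at requested depths.

The EAP template is a two-lobe function: a negative Gaussian trough plus a
delayed positive lobe that rises as sin^2 up to the peak and decays
exponentially afterwards.  The template is parameterised directly by the
trough-to-peak width (tpw) and the repolarization time (rep) so that
feature extraction on noiseless output recovers both to within one sample
of quantization: the positive lobe peaks exactly ``tpw`` after the trough,
and its exponential decay constant ``rep / ln 2`` places the half-peak
crossing exactly ``rep`` after the peak.

All generators are deterministic given (params, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import BoundaryError, ParameterError, TopologyError
from .morphology import MorphologyTree
from .spiketrains import OptoSession
from .waveforms import MultichannelWaveform

__all__ = [
    "ProbeGeometry",
    "EapGenParams",
    "PopulationComponent",
    "SpikeTrainGenParams",
    "PhaseLockGenParams",
    "OptoGenParams",
    "gen_multichannel_eap",
    "gen_unit_population",
    "gen_spike_train",
    "gen_lfp_with_locked_spikes",
    "gen_optotagging_session",
    "gen_morphology",
]


@dataclass(frozen=True)
class ProbeGeometry:
    """One two-column side of a high-density probe.

    Sites are approximated by their vertical spacing (20 µm per row);
    staggered-column lateral offsets are ignored.  At least 21 rows are
    required so a ±200 µm window around a central channel exists.
    """

    n_rows: int = 41
    vertical_spacing: float = 20.0  # µm
    n_cols: int = 2

    def __post_init__(self):
        if self.n_rows < 21:
            raise ParameterError("need >= 21 rows for a +-200 um window")
        if self.vertical_spacing <= 0:
            raise ParameterError("vertical_spacing must be positive")

    @property
    def channel_depths(self) -> np.ndarray:
        """µm offsets relative to row 0, increasing toward the pia."""
        return np.arange(self.n_rows) * self.vertical_spacing


@dataclass(frozen=True)
class EapGenParams:
    """Generative counterparts of the waveform features.

    inv_v_above (>= 0) and inv_v_below (<= 0) are the latency-vs-signed-depth
    slopes in ms/µm; positive depth is toward the pia.
    """

    soma_channel: int = 20
    amplitude: float = 150.0  # µV
    tpw: float = 0.5  # ms
    rep: float = 0.3  # ms
    inv_v_above: float = 0.002  # ms/µm
    inv_v_below: float = -0.002  # ms/µm
    decay_length: float = 100.0  # µm
    noise_sd: float = 0.0  # µV
    sampling_rate: float = 30000.0  # Hz

    def __post_init__(self):
        if self.tpw <= 0 or self.rep <= 0:
            raise ParameterError("tpw and rep must be positive")
        if self.decay_length <= 0:
            raise ParameterError("decay_length must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.amplitude <= 0:
            raise ParameterError("amplitude must be positive")
        if self.inv_v_above < 0 or self.inv_v_below > 0:
            raise ParameterError("inv_v_above must be >= 0 and inv_v_below <= 0")


def _template(t_rel_ms: np.ndarray, tpw: float, rep: float) -> np.ndarray:
    """Unit-amplitude two-lobe EAP template; trough at t=0, peak at t=tpw."""
    sigma = tpw / 5.0
    v = -np.exp(-0.5 * (t_rel_ms / sigma) ** 2)
    lobe = np.zeros_like(t_rel_ms)
    rising = (t_rel_ms >= 0) & (t_rel_ms <= tpw)
    lobe[rising] = np.sin(0.5 * np.pi * t_rel_ms[rising] / tpw) ** 2
    after = t_rel_ms > tpw
    lobe[after] = np.exp(-math.log(2.0) * (t_rel_ms[after] - tpw) / rep)
    return v + 0.4 * lobe


def gen_multichannel_eap(
    params: EapGenParams,
    geometry: ProbeGeometry = ProbeGeometry(),
    seed: int = 0,
    unit_id: object = None,
    pre_ms: float = 2.0,
    post_ms: float = 4.0,
) -> MultichannelWaveform:
    """Generate one multi-channel EAP.

    Per channel at signed depth d relative to the soma channel, the
    amplitude decays as exp(-|d|/decay_length) and the trough latency is
    ``inv_v_above * d`` for d > 0 and ``inv_v_below * d`` for d < 0 (both
    non-negative shifts: the spike propagates outward).  White noise of
    ``noise_sd`` µV is added.
    """
    if not (10 <= params.soma_channel <= geometry.n_rows - 11):
        raise BoundaryError(
            f"soma_channel {params.soma_channel} must be >= 10 rows from both probe ends"
        )
    rng = np.random.default_rng(seed)
    dt = 1000.0 / params.sampling_rate
    n_samples = int(round((pre_ms + post_ms) / dt)) + 1
    # snap the soma trough time to the sample grid
    t0 = round(pre_ms / dt) * dt
    t = np.arange(n_samples) * dt

    depths = geometry.channel_depths
    d = depths - depths[params.soma_channel]
    shift = np.where(d > 0, params.inv_v_above * d, params.inv_v_below * d)
    amp = params.amplitude * np.exp(-np.abs(d) / params.decay_length)

    samples = amp[:, None] * _template(
        t[None, :] - t0 - shift[:, None], params.tpw, params.rep
    )
    if params.noise_sd > 0:
        samples = samples + rng.normal(0.0, params.noise_sd, samples.shape)
    return MultichannelWaveform(
        samples=samples,
        sampling_rate=params.sampling_rate,
        channel_depths=depths,
        unit_id=unit_id,
    )


@dataclass(frozen=True)
class PopulationComponent:
    """One mixture component of a unit population.

    ``sd`` maps EapGenParams field names to Gaussian standard deviations;
    unlisted fields are held at the component mean.
    """

    mean: EapGenParams
    sd: dict = field(default_factory=dict)
    weight: float = 1.0
    name: str = ""

    def __post_init__(self):
        for k, v in self.sd.items():
            if v < 0:
                raise ParameterError(f"negative SD for {k}")
            if not hasattr(self.mean, k):
                raise ParameterError(f"unknown EapGenParams field {k}")


_POSITIVE_FIELDS = {"amplitude", "tpw", "rep", "decay_length", "noise_sd"}


def _draw_params(comp: PopulationComponent, rng: np.random.Generator) -> EapGenParams:
    kw = {}
    for name, sd in comp.sd.items():
        mu = getattr(comp.mean, name)
        val = rng.normal(mu, sd)
        if name in _POSITIVE_FIELDS:
            val = abs(val) or mu
        elif name == "inv_v_above":
            val = max(val, 0.0)
        elif name == "inv_v_below":
            val = min(val, 0.0)
        kw[name] = val
    return replace(comp.mean, **kw) if kw else comp.mean


def gen_unit_population(
    cluster_spec: list[PopulationComponent],
    n_units: int,
    seed: int = 0,
    geometry: ProbeGeometry = ProbeGeometry(),
) -> tuple[list[MultichannelWaveform], np.ndarray]:
    """Draw a mixture population of multi-channel EAPs.

    Returns the waveforms and the ground-truth component index per unit.
    """
    weights = np.array([c.weight for c in cluster_spec], dtype=float)
    if n_units < len(cluster_spec):
        raise ParameterError("n_units must be >= number of components")
    if not math.isclose(weights.sum(), 1.0, rel_tol=1e-6):
        raise ParameterError("component weights must sum to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(cluster_spec), size=n_units, p=weights)
    waveforms = []
    for i, lab in enumerate(labels):
        p = _draw_params(cluster_spec[lab], rng)
        wf_seed = int(rng.integers(0, 2**31 - 1))
        waveforms.append(
            gen_multichannel_eap(p, geometry, seed=wf_seed, unit_id=i)
        )
    return waveforms, labels


@dataclass(frozen=True)
class SpikeTrainGenParams:
    model: str = "poisson"  # {"poisson", "gamma-renewal"}
    rate: float = 5.0  # Hz
    duration: float = 100.0  # s
    gamma_shape: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.rate <= 0 or self.duration <= 0:
            raise ParameterError("rate and duration must be positive")
        if self.model not in ("poisson", "gamma-renewal"):
            raise ParameterError(f"unknown spike-train model {self.model!r}")
        if self.rate * self.duration < 1:
            raise ParameterError("expected spike count below 1")


def gen_spike_train(params: SpikeTrainGenParams) -> np.ndarray:
    """Renewal spike train; sorted strictly increasing times in [0, duration]."""
    rng = np.random.default_rng(params.seed)
    n_guess = int(params.rate * params.duration * 1.5 + 50)
    times = []
    t = 0.0
    while True:
        if params.model == "poisson":
            isis = rng.exponential(1.0 / params.rate, n_guess)
        else:
            k = params.gamma_shape
            isis = rng.gamma(k, 1.0 / (params.rate * k), n_guess)
        for isi in isis:
            t += isi
            if t > params.duration:
                return np.array(times)
            times.append(t)


@dataclass(frozen=True)
class PhaseLockGenParams:
    band_center: float = 40.0  # Hz
    kappa_true: float = 2.0
    preferred_phase_true: float = 180.0  # degrees, 180 = LFP trough
    n_spikes: int = 1000
    lfp_rate: float = 1250.0  # Hz
    noise_amp: float = 0.2  # broadband noise relative to unit sinusoid
    seed: int = 0

    def __post_init__(self):
        if self.kappa_true < 0:
            raise ParameterError("kappa_true must be >= 0")
        if self.band_center >= self.lfp_rate / 2:
            raise ParameterError("band_center at or above Nyquist")


def gen_lfp_with_locked_spikes(
    params: PhaseLockGenParams,
) -> tuple[np.ndarray, np.ndarray]:
    """LFP trace plus spikes phase-locked to it.

    The LFP is a unit cosine at ``band_center`` plus broadband noise, so
    instantaneous phase 0° is the oscillation peak and 180° the trough.
    Spike phases are drawn from a von Mises distribution centred on
    ``preferred_phase_true`` with concentration ``kappa_true`` (uniform for
    kappa 0) and mapped to spike times through the oscillation's phase,
    with the host cycle drawn uniformly.
    """
    rng = np.random.default_rng(params.seed)
    f = params.band_center
    n_cycles = max(50, int(math.ceil(params.n_spikes / 5)))
    duration = n_cycles / f
    n_samp = int(round(duration * params.lfp_rate))
    t = np.arange(n_samp) / params.lfp_rate
    lfp = np.cos(2 * np.pi * f * t)
    if params.noise_amp > 0:
        lfp = lfp + params.noise_amp * rng.standard_normal(n_samp)

    if params.kappa_true == 0:
        phases = rng.uniform(0.0, 2 * np.pi, params.n_spikes)
    else:
        mu = math.radians(params.preferred_phase_true)
        phases = rng.vonmises(mu, params.kappa_true, params.n_spikes) % (2 * np.pi)
    cycles = rng.integers(0, n_cycles - 1, params.n_spikes)
    spike_times = np.sort((cycles + phases / (2 * np.pi)) / f)
    return lfp, spike_times


@dataclass(frozen=True)
class OptoGenParams:
    baseline_rate: float = 5.0  # Hz
    response_rate: float = 50.0  # Hz
    pulse_duration: float = 10.0  # ms
    n_trials: int = 100
    latency_jitter: float = 1.0  # ms; evoked spiking starts at 2 ms + U(0, jitter)
    pre_window: float = 10.0  # ms of raster before pulse onset
    post_window: float = 20.0  # ms of raster after pulse onset
    seed: int = 0

    def __post_init__(self):
        if self.baseline_rate < 0 or self.response_rate < 0:
            raise ParameterError("rates must be >= 0")
        if self.pulse_duration <= 0:
            raise ParameterError("pulse_duration must be positive")
        if self.n_trials < 1:
            raise ParameterError("n_trials must be >= 1")


def _poisson_times(rng, rate_hz: float, t0_ms: float, t1_ms: float) -> np.ndarray:
    if rate_hz <= 0 or t1_ms <= t0_ms:
        return np.empty(0)
    n = rng.poisson(rate_hz * (t1_ms - t0_ms) / 1000.0)
    return np.sort(rng.uniform(t0_ms, t1_ms, n))


def gen_optotagging_session(params: OptoGenParams) -> tuple[OptoSession, np.ndarray]:
    """Trial raster around light pulses.

    Spiking is Poisson at ``baseline_rate`` outside the pulse and at
    ``response_rate`` from a short per-trial latency (2 ms plus uniform
    jitter) to pulse offset.  Returns the raster (times in ms relative to
    pulse onset) and the absolute pulse onset times.
    """
    rng = np.random.default_rng(params.seed)
    trials = []
    iti_ms = 250.0
    onsets = np.arange(params.n_trials) * iti_ms
    for _ in range(params.n_trials):
        latency = 2.0 + rng.uniform(0.0, params.latency_jitter)
        parts = [
            _poisson_times(rng, params.baseline_rate, -params.pre_window, latency),
            _poisson_times(rng, params.response_rate, latency, params.pulse_duration),
            _poisson_times(
                rng, params.baseline_rate, params.pulse_duration, params.post_window
            ),
        ]
        trials.append(np.sort(np.concatenate(parts)))
    session = OptoSession(
        trials=trials,
        pulse_duration=params.pulse_duration,
        pre_window=params.pre_window,
        post_window=params.post_window,
    )
    return session, onsets


def gen_morphology(
    bif_spec: list[tuple[float, int]],
    seed: int = 0,
    soma_radius: float = 6.0,
) -> MorphologyTree:
    """Synthetic dendritic tree with bifurcations at requested depths.

    ``bif_spec`` lists (signed y-offset from the soma in µm, branch order)
    pairs; each entry produces one bifurcation node at exactly that
    vertical offset, reached through ``branch_order`` intermediate nodes,
    with two short terminal children so the node has two children.
    """
    rng = np.random.default_rng(seed)
    rows = [(1, 1, 0.0, 0.0, 0.0, soma_radius, -1)]
    next_id = 2
    for j, (offset, order) in enumerate(bif_spec):
        order = max(1, int(order))
        x_base = 15.0 * (j + 1)
        parent = 1
        for step in range(1, order + 1):
            frac = step / order
            node_type = 3  # basal dendrite
            rows.append(
                (
                    next_id,
                    node_type,
                    x_base * frac + rng.normal(0.0, 0.5),
                    offset * frac,
                    0.0,
                    1.0,
                    parent,
                )
            )
            parent = next_id
            next_id += 1
        # the last chain node is the bifurcation: give it two leaf children
        # (its y equals the requested offset exactly)
        rows[-1] = rows[-1][:3] + (float(offset),) + rows[-1][4:]
        for dx in (-5.0, 5.0):
            rows.append(
                (next_id, 3, x_base + dx, offset + 8.0, 0.0, 0.8, parent)
            )
            next_id += 1
    tree = MorphologyTree.from_rows(rows)
    if sum(1 for r in rows if r[6] == -1) != 1:
        raise TopologyError("exactly one soma/root node required")
    return tree
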