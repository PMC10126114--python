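"""One- and multi-channel EAP waveform feature extraction.

The one-channel features are the classic trough-to-peak width (TPW, time
from the global minimum of the peak-channel waveform to the following local
maximum) and repolarization time (REP, time from that peak to its half-peak
crossing).  The multi-channel features describe how the spike propagates
along the probe: the inverse propagation velocity below (1/V_below) and
above (1/V_above) the soma, obtained by linear regression of per-channel
trough latency against signed channel depth, the spatial spread of the
waveform, and a propagation symmetry index.

Depth convention: channel depths are signed micrometres with positive values
toward the pia ("above" the soma).  With this convention outward propagation
in both directions yields a negative slope below the soma and a positive
slope above it, so the symmetry index |1/V_below + 1/V_above| / sqrt(2)
(the distance of the point to the line y = -x) is zero exactly for
equal-speed propagation in both directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .errors import DegenerateInputError, FeatureUndefinedError

__all__ = [
    "MultichannelWaveform",
    "OneChannelFeatures",
    "MultiChannelFeatures",
    "extract_one_channel_features",
    "extract_multichannel_features",
    "symmetry_index",
]


@dataclass
class MultichannelWaveform:
    """Per-unit mean EAP matrix with channel geometry.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Mean extracellular waveform per channel, in microvolts.
    sampling_rate : float
        Samples per second (30 kHz for Neuropixels acquisition).
    channel_depths : ndarray, shape (n_channels,)
        Signed channel depths in micrometres, strictly increasing toward
        the pia.
    unit_id : hashable
        Opaque unit identifier.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_depths: np.ndarray
    unit_id: object = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_depths = np.asarray(self.channel_depths, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if self.samples.shape[0] != self.channel_depths.size:
            raise ValueError("one depth per channel required")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        d = np.diff(self.channel_depths)
        if self.channel_depths.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("channel depths must be strictly monotone")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def dt_ms(self) -> float:
        """Inter-sample interval in milliseconds (0.0333 ms at 30 kHz)."""
        return 1000.0 / self.sampling_rate

    def peak_channel(self) -> int:
        """Channel with the largest waveform extremum magnitude."""
        return int(np.argmax(np.max(np.abs(self.samples), axis=1)))


@dataclass
class OneChannelFeatures:
    tpw: float  # ms
    rep: float  # ms
    amplitude: float  # µV, magnitude of the trough
    peak_channel: int


@dataclass
class MultiChannelFeatures:
    inv_v_below: float  # ms/µm, slope over channels at d <= 0
    inv_v_above: float  # ms/µm, slope over channels at d >= 0
    symmetry_index: float  # ms/µm
    spread: float  # µm
    n_channels_below: int
    n_channels_above: int
    propagation_ratio: float = math.nan  # 1/V_below over 1/V_above, auxiliary
    flagged: bool = False
    flags: list = field(default_factory=list)


def symmetry_index(inv_v_below: float, inv_v_above: float) -> float:
    """Propagation symmetry index.

    Distance of the point (1/V_below, 1/V_above) from the diagonal line
    y = -x, i.e. |x0 + y0| / sqrt(2).  Zero means the spike propagates at
    equal speed below and above the soma; larger values mean more
    asymmetric propagation.
    """
    return abs(inv_v_below + inv_v_above) / math.sqrt(2.0)


def _trough_and_peak(trace: np.ndarray) -> tuple[int, int]:
    """Indices of the global minimum and the following local maximum."""
    if trace.size < 3 or np.ptp(trace) == 0:
        raise DegenerateInputError("flat or too-short waveform")
    trough = int(np.argmin(trace))
    after = trace[trough:]
    if after.size < 2:
        raise FeatureUndefinedError("trough at the end of the trace; no peak")
    peak = trough + int(np.argmax(after))
    # a maximum at the final sample that is still rising is not a local max
    if peak == trace.size - 1 and trace[-1] > trace[-2]:
        raise FeatureUndefinedError("no local maximum after the trough")
    if peak == trough:
        raise FeatureUndefinedError("no local maximum after the trough")
    return trough, peak


def extract_one_channel_features(w: MultichannelWaveform) -> OneChannelFeatures:
    """Extract TPW, REP and amplitude from the peak channel.

    TPW is the time from the global minimum (trough) of the peak-channel
    waveform to the following local maximum.  REP is the time from that
    peak to the first crossing of half the peak value, found by forward
    scan with linear interpolation between samples.  Amplitude is the
    magnitude of the trough.
    """
    pc = w.peak_channel()
    trace = w.samples[pc]
    trough, peak = _trough_and_peak(trace)
    dt = w.dt_ms
    tpw = (peak - trough) * dt

    peak_val = trace[peak]
    half = peak_val / 2.0
    rep = None
    for i in range(peak + 1, trace.size):
        if trace[i] <= half:
            # linear interpolation between samples i-1 and i
            y0, y1 = trace[i - 1], trace[i]
            frac = (y0 - half) / (y0 - y1) if y1 != y0 else 0.0
            rep = (i - 1 + frac - peak) * dt
            break
    if rep is None:
        raise FeatureUndefinedError("waveform never decays to half peak")
    return OneChannelFeatures(
        tpw=tpw, rep=rep, amplitude=float(abs(trace[trough])), peak_channel=pc
    )


def _side_slope(depths: np.ndarray, latencies: np.ndarray) -> tuple[float, int]:
    """Least-squares slope of latency (ms) vs signed depth (µm)."""
    if depths.size < 3:
        return math.nan, int(depths.size)
    if np.ptp(depths) == 0:
        return math.nan, int(depths.size)
    res = sstats.linregress(depths, latencies)
    return float(res.slope), int(depths.size)


def extract_multichannel_features(
    w: MultichannelWaveform,
    spread_frac: float = 0.12,
    window_um: float = 200.0,
    analysis_window_ms: tuple[float, float] = (1.0, 2.0),
) -> MultiChannelFeatures:
    """Extract propagation-velocity, spread and symmetry features.

    Channels within ``window_um`` of the peak channel are used (10 rows
    above and below at 20 µm pitch).  Per-channel trough latency is the
    time of that channel's minimum relative to the peak-channel trough,
    searched within an analysis window around it.  Channels whose
    amplitude falls below ``spread_frac`` of the maximum are excluded from
    the velocity fits.  The spread is the extent in µm of the contiguous
    supra-threshold run of channels containing the peak channel.
    """
    pc = w.peak_channel()
    depths = w.channel_depths - w.channel_depths[pc]
    in_window = np.abs(depths) <= window_um + 1e-9
    idx = np.flatnonzero(in_window)

    ref_trace = w.samples[pc]
    if np.ptp(ref_trace) == 0:
        raise DegenerateInputError("flat waveform")
    ref_trough = int(np.argmin(ref_trace))
    dt = w.dt_ms
    lo = max(0, ref_trough - int(round(analysis_window_ms[0] / dt)))
    hi = min(ref_trace.size, ref_trough + int(round(analysis_window_ms[1] / dt)) + 1)

    amps = np.max(np.abs(w.samples[idx, lo:hi]), axis=1)
    troughs = lo + np.argmin(w.samples[idx, lo:hi], axis=1)
    latencies = (troughs - ref_trough) * dt
    d = depths[idx]

    amp_max = float(np.max(amps))
    usable = amps >= spread_frac * amp_max

    flags: list[str] = []
    below = usable & (d <= 0)
    above = usable & (d >= 0)
    inv_v_below, n_below = _side_slope(d[below], latencies[below])
    inv_v_above, n_above = _side_slope(d[above], latencies[above])
    if math.isnan(inv_v_below):
        flags.append("inv_v_below_undefined")
    if math.isnan(inv_v_above):
        flags.append("inv_v_above_undefined")

    # contiguous supra-threshold run containing the peak channel
    pc_pos = int(np.searchsorted(idx, pc))
    first = pc_pos
    while first > 0 and usable[first - 1]:
        first -= 1
    last = pc_pos
    while last < usable.size - 1 and usable[last + 1]:
        last += 1
    spread = float(d[last] - d[first])

    si = math.nan
    ratio = math.nan
    if not (math.isnan(inv_v_below) or math.isnan(inv_v_above)):
        si = symmetry_index(inv_v_below, inv_v_above)
        if inv_v_above != 0:
            ratio = inv_v_below / inv_v_above

    return MultiChannelFeatures(
        inv_v_below=inv_v_below,
        inv_v_above=inv_v_above,
        symmetry_index=si,
        spread=spread,
        n_channels_below=n_below,
        n_channels_above=n_above,
        propagation_ratio=ratio,
        flagged=bool(flags),
        flags=flags,
    )
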