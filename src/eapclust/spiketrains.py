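"""Spike-train statistics, visual-response metrics and optotagging detection.

Firing regularity is summarised by the coefficient of variation of
inter-spike intervals, CV = sd(ISI)/mean(ISI), and the local variation

    LV = 1/(n-1) * sum_i 3 (T_i - T_{i+1})^2 / (T_i + T_{i+1})^2

over adjacent ISI pairs (n = number of ISIs).  Both are dimensionless; a
Poisson train has CV = LV = 1 and a clock-like train 0.

Visual-response metrics for drifting gratings: f1/f0 (first-harmonic
amplitude of the preferred-condition PSTH at the stimulus temporal
frequency over the mean rate), the modulation index (z-scored spectral
power at the stimulus frequency relative to the PSTH power spectrum;
MI > 3 indicates strong modulation at the stimulus frequency), and
lifetime sparseness across conditions.

Optotagged units are detected from a 1 ms-binned PSTH around the light
pulse: tagged when the mean rate in the 2-8 ms response window exceeds
25 Hz and 2.5 times the rate in the equally long window just before onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "SpikeTrain",
    "IsiStats",
    "TuningTable",
    "TuningMetrics",
    "OptoSession",
    "OptoDetection",
    "isi_stats",
    "tuning_metrics",
    "detect_optotagged",
]


@dataclass
class SpikeTrain:
    spike_times: np.ndarray  # s, strictly increasing
    duration: float  # s
    unit_id: object = None

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.duration <= 0:
            raise ParameterError("duration must be positive")
        if self.spike_times.size:
            if np.any(np.diff(self.spike_times) <= 0):
                raise ParameterError("spike times must be strictly increasing")
            if self.spike_times[0] < 0 or self.spike_times[-1] > self.duration:
                raise ParameterError("spike times must lie within [0, duration]")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


@dataclass
class IsiStats:
    rate: float  # Hz
    cv: float
    lv: float
    isis_ms: np.ndarray
    flagged: bool = False


def isi_stats(train: SpikeTrain) -> IsiStats:
    """Firing rate, CV and LV of a spike train.

    CV and LV need at least 3 spikes (2 ISIs); with fewer they are NaN and
    the result is flagged.
    """
    n_spk = train.n_spikes
    rate = n_spk / train.duration
    isis = np.diff(train.spike_times) * 1000.0  # ms
    n = isis.size
    if n < 2:
        return IsiStats(rate=rate, cv=math.nan, lv=math.nan, isis_ms=isis, flagged=True)
    mean = isis.mean()
    cv = float(np.sqrt(np.sum((isis - mean) ** 2) / (n - 1)) / mean)
    adj = 3.0 * (isis[:-1] - isis[1:]) ** 2 / (isis[:-1] + isis[1:]) ** 2
    lv = float(adj.sum() / (n - 1))
    return IsiStats(rate=rate, cv=cv, lv=lv, isis_ms=isis)


@dataclass
class TuningTable:
    """Responses across stimulus conditions (orientation x temporal frequency).

    ``mean_rates`` holds the trial-averaged rate per condition (Hz);
    ``psth`` the per-condition PSTH in Hz at ``bin_ms`` resolution;
    ``stim_tf`` the stimulus temporal frequency per condition (Hz).
    """

    mean_rates: np.ndarray  # (n_conditions,)
    psth: np.ndarray  # (n_conditions, n_bins), Hz
    stim_tf: np.ndarray  # (n_conditions,), Hz
    bin_ms: float = 1.0

    def __post_init__(self):
        self.mean_rates = np.asarray(self.mean_rates, dtype=float)
        self.psth = np.atleast_2d(np.asarray(self.psth, dtype=float))
        self.stim_tf = np.asarray(self.stim_tf, dtype=float)
        if np.any(self.mean_rates < 0):
            raise ParameterError("rates must be >= 0")


@dataclass
class TuningMetrics:
    f1_f0: float
    modulation_index: float
    lifetime_sparseness: float
    preferred_condition: int
    flagged: bool = False


def lifetime_sparseness(rates: np.ndarray) -> float:
    """(1 - (Σr/n)² / (Σr²/n)) / (1 - 1/n); 1 = responds to one condition."""
    r = np.asarray(rates, dtype=float)
    n = r.size
    if n < 2 or np.all(r == 0):
        return math.nan
    num = (r.sum() / n) ** 2
    den = (r**2).sum() / n
    return float((1.0 - num / den) / (1.0 - 1.0 / n))


def tuning_metrics(table: TuningTable) -> TuningMetrics:
    """f1/f0, modulation index and lifetime sparseness for one unit."""
    pref = int(np.argmax(table.mean_rates))
    r0 = table.mean_rates[pref]
    if r0 <= 0:
        return TuningMetrics(math.nan, math.nan, math.nan, pref, flagged=True)
    psth = table.psth[pref]
    dt_s = table.bin_ms / 1000.0
    t = (np.arange(psth.size) + 0.5) * dt_s
    f_stim = table.stim_tf[pref]
    f0 = psth.mean()
    # first-harmonic amplitude at the stimulus temporal frequency
    f1 = 2.0 * np.abs(np.mean(psth * np.exp(-2j * np.pi * f_stim * t)))
    f1_f0 = float(f1 / f0) if f0 > 0 else math.nan

    # modulation index: z-scored power at the stimulus frequency w.r.t. the
    # PSTH power spectrum (DC excluded)
    spec = np.abs(np.fft.rfft(psth - psth.mean())) ** 2
    freqs = np.fft.rfftfreq(psth.size, d=dt_s)
    power = spec[1:]
    if power.size < 2 or power.std() == 0:
        mi = math.nan
    else:
        k = int(np.argmin(np.abs(freqs[1:] - f_stim)))
        mi = float((power[k] - power.mean()) / power.std())

    sparse = lifetime_sparseness(table.mean_rates)
    return TuningMetrics(
        f1_f0=f1_f0,
        modulation_index=mi,
        lifetime_sparseness=sparse,
        preferred_condition=pref,
        flagged=math.isnan(sparse),
    )


@dataclass
class OptoSession:
    """Per-trial spike times (ms, relative to pulse onset) around light pulses."""

    trials: list  # list of ndarray, ms relative to onset
    pulse_duration: float = 10.0  # ms
    pre_window: float = 10.0  # raster extent before onset, ms
    post_window: float = 20.0  # raster extent after onset, ms

    def __post_init__(self):
        if len(self.trials) < 1:
            raise ParameterError("n_trials must be >= 1")
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class OptoDetection:
    tagged: bool
    response_rate: float  # Hz, mean across trials in the response window
    baseline_rate: float  # Hz, equally long window ending at onset
    psth: np.ndarray  # Hz per 1 ms bin over the raster extent
    psth_edges: np.ndarray  # ms


def detect_optotagged(
    session: OptoSession,
    window: tuple[float, float] = (2.0, 8.0),
    rate_floor: float = 25.0,
    ratio: float = 2.5,
) -> OptoDetection:
    """Light-evoked response detection.

    Rates are computed per trial then averaged.  A unit is tagged when the
    response-window rate exceeds ``rate_floor`` Hz and ``ratio`` times the
    baseline rate in the window of equal length immediately before onset.
    """
    w0, w1 = window
    wlen = w1 - w0
    if session.pre_window < wlen or session.post_window < w1:
        raise ParameterError("raster shorter than the required response/baseline windows")
    resp_rates = []
    base_rates = []
    for tr in session.trials:
        resp = np.count_nonzero((tr >= w0) & (tr < w1))
        base = np.count_nonzero((tr >= -wlen) & (tr < 0.0))
        resp_rates.append(resp / (wlen / 1000.0))
        base_rates.append(base / (wlen / 1000.0))
    response_rate = float(np.mean(resp_rates))
    baseline_rate = float(np.mean(base_rates))
    tagged = response_rate > rate_floor and response_rate > ratio * baseline_rate

    edges = np.arange(-session.pre_window, session.post_window + 1.0, 1.0)
    counts = np.zeros(edges.size - 1)
    for tr in session.trials:
        counts += np.histogram(tr, bins=edges)[0]
    psth = counts / session.n_trials / 0.001  # Hz per 1 ms bin
    return OptoDetection(
        tagged=bool(tagged),
        response_rate=response_rate,
        baseline_rate=baseline_rate,
        psth=psth,
        psth_edges=edges,
    )
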