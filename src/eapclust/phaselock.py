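"""Spike-LFP phase locking: phase assignment, Rayleigh test, von Mises fit.

The LFP is bandpass filtered (zero-phase FIR, forward-backward) in each
band and the instantaneous phase taken as the angle of the analytic
(Hilbert) signal, so that 0 deg marks the oscillation peak and 180 deg the
trough.  Each spike is assigned the phase of the nearest LFP sample; a
unit is phase-locked in a band when the Rayleigh test rejects uniformity
at p < 0.001, in which case a von Mises distribution is fitted by maximum
likelihood to obtain the concentration kappa and the preferred phase.
Both kappa (unbounded) and the mean resultant length (in [0, 1]) are
reported.

Band presets: the default set is theta 3-8, alpha 8-12.5, beta 12.5-30,
low gamma 30-50, high gamma 50-90 Hz; an alternative preset with alpha
8-12 and beta 12-30 Hz is provided ("methods").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import signal as ssig
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .errors import InsufficientDataError, ParameterError

__all__ = [
    "BandSpec",
    "DEFAULT_BANDS",
    "METHODS_BANDS",
    "PhaseLockingResult",
    "instantaneous_phase",
    "rayleigh_test",
    "unit_phase_locking",
    "population_summary",
    "holm_bonferroni",
    "circular_mean_deg",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandSpec:
    name: str
    low: float  # Hz
    high: float  # Hz

    def __post_init__(self):
        if not (0 < self.low < self.high):
            raise ParameterError("need 0 < low < high")


DEFAULT_BANDS = (
    BandSpec("theta", 3.0, 8.0),
    BandSpec("alpha", 8.0, 12.5),
    BandSpec("beta", 12.5, 30.0),
    BandSpec("low_gamma", 30.0, 50.0),
    BandSpec("high_gamma", 50.0, 90.0),
)

METHODS_BANDS = (
    BandSpec("theta", 3.0, 8.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("beta", 12.0, 30.0),
    BandSpec("low_gamma", 30.0, 50.0),
    BandSpec("high_gamma", 50.0, 90.0),
)


def instantaneous_phase(lfp: np.ndarray, fs: float, band: BandSpec) -> np.ndarray:
    """Instantaneous phase (degrees, [0, 360)) of the band-filtered LFP.

    Zero-phase FIR bandpass (filter length covering >= 3 cycles of
    ``band.low``) followed by the Hilbert transform; a positive peak reads
    0 deg and a trough 180 deg.
    """
    lfp = np.asarray(lfp, dtype=float)
    if band.high >= fs / 2:
        raise ParameterError(f"band {band.name} upper edge at or above Nyquist")
    numtaps = int(3 * fs / band.low)
    numtaps += 1 - numtaps % 2  # odd length
    max_taps = (lfp.size - 1) // 3
    if numtaps > max_taps:
        raise ParameterError("LFP trace too short for the requested band")
    taps = ssig.firwin(numtaps, [band.low, band.high], pass_zero=False, fs=fs)
    filtered = ssig.filtfilt(taps, [1.0], lfp)
    analytic = ssig.hilbert(filtered)
    return np.degrees(np.angle(analytic)) % 360.0


def rayleigh_test(phases_deg: np.ndarray) -> tuple[float, float]:
    """Rayleigh test for non-uniformity of circular data.

    Returns (p, z) with z = R^2/n the Rayleigh statistic; p uses the
    standard finite-n approximation exp(sqrt(1+4n+4(n^2-R^2)) - (1+2n)).
    """
    th = np.radians(np.asarray(phases_deg, dtype=float))
    n = th.size
    if n == 0:
        raise ParameterError("no phases")
    r = np.abs(np.mean(np.exp(1j * th)))
    R = n * r
    z = R**2 / n
    p = math.exp(math.sqrt(1 + 4 * n + 4 * (n**2 - R**2)) - (1 + 2 * n))
    return min(p, 1.0), z


def circular_mean_deg(phases_deg: np.ndarray) -> float:
    th = np.radians(np.asarray(phases_deg, dtype=float))
    deg = float(np.degrees(np.angle(np.mean(np.exp(1j * th)))) % 360.0)
    return 0.0 if deg >= 360.0 else deg


def resultant_length(phases_deg: np.ndarray) -> float:
    th = np.radians(np.asarray(phases_deg, dtype=float))
    return float(np.abs(np.mean(np.exp(1j * th))))


def vonmises_fit(phases_deg: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood von Mises fit; returns (kappa, mean phase deg)."""
    th = np.radians(np.asarray(phases_deg, dtype=float))
    kappa, loc, _ = sstats.vonmises.fit(th, fscale=1)
    return float(kappa), float(np.degrees(loc) % 360.0)


@dataclass
class PhaseLockingResult:
    unit_id: object
    band: str
    n_spikes_used: int
    n_dropped: int
    rayleigh_p: float
    locked: bool
    kappa: float
    preferred_phase: float  # degrees, 180 = trough
    resultant_length: float
    reliable: bool  # False when the Rayleigh test did not reject


def unit_phase_locking(
    spike_times: np.ndarray,
    phase_series: np.ndarray,
    fs: float,
    t0: float = 0.0,
    cap: int = 10000,
    alpha_p: float = 0.001,
    min_spikes: int = 100,
    unit_id: object = None,
    band_name: str = "",
) -> PhaseLockingResult:
    """Phase-locking statistics of one unit in one band.

    The first ``cap`` spikes (chronologically) inside the LFP span are
    used; each is assigned the phase at its nearest sample.  If the
    Rayleigh test rejects at ``alpha_p`` a von Mises fit supplies kappa
    and the preferred phase; otherwise they are still reported but marked
    unreliable.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    idx = np.round((spike_times - t0) * fs).astype(int)
    inside = (idx >= 0) & (idx < len(phase_series))
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.info("unit %s: %d spikes outside the LFP span dropped", unit_id, n_dropped)
    idx = idx[inside][:cap]
    if idx.size < min_spikes:
        raise InsufficientDataError(
            f"unit {unit_id!r}: {idx.size} usable spikes < required {min_spikes}"
        )
    phases = np.asarray(phase_series, dtype=float)[idx]
    p, _ = rayleigh_test(phases)
    locked = p < alpha_p
    kappa, mu = vonmises_fit(phases)
    return PhaseLockingResult(
        unit_id=unit_id,
        band=band_name,
        n_spikes_used=int(idx.size),
        n_dropped=n_dropped,
        rayleigh_p=p,
        locked=bool(locked),
        kappa=kappa,
        preferred_phase=mu,
        resultant_length=resultant_length(phases),
        reliable=bool(locked),
    )


def holm_bonferroni(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def population_summary(
    results: list[PhaseLockingResult],
    groups: dict,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group x band summary plus pairwise group comparisons.

    ``groups`` maps unit_id to a group label.  The summary reports the
    percentage of locked units, mean kappa +- SEM (locked units) and the
    circular mean preferred phase per group and band.  For each band and
    group pair, a two-sample z test compares locked proportions and a
    Mann-Whitney U test compares kappa of locked units; p-values are
    Holm-Bonferroni corrected across bands within each pair and test.
    """
    rows = []
    df = pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "band": r.band,
                "locked": r.locked,
                "kappa": r.kappa,
                "preferred_phase": r.preferred_phase,
                "group": groups.get(r.unit_id),
            }
            for r in results
        ]
    )
    df = df[df["group"].notna()]
    group_names = sorted(df["group"].unique().tolist())
    if len(group_names) < 2:
        raise ParameterError("need at least 2 groups")
    bands = list(dict.fromkeys(df["band"].tolist()))

    for g in group_names:
        for b in bands:
            sub = df[(df["group"] == g) & (df["band"] == b)]
            if sub.empty:
                logger.warning("group %s has no units in band %s; excluded", g, b)
                continue
            locked = sub[sub["locked"]]
            kappas = locked["kappa"].to_numpy()
            rows.append(
                {
                    "group": g,
                    "band": b,
                    "n_units": len(sub),
                    "percent_locked": 100.0 * len(locked) / len(sub),
                    "mean_kappa": kappas.mean() if kappas.size else math.nan,
                    "sem_kappa": (
                        kappas.std(ddof=1) / math.sqrt(kappas.size)
                        if kappas.size > 1
                        else math.nan
                    ),
                    "preferred_phase": (
                        circular_mean_deg(locked["preferred_phase"].to_numpy())
                        if len(locked)
                        else math.nan
                    ),
                }
            )
    summary = pd.DataFrame(rows)

    comp_rows = []
    for ga, gb in combinations(group_names, 2):
        prop_ps, kappa_ps, band_order = [], [], []
        for b in bands:
            a = df[(df["group"] == ga) & (df["band"] == b)]
            c = df[(df["group"] == gb) & (df["band"] == b)]
            if a.empty or c.empty:
                continue
            band_order.append(b)
            count = np.array([a["locked"].sum(), c["locked"].sum()])
            nobs = np.array([len(a), len(c)])
            if count.sum() in (0, nobs.sum()):
                prop_ps.append(1.0)
            else:
                prop_ps.append(proportions_ztest(count, nobs)[1])
            ka = a.loc[a["locked"], "kappa"].to_numpy()
            kb = c.loc[c["locked"], "kappa"].to_numpy()
            if ka.size >= 2 and kb.size >= 2:
                kappa_ps.append(sstats.mannwhitneyu(ka, kb).pvalue)
            else:
                kappa_ps.append(math.nan)
        prop_adj = holm_bonferroni(prop_ps)
        finite = ~np.isnan(kappa_ps)
        kappa_adj = np.full(len(kappa_ps), math.nan)
        if finite.any():
            kappa_adj[finite] = holm_bonferroni(np.asarray(kappa_ps)[finite])
        for i, b in enumerate(band_order):
            comp_rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "band": b,
                    "p_proportion": prop_ps[i],
                    "p_proportion_holm": prop_adj[i],
                    "p_kappa": kappa_ps[i],
                    "p_kappa_holm": kappa_adj[i],
                }
            )
    comparisons = pd.DataFrame(comp_rows)
    return summary, comparisons
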