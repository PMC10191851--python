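"""Multi-electrode-array analytics: spikes, bursts, network bursts, synchrony.

Conventions follow standard in-vitro MEA practice for 16-electrode
wells: spikes are threshold crossings at 5 SD of the (robustly
estimated) noise on the 200-3,000 Hz band-passed trace; an electrode is
active at >= 5 spikes/min; a burst is a run of >= 5 spikes with every
inter-spike interval <= 100 ms; a network burst requires bursts
overlapping on >= 35% of active electrodes with >= 50 spikes in total;
and synchrony is summarized by the area under the normalized
cross-correlogram (AUNCC) over +/- 100 ms lags.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeTrainSet",
    "detect_spikes",
    "detect_bursts",
    "detect_network_bursts",
    "summarize_firing",
    "compute_auncc",
]


@dataclass
class SpikeTrainSet:
    """Spike times per (well, electrode), sorted, within [0, duration)."""

    spikes: dict  # (well, electrode) -> 1-D float array of times in s
    duration: float = 1800.0
    n_electrodes_per_well: int = 16

    def __post_init__(self) -> None:
        clean = {}
        for key, t in self.spikes.items():
            t = np.asarray(t, dtype=float)
            if t.size and (t.min() < 0 or t.max() >= self.duration):
                raise ValueError(f"spike times outside [0, duration) for {key}")
            if t.size and np.any(np.diff(t) <= 0):
                raise ValueError(f"spike times not strictly increasing for {key}")
            clean[key] = t
        self.spikes = clean

    @property
    def wells(self) -> list:
        return sorted({w for (w, _) in self.spikes})

    def well_trains(self, well) -> dict:
        return {e: t for (w, e), t in self.spikes.items() if w == well}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (w, e, t)
            for (w, e), times in sorted(self.spikes.items())
            for t in times
        ]
        return pd.DataFrame(rows, columns=["well", "electrode", "time_s"])

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, duration: float = 1800.0, n_electrodes_per_well: int = 16
    ) -> "SpikeTrainSet":
        spikes = {
            (w, e): np.sort(g["time_s"].to_numpy(float))
            for (w, e), g in df.groupby(["well", "electrode"], sort=True)
        }
        return cls(spikes=spikes, duration=duration, n_electrodes_per_well=n_electrodes_per_well)


def robust_noise_sd(trace: np.ndarray) -> float:
    """Median-absolute-deviation noise estimate, robust to embedded spikes."""
    return float(np.median(np.abs(trace)) / 0.6745)


def detect_spikes(
    voltage: np.ndarray,
    fs: float = 12500.0,
    threshold_mult: float = 5.0,
    dead_time_s: float = 0.001,
    band: tuple[float, float] = (200.0, 3000.0),
    prefiltered: bool = False,
) -> np.ndarray:
    """Threshold-crossing spike detection on a single voltage trace.

    The trace is band-pass filtered (200-3,000 Hz) unless
    ``prefiltered``; the noise SD is estimated as median(|v|)/0.6745 and
    events are absolute-value crossings of ``threshold_mult`` x SD,
    with at most one event per ``dead_time_s`` window, timestamped at
    the crossing sample.  Returns spike times in seconds.
    """
    v = np.asarray(voltage, dtype=float)
    if v.ndim != 1:
        raise ValueError("voltage must be a 1-D trace")
    if not prefiltered:
        sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
        v = sps.sosfiltfilt(sos, v)
    sd = robust_noise_sd(v)
    if sd == 0:
        logger.warning("zero-variance trace: no spikes detected")
        return np.array([])
    thr = threshold_mult * sd
    above = np.abs(v) >= thr
    crossings = np.flatnonzero(above & ~np.r_[False, above[:-1]])
    if crossings.size == 0:
        return np.array([])
    dead = int(round(dead_time_s * fs))
    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] >= dead:
            kept.append(c)
    return np.asarray(kept, dtype=float) / fs


def detect_bursts(
    train: np.ndarray, min_spikes: int = 5, max_isi_s: float = 0.100
) -> pd.DataFrame:
    """Single-electrode burst detection by the inter-spike-interval rule.

    A burst is a maximal run of consecutive spikes whose every ISI is
    <= ``max_isi_s``; runs with at least ``min_spikes`` spikes are
    emitted.  Returns columns start_s, end_s, n_spikes.
    """
    t = np.asarray(train, dtype=float)
    rows = []
    if t.size:
        isi_ok = np.diff(t) <= max_isi_s
        start = 0
        for i in range(len(t)):
            run_ends = i == len(t) - 1 or not isi_ok[i]
            if run_ends:
                n = i - start + 1
                if n >= min_spikes:
                    rows.append((t[start], t[i], n))
                start = i + 1
    return pd.DataFrame(rows, columns=["start_s", "end_s", "n_spikes"])


def detect_network_bursts(
    trains: dict,
    active_electrodes: list | None = None,
    min_total_spikes: int = 50,
    min_electrode_frac: float = 0.35,
    min_spikes_per_burst: int = 5,
    max_isi_s: float = 0.100,
) -> pd.DataFrame:
    """Well-level network-burst detection.

    Single-electrode bursts on active electrodes are merged where their
    intervals overlap (interval union); a merged window is a network
    burst when the distinct participating electrodes reach
    ceil(``min_electrode_frac`` x n_active) and the total spikes from
    active electrodes inside the window reach ``min_total_spikes``.
    Returns columns start_s, end_s, n_electrodes, n_spikes.
    """
    if active_electrodes is None:
        active_electrodes = sorted(trains)
    if len(active_electrodes) == 0:
        raise ValueError("no active electrodes")
    n_active = len(active_electrodes)
    min_elec = math.ceil(min_electrode_frac * n_active)

    intervals = []  # (start, end, electrode)
    for e in active_electrodes:
        bursts = detect_bursts(trains.get(e, np.array([])), min_spikes_per_burst, max_isi_s)
        intervals.extend((r.start_s, r.end_s, e) for r in bursts.itertuples())
    intervals.sort()
    rows = []
    i = 0
    while i < len(intervals):
        start, end, elecs = intervals[i][0], intervals[i][1], {intervals[i][2]}
        j = i + 1
        while j < len(intervals) and intervals[j][0] <= end:
            end = max(end, intervals[j][1])
            elecs.add(intervals[j][2])
            j += 1
        n_spk = sum(
            int(np.sum((trains.get(e, np.array([])) >= start) & (trains.get(e, np.array([])) <= end)))
            for e in active_electrodes
        )
        if len(elecs) >= min_elec and n_spk >= min_total_spikes:
            rows.append((start, end, len(elecs), n_spk))
        i = j
    return pd.DataFrame(rows, columns=["start_s", "end_s", "n_electrodes", "n_spikes"])


def summarize_firing(
    trains: dict,
    duration: float = 1800.0,
    active_rate_per_min: float = 5.0,
    network_bursts: pd.DataFrame | None = None,
    wmfr_mode: str = "mean_active",
) -> dict:
    """Per-well firing metrics.

    mfr is spikes/duration per electrode; an electrode is active at
    >= ``active_rate_per_min`` spikes per minute.  wMFR follows the
    vendor convention (mean firing rate over active electrodes) by
    default; ``wmfr_mode="literal"`` instead multiplies the well spike
    rate by the active-electrode count.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    mfr = {e: len(t) / duration for e, t in trains.items()}
    active = {e: (len(t) / duration) * 60.0 >= active_rate_per_min for e, t in trains.items()}
    act = [e for e in trains if active[e]]
    if wmfr_mode == "mean_active":
        wmfr = float(np.mean([mfr[e] for e in act])) if act else 0.0
    elif wmfr_mode == "literal":
        wmfr = (sum(len(t) for t in trains.values()) / duration) * len(act)
    else:
        raise ValueError(f"unknown wmfr_mode {wmfr_mode!r}")
    out = {
        "mfr": mfr,
        "active": active,
        "n_active": len(act),
        "wmfr": wmfr,
    }
    if network_bursts is not None:
        out["network_burst_freq"] = len(network_bursts) / duration
    return out


def compute_auncc(
    trains: dict,
    duration: float,
    bin_s: float = 0.005,
    max_lag_s: float = 0.100,
    electrodes: list | None = None,
    area_mode: str = "squared",
) -> tuple[float, np.ndarray]:
    """Area under the normalized cross-correlogram, averaged over pairs.

    Spike trains are binned at ``bin_s``; for each electrode pair the
    correlogram rho_xy(tau) = C_xy(tau) / sqrt(C_xx(0) C_yy(0)) is
    evaluated for |tau| <= ``max_lag_s``.  Counts are nonnegative so
    Cauchy-Schwarz bounds every rho in [0, 1].

    ``area_mode="squared"`` (default) takes the area under the squared
    correlogram, sum rho(tau)^2 x bin width.  Temporal jitter spreads
    correlogram mass across lags without changing its linear sum, so
    the squared (peak-concentration) area is the variant that decreases
    monotonically as synchrony loosens; ``area_mode="linear"`` gives
    the plain sum rho(tau) x bin width.  Higher AUNCC means tighter
    network synchrony.

    Returns (mean AUNCC over pairs, per-pair rho matrix of shape
    n_pairs x n_lags).
    """
    if electrodes is None:
        electrodes = sorted(trains)
    if len(electrodes) < 2:
        raise ValueError("need at least 2 electrodes for cross-correlation")
    n_bins = int(np.ceil(duration / bin_s))
    edges = np.arange(n_bins + 1) * bin_s
    counts = {e: np.histogram(trains[e], bins=edges)[0].astype(float) for e in electrodes}
    lags = np.arange(-int(round(max_lag_s / bin_s)), int(round(max_lag_s / bin_s)) + 1)
    rhos = []
    areas = []
    for a in range(len(electrodes)):
        for b in range(a + 1, len(electrodes)):
            x, y = counts[electrodes[a]], counts[electrodes[b]]
            c0 = np.dot(x, x) * np.dot(y, y)
            if c0 == 0:
                continue
            row = np.empty(lags.size)
            for li, lag in enumerate(lags):
                if lag >= 0:
                    row[li] = np.dot(x[: n_bins - lag], y[lag:])
                else:
                    row[li] = np.dot(x[-lag:], y[: n_bins + lag])
            row /= np.sqrt(c0)
            rhos.append(row)
            if area_mode == "squared":
                areas.append((row**2).sum() * bin_s)
            elif area_mode == "linear":
                areas.append(row.sum() * bin_s)
            else:
                raise ValueError(f"unknown area_mode {area_mode!r}")
    if not areas:
        raise ValueError("no scorable electrode pairs (all trains empty)")
    return float(np.mean(areas)), np.asarray(rhos)
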