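"""Speech-locked ECoG preprocessing and high-gamma power extraction.

The analysis chain mirrors intraoperative picture-naming recordings:
channels are screened by sample kurtosis, trials by response correctness
and latency, signals are epoched around speech onset (time 0), and
high-gamma band power (HGp, 70-110 Hz) is computed as the squared
magnitude of the analytic signal after zero-phase FIR band-pass
filtering.  An event-related spectral perturbation (ERSP) variant
produces a per-trial z-scored 70-170 Hz envelope resampled to 100 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.signal as sps
from scipy.ndimage import gaussian_filter1d
from scipy.stats import kurtosis as _kurtosis

logger = logging.getLogger(__name__)

TISSUE_LABELS = ("tumour", "non_tumour", "unknown")

__all__ = [
    "Recording",
    "EpochSet",
    "HgpSeries",
    "make_trial_table",
    "label_electrodes",
    "reject_noisy_channels",
    "select_trials",
    "epoch_speech_locked",
    "compute_hgp",
    "compute_ersp",
]


@dataclass
class Recording:
    """Multichannel ECoG recording.

    Attributes
    ----------
    samples : (n_channels, n_times) float array, signal units.
    fs : sampling rate in Hz.
    channel_ids : per-channel string labels.
    channel_coords : (n_channels, 3) mm coordinates, NaN where unknown.
    tissue_label : per-channel label in {tumour, non_tumour, unknown}.
    """

    samples: np.ndarray
    fs: float
    channel_ids: list[str]
    channel_coords: np.ndarray
    tissue_label: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        n = self.samples.shape[0]
        self.channel_coords = np.asarray(self.channel_coords, dtype=float)
        if len(self.channel_ids) != n or self.channel_coords.shape != (n, 3):
            raise ValueError("channel metadata does not match channel count")
        bad = set(self.tissue_label) - set(TISSUE_LABELS)
        if bad:
            raise ValueError(f"unknown tissue labels: {sorted(bad)}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs

    def subset_channels(self, keep: Sequence[int]) -> "Recording":
        keep = list(keep)
        return Recording(
            samples=self.samples[keep],
            fs=self.fs,
            channel_ids=[self.channel_ids[i] for i in keep],
            channel_coords=self.channel_coords[keep],
            tissue_label=[self.tissue_label[i] for i in keep],
            meta=dict(self.meta),
        )


def make_trial_table(
    onset_s: Sequence[float],
    condition: Sequence[str],
    correct: Sequence[bool],
    latency_s: Sequence[float],
) -> pd.DataFrame:
    """Build a validated trial table (one row per vocalization event)."""
    df = pd.DataFrame(
        {
            "onset_s": np.asarray(onset_s, dtype=float),
            "condition": list(condition),
            "correct": np.asarray(correct, dtype=bool),
            "latency_s": np.asarray(latency_s, dtype=float),
        }
    )
    if not np.all(np.diff(df["onset_s"].to_numpy()) > 0):
        raise ValueError("trial onsets must be strictly increasing")
    if (df["latency_s"] < 0).any():
        raise ValueError("latency_s must be nonnegative")
    return df


@dataclass
class EpochSet:
    """Speech-locked epochs: trials x channels x time, window [-2, +2) s."""

    data: np.ndarray
    fs: float
    window_s: tuple[float, float] = (-2.0, 2.0)
    trials: pd.DataFrame | None = None
    channel_ids: list[str] | None = None
    tissue_label: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x time")
        span = self.window_s[1] - self.window_s[0]
        expected = int(round(span * self.fs))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"time axis has {self.data.shape[2]} samples, expected {expected}"
            )

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.window_s[0] + np.arange(n) / self.fs

    @property
    def onset_index(self) -> int:
        return int(round(-self.window_s[0] * self.fs))


@dataclass
class HgpSeries:
    """Time-resolved high-gamma power per trial and channel (nonnegative)."""

    values: np.ndarray  # trials x channels x time
    fs: float
    band: tuple[float, float]
    window_s: tuple[float, float]
    provenance: str = ""
    channel_ids: list[str] | None = None
    tissue_label: list[str] | None = None
    trials: pd.DataFrame | None = None

    def channel_task_mean(
        self, task_window_s: tuple[float, float] = (0.0, 1.0)
    ) -> np.ndarray:
        """Per-channel HGp averaged over trials and a task window.

        This is the single responsivity number per electrode that the
        tissue-contrast mixed model consumes.
        """
        n = self.values.shape[2]
        t = self.window_s[0] + np.arange(n) / self.fs
        sel = (t >= task_window_s[0]) & (t < task_window_s[1])
        return self.values[:, :, sel].mean(axis=(0, 2))


def label_electrodes(
    channel_coords: np.ndarray,
    tumour_core_geometry: np.ndarray,
    radius_mm: float = 10.0,
) -> tuple[list[str], np.ndarray]:
    """Label electrodes by distance to the necrotic tumour core.

    An electrode whose minimum Euclidean distance to any core point is
    <= ``radius_mm`` (inclusive) is labelled ``tumour``; otherwise
    ``non_tumour``.  Coordinates must share a space and unit (mm).

    Returns (labels, per-channel minimum distance in mm).
    """
    coords = np.atleast_2d(np.asarray(channel_coords, dtype=float))
    core = np.atleast_2d(np.asarray(tumour_core_geometry, dtype=float))
    if core.size == 0:
        raise ValueError("tumour core geometry is empty")
    if coords.shape[1] != 3 or core.shape[1] != 3:
        raise ValueError("coordinates must be (n, 3) mm triples")
    d = np.linalg.norm(coords[:, None, :] - core[None, :, :], axis=2)
    dmin = d.min(axis=1)
    labels = ["tumour" if x <= radius_mm else "non_tumour" for x in dmin]
    return labels, dmin


def reject_noisy_channels(
    recording: Recording, kurtosis_max: float = 5.0
) -> tuple[Recording, pd.DataFrame]:
    """Drop channels whose sample kurtosis exceeds ``kurtosis_max``.

    Kurtosis uses the Pearson convention (a Gaussian scores 3), matching
    the scale on which a 5.0 cutoff flags heavy-tailed artifact channels.
    Zero-variance channels are removed with reason ``degenerate``.
    """
    if recording.n_channels < 2:
        raise ValueError("need at least 2 channels to screen")
    rows = []
    keep = []
    for i in range(recording.n_channels):
        x = recording.samples[i]
        if np.ptp(x) == 0 or np.var(x) == 0:
            rows.append((recording.channel_ids[i], np.nan, "degenerate"))
            continue
        k = float(_kurtosis(x, fisher=False, bias=True))
        if k > kurtosis_max:
            rows.append((recording.channel_ids[i], k, "kurtosis"))
        else:
            keep.append(i)
            rows.append((recording.channel_ids[i], k, "retained"))
    report = pd.DataFrame(rows, columns=["channel", "kurtosis", "status"])
    if not keep:
        raise ValueError("all channels rejected by the kurtosis screen")
    rejected = report[report["status"] != "retained"]
    if len(rejected):
        logger.info("rejected %d channels: %s", len(rejected), list(rejected["channel"]))
    return recording.subset_channels(keep), report


def select_trials(
    trials: pd.DataFrame, max_latency_s: float = 2.0
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep correct-response trials with latency not exceeding 2 s.

    Latency exactly at the threshold is kept: only responses *more* than
    ``max_latency_s`` after the stimulus are discarded.
    """
    incorrect = ~trials["correct"].to_numpy(dtype=bool)
    slow = trials["latency_s"].to_numpy() > max_latency_s
    keep = ~(incorrect | slow)
    counts = {
        "kept": int(keep.sum()),
        "incorrect": int(incorrect.sum()),
        "slow_response": int((slow & ~incorrect).sum()),
    }
    return trials.loc[keep].reset_index(drop=True), counts


def epoch_speech_locked(
    recording: Recording,
    trials: pd.DataFrame,
    window_s: tuple[float, float] = (-2.0, 2.0),
) -> EpochSet:
    """Cut speech-onset-locked epochs, window [-2.0, +2.0) s, half-open.

    Trials whose window would cross a recording edge are dropped and
    logged.  Raises if no trial survives.
    """
    fs = recording.fs
    n_samp = int(round((window_s[1] - window_s[0]) * fs))
    n_total = recording.samples.shape[1]
    cut, kept_rows = [], []
    for _, row in trials.iterrows():
        i0 = int(round(row["onset_s"] * fs)) + int(round(window_s[0] * fs))
        if i0 < 0 or i0 + n_samp > n_total:
            logger.info("dropping trial at %.3f s: window crosses edge", row["onset_s"])
            continue
        cut.append(recording.samples[:, i0 : i0 + n_samp])
        kept_rows.append(row)
    if not cut:
        raise ValueError("no trials survive epoching (all windows cross an edge)")
    data = np.stack(cut, axis=0)
    return EpochSet(
        data=data,
        fs=fs,
        window_s=window_s,
        trials=pd.DataFrame(kept_rows).reset_index(drop=True),
        channel_ids=list(recording.channel_ids),
        tissue_label=list(recording.tissue_label),
    )


def _common_average(data: np.ndarray) -> np.ndarray:
    # reference each sample to the mean over (retained) channels
    return data - data.mean(axis=-2, keepdims=True)


def _highpass(data: np.ndarray, fs: float, cutoff: float = 0.1) -> np.ndarray:
    sos = sps.butter(2, cutoff, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, data, axis=-1)


def _fir_bandpass(
    data: np.ndarray, fs: float, band: tuple[float, float], order: int
) -> np.ndarray:
    taps = sps.firwin(order + 1, band, fs=fs, pass_zero=False, window="hamming")
    return sps.filtfilt(taps, [1.0], data, axis=-1)


def compute_hgp(
    epochs: EpochSet,
    band: tuple[float, float] = (70.0, 110.0),
    fir_order: int = 300,
    apply_car: bool = True,
) -> HgpSeries:
    """High-gamma power via the squared analytic-signal envelope.

    Chain, in order: common-average reference (over the channels present,
    which are assumed kurtosis-screened) -> 0.1 Hz high-pass -> 70-110 Hz
    FIR band-pass (``fir_order`` designed taps, applied forward-backward
    for zero phase) -> magnitude of the analytic signal, squared.
    """
    if band[1] >= epochs.fs / 2:
        raise ValueError(f"band edge {band[1]} Hz >= Nyquist {epochs.fs / 2} Hz")
    x = epochs.data
    if apply_car:
        x = _common_average(x)
    x = _highpass(x, epochs.fs)
    x = _fir_bandpass(x, epochs.fs, band, fir_order)
    env2 = np.abs(sps.hilbert(x, axis=-1)) ** 2
    return HgpSeries(
        values=env2,
        fs=epochs.fs,
        band=band,
        window_s=epochs.window_s,
        provenance=(
            f"CAR={apply_car} -> HP 0.1 Hz -> FIR {band[0]}-{band[1]} Hz "
            f"order {fir_order} (zero-phase) -> |analytic|^2"
        ),
        channel_ids=epochs.channel_ids,
        tissue_label=epochs.tissue_label,
        trials=epochs.trials,
    )


def compute_ersp(
    recording: Recording,
    trials: pd.DataFrame,
    band: tuple[float, float] = (70.0, 170.0),
    intermediate_fs: float = 600.0,
    out_fs: float = 100.0,
    smooth_ms: float = 100.0,
    notch_base: float = 60.0,
    window_s: tuple[float, float] = (-2.0, 2.0),
) -> tuple[EpochSet, np.ndarray]:
    """Per-trial z-scored high-gamma envelope at 100 Hz.

    Continuous chain: resample to 600 Hz -> 0.1 Hz high-pass -> notch at
    60 Hz and harmonics below the new Nyquist -> 70-170 Hz Hamming
    windowed-sinc FIR band-pass -> analytic-signal envelope -> Gaussian
    smoothing (``smooth_ms`` FWHM) -> resample to 100 Hz.  Epochs are
    then cut at the output rate and z-scored across each trial (per
    channel).  Zero-variance trials are flagged and left as NaN.

    Returns (z-scored EpochSet at ``out_fs``, boolean degenerate-trial
    mask of shape trials x channels).
    """
    fs = recording.fs
    up, down = _resample_ratio(intermediate_fs, fs)
    x = sps.resample_poly(recording.samples, up, down, axis=-1)
    x = _highpass(x, intermediate_fs)
    nyq = intermediate_fs / 2
    k = 1
    while notch_base * k < nyq:
        b, a = sps.iirnotch(notch_base * k, Q=30.0, fs=intermediate_fs)
        x = sps.filtfilt(b, a, x, axis=-1)
        k += 1
    numtaps = int(round(intermediate_fs)) + 1  # ~1 s windowed-sinc kernel
    x = _fir_bandpass(x, intermediate_fs, band, numtaps - 1)
    env = np.abs(sps.hilbert(x, axis=-1))
    sigma_samples = (smooth_ms / 1000.0) / 2.3548 * intermediate_fs  # FWHM -> SD
    env = gaussian_filter1d(env, sigma_samples, axis=-1, mode="nearest")
    up, down = _resample_ratio(out_fs, intermediate_fs)
    env = sps.resample_poly(env, up, down, axis=-1)

    low_rec = Recording(
        samples=env,
        fs=out_fs,
        channel_ids=list(recording.channel_ids),
        channel_coords=recording.channel_coords,
        tissue_label=list(recording.tissue_label),
    )
    epochs = epoch_speech_locked(low_rec, trials, window_s=window_s)
    data = epochs.data
    mu = data.mean(axis=2, keepdims=True)
    sd = data.std(axis=2, keepdims=True)
    degenerate = sd[:, :, 0] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (data - mu) / sd
    z[np.broadcast_to(degenerate[:, :, None], z.shape)] = np.nan
    if degenerate.any():
        logger.warning("%d degenerate trial-channel pairs in ERSP", degenerate.sum())
    epochs.data = z
    return epochs, degenerate


def _resample_ratio(target_fs: float, fs: float) -> tuple[int, int]:
    from fractions import Fraction

    frac = Fraction(target_fs / fs).limit_denominator(10000)
    return frac.numerator, frac.denominator
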