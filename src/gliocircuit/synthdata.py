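"""Seeded synthetic-data generators for every pipeline input class.

Each generator is a pure function of its spec (including the seed):
identical spec -> bitwise-identical output.  Random streams are split
per participant / well / voxel via ``numpy.random.SeedSequence.spawn``
so changing one count does not perturb the data generated for the
others.  Every generator returns a ground-truth record sufficient to
score the downstream stage (true tissue labels, true coupled voxels,
true burst schedule, true aperiodic parameters, true group medians).

These generators emulate study conditions, not patients: effect sizes
are calibration choices for exercising the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal as sps

from .ecog import Recording, make_trial_table
from .megconn import VoxelSeries
from .mea import SpikeTrainSet
from .spectral import SpectrumEstimate, aperiodic_model

__all__ = [
    "EcogSimSpec",
    "VoxelSimSpec",
    "RasterSimSpec",
    "SpectrumSimSpec",
    "CohortSimSpec",
    "generate_ecog_dataset",
    "generate_voxel_dataset",
    "generate_spike_data",
    "generate_spectrum",
    "generate_cohort",
]


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{name}: {msg}")


# ---------------------------------------------------------------- ECoG


@dataclass
class EcogSimSpec:
    """Task-locked ECoG simulation: high-gamma bursts at speech onset.

    Bursts are amplitude-modulated narrowband noise in ``burst_band``
    under a raised-cosine envelope spanning ``burst_window_ms`` around
    onset.  Tumour-labelled channels scale the burst by
    ``tumour_amplitude_ratio`` (1 -> no tissue effect); high-frequency
    -word trials add ``condition_effect_size`` noise SDs of burst
    amplitude relative to low-frequency-word trials.
    """

    n_participants: int = 10
    n_channels: int = 16
    fraction_tumour_channels: float = 0.5
    fs: float = 1200.0
    n_trials_per_condition: int = 10
    burst_band: tuple[float, float] = (70.0, 110.0)
    burst_window_ms: tuple[float, float] = (0.0, 400.0)
    tumour_amplitude_ratio: float = 1.0
    condition_effect_size: float = 0.0
    noise_sd: float = 1.0
    trial_spacing_s: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_participants >= 1, "n_participants", "must be >= 1")
        _check(self.n_channels >= 2, "n_channels", "must be >= 2")
        _check(
            0 < self.fraction_tumour_channels < 1,
            "fraction_tumour_channels",
            "must lie in (0, 1)",
        )
        _check(self.fs > 2 * self.burst_band[1], "fs", "must exceed twice the upper burst band edge")
        _check(self.n_trials_per_condition >= 1, "n_trials_per_condition", "must be >= 1")
        _check(self.tumour_amplitude_ratio >= 0, "tumour_amplitude_ratio", "must be >= 0")
        _check(self.noise_sd > 0, "noise_sd", "must be positive")


def _narrowband_burst(rng, fs, band, n_env, n_pad=None):
    """Raised-cosine-enveloped narrowband noise, unit peak-envelope RMS."""
    n = n_env if n_pad is None else n_pad
    white = rng.standard_normal(n + 2 * int(fs))
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    nb = sps.sosfiltfilt(sos, white)[int(fs) : int(fs) + n]
    nb = nb / nb.std()
    env = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n_env) / max(n_env - 1, 1)))
    out = np.zeros(n)
    out[:n_env] = nb[:n_env] * env
    return out


def generate_ecog_dataset(spec: EcogSimSpec):
    """Simulate speech-locked recordings for every participant.

    Returns ``(recordings, trial_tables, truth)`` where recordings and
    trial tables are per-participant lists and ``truth`` records the
    labels and amplitudes actually injected.
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    participant_seeds = root.spawn(spec.n_participants)
    n_trials = 2 * spec.n_trials_per_condition
    duration = 4.0 + spec.trial_spacing_s * n_trials
    n_samp = int(round(duration * spec.fs))
    n_tum = max(1, int(round(spec.fraction_tumour_channels * spec.n_channels)))

    recordings, trial_tables = [], []
    truth = {
        "tumour_amplitude_ratio": spec.tumour_amplitude_ratio,
        "condition_effect_size": spec.condition_effect_size,
        "participants": [],
    }
    # modest burst RMS relative to broadband noise, so synthetic channels
    # stay mesokurtic enough to survive the artifact (kurtosis) screen
    base_amp = 0.5 * spec.noise_sd
    amp_high = base_amp + spec.condition_effect_size * spec.noise_sd

    for p, pseed in enumerate(participant_seeds):
        rng = np.random.default_rng(pseed)
        tissue = ["tumour"] * n_tum + ["non_tumour"] * (spec.n_channels - n_tum)
        # tumour contacts sit within 10 mm of a core at the origin
        coords = np.zeros((spec.n_channels, 3))
        coords[:n_tum] = rng.uniform(-5, 5, size=(n_tum, 3))
        coords[n_tum:] = rng.uniform(25, 60, size=(spec.n_channels - n_tum, 3))

        data = spec.noise_sd * rng.standard_normal((spec.n_channels, n_samp))
        conditions = np.array(
            ["low_freq_word", "high_freq_word"] * spec.n_trials_per_condition
        )
        rng.shuffle(conditions)
        onsets = 2.5 + spec.trial_spacing_s * np.arange(n_trials)
        w0, w1 = spec.burst_window_ms
        n_env = int(round((w1 - w0) / 1000.0 * spec.fs))
        for onset, cond in zip(onsets, conditions):
            amp = base_amp if cond == "low_freq_word" else amp_high
            i0 = int(round((onset + w0 / 1000.0) * spec.fs))
            for c in range(spec.n_channels):
                a = amp * (spec.tumour_amplitude_ratio if tissue[c] == "tumour" else 1.0)
                data[c, i0 : i0 + n_env] += a * _narrowband_burst(
                    rng, spec.fs, spec.burst_band, n_env
                )
        rec = Recording(
            samples=data,
            fs=spec.fs,
            channel_ids=[f"P{p}C{c}" for c in range(spec.n_channels)],
            channel_coords=coords,
            tissue_label=tissue,
            meta={"participant": p},
        )
        trials = make_trial_table(
            onset_s=onsets,
            condition=conditions,
            correct=np.ones(n_trials, dtype=bool),
            latency_s=rng.uniform(0.5, 1.5, size=n_trials),
        )
        recordings.append(rec)
        trial_tables.append(trials)
        truth["participants"].append(
            {
                "participant": p,
                "tissue": tissue,
                "base_amp": base_amp,
                "amp_high": amp_high,
                "onsets": onsets.tolist(),
            }
        )
    return recordings, trial_tables, truth


# --------------------------------------------------------------- Voxels


@dataclass
class VoxelSimSpec:
    """Alpha-band coupled oscillators on a mirror-symmetric voxel grid.

    Every voxel carries a share of a common narrowband alpha source,
    phase-shifted by a per-voxel offset that is a random integer
    multiple of ``phase_lag`` spanning the full alpha cycle, plus
    independent noise.  Pairwise phase differences are therefore
    nonzero multiples of ``phase_lag`` (imaginary coherence > 0), and
    because the per-voxel phases are uniform on the cycle and mirror
    twins share an offset, the two hemispheres are statistically
    exchangeable when no lesion boost is applied.  Voxels in
    ``lesion_voxel_ids`` have their source amplitude multiplied by
    ``lesion_coupling_boost``.
    """

    n_voxels_per_hemisphere: int = 100
    grid_spacing_mm: float = 8.0
    fs: float = 200.0
    duration: float = 60.0
    alpha_freq: float = 10.0
    base_coupling: float = 0.3
    lesion_voxel_ids: tuple = ()
    lesion_coupling_boost: float = 1.0
    phase_lag: float = np.pi / 4
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_voxels_per_hemisphere >= 2, "n_voxels_per_hemisphere", "must be >= 2")
        _check(8.0 <= self.alpha_freq <= 12.0, "alpha_freq", "must lie in [8, 12] Hz")
        _check(0 < self.base_coupling < 1, "base_coupling", "must lie in (0, 1)")
        _check(self.lesion_coupling_boost >= 1, "lesion_coupling_boost", "must be >= 1")
        _check(self.noise_sd > 0, "noise_sd", "must be positive")
        n_seg = int(self.duration * self.fs - self.fs) // int(self.fs / 2) + 1
        _check(n_seg >= 20, "duration", "must provide >= 20 one-second analysis segments")
        nh = self.n_voxels_per_hemisphere
        ids = np.asarray(self.lesion_voxel_ids, dtype=int)
        _check(
            np.all((ids >= 0) & (ids < 2 * nh)) if ids.size else True,
            "lesion_voxel_ids",
            "outside the voxel grid",
        )
        if ids.size:
            _check(
                np.all(ids < nh) or np.all(ids >= nh),
                "lesion_voxel_ids",
                "lesion voxels must all lie in one hemisphere",
            )


def generate_voxel_dataset(spec: VoxelSimSpec) -> VoxelSeries:
    """Simulate the mirrored voxel grid with alpha-band coupling."""
    spec.validate()
    nh = spec.n_voxels_per_hemisphere
    n = 2 * nh
    root = np.random.SeedSequence(spec.seed)
    src_seed, lag_seed, *voxel_seeds = root.spawn(2 + n)

    side = int(np.ceil(nh ** (1 / 3)))
    base = np.stack(
        np.unravel_index(np.arange(nh), (side, side, side)), axis=1
    )
    grid = np.zeros((n, 3), dtype=int)
    grid[:nh] = base * np.array([1, 1, 1])
    grid[:nh, 0] = -(base[:, 0] + 1)  # left hemisphere
    grid[nh:] = base
    grid[nh:, 0] = base[:, 0] + 1  # right hemisphere
    mirror = np.r_[np.arange(nh) + nh, np.arange(nh)]
    hemisphere = np.array(["left"] * nh + ["right"] * nh)

    n_samp = int(round(spec.duration * spec.fs))
    pad = int(spec.fs)
    rng_src = np.random.default_rng(src_seed)
    white = rng_src.standard_normal(n_samp + 2 * pad)
    sos = sps.butter(
        4,
        (spec.alpha_freq - 1.0, spec.alpha_freq + 1.0),
        btype="bandpass",
        fs=spec.fs,
        output="sos",
    )
    source = sps.sosfiltfilt(sos, white)
    source = source / source[pad:-pad].std()

    rng_lag = np.random.default_rng(lag_seed)
    n_phase_bins = max(2, int(round(2 * np.pi / spec.phase_lag)))
    # balanced assignment: each phase bin is used equally often (+-1),
    # so the empirical phase distribution is uniform in every realization
    k_base = np.resize(np.arange(n_phase_bins), nh)
    rng_lag.shuffle(k_base)
    k_all = np.r_[k_base, k_base]  # mirror twins share a phase offset
    # exact fractional delays of the source, one per phase bin
    freqs = np.fft.rfftfreq(source.size, 1.0 / spec.fs)
    src_fft = np.fft.rfft(source)
    shifted_sources = {}
    for k in np.unique(k_all):
        tau = k * spec.phase_lag / (2 * np.pi * spec.alpha_freq)
        shifted = np.fft.irfft(
            src_fft * np.exp(-2j * np.pi * freqs * tau), n=source.size
        )
        shifted_sources[int(k)] = shifted[pad : pad + n_samp]

    amp = spec.noise_sd * np.sqrt(spec.base_coupling / (1 - spec.base_coupling))
    lesion = np.zeros(n, dtype=bool)
    if len(spec.lesion_voxel_ids):
        lesion[np.asarray(spec.lesion_voxel_ids, dtype=int)] = True

    series = np.empty((n, n_samp))
    for v in range(n):
        a = amp * (spec.lesion_coupling_boost if lesion[v] else 1.0)
        rng_v = np.random.default_rng(voxel_seeds[v])
        series[v] = a * shifted_sources[int(k_all[v])] + spec.noise_sd * rng_v.standard_normal(
            n_samp
        )

    return VoxelSeries(
        series=series,
        fs=spec.fs,
        grid_index=grid,
        spacing_mm=spec.grid_spacing_mm,
        hemisphere=hemisphere,
        mirror_pair=mirror,
        tumour_mask=lesion,
        meta={
            "truth": {
                "lesion_voxel_ids": list(map(int, np.flatnonzero(lesion))),
                "lesion_coupling_boost": spec.lesion_coupling_boost,
                "base_coupling": spec.base_coupling,
                "phase_bin": k_all.tolist(),
                "phase_lag": spec.phase_lag,
            }
        },
    )


# -------------------------------------------------------------- Rasters


@dataclass
class RasterSimSpec:
    """Poisson background spiking plus scheduled network bursts.

    ``network_burst_schedule`` entries are (time s, participating
    electrode fraction, spikes per participating electrode); burst
    spikes are laid down at a 10 ms base ISI with Gaussian jitter of
    ``within_burst_jitter_sd_ms``.  With ``emit_voltage``, spikes are
    embedded in Gaussian noise as 1 ms biphasic pulses whose peak is
    ``spike_snr`` noise SDs.
    """

    n_wells: int = 1
    n_electrodes_per_well: int = 16
    duration: float = 1800.0
    background_rate: float = 0.5
    network_burst_schedule: tuple = ()
    within_burst_jitter_sd_ms: float = 1.0
    emit_voltage: bool = False
    spike_snr: float = 10.0
    voltage_fs: float = 12500.0
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_wells >= 1, "n_wells", "must be >= 1")
        _check(self.n_electrodes_per_well >= 1, "n_electrodes_per_well", "must be >= 1")
        _check(self.duration > 0, "duration", "must be positive")
        _check(self.background_rate >= 0, "background_rate", "must be >= 0")
        for t, frac, nspk in self.network_burst_schedule:
            _check(0 <= t < self.duration, "network_burst_schedule", f"burst time {t} outside [0, duration)")
            _check(0 < frac <= 1, "network_burst_schedule", "electrode fraction must lie in (0, 1]")
            _check(nspk >= 1, "network_burst_schedule", "spikes per burst must be >= 1")
        if self.emit_voltage:
            _check(self.spike_snr > 0, "spike_snr", "must be positive when emitting voltage")


BIPHASIC_MS = 1.0  # spike template duration


def _biphasic_template(fs: float) -> np.ndarray:
    n = max(int(round(BIPHASIC_MS / 1000.0 * fs)), 4)
    t = np.linspace(0, 1, n)
    tpl = -np.sin(np.pi * t) * (t < 0.5) + 0.6 * np.sin(np.pi * t) * (t >= 0.5)
    return tpl / np.abs(tpl).max()


def generate_spike_data(spec: RasterSimSpec):
    """Simulate spike rasters (and optionally raw voltage traces).

    Returns ``(SpikeTrainSet, voltage_or_None, truth)``; truth holds the
    realized schedule (times and participating electrodes per network
    burst).
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    well_seeds = root.spawn(spec.n_wells)
    spikes = {}
    truth = {"wells": {}}
    voltage = {} if spec.emit_voltage else None
    for w, wseed in enumerate(well_seeds):
        rng = np.random.default_rng(wseed)
        n_e = spec.n_electrodes_per_well
        per_elec = [[] for _ in range(n_e)]
        for e in range(n_e):
            if spec.background_rate > 0:
                n_bg = rng.poisson(spec.background_rate * spec.duration)
                per_elec[e].extend(rng.uniform(0, spec.duration, size=n_bg))
        realized = []
        for t0, frac, nspk in spec.network_burst_schedule:
            k = max(1, int(round(frac * n_e)))
            chosen = rng.choice(n_e, size=k, replace=False)
            for e in chosen:
                base = t0 + 0.010 * np.arange(int(nspk))
                jit = rng.normal(0.0, spec.within_burst_jitter_sd_ms / 1000.0, int(nspk))
                per_elec[e].extend(np.clip(base + jit, 0, spec.duration - 1e-9))
            realized.append(
                {"time_s": t0, "electrodes": sorted(int(c) for c in chosen), "spikes_per_electrode": int(nspk)}
            )
        for e in range(n_e):
            t = np.unique(np.sort(np.asarray(per_elec[e], dtype=float)))
            t = t[(t >= 0) & (t < spec.duration)]
            spikes[(w, e)] = t
        truth["wells"][w] = realized
        if spec.emit_voltage:
            n_samp = int(round(spec.duration * spec.voltage_fs))
            tpl = _biphasic_template(spec.voltage_fs)
            vrng = np.random.default_rng(wseed.spawn(1)[0])
            traces = vrng.standard_normal((n_e, n_samp))
            for e in range(n_e):
                for t in spikes[(w, e)]:
                    i0 = int(round(t * spec.voltage_fs))
                    seg = tpl[: n_samp - i0]
                    traces[e, i0 : i0 + len(seg)] += spec.spike_snr * seg
            voltage[w] = traces
    return (
        SpikeTrainSet(
            spikes=spikes,
            duration=spec.duration,
            n_electrodes_per_well=spec.n_electrodes_per_well,
        ),
        voltage,
        truth,
    )


# -------------------------------------------------------------- Spectra


@dataclass
class SpectrumSimSpec:
    """Closed-form aperiodic spectrum plus Gaussian oscillatory peaks.

    log10 P(f) = offset_b - log10(knee_k + f**exponent_chi)
                 + sum_i height_i * exp(-(f - centre_i)^2 / (2 width_i^2))
                 + N(0, noise_sd_log)
    """

    offset_b: float = 1.0
    knee_k: float = 0.0
    exponent_chi: float = 2.0
    peaks: tuple = ()  # (centre Hz, height log10, width Hz)
    freq_range: tuple[float, float] = (1.0, 50.0)
    freq_step: float = 0.25
    noise_sd_log: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        _check(self.exponent_chi >= 0, "exponent_chi", "must be >= 0")
        _check(self.knee_k >= 0, "knee_k", "must be >= 0")
        lo, hi = self.freq_range
        _check(lo > 0 and hi > lo, "freq_range", "must be an increasing positive pair")
        for c, h, wdt in self.peaks:
            _check(lo <= c <= hi, "peaks", f"peak centre {c} Hz outside freq_range")
            _check(wdt > 0, "peaks", "peak width must be positive")


def generate_spectrum(spec: SpectrumSimSpec) -> tuple[SpectrumEstimate, dict]:
    """Tabulate the closed-form spectrum on its frequency grid."""
    spec.validate()
    f = np.arange(spec.freq_range[0], spec.freq_range[1] + spec.freq_step / 2, spec.freq_step)
    logp = aperiodic_model(f, spec.offset_b, spec.knee_k, spec.exponent_chi)
    for c, h, wdt in spec.peaks:
        logp = logp + h * np.exp(-((f - c) ** 2) / (2 * wdt**2))
    if spec.noise_sd_log > 0:
        rng = np.random.default_rng(spec.seed)
        logp = logp + rng.normal(0.0, spec.noise_sd_log, size=f.size)
    truth = {
        "offset_b": spec.offset_b,
        "knee_k": spec.knee_k,
        "exponent_chi": spec.exponent_chi,
        "peaks": list(spec.peaks),
    }
    return SpectrumEstimate(freqs=f, psd=10.0**logp, fs=0.0, n_tapers=0), truth


# -------------------------------------------------------------- Cohorts


@dataclass
class CohortSimSpec:
    """Right-censored two-group survival cohort with exponential times."""

    n_per_group: int = 100
    median_survival_weeks: tuple[float, float] = (71.0, 123.0)
    censoring_fraction: float = 0.2
    group_names: tuple[str, str] = ("A", "B")
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_per_group >= 1, "n_per_group", "must be >= 1")
        _check(all(m > 0 for m in self.median_survival_weeks), "median_survival_weeks", "medians must be positive")
        _check(0 <= self.censoring_fraction < 1, "censoring_fraction", "must lie in [0, 1)")


def generate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Exponential event times at the stated group medians with
    independent exponential censoring at the stated expected fraction."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    rows = []
    for gseed, name, median in zip(
        root.spawn(len(spec.group_names)), spec.group_names, spec.median_survival_weeks
    ):
        rng = np.random.default_rng(gseed)
        lam = np.log(2) / median
        t_event = rng.exponential(1 / lam, size=spec.n_per_group)
        if spec.censoring_fraction > 0:
            mu = lam * spec.censoring_fraction / (1 - spec.censoring_fraction)
            t_cens = rng.exponential(1 / mu, size=spec.n_per_group)
        else:
            t_cens = np.full(spec.n_per_group, np.inf)
        time = np.minimum(t_event, t_cens)
        event = t_event <= t_cens
        for i in range(spec.n_per_group):
            rows.append((f"{name}{i}", name, max(time[i], 1e-6), bool(event[i])))
    return pd.DataFrame(rows, columns=["id", "group", "time_weeks", "event"])
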