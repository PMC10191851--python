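"""End-to-end pipeline: simulate inputs, run every analysis stage, report.

Stages run in dependency order (simulate -> ecog -> decode | connect |
spectra | mea | stats); each stage reads the products of its upstream
stage from the in-memory product store and writes its tables under the
configured output directory.  The JSON report echoes every parameter
actually used, and a re-run with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding, ecog, io, mea, megconn, spectral, stats, synthdata
from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


class MissingUpstreamError(RuntimeError):
    pass


def _need(products: dict, key: str, stage: str):
    if key not in products:
        raise MissingUpstreamError(
            f"stage {stage!r} needs upstream product {key!r}; "
            "run the 'simulate' stage or provide input files"
        )
    return products[key]


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    out = Path(out_dir if out_dir is not None else config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.as_dict(), "stages": {}}
    products: dict = {}
    for stage in config.stages:
        logger.info("running stage %s", stage)
        report["stages"][stage] = _STAGES[stage](config, products, out)
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, sort_keys=True, indent=2, default=_jsonify))
    return report


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"cannot serialize {type(x)}")


# ----------------------------------------------------------------- stages


def _stage_simulate(cfg: PipelineConfig, products: dict, out: Path) -> dict:
    seed = cfg.seed
    sim = cfg["simulate"]

    e = sim["ecog"]
    espec = synthdata.EcogSimSpec(
        n_participants=e["n_participants"],
        n_channels=e["n_channels"],
        fraction_tumour_channels=e["fraction_tumour_channels"],
        fs=e["fs"],
        n_trials_per_condition=e["n_trials_per_condition"],
        tumour_amplitude_ratio=e["tumour_amplitude_ratio"],
        condition_effect_size=e["condition_effect_size"],
        noise_sd=e["noise_sd"],
        seed=seed,
    )
    recs, trials, ecog_truth = synthdata.generate_ecog_dataset(espec)
    products["ecog_recordings"] = recs
    products["ecog_trials"] = trials

    v = sim["voxel"]
    lesion = tuple(range(v["n_lesion_voxels"]))
    vspec = synthdata.VoxelSimSpec(
        n_voxels_per_hemisphere=v["n_voxels_per_hemisphere"],
        fs=v["fs"],
        duration=v["duration"],
        alpha_freq=v["alpha_freq"],
        base_coupling=v["base_coupling"],
        lesion_voxel_ids=lesion,
        lesion_coupling_boost=v["lesion_coupling_boost"],
        noise_sd=v["noise_sd"],
        seed=seed + 1,
    )
    vs = synthdata.generate_voxel_dataset(vspec)
    products["voxel_series"] = vs
    io.write_voxel_series_h5(vs, out / "voxel_series.h5")

    r = sim["raster"]
    times = np.linspace(10.0, r["duration"] - 10.0, r["n_network_bursts"])
    schedule = tuple(
        (float(t), r["burst_electrode_fraction"], r["spikes_per_burst"]) for t in times
    )
    rspec = synthdata.RasterSimSpec(
        n_wells=r["n_wells"],
        n_electrodes_per_well=r["n_electrodes_per_well"],
        duration=r["duration"],
        background_rate=r["background_rate"],
        network_burst_schedule=schedule,
        within_burst_jitter_sd_ms=r["within_burst_jitter_sd_ms"],
        seed=seed + 2,
    )
    sts, _, raster_truth = synthdata.generate_spike_data(rspec)
    products["spike_trains"] = sts
    io.write_spike_csv(sts, out / "spikes.csv")

    s = sim["spectrum"]
    sspec = synthdata.SpectrumSimSpec(
        offset_b=s["offset_b"],
        knee_k=s["knee_k"],
        exponent_chi=s["exponent_chi"],
        peaks=((s["peak_centre_hz"], s["peak_height"], s["peak_width_hz"]),),
        noise_sd_log=s["noise_sd_log"],
        seed=seed + 3,
    )
    spectrum, spec_truth = synthdata.generate_spectrum(sspec)
    products["spectrum"] = spectrum
    products["spectrum_truth"] = spec_truth

    c = sim["cohort"]
    cspec = synthdata.CohortSimSpec(
        n_per_group=c["n_per_group"],
        median_survival_weeks=(c["median_low_weeks"], c["median_high_weeks"]),
        censoring_fraction=c["censoring_fraction"],
        seed=seed + 4,
    )
    cohort = synthdata.generate_cohort(cspec)
    products["cohort"] = cohort
    cohort.to_csv(out / "cohort.csv", index=False, lineterminator="\n")

    # first participant's recording doubles as the container round-trip demo
    io.write_recording_h5(recs[0], out / "recording_p0.h5")
    return {
        "n_participants": len(recs),
        "n_voxels": vs.n_voxels,
        "n_wells": len(sts.wells),
        "n_scheduled_network_bursts": len(schedule),
        "truth": {"ecog": {"tumour_amplitude_ratio": ecog_truth["tumour_amplitude_ratio"]},
                  "raster_bursts": {w: len(b) for w, b in raster_truth["wells"].items()}},
    }


def _stage_ecog(cfg: PipelineConfig, products: dict, out: Path) -> dict:
    recs = _need(products, "ecog_recordings", "ecog")
    trials = _need(products, "ecog_trials", "ecog")
    p = cfg["ecog"]
    rows = []
    hgp_epochs = {}
    for rec, tt in zip(recs, trials):
        participant = rec.meta.get("participant", rec.channel_ids[0][:2])
        screened, _ = ecog.reject_noisy_channels(rec, p["kurtosis_max"])
        kept, _ = ecog.select_trials(tt, p["max_latency_s"])
        epochs = ecog.epoch_speech_locked(screened, kept)
        hgp = ecog.compute_hgp(
            epochs, band=tuple(p["hgp_band"]), fir_order=p["fir_order"]
        )
        hgp_epochs[participant] = hgp
        means = hgp.channel_task_mean(tuple(p["task_window_s"]))
        for ch, tis, m in zip(screened.channel_ids, screened.tissue_label, means):
            rows.append((participant, ch, tis, m))
    table = pd.DataFrame(rows, columns=["participant", "channel", "tissue", "hgp"])
    table.to_csv(out / "hgp_table.csv", index=False, lineterminator="\n")
    products["hgp_table"] = table
    products["hgp_epochs"] = hgp_epochs
    return {"n_channels_analysed": len(table)}


def _stage_decode(cfg: PipelineConfig, products: dict, out: Path) -> dict:
    hgp_epochs = _need(products, "hgp_epochs", "decode")
    d = cfg["decoding"]
    w0, w1 = d["window_s"]
    X, y, groups = [], [], []
    for participant, hgp in hgp_epochs.items():
        t = hgp.window_s[0] + np.arange(hgp.values.shape[2]) / hgp.fs
        sel = (t >= w0) & (t < w1)
        # channel-mean envelope per time bin: a feature space shared across
        # participants regardless of how many channels survived screening
        vals = hgp.values[:, :, sel].mean(axis=1)
        bins = np.array_split(np.arange(vals.shape[1]), d["n_time_bins"])
        feats = np.stack([vals[:, b].mean(axis=1) for b in bins], axis=1)
        X.append(feats)
        y.extend(hgp.trials["condition"].tolist())
        groups.extend([participant] * len(feats))
    fm = decoding.FeatureMatrix(np.vstack(X), np.array(y), np.array(groups))
    result = decoding.decode_lopo(fm, cost=d["cost"])
    (out / "decode_result.json").write_text(
        json.dumps(result.to_dict(), sort_keys=True, indent=2)
    )
    return result.to_dict()


def _stage_connect(cfg: PipelineConfig, products: dict, out: Path) -> dict:
    vs = _need(products, "voxel_series", "connect")
    m = cfg["megconn"]
    cmap = megconn.connectivity_map(
        vs,
        band=tuple(m["band"]),
        segment_s=m["segment_s"],
        overlap=m["overlap"],
        test_method=m["test_method"],
        fdr_alpha=m["fdr_alpha"],
    )
    io.write_connectivity_nifti(cmap, out / "connectivity")
    io.write_connectivity_csv(cmap, out / "connectivity.csv")
    count, positive = megconn.count_hfc_in_tumour(cmap.conn_class, vs.tumour_mask)
    products["connectivity_map"] = cmap
    products["hfc_count"] = count
    lesion = np.asarray(vs.tumour_mask, bool)
    frac_hfc = float(np.mean(cmap.conn_class[lesion] == "HFC")) if lesion.any() else np.nan
    return {
        "hfc_voxels_in_tumour": count,
        "hfc_positive": bool(positive),
        "lesion_fraction_hfc": frac_hfc,
    }


def _stage_spectra(cfg: PipelineConfig, products: dict, out: Path) -> dict:
    spectrum = _need(products, "spectrum", "spectra")
    truth = products.get("spectrum_truth", {})
    s = cfg["spectral"]
    fit = spectral.fit_aperiodic(spectrum)
    gp = spectral.gamma_power(spectrum, fit, band=tuple(s["gamma_band"]))
    row = {
        "offset_b": fit.offset_b,
        "knee_k": fit.knee_k,
        "exponent_chi": fit.exponent_chi,
        "fit_residual_rms": fit.fit_residual_rms,
        "gamma_power": gp,
    }
    pd.DataFrame([row]).to_csv(out / "aperiodic_fit.csv", index=False, lineterminator="\n")
    if truth:
        row["true_exponent_chi"] = truth["exponent_chi"]
    return row


def _stage_mea(cfg: PipelineConfig, products: dict, out: Path) -> dict:
    sts = _need(products, "spike_trains", "mea")
    p = cfg["mea"]
    rows = []
    for well in sts.wells:
        trains = sts.well_trains(well)
        summary = mea.summarize_firing(
            trains,
            duration=sts.duration,
            active_rate_per_min=p["active_rate_per_min"],
            wmfr_mode=p["wmfr_mode"],
        )
        active = [e for e, a in summary["active"].items() if a]
        nb = mea.detect_network_bursts(
            trains,
            active_electrodes=active,
            min_total_spikes=p["min_network_spikes"],
            min_electrode_frac=p["min_electrode_frac"],
            min_spikes_per_burst=p["min_spikes_per_burst"],
            max_isi_s=p["max_isi_s"],
        )
        auncc, _ = mea.compute_auncc(
            trains,
            duration=sts.duration,
            bin_s=p["auncc_bin_s"],
            max_lag_s=p["auncc_max_lag_s"],
            electrodes=active if len(active) >= 2 else None,
        )
        rows.append(
            {
                "well": well,
                "n_active": summary["n_active"],
                "wmfr_hz": summary["wmfr"],
                "n_network_bursts": len(nb),
                "network_burst_freq_hz": len(nb) / sts.duration,
                "auncc": auncc,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "mea_metrics.csv", index=False, lineterminator="\n")
    return {"wells": rows}


def _stage_stats(cfg: PipelineConfig, products: dict, out: Path) -> dict:
    result: dict = {}
    if "hgp_table" in products:
        lme = stats.fit_lme_tissue(products["hgp_table"])
        result["lme_tissue"] = {
            "estimate": lme.fixed_effect_estimate,
            "se": lme.standard_error,
            "F": lme.f_stat,
            "df": [lme.df_num, lme.df_den],
            "p": lme.p_value,
            "participant_sd": lme.participant_random_intercept_sd,
        }
    cohort = _need(products, "cohort", "stats")
    km = stats.km_logrank(cohort, reverse_km_followup=True)
    result["km"] = {
        "median_weeks": {str(g): (None if np.isinf(m) else m) for g, m in km.median.items()},
        "logrank_chi2": km.logrank_chi2,
        "logrank_p": km.logrank_p,
        "median_followup_weeks": km.median_followup,
    }
    (out / "stats_summary.json").write_text(
        json.dumps(result, sort_keys=True, indent=2, default=_jsonify)
    )
    return result


_STAGES = {
    "simulate": _stage_simulate,
    "ecog": _stage_ecog,
    "decode": _stage_decode,
    "connect": _stage_connect,
    "spectra": _stage_spectra,
    "mea": _stage_mea,
    "stats": _stage_stats,
}
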