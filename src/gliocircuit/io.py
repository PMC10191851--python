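"""On-disk formats: HDF5 signal containers, CSV tables, NIfTI maps, EDF import.

HDF5 layout for a Recording:

    /signal            channels x time float64
    /fs                scalar
    /channels/id       string labels
    /channels/coord    channels x 3 mm
    /channels/tissue   string labels

VoxelSeries uses /series, /fs, /grid_index, /spacing_mm, /hemisphere,
/mirror_pair, /tumour_mask.  Connectivity maps are written as one NIfTI
volume per field with an isotropic grid affine, plus a tidy CSV.  All
readers raise named errors on malformed files rather than returning
partial objects.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .ecog import Recording
from .megconn import CLASS_CODES, ConnectivityMap, VoxelSeries
from .mea import SpikeTrainSet

__all__ = [
    "write_recording_h5",
    "read_recording_h5",
    "write_voxel_series_h5",
    "read_voxel_series_h5",
    "write_spike_csv",
    "read_spike_csv",
    "write_connectivity_nifti",
    "read_connectivity_nifti",
    "write_connectivity_csv",
    "read_edf",
    "write_edf",
]


class FileFormatError(RuntimeError):
    """A file could not be parsed as the expected container."""


def _open_h5(path, mode="r"):
    try:
        return h5py.File(path, mode)
    except (OSError, IOError) as exc:
        raise FileFormatError(f"cannot open {path} as HDF5: {exc}") from exc


def write_recording_h5(rec: Recording, path) -> None:
    with _open_h5(path, "w") as f:
        f.create_dataset("signal", data=rec.samples)
        f.create_dataset("fs", data=float(rec.fs))
        g = f.create_group("channels")
        g.create_dataset("id", data=np.array(rec.channel_ids, dtype="S"))
        g.create_dataset("coord", data=rec.channel_coords)
        g.create_dataset("tissue", data=np.array(rec.tissue_label, dtype="S"))
        if rec.meta:
            f.attrs["meta"] = json.dumps(rec.meta, sort_keys=True, default=str)


def read_recording_h5(path) -> Recording:
    with _open_h5(path) as f:
        try:
            rec = Recording(
                samples=f["signal"][()],
                fs=float(f["fs"][()]),
                channel_ids=[s.decode() for s in f["channels/id"][()]],
                channel_coords=f["channels/coord"][()],
                tissue_label=[s.decode() for s in f["channels/tissue"][()]],
                meta=json.loads(f.attrs.get("meta", "{}")),
            )
        except KeyError as exc:
            raise FileFormatError(f"missing dataset in {path}: {exc}") from exc
    return rec


def write_voxel_series_h5(vs: VoxelSeries, path) -> None:
    with _open_h5(path, "w") as f:
        f.create_dataset("series", data=vs.series)
        f.create_dataset("fs", data=float(vs.fs))
        f.create_dataset("grid_index", data=vs.grid_index)
        f.create_dataset("spacing_mm", data=float(vs.spacing_mm))
        f.create_dataset("hemisphere", data=np.array(vs.hemisphere, dtype="S"))
        f.create_dataset("mirror_pair", data=vs.mirror_pair)
        f.create_dataset("tumour_mask", data=vs.tumour_mask)
        if vs.meta:
            f.attrs["meta"] = json.dumps(vs.meta, sort_keys=True, default=str)


def read_voxel_series_h5(path) -> VoxelSeries:
    with _open_h5(path) as f:
        try:
            vs = VoxelSeries(
                series=f["series"][()],
                fs=float(f["fs"][()]),
                grid_index=f["grid_index"][()],
                spacing_mm=float(f["spacing_mm"][()]),
                hemisphere=np.array([s.decode() for s in f["hemisphere"][()]]),
                mirror_pair=f["mirror_pair"][()],
                tumour_mask=f["tumour_mask"][()],
                meta=json.loads(f.attrs.get("meta", "{}")),
            )
        except KeyError as exc:
            raise FileFormatError(f"missing dataset in {path}: {exc}") from exc
    return vs


def write_spike_csv(sts: SpikeTrainSet, path) -> None:
    path = Path(path)
    with open(path, "w") as f:
        f.write(f"# duration_s={sts.duration}\n")
        f.write(f"# n_electrodes_per_well={sts.n_electrodes_per_well}\n")
        sts.to_frame().to_csv(f, index=False, lineterminator="\n")


def read_spike_csv(path) -> SpikeTrainSet:
    path = Path(path)
    duration, n_epw = 1800.0, 16
    with open(path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            key, val = line[1:].strip().split("=")
            if key.strip() == "duration_s":
                duration = float(val)
            elif key.strip() == "n_electrodes_per_well":
                n_epw = int(val)
    try:
        df = pd.read_csv(path, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FileFormatError(f"cannot parse spike CSV {path}: {exc}") from exc
    if not {"well", "electrode", "time_s"} <= set(df.columns):
        raise FileFormatError(f"{path} lacks well/electrode/time_s columns")
    return SpikeTrainSet.from_frame(df, duration=duration, n_electrodes_per_well=n_epw)


# ----------------------------------------------------------------- NIfTI

_NIFTI_FIELDS = ("mean_ic", "z_conn", "t_stat", "p_value", "p_fdr", "class_code")


def _grid_to_volume(grid: np.ndarray, values: np.ndarray):
    offset = grid.min(axis=0)
    shape = grid.max(axis=0) - offset + 1
    vol = np.full(shape, np.nan)
    idx = grid - offset
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = values
    return vol, offset


def write_connectivity_nifti(cmap: ConnectivityMap, prefix) -> list[Path]:
    """One NIfTI volume per map field, isotropic ``spacing_mm`` affine."""
    import nibabel as nib

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    class_code = np.array([CLASS_CODES[c] for c in cmap.conn_class], dtype=float)
    fields = {
        "mean_ic": cmap.mean_ic,
        "z_conn": cmap.z_conn,
        "t_stat": cmap.t_stat,
        "p_value": cmap.p_value,
        "p_fdr": cmap.p_fdr,
        "class_code": class_code,
    }
    written = []
    s = cmap.spacing_mm
    for name, values in fields.items():
        vol, offset = _grid_to_volume(cmap.grid_index, np.asarray(values, float))
        affine = np.diag([s, s, s, 1.0])
        affine[:3, 3] = offset * s
        img = nib.Nifti1Image(vol, affine)
        img.header.set_zooms((s, s, s))
        out = prefix.parent / f"{prefix.name}_{name}.nii"
        nib.save(img, out)
        written.append(out)
    return written


def read_connectivity_nifti(prefix) -> dict:
    """Read back the per-field volumes written by write_connectivity_nifti."""
    import nibabel as nib

    prefix = Path(prefix)
    out = {}
    for name in _NIFTI_FIELDS:
        path = prefix.parent / f"{prefix.name}_{name}.nii"
        try:
            img = nib.load(path)
        except Exception as exc:  # nibabel raises several types here
            raise FileFormatError(f"cannot read NIfTI {path}: {exc}") from exc
        out[name] = img
    return out


def write_connectivity_csv(cmap: ConnectivityMap, path) -> None:
    cmap.to_frame().to_csv(path, index=False, lineterminator="\n")


# ------------------------------------------------------------------- EDF


def read_edf(path, tissue_label: list | None = None) -> Recording:
    """Import a continuous EDF recording as a Recording.

    Channel coordinates are not carried by EDF and are set to NaN;
    tissue labels default to ``unknown``.
    """
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise FileFormatError(f"cannot read EDF {path}: {exc}") from exc
    # recordings are stored in microvolts; undo the reader's SI conversion
    data = raw.get_data(units="uV")
    n = data.shape[0]
    return Recording(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel_ids=list(raw.ch_names),
        channel_coords=np.full((n, 3), np.nan),
        tissue_label=list(tissue_label) if tissue_label else ["unknown"] * n,
    )


def write_edf(samples: np.ndarray, fs: float, channel_ids: list[str], path) -> None:
    """Minimal EDF writer for continuous 16-bit recordings.

    Supports integer 1-s data records; intended for export and for
    exercising the EDF import path, not for clinical archiving.
    """
    x = np.asarray(samples, dtype=float)
    n_ch, n_samp = x.shape
    spr = int(round(fs))  # samples per 1-s record
    if abs(spr - fs) > 1e-9:
        raise ValueError("write_edf requires an integer sampling rate")
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = x
    pmin = padded.min(axis=1)
    pmax = padded.max(axis=1)
    pmax = np.where(pmax == pmin, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scaled = (padded - pmin[:, None]) / (pmax - pmin)[:, None]
    digital = np.round(scaled * (dmax - dmin) + dmin).astype("<i2")

    def pad(s, n):
        s = str(s)[:n]
        return s + " " * (n - len(s))

    header = (
        pad("0", 8)
        + pad("synthetic", 80)
        + pad("synthetic", 80)
        + pad("01.01.00", 8)
        + pad("00.00.00", 8)
        + pad(256 + 256 * n_ch, 8)
        + pad("", 44)
        + pad(n_rec, 8)
        + pad("1", 8)
        + pad(n_ch, 4)
    )
    fields = [
        ("".join(pad(c, 16) for c in channel_ids)),
        ("".join(pad("", 80) for _ in range(n_ch))),
        ("".join(pad("uV", 8) for _ in range(n_ch))),
        ("".join(pad(f"{pmin[i]:.6g}"[:8], 8) for i in range(n_ch))),
        ("".join(pad(f"{pmax[i]:.6g}"[:8], 8) for i in range(n_ch))),
        ("".join(pad(dmin, 8) for _ in range(n_ch))),
        ("".join(pad(dmax, 8) for _ in range(n_ch))),
        ("".join(pad("", 80) for _ in range(n_ch))),
        ("".join(pad(spr, 8) for _ in range(n_ch))),
        ("".join(pad("", 32) for _ in range(n_ch))),
    ]
    with open(path, "wb") as f:
        f.write(header.encode("ascii"))
        f.write("".join(fields).encode("ascii"))
        for r in range(n_rec):
            for c in range(n_ch):
                f.write(digital[c, r * spr : (r + 1) * spr].tobytes())
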