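"""Voxel-level functional connectivity from band-limited imaginary coherence.

Source-space voxel time series (8-mm grid, one hemisphere mirrored onto
the other) are reduced to a voxel-by-voxel imaginary-coherence (IC)
matrix in the alpha band.  Imaginary coherence discards the real part of
the coherency and is therefore insensitive to zero-lag (volume-
conducted) mixing.  Per-voxel connectivity is the Fisher-transformed
mean IC to the rest of the brain, standardized across voxels; voxels are
tested against the contralesional hemisphere and split into tertiles
(HFC = upper, LFC = lower).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal as sps
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelSeries",
    "ConnectivityMap",
    "pairwise_imaginary_coherence",
    "voxel_connectivity_z",
    "contralesional_test",
    "classify_tertiles",
    "count_hfc_in_tumour",
    "connectivity_map",
]

CLASS_CODES = {"LFC": 0, "intermediate": 1, "HFC": 2}


@dataclass
class VoxelSeries:
    """Voxel-grid time series with hemisphere, mirror-pair and tumour masks."""

    series: np.ndarray  # voxels x time
    fs: float
    grid_index: np.ndarray  # voxels x 3 integer grid coordinates
    spacing_mm: float = 8.0
    hemisphere: np.ndarray | None = None  # 'left' / 'right' per voxel
    mirror_pair: np.ndarray | None = None  # partner voxel id, -1 if none
    tumour_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        self.grid_index = np.asarray(self.grid_index, dtype=int)
        n = self.series.shape[0]
        if self.grid_index.shape != (n, 3):
            raise ValueError("grid_index must be voxels x 3")
        if self.hemisphere is None:
            self.hemisphere = np.where(self.grid_index[:, 0] < 0, "left", "right")
        self.hemisphere = np.asarray(self.hemisphere)
        if self.mirror_pair is None:
            self.mirror_pair = _mirror_from_grid(self.grid_index)
        self.mirror_pair = np.asarray(self.mirror_pair, dtype=int)
        if self.tumour_mask is None:
            self.tumour_mask = np.zeros(n, dtype=bool)
        self.tumour_mask = np.asarray(self.tumour_mask, dtype=bool)
        mp = self.mirror_pair
        ok = mp >= 0
        if not np.all(mp[mp[ok]] == np.arange(n)[ok]):
            raise ValueError("mirror pairing is not an involution")

    @property
    def n_voxels(self) -> int:
        return self.series.shape[0]

    @property
    def duration(self) -> float:
        return self.series.shape[1] / self.fs


def _mirror_from_grid(grid: np.ndarray) -> np.ndarray:
    """Mirror pairing by reflecting the x grid index across the midline."""
    lookup = {tuple(g): i for i, g in enumerate(grid)}
    out = np.full(len(grid), -1, dtype=int)
    for i, g in enumerate(grid):
        j = lookup.get((-g[0], g[1], g[2]))
        if j is not None and j != i:
            out[i] = j
    return out


@dataclass
class ConnectivityMap:
    mean_ic: np.ndarray
    z_conn: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    p_fdr: np.ndarray
    conn_class: np.ndarray  # strings: HFC / LFC / intermediate
    grid_index: np.ndarray
    spacing_mm: float = 8.0
    tumour_mask: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.grid_index, columns=["gx", "gy", "gz"])
        df["mean_ic"] = self.mean_ic
        df["z_conn"] = self.z_conn
        df["t_stat"] = self.t_stat
        df["p_value"] = self.p_value
        df["p_fdr"] = self.p_fdr
        df["conn_class"] = self.conn_class
        if self.tumour_mask is not None:
            df["tumour"] = self.tumour_mask
        return df


def pairwise_imaginary_coherence(
    vs: VoxelSeries,
    band: tuple[float, float] = (8.0, 12.0),
    segment_s: float = 1.0,
    overlap: float = 0.5,
) -> np.ndarray:
    """Voxel-by-voxel imaginary coherence averaged over a frequency band.

    Cross-spectra are estimated by Welch segmentation (Hann window,
    ``segment_s`` segments, fractional ``overlap``); the coherency
    C_xy(f) = S_xy / sqrt(S_xx S_yy) is computed per band bin and
    IC(x, y) is the band average of |Im C_xy(f)| weighted by the
    pair's cross-power sqrt(S_xx S_yy), so bins carrying no signal
    energy (where coherency is numerically undefined) do not dilute
    the estimate.  The weighting is invariant to per-voxel amplitude
    rescaling.  The result is symmetric with zero diagonal and entries
    in [0, 1].
    """
    Z = _segment_ffts(vs, band, segment_s, overlap)
    return _ic_from_ffts(Z)


def _segment_ffts(
    vs: VoxelSeries,
    band: tuple[float, float],
    segment_s: float,
    overlap: float,
    min_segments: int = 20,
) -> np.ndarray:
    """Hann-windowed segment FFT coefficients restricted to the band
    (n_segments x n_voxels x n_band_bins complex)."""
    x = vs.series
    n_vox, n_time = x.shape
    nper = int(round(segment_s * vs.fs))
    step = max(1, int(round(nper * (1.0 - overlap))))
    n_seg = (n_time - nper) // step + 1
    if n_seg < min_segments:
        raise ValueError(f"only {n_seg} analysis segments available; need >= {min_segments}")
    if np.any(x.std(axis=1) == 0):
        raise ValueError("constant voxel series present")
    win = sps.get_window("hann", nper)
    freqs = np.fft.rfftfreq(nper, 1.0 / vs.fs)
    fsel = np.flatnonzero((freqs >= band[0]) & (freqs <= band[1]))
    if fsel.size == 0:
        raise ValueError("no frequency bins inside the requested band")
    Z = np.empty((n_seg, n_vox, fsel.size), dtype=complex)
    for k in range(n_seg):
        seg = x[:, k * step : k * step + nper] * win
        Z[k] = np.fft.rfft(seg, axis=1)[:, fsel]
    return Z


def _ic_from_ffts(Z: np.ndarray, seg_idx: np.ndarray | None = None) -> np.ndarray:
    """IC matrix from (a subset of) segment FFT coefficients."""
    if seg_idx is not None:
        Z = Z[seg_idx]
    S = np.einsum("kvf,kwf->vwf", Z, np.conj(Z)) / Z.shape[0]
    auto = np.real(np.einsum("iif->if", S))  # S_xx per voxel and bin
    denom = np.sqrt(auto[:, None, :] * auto[None, :, :])
    C = S / denom
    ic = np.average(np.abs(np.imag(C)), axis=2, weights=denom + 1e-300)
    ic = np.clip((ic + ic.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(ic, 0.0)
    return ic


def _fisher(ic: np.ndarray) -> np.ndarray:
    if np.any(ic >= 1.0):
        warnings.warn("IC entries at 1.0 clipped to 1 - 1e-6 before atanh")
    return np.arctanh(np.clip(ic, 0.0, 1.0 - 1e-6))


def voxel_connectivity_z(ic: np.ndarray) -> np.ndarray:
    """Z-transformed connectivity: Fisher atanh, mean to the rest of the
    brain, then standardization across voxels (zero mean, unit SD)."""
    n = ic.shape[0]
    if n < 3:
        raise ValueError("need at least 3 voxels")
    F = _fisher(ic)
    np.fill_diagonal(F, 0.0)
    m = F.sum(axis=1) / (n - 1)
    sd = m.std()
    if sd == 0:
        return np.zeros(n)
    return (m - m.mean()) / sd


def contralesional_test(
    data,
    hemisphere: np.ndarray | None = None,
    tumour_mask: np.ndarray | None = None,
    method: str = "mirror_block",
    mirror_pair: np.ndarray | None = None,
    n_blocks: int = 12,
    band: tuple[float, float] = (8.0, 12.0),
    segment_s: float = 1.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-tailed voxel test against the contralesional reference.

    The tested null is that the Fisher-transformed IC between index
    voxel i and the non-tumour targets equals the contralesional
    reference connectivity to the same targets.  ``data`` is a
    VoxelSeries (required for the default method) or a precomputed IC
    matrix.  ``method``:

    - ``"mirror_block"`` (default): the contrast
      mean_j [F(i, j) - F(mirror(i), j)] is computed independently on
      ``n_blocks`` disjoint time blocks of the epoch and tested with a
      one-sample two-tailed t-test across blocks.  The mirror twin
      shares i's structural connectivity profile, and time blocks give
      independent replicates, so the statistic is calibrated under
      hemispheric exchangeability.  Voxels without a mirror pair get
      NaN.
    - ``"mirror"``: paired t-test of F(i, j) vs F(mirror(i), j) over
      targets j (anticonservative: estimation noise is shared along a
      voxel's row, so targets are not independent replicates).
    - ``"contra_mean_paired"`` / ``"welch"``: reference B_j is the mean
      Fisher IC between all voxels contralateral to i and target j;
      paired, respectively unpaired Welch, t-test over targets.

    Returns (t_stat, p_value) per voxel; NaN where undefined.
    """
    if isinstance(data, VoxelSeries):
        vs = data
        hemisphere = vs.hemisphere if hemisphere is None else hemisphere
        tumour_mask = vs.tumour_mask if tumour_mask is None else tumour_mask
        mirror_pair = vs.mirror_pair if mirror_pair is None else mirror_pair
        ic = None
    else:
        vs = None
        ic = np.asarray(data, dtype=float)
        if hemisphere is None:
            raise ValueError("hemisphere labels required with a precomputed IC matrix")
    n = len(hemisphere)
    hemisphere = np.asarray(hemisphere)
    if tumour_mask is None:
        tumour_mask = np.zeros(n, dtype=bool)
    non_tumour = np.flatnonzero(~np.asarray(tumour_mask, dtype=bool))
    if non_tumour.size == 0:
        raise ValueError("non-tumour voxel set is empty")
    if method == "mirror_block":
        if vs is None:
            raise ValueError("method 'mirror_block' needs the VoxelSeries, not an IC matrix")
        if mirror_pair is None:
            raise ValueError("method 'mirror_block' requires mirror pairing")
        return _mirror_block_test(
            vs, non_tumour, mirror_pair, n_blocks, band, segment_s, overlap
        )
    if ic is None:
        ic = pairwise_imaginary_coherence(vs, band=band, segment_s=segment_s, overlap=overlap)
    if method == "mirror" and mirror_pair is None:
        raise ValueError("method 'mirror' requires mirror pairing")
    F = _fisher(ic)
    np.fill_diagonal(F, 0.0)

    t_out = np.full(n, np.nan)
    p_out = np.full(n, np.nan)
    for hemi in np.unique(hemisphere):
        idx = np.flatnonzero(hemisphere == hemi)
        contra = np.flatnonzero(hemisphere != hemi)
        if contra.size == 0:
            continue
        # column j: mean F(c, j) over contralateral voxels c (c == j excluded)
        colsum = F[contra].sum(axis=0)
        in_contra = np.isin(np.arange(n), contra)
        denom = contra.size - in_contra.astype(int)
        contra_mean = colsum / denom
        for i in idx:
            if method == "mirror":
                m = int(mirror_pair[i])
                if m < 0:
                    continue  # no contralesional pair: NaN
                targets = non_tumour[(non_tumour != i) & (non_tumour != m)]
            else:
                targets = non_tumour[non_tumour != i]
            if targets.size < 3:
                continue
            A = F[i, targets]
            if method == "mirror":
                B = F[m, targets]
            elif method in ("contra_mean_paired", "welch"):
                B = contra_mean[targets]
            else:
                raise ValueError(f"unknown method {method!r}")
            if np.allclose(A, B):
                t_out[i], p_out[i] = 0.0, 1.0
                continue
            if method == "welch":
                t, p = stats.ttest_ind(A, B, equal_var=False)
            else:
                t, p = stats.ttest_rel(A, B)
            t_out[i], p_out[i] = float(t), float(p)
    return t_out, p_out


def _mirror_block_test(
    vs: VoxelSeries,
    non_tumour: np.ndarray,
    mirror_pair: np.ndarray,
    n_blocks: int,
    band: tuple[float, float],
    segment_s: float,
    overlap: float,
) -> tuple[np.ndarray, np.ndarray]:
    n = vs.n_voxels
    Z = _segment_ffts(vs, band, segment_s, overlap)
    n_seg = Z.shape[0]
    if n_blocks < 3:
        raise ValueError("need at least 3 time blocks")
    blocks = np.array_split(np.arange(n_seg), n_blocks)
    nt_mask = np.zeros(n, dtype=bool)
    nt_mask[non_tumour] = True
    contrast = np.full((n_blocks, n), np.nan)
    for b, seg_idx in enumerate(blocks):
        F = _fisher(_ic_from_ffts(Z, seg_idx))
        np.fill_diagonal(F, 0.0)
        for i in range(n):
            m = int(mirror_pair[i])
            if m < 0:
                continue
            t_mask = nt_mask.copy()
            t_mask[[i, m]] = False
            k = t_mask.sum()
            if k < 3:
                continue
            contrast[b, i] = (F[i, t_mask].sum() - F[m, t_mask].sum()) / k
    t_out = np.full(n, np.nan)
    p_out = np.full(n, np.nan)
    valid = ~np.isnan(contrast).any(axis=0)
    if valid.any():
        d = contrast[:, valid]
        if np.allclose(d, 0.0):
            t_out[valid], p_out[valid] = 0.0, 1.0
        else:
            t, p = stats.ttest_1samp(d, 0.0, axis=0)
            t_out[valid], p_out[valid] = t, p
    return t_out, p_out


def classify_tertiles(
    z_conn: np.ndarray, voxel_ids: np.ndarray | None = None
) -> np.ndarray:
    """Split voxels into connectivity tertiles.

    Top floor(n/3) ranked values -> HFC, bottom floor(n/3) -> LFC, the
    remainder intermediate.  Ties are broken by voxel id so the split is
    deterministic.  A constant vector yields all-intermediate with a
    warning.
    """
    z = np.asarray(z_conn, dtype=float)
    n = len(z)
    if n < 3:
        raise ValueError("need at least 3 voxels to form tertiles")
    if voxel_ids is None:
        voxel_ids = np.arange(n)
    out = np.array(["intermediate"] * n, dtype=object)
    if np.all(z == z[0]):
        warnings.warn("constant connectivity vector: all voxels intermediate")
        return out
    k = n // 3
    order = np.lexsort((np.asarray(voxel_ids), z))  # ascending, id breaks ties
    out[order[:k]] = "LFC"
    out[order[n - k :]] = "HFC"
    return out


def count_hfc_in_tumour(
    conn_class: np.ndarray, enhancing_tumour_mask: np.ndarray
) -> tuple[int, bool]:
    """Count HFC voxels inside the contrast-enhancing tumour mask.

    A tumour is HFC-positive when at least one HFC voxel falls inside
    the mask.
    """
    mask = np.asarray(enhancing_tumour_mask, dtype=bool)
    if not mask.any():
        raise ValueError("enhancing tumour mask is empty")
    count = int(np.sum((np.asarray(conn_class) == "HFC") & mask))
    return count, count >= 1


def connectivity_map(
    vs: VoxelSeries,
    band: tuple[float, float] = (8.0, 12.0),
    segment_s: float = 1.0,
    overlap: float = 0.5,
    test_method: str = "mirror_block",
    fdr_alpha: float = 0.05,
) -> ConnectivityMap:
    """End-to-end connectivity mapping: IC -> z -> voxel test -> tertiles."""
    from .stats import fdr_adjust

    ic = pairwise_imaginary_coherence(vs, band=band, segment_s=segment_s, overlap=overlap)
    z = voxel_connectivity_z(ic)
    t, p = contralesional_test(
        vs, method=test_method, band=band, segment_s=segment_s, overlap=overlap
    )
    p_fdr = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        p_fdr[ok] = fdr_adjust(p[ok])
    classes = classify_tertiles(z)
    mean_ic = ic.sum(axis=1) / (ic.shape[0] - 1)
    return ConnectivityMap(
        mean_ic=mean_ic,
        z_conn=z,
        t_stat=t,
        p_value=p,
        p_fdr=p_fdr,
        conn_class=classes,
        grid_index=vs.grid_index,
        spacing_mm=vs.spacing_mm,
        tumour_mask=vs.tumour_mask,
    )
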