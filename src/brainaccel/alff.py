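"""Amplitude of low-frequency fluctuation (ALFF) and voxelwise group statistics.

ALFF summarizes resting-state BOLD activity at a voxel as the mean spectral
amplitude of its time series within a low-frequency band (default
0.01-0.08 Hz).  Per subject, voxel amplitudes are normalized to the mean over
a gray-matter mask, which removes global scaling differences between
subjects.  Group contrasts are fitted per voxel, converted to z by two-sided
tail matching, and thresholded with Benjamini-Hochberg FDR plus a minimum
cluster extent under face (6-neighbour) connectivity.

Amplitude convention: after linear detrending, with ``X(f)`` the unpadded
discrete Fourier transform of the length-``N`` series, the per-bin amplitude
is ``sqrt(2) * |X(f)| / N`` and ALFF is the mean over the in-band bins
(band edges inclusive).  For a pure sinusoid ``A*sin(2*pi*f*t)`` exactly on a
bin this gives ``A / sqrt(2)``, the RMS amplitude.  The constant is
immaterial downstream because maps are global-mean normalized, but it is
fixed so amplitudes are comparable across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .effects import bh_fdr

DEFAULT_BAND = (0.01, 0.08)


@dataclass
class VoxelTimeSeries:
    """A 4D BOLD acquisition: (x, y, z, t) data with TR and gray-matter mask."""

    data: np.ndarray
    tr: float
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.data.shape[3] < 16:
            raise ValueError("need at least 16 timepoints")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must equal the spatial shape")


@dataclass
class ALFFMap:
    """Voxelwise ALFF values; NaN outside the mask."""

    values: np.ndarray
    band: tuple[float, float]
    normalized: bool


@dataclass
class Cluster:
    voxels: np.ndarray          # (k, 3) integer coordinates
    size: int
    peak: tuple[int, int, int]
    peak_z: float
    sign: int                   # +1 increased, -1 decreased


@dataclass
class ClusterSet:
    clusters: list[Cluster] = field(default_factory=list)
    threshold_p: float = 0.05
    min_size: int = 12

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"cluster": i + 1, "size": c.size,
                 "peak_x": c.peak[0], "peak_y": c.peak[1], "peak_z_coord": c.peak[2],
                 "peak_z": c.peak_z, "sign": c.sign}
                for i, c in enumerate(self.clusters)]
        return pd.DataFrame(rows, columns=["cluster", "size", "peak_x", "peak_y",
                                           "peak_z_coord", "peak_z", "sign"])


def _band_bins(n: int, tr: float, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    nyquist = 0.5 / tr
    if not (0.0 < lo <= hi < nyquist):
        raise ValueError(f"band {band} outside (0, Nyquist={nyquist:g}) Hz")
    freqs = np.fft.rfftfreq(n, d=tr)
    bins = np.nonzero((freqs >= lo) & (freqs <= hi))[0]
    if bins.size == 0:
        raise ValueError(f"no DFT bin falls in band {band} for N={n}, TR={tr}")
    return bins


def bandpass_amplitude(series, tr: float, band: tuple[float, float] = DEFAULT_BAND) -> float:
    """Mean in-band spectral amplitude of one detrended time series."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 16:
        raise ValueError("series must be 1D with at least 16 timepoints")
    bins = _band_bins(series.size, tr, band)
    spec = np.abs(np.fft.rfft(signal.detrend(series, type="linear")))
    return float(np.mean(np.sqrt(2.0) * spec[bins] / series.size))


def compute_alff_map(vol: VoxelTimeSeries,
                     band: tuple[float, float] = DEFAULT_BAND) -> ALFFMap:
    """Voxelwise ALFF, normalized to the subject's global (in-mask) mean.

    Out-of-mask voxels are NaN.  Doubling the entire 4D signal leaves the
    normalized map unchanged; the in-mask mean of the result is exactly 1.
    """
    mask = vol.mask.astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    n_t = vol.data.shape[3]
    bins = _band_bins(n_t, vol.tr, band)
    ts = vol.data[mask]                                    # (V, t)
    spec = np.abs(np.fft.rfft(signal.detrend(ts, axis=1, type="linear"), axis=1))
    amp = np.mean(np.sqrt(2.0) * spec[:, bins] / n_t, axis=1)
    gmean = amp.mean()
    if gmean == 0:
        raise ValueError("global mean amplitude is zero; cannot normalize")
    values = np.full(vol.data.shape[:3], np.nan)
    values[mask] = amp / gmean
    return ALFFMap(values=values, band=tuple(band), normalized=True)


def smooth_gaussian(volume: np.ndarray, fwhm: float,
                    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> np.ndarray:
    """Gaussian spatial smoothing with the kernel width given as FWHM in mm."""
    if fwhm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm == 0:
        return np.array(volume, dtype=float)
    sigma_mm = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigmas = [sigma_mm / vs for vs in voxel_size]
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma=sigmas)


def subject_alff(vol: VoxelTimeSeries, band: tuple[float, float] = DEFAULT_BAND,
                 fwhm: float = 0.0, smooth_first: bool = True) -> ALFFMap:
    """Full single-subject ALFF: smoothing plus amplitude plus normalization.

    ``smooth_first=True`` (default) smooths each time frame before computing
    amplitudes, the conventional image-space ordering; ``False`` smooths the
    normalized amplitude map instead.
    """
    if fwhm > 0 and smooth_first:
        smoothed = np.stack([smooth_gaussian(vol.data[..., t], fwhm, vol.voxel_size)
                             for t in range(vol.data.shape[3])], axis=-1)
        vol = VoxelTimeSeries(smoothed, vol.tr, vol.mask, vol.voxel_size)
    amap = compute_alff_map(vol, band)
    if fwhm > 0 and not smooth_first:
        sm = smooth_gaussian(np.nan_to_num(amap.values), fwhm, vol.voxel_size)
        sm[~vol.mask.astype(bool)] = np.nan
        amap = ALFFMap(values=sm, band=amap.band, normalized=amap.normalized)
    return amap


def voxelwise_group_stats(maps, factor, covariates: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel OLS of ALFF on a factor, returned as a signed z map.

    ``maps`` is a sequence of :class:`ALFFMap` (or 3D arrays) over subjects,
    ``factor`` the per-subject regressor (0/1 group or continuous), and
    ``covariates`` an optional (n, c) matrix.  The factor's t statistic is
    converted to z by matching two-sided tail probabilities with the sign
    preserved, making values comparable across differing residual degrees of
    freedom.  Voxels missing (NaN) in any subject come back NaN.
    """
    arrays = [m.values if isinstance(m, ALFFMap) else np.asarray(m, dtype=float)
              for m in maps]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all maps must share one spatial shape")
    Y = np.stack([a.ravel() for a in arrays])               # (n, V)
    fac = np.asarray(factor, dtype=float)
    if fac.shape[0] != Y.shape[0]:
        raise ValueError("factor length must equal number of maps")
    X = [np.ones_like(fac), fac]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != fac.shape[0]:
            cov = cov.T
        X.extend(cov.T)
    X = np.column_stack(X)
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValueError("not enough subjects for the model")

    ok = ~np.isnan(Y).any(axis=0)
    z = np.full(Y.shape[1], np.nan)
    if ok.any():
        Yok = Y[:, ok]
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ (X.T @ Yok)                        # (p, V)
        resid = Yok - X @ beta
        sigma2 = np.einsum("ij,ij->j", resid, resid) / df
        se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = beta[1] / se
        tstat = np.where(se == 0, np.sign(beta[1]) * np.inf, tstat)
        p_two = 2.0 * stats.t.sf(np.abs(tstat), df)
        zval = stats.norm.isf(np.clip(p_two / 2.0, 1e-300, 1.0))
        z[ok] = np.sign(tstat) * zval
    return z.reshape(shape)


_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


def threshold_clusters(z: np.ndarray, q: float = 0.05, min_size: int = 12,
                       mask: np.ndarray | None = None) -> ClusterSet:
    """FDR- and extent-thresholded clusters of a signed z map.

    Two-sided voxel p-values are Benjamini-Hochberg adjusted across in-mask
    voxels; suprathreshold voxels are grouped by face connectivity separately
    for each sign (a cluster never mixes increases and decreases) and
    clusters smaller than ``min_size`` voxels are discarded.  Because the
    adjusted p-values are fixed, cluster voxel sets are monotone in ``q``.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError("q must lie in (0, 1]")
    z = np.asarray(z, dtype=float)
    mask = ~np.isnan(z) if mask is None else (np.asarray(mask, dtype=bool) & ~np.isnan(z))
    out = ClusterSet(clusters=[], threshold_p=q, min_size=min_size)
    if not mask.any():
        return out
    p = 2.0 * stats.norm.sf(np.abs(z[mask]))
    p_adj = bh_fdr(p)
    sig = np.zeros(z.shape, dtype=bool)
    sig[mask] = p_adj <= q
    for sgn in (1, -1):
        blob = sig & ((z > 0) if sgn == 1 else (z < 0))
        labels, n_lab = ndimage.label(blob, structure=_FACE_STRUCTURE)
        for lab in range(1, n_lab + 1):
            coords = np.argwhere(labels == lab)
            if len(coords) < min_size:
                continue
            zvals = z[tuple(coords.T)]
            k = int(np.argmax(np.abs(zvals)))
            out.clusters.append(Cluster(voxels=coords, size=len(coords),
                                        peak=tuple(int(v) for v in coords[k]),
                                        peak_z=float(zvals[k]), sign=sgn))
    out.clusters.sort(key=lambda c: -c.size)
    return out


def aggregate_regions(volume: np.ndarray, region_labels: np.ndarray,
                      region_names: dict[int, str] | None = None) -> pd.Series:
    """Mean map value per labelled region (labels > 0), skipping NaN voxels.

    This coarse-grains a voxel map (ALFF, z, or any externally produced
    statistic map) to the regional grain of the gray-matter analysis.  An
    empty region yields NaN with a warning.
    """
    volume = np.asarray(volume, dtype=float)
    labels = np.asarray(region_labels)
    if labels.shape != volume.shape:
        raise ValueError("label volume shape must match the map shape")
    out = {}
    for lab in np.unique(labels):
        if lab <= 0:
            continue
        vals = volume[labels == lab]
        vals = vals[~np.isnan(vals)]
        name = region_names[int(lab)] if region_names else int(lab)
        if vals.size == 0:
            warnings.warn(f"region {name!r} has no usable voxels", stacklevel=2)
            out[name] = np.nan
        else:
            out[name] = float(vals.mean())
    s = pd.Series(out)
    s.index.name = "region"
    return s
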