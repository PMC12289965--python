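"""Quantification chain: raw per-pixel spectra -> shift/linewidth maps ->
aggregate-vs-periphery statistics over time.

The spectral model is a baseline plus two mirrored Lorentzian peaks
(anti-Stokes at nu, Stokes at FSR - nu, shared width) plus Rayleigh
Lorentzians pinned at the axis ends.  Lorentzian convolution adds widths
exactly, so the instrumental response (0.270 GHz by default) is removed by
linear subtraction from the fitted width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .synthetic_scope import Spectrum

INSTRUMENTAL_LINEWIDTH_GHZ = 0.270
_RAYLEIGH_GUARD_GHZ = 0.5  # excluded from peak initialization


@dataclass
class SpectralFit:
    shift_GHz: float
    linewidth_meas_GHz: float
    linewidth_corr_GHz: float
    amplitude: float
    baseline: float
    residual_rms: float
    valid: bool


@dataclass
class BrillouinMap:
    shift_map: np.ndarray
    linewidth_map: np.ndarray  # deconvolved widths (GHz)
    linewidth_meas_map: np.ndarray
    valid_mask: np.ndarray
    step_um: float = 1.0
    timestamp_s: float = 0.0


@dataclass
class RegionMasks:
    aggregate: np.ndarray
    signal_shift: np.ndarray
    signal_lw: np.ndarray

    @property
    def periphery_shift(self) -> np.ndarray:
        return self.signal_shift & ~self.aggregate

    @property
    def periphery_lw(self) -> np.ndarray:
        return self.signal_lw & ~self.aggregate


@dataclass
class RegionTimepointStats:
    timestamp_s: float
    shift_agg_mean: Optional[float]
    shift_agg_sd: Optional[float]
    shift_peri_mean: Optional[float]
    shift_peri_sd: Optional[float]
    lw_agg_mean: Optional[float]
    lw_agg_sd: Optional[float]
    lw_peri_mean: Optional[float]
    lw_peri_sd: Optional[float]
    n_agg: int = 0
    n_peri_shift: int = 0
    n_peri_lw: int = 0


@dataclass
class RegionStats:
    timepoints: list[RegionTimepointStats] = field(default_factory=list)


# ---------------------------------------------------------------------------
# spectral fitting


def _lorentzian(x, x0, fwhm):
    g = 0.5 * fwhm
    return g * g / ((x - x0) ** 2 + g * g)


def spectral_model(x, baseline, amp, nu, gamma, amp_r, gamma_r, fsr):
    """Baseline + mirrored Brillouin doublet + end-pinned Rayleigh peaks."""
    return (
        baseline
        + amp * (_lorentzian(x, nu, gamma) + _lorentzian(x, fsr - nu, gamma))
        + amp_r * (_lorentzian(x, 0.0, gamma_r) + _lorentzian(x, fsr, gamma_r))
    )


def fit_spectrum(
    spec: Spectrum,
    fsr_GHz: float,
    init: Optional[dict] = None,
    instr_linewidth_GHz: float = INSTRUMENTAL_LINEWIDTH_GHZ,
) -> SpectralFit:
    """Nonlinear least-squares fit of one spectrum.

    Initialization takes the largest interior maximum outside the Rayleigh
    guard bands; validity requires a peak above baseline + 3 sigma and a
    measured width above the instrumental width.
    """
    x = spec.freq_axis_GHz
    y = spec.counts
    if len(x) < 32:
        raise ValueError("need at least 32 spectral bins")
    if not np.any(y > 0):
        raise ValueError("spectrum has no positive counts")

    interior = (x > _RAYLEIGH_GUARD_GHZ) & (x < fsr_GHz - _RAYLEIGH_GUARD_GHZ)
    baseline0 = float(np.median(y[interior]))
    noise_sd = math.sqrt(max(baseline0, 1.0))
    invalid = SpectralFit(shift_GHz=float("nan"), linewidth_meas_GHz=float("nan"),
                          linewidth_corr_GHz=float("nan"), amplitude=0.0,
                          baseline=baseline0, residual_rms=float("nan"),
                          valid=False)
    if float(y[interior].max()) < baseline0 + 3.0 * noise_sd:
        return invalid

    half = interior & (x <= fsr_GHz / 2.0)
    xi = x[half]
    nu0 = float(xi[np.argmax(y[half])])
    if init:
        nu0 = float(init.get("shift_GHz", nu0))
    gamma0 = float(init.get("linewidth_GHz", 0.5)) if init else 0.5
    amp0 = max(float(y[half].max()) - baseline0, 1.0)
    amp_r0 = max(float(y.max()) - baseline0, amp0)

    p0 = [baseline0, amp0, nu0, gamma0, amp_r0, instr_linewidth_GHz]
    lo = [0.0, 0.0, 0.3, 0.03, 0.0, 0.03]
    hi = [np.inf, np.inf, fsr_GHz / 2.0, 5.0, np.inf, 5.0]
    try:
        popt, _ = curve_fit(
            lambda xx, b, a, nu, g, ar, gr: spectral_model(xx, b, a, nu, g, ar,
                                                           gr, fsr_GHz),
            x, y, p0=p0, bounds=(lo, hi), maxfev=20000)
    except (RuntimeError, ValueError):
        return invalid
    baseline, amp, nu, gamma, amp_r, gamma_r = (float(v) for v in popt)
    resid = y - spectral_model(x, *popt, fsr_GHz)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    corr, corr_valid = deconvolve_linewidth(gamma, instr_linewidth_GHz)
    valid = corr_valid and amp > 3.0 * noise_sd and 0.0 < nu < fsr_GHz / 2.0
    return SpectralFit(shift_GHz=nu, linewidth_meas_GHz=gamma,
                       linewidth_corr_GHz=corr, amplitude=amp,
                       baseline=baseline, residual_rms=rms, valid=valid)


def deconvolve_linewidth(
    gamma_meas_GHz: float,
    gamma_instr_GHz: float = INSTRUMENTAL_LINEWIDTH_GHZ,
) -> tuple[float, bool]:
    """Remove instrumental broadening by width subtraction.

    Returns (corrected width, valid); sub-resolution widths clamp to
    (0, False) — never negative.
    """
    if gamma_meas_GHz <= 0:
        raise ValueError("measured linewidth must be > 0")
    corr = gamma_meas_GHz - gamma_instr_GHz
    if corr <= 0:
        return 0.0, False
    return corr, True


def build_map(
    spectra: Sequence[Sequence[Spectrum]],
    fsr_GHz: float,
    step_um: float = 1.0,
    timestamp_s: float = 0.0,
    instr_linewidth_GHz: float = INSTRUMENTAL_LINEWIDTH_GHZ,
) -> BrillouinMap:
    """Fit every pixel of a rectangular grid of spectra."""
    n_rows = len(spectra)
    n_cols = len(spectra[0])
    if any(len(row) != n_cols for row in spectra):
        raise ValueError("spectra grid must be rectangular")
    shift = np.full((n_rows, n_cols), np.nan)
    lw = np.full((n_rows, n_cols), np.nan)
    lw_meas = np.full((n_rows, n_cols), np.nan)
    valid = np.zeros((n_rows, n_cols), dtype=bool)
    for i, row in enumerate(spectra):
        for j, spec in enumerate(row):
            fit = fit_spectrum(spec, fsr_GHz, instr_linewidth_GHz=instr_linewidth_GHz)
            if fit.valid:
                shift[i, j] = fit.shift_GHz
                lw[i, j] = fit.linewidth_corr_GHz
                lw_meas[i, j] = fit.linewidth_meas_GHz
                valid[i, j] = True
    return BrillouinMap(shift_map=shift, linewidth_map=lw,
                        linewidth_meas_map=lw_meas, valid_mask=valid,
                        step_um=step_um, timestamp_s=timestamp_s)


# ---------------------------------------------------------------------------
# segmentation


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance.

    Ties break to the lowest threshold; the foreground convention is
    ``value > threshold``.  Returns the bin edge.
    """
    vals = np.asarray(image, dtype=np.float64).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0 or np.unique(vals).size < 2:
        raise ValueError("image must contain at least 2 distinct finite values")
    counts, edges = np.histogram(vals, bins=n_bins)
    counts = counts.astype(np.float64)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    cum = np.cumsum(counts * centers)
    mu0 = np.where(w0 > 0, cum / np.maximum(w0, 1e-300), 0.0)
    mu1 = np.where(w1 > 0, (cum[-1] - cum) / np.maximum(w1, 1e-300), 0.0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    between[(w0 == 0) | (w1 == 0)] = -np.inf
    k = int(np.argmax(between))  # argmax takes the first (lowest) maximum
    return float(edges[k + 1])


def resample_nearest(image: np.ndarray, out_shape: tuple[int, int],
                     image_fov_um: Optional[float] = None,
                     out_fov_um: Optional[float] = None) -> np.ndarray:
    """Nearest-neighbor resampling onto a (possibly smaller-FOV) grid.

    Both grids are assumed concentric; if FOVs are omitted they are taken
    to span the same extent.
    """
    image = np.asarray(image)
    h, w = image.shape
    oh, ow = out_shape
    if image_fov_um is None or out_fov_um is None:
        ratio = 1.0
    else:
        ratio = out_fov_um / image_fov_um
    # output pixel centers mapped into concentric source coordinates
    ys = (np.arange(oh) - (oh - 1) / 2.0) * ratio * (h - 1) / max(oh - 1, 1) \
        + (h - 1) / 2.0
    xs = (np.arange(ow) - (ow - 1) / 2.0) * ratio * (w - 1) / max(ow - 1, 1) \
        + (w - 1) / 2.0
    iy = np.clip(np.round(ys).astype(int), 0, h - 1)
    ix = np.clip(np.round(xs).astype(int), 0, w - 1)
    return image[np.ix_(iy, ix)]


def segment_regions(
    fluor_image: np.ndarray,
    bmap: BrillouinMap,
    fluor_fov_um: Optional[float] = None,
    map_fov_um: Optional[float] = None,
) -> RegionMasks:
    """Otsu-based masks: aggregate from fluorescence, signal from each map.

    The fluorescence image is resampled (nearest neighbor) onto the map
    grid; each quantity's periphery mask is its own signal support minus
    the aggregate.
    """
    fluor = resample_nearest(np.asarray(fluor_image, dtype=np.float64),
                             bmap.shift_map.shape, fluor_fov_um, map_fov_um)
    agg = fluor > otsu_threshold(fluor)

    def _signal(mapdata):
        filled = np.where(bmap.valid_mask & np.isfinite(mapdata), mapdata, np.nan)
        lo = np.nanmin(filled) if np.isfinite(filled).any() else 0.0
        work = np.where(np.isfinite(filled), filled, lo)
        try:
            thr = otsu_threshold(work)
        except ValueError:
            return np.zeros_like(agg)
        return (work > thr) & bmap.valid_mask

    return RegionMasks(aggregate=agg, signal_shift=_signal(bmap.shift_map),
                       signal_lw=_signal(bmap.linewidth_map))


def _region_mean_sd(mapdata: np.ndarray, mask: np.ndarray,
                    valid: np.ndarray) -> tuple[Optional[float], Optional[float], int]:
    sel = mask & valid & np.isfinite(mapdata)
    n = int(sel.sum())
    if n == 0:
        return None, None, 0
    vals = mapdata[sel]
    return float(vals.mean()), float(vals.std(ddof=0)), n


def region_stats(
    maps: Sequence[BrillouinMap],
    masks: Sequence[RegionMasks],
) -> RegionStats:
    """Mean +/- SD of shift and linewidth per region at each timepoint.

    Empty regions are flagged with ``None`` (a valid pre-onset state).
    """
    if len(maps) != len(masks):
        raise ValueError("need one mask set per map")
    out = RegionStats()
    for bmap, mk in zip(maps, masks):
        sam, sas, na = _region_mean_sd(bmap.shift_map, mk.aggregate, bmap.valid_mask)
        spm, sps, nps = _region_mean_sd(bmap.shift_map, mk.periphery_shift,
                                        bmap.valid_mask)
        lam, las, _ = _region_mean_sd(bmap.linewidth_map, mk.aggregate,
                                      bmap.valid_mask)
        lpm, lps, npl = _region_mean_sd(bmap.linewidth_map, mk.periphery_lw,
                                        bmap.valid_mask)
        out.timepoints.append(RegionTimepointStats(
            timestamp_s=bmap.timestamp_s,
            shift_agg_mean=sam, shift_agg_sd=sas,
            shift_peri_mean=spm, shift_peri_sd=sps,
            lw_agg_mean=lam, lw_agg_sd=las,
            lw_peri_mean=lpm, lw_peri_sd=lps,
            n_agg=na, n_peri_shift=nps, n_peri_lw=npl,
        ))
    return out
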