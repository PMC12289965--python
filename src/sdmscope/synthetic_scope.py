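"""Generative stand-in for the microscope.

Renders multi-plane fluorescence stacks, brightfield images, and per-pixel
Brillouin spectra from a ground-truth virtual sample evolving on a virtual
clock.  Every generator is a pure function of (config, seed): identical
inputs give bit-identical outputs.

Conventions
-----------
* All geometry is defined in micrometres and converted to pixels through
  ``SimConfig.pixel_size_um``; image arrays are indexed (row, col) = (y, x).
* A ``W`` µm scan at step ``s`` includes both endpoints: ``floor(W/s) + 1``
  points per axis.
* Aggregation kinetics: an EVENT cell shows a growing low-contrast
  proto-punctum (the learnable cue) during ``[t0 - cue_lead_time, t0]``;
  over ``[t0, t0 + onset_duration]`` the soluble pool condenses into a
  punctum with total fluorescence conserved up to bleaching.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from ._rng import substream

# fraction of a cell's total fluorescence condensed into the punctum
_F_CUE_MAX = 0.15  # at full cue ramp, scaled by cue_contrast
_F_FINAL = 0.85  # mature aggregate
_TEXTURE_GAIN = 0.10  # local variance cue amplitude relative to body peak

# Brillouin spectral generator rates (counts per second of dwell)
_BRI_PEAK_RATE = 3000.0
_BRI_BASELINE_RATE = 30.0
_RAYLEIGH_GAIN = 5.0


class Fate(str, Enum):
    EVENT = "EVENT"
    NON_EVENT = "NON_EVENT"


class Modality(str, Enum):
    FLUOR = "FLUOR"
    BRIGHTFIELD = "BRIGHTFIELD"
    BRILLOUIN = "BRILLOUIN"


@dataclass(frozen=True)
class SimConfig:
    """Acquisition geometry, noise model and kinetics of the virtual scope."""

    image_size_px: int = 352
    pixel_size_um: float = 0.111
    n_zplanes: int = 8
    z_spacing_um: float = 0.35
    frame_interval_s: float = 60.0
    session_duration_s: float = 14400.0
    photon_budget: float = 1000.0
    read_noise_sd: float = 2.0
    bleach_rate_per_s: float = 0.0
    cue_contrast: float = 0.35
    cue_lead_time_s: float = 600.0
    onset_duration_s: float = 300.0
    shot_noise: bool = True
    fsr_GHz: float = 15.0
    n_spectral_bins: int = 512
    instr_linewidth_GHz: float = 0.270
    brillouin_dwell_s: float = 0.100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size_px <= 0:
            raise ValueError("image_size_px must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if not (0.0 <= self.cue_contrast <= 1.0):
            raise ValueError("cue_contrast must lie in [0, 1]")
        for name in ("frame_interval_s", "session_duration_s", "cue_lead_time_s",
                     "onset_duration_s", "brillouin_dwell_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bleach_rate_per_s < 0:
            raise ValueError("bleach_rate_per_s must be >= 0")
        if self.n_zplanes < 1:
            raise ValueError("n_zplanes must be >= 1")

    @property
    def fov_um(self) -> float:
        return self.image_size_px * self.pixel_size_um

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def config_hash(obj) -> str:
    """sha256 of the canonical JSON encoding (key-order independent)."""
    blob = json.dumps(obj, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:16]


def benchmark_config(**overrides) -> SimConfig:
    """128 px preset keeping the default ~39 µm field of view.

    Sized so that dataset generation plus classifier training stays within
    a few minutes on one CPU.
    """
    kw = dict(
        image_size_px=128,
        pixel_size_um=0.111 * 352 / 128,
        photon_budget=2000.0,
        read_noise_sd=2.0,
        cue_contrast=0.6,
    )
    kw.update(overrides)
    return SimConfig(**kw)


@dataclass(frozen=True)
class BrillouinTruth:
    """Per-cell ground-truth shift/linewidth values (GHz)."""

    shift_peri_GHz: float = 6.39
    shift_agg_GHz: float = 6.51
    lw_peri_GHz: float = 0.54
    lw_agg_GHz: float = 0.58
    background_shift_GHz: float = 5.00
    background_lw_GHz: float = 0.35

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be > 0")


@dataclass(frozen=True)
class Cell:
    cell_id: int
    fov_index: int
    centroid_offset_um: tuple[float, float]  # (dy, dx) from FOV centre
    radius_um: float
    fate: Fate
    onset_time_s: float  # nan for NON_EVENT
    agg_offset_um: tuple[float, float]  # aggregate site, relative to centroid
    agg_radius_um: float
    punctum_sigma_um: float
    growth_tau_s: float
    brillouin: BrillouinTruth
    # pseudo onset used to draw matched observation times for non-events
    matched_time_s: float = float("nan")


@dataclass(frozen=True)
class GridLayout:
    n_rows: int
    n_cols: int
    n_events: Optional[int] = None
    event_fraction: Optional[float] = None

    def resolve_n_events(self) -> int:
        n = self.n_rows * self.n_cols
        if self.n_events is not None:
            if not (0 <= self.n_events <= n):
                raise ValueError("n_events out of range")
            return self.n_events
        if self.event_fraction is None:
            raise ValueError("give n_events or event_fraction")
        if not (0.0 <= self.event_fraction <= 1.0):
            raise ValueError("event_fraction must lie in [0, 1]")
        return int(round(self.event_fraction * n))


@dataclass(frozen=True)
class VirtualSample:
    """Ground-truth world state: cell layout, fates, Brillouin fields."""

    config: SimConfig
    layout: GridLayout
    stage_grid: tuple[tuple[float, float], ...]  # (y_um, x_um) per FOV
    cells: tuple[Cell, ...]
    seed: int

    @property
    def n_fovs(self) -> int:
        return len(self.stage_grid)

    def cells_at(self, fov_index: int) -> list[Cell]:
        return [c for c in self.cells if c.fov_index == fov_index]

    @property
    def hash(self) -> str:
        return config_hash({"config": self.config.to_dict(),
                            "layout": dataclasses.asdict(self.layout),
                            "seed": self.seed})


@dataclass
class ImageStack:
    data: np.ndarray  # (T, Z, H, W) nonnegative intensities
    timestamps_s: np.ndarray  # (T,), strictly increasing
    modality: Modality
    position: int  # FOV index
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("ImageStack data must be (T, Z, H, W)")
        if np.any(self.data < 0):
            raise ValueError("intensities must be >= 0")
        if len(self.timestamps_s) != self.data.shape[0]:
            raise ValueError("timestamps length must match T")
        if len(self.timestamps_s) > 1 and np.any(np.diff(self.timestamps_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class Spectrum:
    freq_axis_GHz: np.ndarray
    counts: np.ndarray
    dwell_s: float = 0.100
    pixel_index: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.freq_axis_GHz = np.asarray(self.freq_axis_GHz, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.freq_axis_GHz.shape != self.counts.shape:
            raise ValueError("axis and counts must have the same length")
        if np.any(np.diff(self.freq_axis_GHz) <= 0):
            raise ValueError("frequency axis must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")


@dataclass
class GroundTruthMaps:
    shift_GHz: np.ndarray
    linewidth_GHz: np.ndarray
    aggregate_mask: np.ndarray
    cell_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.aggregate_mask & ~self.cell_mask):
            raise ValueError("aggregate_mask must be a subset of cell_mask")


@dataclass
class LabeledExample:
    """A (T, Z, H, W) tensor with a binary onset label."""

    tensor: np.ndarray
    label: int
    cell_id: int
    time_to_onset_s: float = float("nan")  # t0 - observation time (EVENT only)

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=np.float32)
        if self.tensor.ndim != 4:
            raise ValueError("tensor must be (T, Z, H, W)")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if not np.all(np.isfinite(self.tensor)):
            raise ValueError("tensor must be finite")


# ---------------------------------------------------------------------------
# sample construction


def make_sample(config: SimConfig, layout: GridLayout, seed: int) -> VirtualSample:
    """Build a virtual sample with exact event/non-event counts.

    Onset times are drawn uniformly over the usable session window
    ``[cue_lead_time, session_duration]`` so every EVENT cell carries a full
    pre-onset cue window.
    """
    if layout.n_rows < 1 or layout.n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    n_cells = layout.n_rows * layout.n_cols
    n_events = layout.resolve_n_events()
    rng = substream(seed, "sample")

    fates = [Fate.EVENT] * n_events + [Fate.NON_EVENT] * (n_cells - n_events)
    fates = [fates[i] for i in rng.permutation(n_cells)]

    fov = config.fov_um
    pitch = fov
    grid = tuple(
        (r * pitch, c * pitch) for r in range(layout.n_rows) for c in range(layout.n_cols)
    )

    t_lo = config.cue_lead_time_s
    t_hi = max(t_lo + 1.0, config.session_duration_s)
    cells = []
    for i in range(n_cells):
        cy, cx = rng.uniform(-0.05, 0.05, size=2) * fov
        radius = rng.uniform(0.30, 0.38) * fov
        theta = rng.uniform(0.0, 2.0 * math.pi)
        rho = rng.uniform(0.0, 0.4) * radius
        agg_dy, agg_dx = rho * math.sin(theta), rho * math.cos(theta)
        agg_radius = rng.uniform(1.8, 2.4)
        t0 = rng.uniform(t_lo, t_hi)
        matched = rng.uniform(t_lo, t_hi)
        cells.append(
            Cell(
                cell_id=i,
                fov_index=i % n_cells,
                centroid_offset_um=(float(cy), float(cx)),
                radius_um=float(radius),
                fate=Fate(fates[i]),
                onset_time_s=float(t0) if fates[i] == Fate.EVENT else float("nan"),
                agg_offset_um=(float(agg_dy), float(agg_dx)),
                agg_radius_um=float(agg_radius),
                punctum_sigma_um=float(agg_radius / 1.7),
                growth_tau_s=float(rng.uniform(0.5, 1.0) * config.onset_duration_s),
                brillouin=BrillouinTruth(),
                matched_time_s=float(matched),
            )
        )
    # one cell per FOV: fov_index == cell index
    return VirtualSample(config=config, layout=layout, stage_grid=grid,
                         cells=tuple(cells), seed=seed)


# ---------------------------------------------------------------------------
# fluorescence rendering


def _pixel_grids(config: SimConfig):
    h = config.image_size_px
    coords = (np.arange(h) - (h - 1) / 2.0) * config.pixel_size_um
    return np.meshgrid(coords, coords, indexing="ij")  # (Y, X) in µm


def _condensed_fraction(cell: Cell, config: SimConfig, t: float) -> tuple[float, float]:
    """Return (punctum mass fraction, cue ramp in [0,1]) at clock time t."""
    if cell.fate is not Fate.EVENT:
        return 0.0, 0.0
    t0 = cell.onset_time_s
    lead = config.cue_lead_time_s
    if t < t0 - lead:
        return 0.0, 0.0
    if t < t0:
        ramp = (t - (t0 - lead)) / lead if lead > 0 else 1.0
        return _F_CUE_MAX * config.cue_contrast * ramp, ramp
    dur = config.onset_duration_s
    prog = 1.0 if dur == 0 else min(1.0, (t - t0) / dur)
    f_start = _F_CUE_MAX * config.cue_contrast
    return f_start + (_F_FINAL - f_start) * prog, 0.0


def _onset_progress(cell: Cell, config: SimConfig, t: float) -> float:
    """0 before onset, ramping to 1 at t0 + onset_duration."""
    if cell.fate is not Fate.EVENT or t < cell.onset_time_s:
        return 0.0
    dur = config.onset_duration_s
    if dur == 0:
        return 1.0
    return min(1.0, (t - cell.onset_time_s) / dur)


def _cell_profiles(cell: Cell, config: SimConfig, sample_seed: int):
    """Unit-sum body and punctum profiles plus a zero-sum cue texture."""
    yy, xx = _pixel_grids(config)
    cy, cx = cell.centroid_offset_um
    r = np.hypot(yy - cy, xx - cx)
    body = np.exp(-((r / cell.radius_um) ** 8))
    body /= body.sum()

    ay, ax = cy + cell.agg_offset_um[0], cx + cell.agg_offset_um[1]
    d2 = (yy - ay) ** 2 + (xx - ax) ** 2
    sig = cell.punctum_sigma_um
    punctum = np.exp(-d2 / (2.0 * sig * sig))
    punctum /= punctum.sum()

    rng = substream(sample_seed, "texture", cell.cell_id)
    speckle = gaussian_filter(rng.standard_normal(body.shape), 2.0)
    window = np.exp(-d2 / (2.0 * (2.0 * sig) ** 2))
    tex = speckle * window
    wsum = window.sum()
    if wsum > 0:
        tex = tex - (tex.sum() / wsum) * window  # exact zero-sum
    peak = np.abs(tex).max()
    if peak > 0:
        tex = tex / peak
    return body, punctum, tex


def _defocus_sigma_px(z_offset_um: float, config: SimConfig) -> float:
    return 0.6 * abs(z_offset_um) / config.pixel_size_um


def _zplane_offsets(config: SimConfig, n_planes: Optional[int] = None) -> np.ndarray:
    z = n_planes or config.n_zplanes
    return (np.arange(z) - (z - 1) / 2.0) * config.z_spacing_um


def render_fluorescence(
    sample: VirtualSample,
    position: int,
    time_s: float,
    config: Optional[SimConfig] = None,
    n_planes: Optional[int] = None,
    noise: Optional[bool] = None,
) -> ImageStack:
    """Render one fluorescence timepoint (all z planes) at a FOV.

    ``noise=False`` disables both shot and read noise regardless of config;
    with noise and bleaching disabled the per-cell total fluorescence is
    time-invariant through aggregation.
    """
    config = config or sample.config
    if not (0 <= position < sample.n_fovs):
        raise ValueError(f"invalid FOV index {position}")
    if time_s < 0:
        raise ValueError("time must be >= 0")
    use_noise = config.shot_noise if noise is None else noise

    h = config.image_size_px
    ideal = np.zeros((h, h), dtype=np.float64)
    for cell in sample.cells_at(position):
        body, punctum, tex = _cell_profiles(cell, config, sample.seed)
        f, cue_ramp = _condensed_fraction(cell, config, time_s)
        total = config.photon_budget / body.max()  # peak photons at t=0
        bleach = math.exp(-config.bleach_rate_per_s * time_s)
        img = total * bleach * ((1.0 - f) * body + f * punctum)
        amp = _TEXTURE_GAIN * config.cue_contrast * cue_ramp
        if amp > 0:
            img = img + amp * total * bleach * body.max() * tex
        ideal += img

    offsets = _zplane_offsets(config, n_planes)
    planes = np.empty((len(offsets), h, h), dtype=np.float64)
    for k, dz in enumerate(offsets):
        s = _defocus_sigma_px(dz, config)
        planes[k] = gaussian_filter(ideal, s, mode="constant") if s > 0 else ideal

    if use_noise:
        rng = substream(sample.seed, "fluor", position, round(time_s * 1e3))
        planes = rng.poisson(np.clip(planes, 0, None)).astype(np.float64)
        if config.read_noise_sd > 0:
            planes = planes + rng.normal(0.0, config.read_noise_sd, planes.shape)
    planes = np.clip(planes, 0, None)

    return ImageStack(
        data=planes[None, ...],
        timestamps_s=np.array([time_s]),
        modality=Modality.FLUOR,
        position=position,
        settings={"config_hash": config.hash},
    )


def render_brightfield(
    sample: VirtualSample,
    position: int,
    time_s: float,
    config: Optional[SimConfig] = None,
    noise: Optional[bool] = None,
    background_level: float = 1000.0,
) -> ImageStack:
    """Render a single-plane brightfield image.

    Cells appear as low-contrast ring/halo objects on a bright background;
    mature aggregates add a localized high-contrast punctum with a faint
    diffraction ring.
    """
    config = config or sample.config
    if not (0 <= position < sample.n_fovs):
        raise ValueError(f"invalid FOV index {position}")
    use_noise = config.shot_noise if noise is None else noise

    yy, xx = _pixel_grids(config)
    trans = np.ones_like(yy)
    for cell in sample.cells_at(position):
        cy, cx = cell.centroid_offset_um
        r = np.hypot(yy - cy, xx - cx)
        ring = np.exp(-(((r - cell.radius_um) / (0.08 * cell.radius_um)) ** 2))
        interior = r < cell.radius_um
        trans = trans * (1.0 - 0.04 * ring)
        trans = np.where(interior, trans * 0.99, trans)
        prog = _onset_progress(cell, config, time_s)
        if prog > 0:
            ay = cy + cell.agg_offset_um[0]
            ax = cx + cell.agg_offset_um[1]
            d = np.hypot(yy - ay, xx - ax)
            sig = 0.8 * cell.punctum_sigma_um
            core = np.exp(-(d * d) / (2.0 * sig * sig))
            halo = np.exp(-(((d - 2.5 * sig) / (0.7 * sig)) ** 2))
            trans = trans * (1.0 - 0.35 * prog * core) * (1.0 + 0.08 * prog * halo)

    img = background_level * trans
    img = gaussian_filter(img, 1.0, mode="nearest")
    if use_noise:
        rng = substream(sample.seed, "bf", position, round(time_s * 1e3))
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        if config.read_noise_sd > 0:
            img = img + rng.normal(0.0, config.read_noise_sd, img.shape)
    img = np.clip(img, 0, None)

    return ImageStack(
        data=img[None, None, ...],
        timestamps_s=np.array([time_s]),
        modality=Modality.BRIGHTFIELD,
        position=position,
        settings={"config_hash": config.hash},
    )


# ---------------------------------------------------------------------------
# Brillouin ground truth and spectra


def _point_truth(sample: VirtualSample, position: int, dy_um: float, dx_um: float,
                 time_s: float) -> tuple[float, float, bool, bool]:
    """(shift, linewidth, in_cell, in_aggregate) at a µm offset from FOV centre.

    During onset the aggregate-region values interpolate linearly in time
    from periphery to mature-aggregate truth.
    """
    for cell in sample.cells_at(position):
        cy, cx = cell.centroid_offset_um
        dc = math.hypot(dy_um - cy, dx_um - cx)
        if dc > cell.radius_um:
            continue
        bt = cell.brillouin
        ay, ax = cy + cell.agg_offset_um[0], cx + cell.agg_offset_um[1]
        da = math.hypot(dy_um - ay, dx_um - ax)
        prog = _onset_progress(cell, sample.config, time_s)
        if prog > 0 and da <= cell.agg_radius_um:
            shift = bt.shift_peri_GHz + prog * (bt.shift_agg_GHz - bt.shift_peri_GHz)
            lw = bt.lw_peri_GHz + prog * (bt.lw_agg_GHz - bt.lw_peri_GHz)
            return shift, lw, True, True
        return bt.shift_peri_GHz, bt.lw_peri_GHz, True, False
    bt = sample.cells[0].brillouin if sample.cells else BrillouinTruth()
    return bt.background_shift_GHz, bt.background_lw_GHz, False, False


def _lorentzian(x: np.ndarray, x0: float, fwhm: float) -> np.ndarray:
    g = 0.5 * fwhm
    return g * g / ((x - x0) ** 2 + g * g)


def spectral_axis(config: SimConfig) -> np.ndarray:
    return np.linspace(0.0, config.fsr_GHz, config.n_spectral_bins)


def synth_spectrum(
    shift_GHz: float,
    linewidth_GHz: float,
    config: SimConfig,
    dwell_s: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    pixel_index: tuple[int, int] = (0, 0),
) -> Spectrum:
    """Build a spectrum from truth values; ``rng=None`` means noiseless.

    Counts = baseline + Rayleigh Lorentzians pinned at the axis ends + two
    Brillouin Lorentzians (anti-Stokes at ``shift``, Stokes at
    ``FSR - shift``); the measured width is the true width broadened by the
    instrumental Lorentzian (widths add exactly).  Expected amplitude scales
    linearly with dwell.
    """
    dwell = config.brillouin_dwell_s if dwell_s is None else dwell_s
    x = spectral_axis(config)
    gamma_meas = linewidth_GHz + config.instr_linewidth_GHz
    amp = _BRI_PEAK_RATE * dwell
    base = _BRI_BASELINE_RATE * dwell
    counts = (
        base
        + amp * (_lorentzian(x, shift_GHz, gamma_meas)
                 + _lorentzian(x, config.fsr_GHz - shift_GHz, gamma_meas))
        + _RAYLEIGH_GAIN * amp * (_lorentzian(x, 0.0, config.instr_linewidth_GHz)
                                  + _lorentzian(x, config.fsr_GHz,
                                                config.instr_linewidth_GHz))
    )
    if rng is not None:
        counts = rng.poisson(counts).astype(np.float64)
    return Spectrum(freq_axis_GHz=x, counts=counts, dwell_s=dwell,
                    pixel_index=pixel_index)


def render_brillouin_spectrum(
    sample: VirtualSample,
    position: int,
    pixel: tuple[int, int],
    time_s: float,
    config: Optional[SimConfig] = None,
    dwell_s: Optional[float] = None,
    noise: Optional[bool] = None,
) -> Spectrum:
    """Render the Brillouin spectrum of one camera pixel of a FOV."""
    config = config or sample.config
    h = config.image_size_px
    row, col = pixel
    if not (0 <= row < h and 0 <= col < h):
        raise ValueError("pixel outside FOV")
    dy = (row - (h - 1) / 2.0) * config.pixel_size_um
    dx = (col - (h - 1) / 2.0) * config.pixel_size_um
    shift, lw, _, _ = _point_truth(sample, position, dy, dx, time_s)
    use_noise = config.shot_noise if noise is None else noise
    rng = None
    if use_noise:
        rng = substream(sample.seed, "brillouin", position, pixel, round(time_s * 1e3))
    return synth_spectrum(shift, lw, config, dwell_s=dwell_s, rng=rng,
                          pixel_index=pixel)


def map_grid_points(fov_um: float, step_um: float) -> np.ndarray:
    """Inclusive-endpoint scan offsets (µm, centred) for a fov/step pair."""
    if step_um <= 0:
        raise ValueError("step_um must be > 0")
    n = int(math.floor(fov_um / step_um + 1e-9)) + 1
    return (np.arange(n) - (n - 1) / 2.0) * step_um


def true_brillouin_maps(
    sample: VirtualSample,
    position: int,
    time_s: float,
    step_um: float,
    fov_um: Optional[float] = None,
) -> GroundTruthMaps:
    """Ground-truth shift/linewidth maps sampled on the scan grid."""
    fov = sample.config.fov_um if fov_um is None else fov_um
    offs = map_grid_points(fov, step_um)
    n = len(offs)
    shift = np.empty((n, n))
    lw = np.empty((n, n))
    agg = np.zeros((n, n), dtype=bool)
    cellm = np.zeros((n, n), dtype=bool)
    for i, dy in enumerate(offs):
        for j, dx in enumerate(offs):
            s, g, in_cell, in_agg = _point_truth(sample, position, dy, dx, time_s)
            shift[i, j], lw[i, j] = s, g
            cellm[i, j], agg[i, j] = in_cell, in_agg
    return GroundTruthMaps(shift_GHz=shift, linewidth_GHz=lw,
                           aggregate_mask=agg, cell_mask=cellm)


def render_brillouin_map(
    sample: VirtualSample,
    position: int,
    time_s: float,
    step_um: float,
    fov_um: Optional[float] = None,
    dwell_s: Optional[float] = None,
    noise: Optional[bool] = None,
) -> list[list[Spectrum]]:
    """Point-scan a FOV: grid of per-pixel spectra (row-major)."""
    config = sample.config
    fov = config.fov_um if fov_um is None else fov_um
    offs = map_grid_points(fov, step_um)
    use_noise = config.shot_noise if noise is None else noise
    out: list[list[Spectrum]] = []
    for i, dy in enumerate(offs):
        row: list[Spectrum] = []
        for j, dx in enumerate(offs):
            s, g, _, _ = _point_truth(sample, position, dy, dx, time_s)
            rng = None
            if use_noise:
                rng = substream(sample.seed, "brimap", position, (i, j),
                                round(time_s * 1e3))
            row.append(synth_spectrum(s, g, config, dwell_s=dwell_s, rng=rng,
                                      pixel_index=(i, j)))
        out.append(row)
    return out


# ---------------------------------------------------------------------------
# labeled datasets


def _observation_time(cell: Cell, config: SimConfig, rng: np.random.Generator,
                      T: int) -> float:
    """Pick the last-frame time of a T-frame observation.

    EVENT cells are sampled strictly inside the pre-onset cue window;
    non-events use their matched pseudo-onset so both classes share the
    same time distribution.
    """
    anchor = cell.onset_time_s if cell.fate is Fate.EVENT else cell.matched_time_s
    lead = config.cue_lead_time_s
    lo, hi = anchor - 0.8 * lead, anchor - 0.05 * lead
    t = float(rng.uniform(lo, hi))
    return max(t, (T - 1) * config.frame_interval_s)


def simulate_onset_dataset(
    config: SimConfig,
    n_events: int = 71,
    n_nonevents: int = 68,
    T: int = 1,
    Z: int = 8,
    seed: int = 0,
) -> tuple[list[LabeledExample], dict]:
    """Generate the labeled onset benchmark (default composition 71/68).

    EVENT examples (label 1, "will aggregate") are drawn inside the
    pre-onset cue window; NON_EVENT examples come from matched times in
    non-aggregating cells.  Returns (examples, manifest).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if not (1 <= Z <= config.n_zplanes):
        raise ValueError(f"Z must lie in 1..{config.n_zplanes}")
    n = n_events + n_nonevents
    layout = GridLayout(n_rows=1, n_cols=n, n_events=n_events)
    sample = make_sample(config, layout, seed)
    rng = substream(seed, "dataset")

    examples: list[LabeledExample] = []
    entries = []
    for cell in sample.cells:
        t_last = _observation_time(cell, config, rng, T)
        times = [t_last - (T - 1 - k) * config.frame_interval_s for k in range(T)]
        frames = []
        for t in times:
            stack = render_fluorescence(sample, cell.fov_index, t, config,
                                        n_planes=Z)
            frames.append(stack.data[0])
        tensor = np.stack(frames, axis=0)  # (T, Z, H, W)
        label = 1 if cell.fate is Fate.EVENT else 0
        tto = cell.onset_time_s - t_last if label == 1 else float("nan")
        examples.append(LabeledExample(tensor=tensor, label=label,
                                       cell_id=cell.cell_id, time_to_onset_s=tto))
        entries.append({
            "id": cell.cell_id,
            "label": label,
            "T": T,
            "Z": Z,
            "t0_offset_s": None if label == 0 else round(tto, 6),
        })
    manifest = {
        "seed": seed,
        "config_hash": config.hash,
        "sample_hash": sample.hash,
        "n_events": n_events,
        "n_nonevents": n_nonevents,
        "T": T,
        "Z": Z,
        "modality": "FLUOR",
        "entries": entries,
    }
    return examples, manifest


def simulate_brightfield_dataset(
    config: SimConfig,
    n_positive: int = 100,
    n_negative: int = 100,
    seed: int = 0,
) -> tuple[list[LabeledExample], dict]:
    """Balanced brightfield dataset: mature aggregate present vs. absent.

    Positives are EVENT cells imaged after the transition has completed;
    negatives are non-aggregating cells at matched times (label 0).
    """
    n = n_positive + n_negative
    layout = GridLayout(n_rows=1, n_cols=n, n_events=n_positive)
    sample = make_sample(config, layout, seed)
    rng = substream(seed, "bf-dataset")

    examples: list[LabeledExample] = []
    entries = []
    for cell in sample.cells:
        if cell.fate is Fate.EVENT:
            t = cell.onset_time_s + config.onset_duration_s + float(
                rng.uniform(60.0, 600.0))
            label = 1
        else:
            t = cell.matched_time_s + config.onset_duration_s + float(
                rng.uniform(60.0, 600.0))
            label = 0
        stack = render_brightfield(sample, cell.fov_index, t, config)
        examples.append(LabeledExample(tensor=stack.data, label=label,
                                       cell_id=cell.cell_id))
        entries.append({"id": cell.cell_id, "label": label, "T": 1, "Z": 1,
                        "t0_offset_s": None})
    manifest = {
        "seed": seed,
        "config_hash": config.hash,
        "sample_hash": sample.hash,
        "n_events": n_positive,
        "n_nonevents": n_negative,
        "T": 1,
        "Z": 1,
        "modality": "BRIGHTFIELD",
        "entries": entries,
    }
    return examples, manifest
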