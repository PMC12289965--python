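"""Reference benchmark runs: dataset generation -> training -> evaluation.

These drive the headline checks: onset classification from a single
multi-plane (or single-plane) fluorescence timepoint, brightfield
aggregate detection, and the full Brillouin recovery chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import brillouin_analysis as ba
from .classifiers import (
    ArchSpec,
    ArchVariant,
    ConfusionMatrix,
    Metrics,
    TrainConfig,
    evaluate,
    split_dataset,
    train_classifier,
)
from .synthetic_scope import (
    GridLayout,
    SimConfig,
    benchmark_config,
    make_sample,
    render_brillouin_map,
    render_fluorescence,
    simulate_brightfield_dataset,
    simulate_onset_dataset,
    true_brillouin_maps,
)


@dataclass
class BenchmarkResult:
    confusion: ConfusionMatrix
    metrics: Metrics
    n_test: int
    epochs: int


def onset_benchmark(Z: int = 8, seed: int = 0, n_events: int = 71,
                    n_nonevents: int = 68,
                    config: SimConfig | None = None) -> BenchmarkResult:
    """Train the single-frame conv variant on the onset benchmark."""
    cfg = config or benchmark_config()
    examples, _ = simulate_onset_dataset(cfg, n_events, n_nonevents, T=1, Z=Z,
                                         seed=seed)
    tcfg = TrainConfig(seed=seed)
    train, val, test = split_dataset(examples, tcfg.test_fraction,
                                     tcfg.val_fraction, seed)
    arch = ArchSpec(ArchVariant.SINGLE_FRAME_CONV,
                    (1, Z, cfg.image_size_px, cfg.image_size_px))
    model = train_classifier(train, val, arch, tcfg)
    cm, metrics = evaluate(model, test)
    return BenchmarkResult(confusion=cm, metrics=metrics, n_test=len(test),
                           epochs=model.history.get("epochs", 0))


def brightfield_benchmark(seed: int = 0, n_positive: int = 100,
                          n_negative: int = 100,
                          config: SimConfig | None = None) -> BenchmarkResult:
    """Train the brightfield aggregate-presence classifier."""
    cfg = config or benchmark_config()
    examples, _ = simulate_brightfield_dataset(cfg, n_positive, n_negative,
                                               seed=seed)
    tcfg = TrainConfig(seed=seed)
    train, val, test = split_dataset(examples, tcfg.test_fraction,
                                     tcfg.val_fraction, seed)
    arch = ArchSpec(ArchVariant.SINGLE_FRAME_CONV,
                    (1, 1, cfg.image_size_px, cfg.image_size_px))
    model = train_classifier(train, val, arch, tcfg)
    cm, metrics = evaluate(model, test)
    return BenchmarkResult(confusion=cm, metrics=metrics, n_test=len(test),
                           epochs=model.history.get("epochs", 0))


def brillouin_recovery(seed: int = 7, step_um: float = 1.0,
                       fov_um: float = 35.0, n_timepoints: int = 4):
    """Full spectra -> fit -> deconvolve -> segment -> stats chain.

    One EVENT cell imaged through its aggregation transition; returns
    (RegionStats, final RegionTimepointStats, ground truth values).
    """
    cfg = SimConfig()
    sample = make_sample(cfg, GridLayout(1, 1, n_events=1), seed=seed)
    cell = sample.cells[0]
    t0 = cell.onset_time_s
    fracs = np.linspace(0.25, 2.0, n_timepoints)
    maps, masks = [], []
    for frac in fracs:
        t = t0 + float(frac) * cfg.onset_duration_s
        spectra = render_brillouin_map(sample, 0, t, step_um=step_um,
                                       fov_um=fov_um)
        bmap = ba.build_map(spectra, cfg.fsr_GHz, step_um=step_um,
                            timestamp_s=t)
        fluor = render_fluorescence(sample, 0, t).data[0, cfg.n_zplanes // 2]
        masks.append(ba.segment_regions(fluor, bmap, fluor_fov_um=cfg.fov_um,
                                        map_fov_um=fov_um))
        maps.append(bmap)
    stats = ba.region_stats(maps, masks)
    return stats, stats.timepoints[-1], cell.brillouin
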