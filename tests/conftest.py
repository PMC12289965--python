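import dataclasses

import numpy as np
import pytest

from sdmscope.synthetic_scope import (
    BrillouinTruth,
    Cell,
    Fate,
    GridLayout,
    SimConfig,
    VirtualSample,
    benchmark_config,
)


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """32 px preset for fast unit tests (same 39 µm FOV)."""
    return benchmark_config(image_size_px=32, pixel_size_um=0.111 * 352 / 32)


@pytest.fixture(scope="session")
def bench_config() -> SimConfig:
    return benchmark_config()


def make_cell(cell_id=0, fov_index=0, fate=Fate.EVENT, onset_time_s=1000.0,
              centroid=(0.0, 0.0), radius_um=13.0, agg_offset=(2.0, 1.0),
              agg_radius_um=2.0, truth=None, matched_time_s=1000.0) -> Cell:
    return Cell(
        cell_id=cell_id,
        fov_index=fov_index,
        centroid_offset_um=centroid,
        radius_um=radius_um,
        fate=fate,
        onset_time_s=onset_time_s if fate is Fate.EVENT else float("nan"),
        agg_offset_um=agg_offset,
        agg_radius_um=agg_radius_um,
        punctum_sigma_um=agg_radius_um / 1.7,
        growth_tau_s=200.0,
        brillouin=truth or BrillouinTruth(),
        matched_time_s=matched_time_s,
    )


def make_manual_sample(config: SimConfig, cells, n_fovs=None,
                       seed=0) -> VirtualSample:
    """Hand-built sample with explicit cells (for oracle/engine tests)."""
    n = n_fovs or (max((c.fov_index for c in cells), default=0) + 1)
    rows = 1
    grid = tuple((0.0, i * config.fov_um) for i in range(n))
    layout = GridLayout(n_rows=rows, n_cols=n, n_events=sum(
        1 for c in cells if c.fate is Fate.EVENT))
    return VirtualSample(config=config, layout=layout, stage_grid=grid,
                         cells=tuple(cells), seed=seed)
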