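"""Shared fixtures: heavy pipeline products are computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from uncrowding import cortical_dynamics as cd
from uncrowding import decision as dec
from uncrowding import grouping_segmentation as gseg
from uncrowding import stimuli as stim


@pytest.fixture(scope="session")
def config() -> stim.DisplayConfig:
    return stim.DisplayConfig()


@pytest.fixture(scope="session")
def clock() -> cd.SimulationClock:
    return cd.SimulationClock()


@pytest.fixture(scope="session")
def pipeline_products(config, clock):
    """Per-condition graph, selection, segmentation state (right offset)."""
    out = {}
    for cond in stim.CONDITIONS:
        spec = stim.make_condition_spec(cond)
        img = stim.render(spec, config)
        field = cd.evolve(cd.oriented_response(img), clock)
        acc = cd.accumulate(field, clock.offset_ms)
        graph = gseg.build_graph(acc, config)
        signal = gseg.place_selection(spec)
        state = gseg.spread(graph, signal, clock)
        out[cond] = {
            "spec": spec,
            "img": img,
            "field": field,
            "graph": graph,
            "signal": signal,
            "state": state,
        }
    return out


@pytest.fixture(scope="session")
def battery():
    """Evidence table for all 8 conditions, right offset, defaults."""
    with np.errstate(all="ignore"):
        df = dec.run_battery()
    return dict(zip(df["condition"], df["evidence"]))


def make_bar_image(
    bars: list[tuple[float, float, float]],
    config: stim.DisplayConfig,
    width_deg: float = 0.06,
) -> stim.LuminanceImage:
    """Synthetic display of vertical bars: (x_deg, y_center_deg, height_deg)."""
    grid = np.full((config.n_rows, config.n_cols), config.background_luminance)
    ppd = config.pixels_per_degree
    for x, yc, h in bars:
        c = config.center_col + int(np.trunc(x * ppd))
        r0 = config.center_row + int(np.floor((yc - h / 2) * ppd + 0.5))
        r1 = config.center_row + int(np.floor((yc + h / 2) * ppd + 0.5))
        w = max(1, int(round(width_deg * ppd)))
        grid[r0:r1, c : c + w] = config.element_luminance
    return stim.LuminanceImage(
        grid=grid,
        origin_deg=(-config.center_col / ppd, -config.center_row / ppd),
        pixels_per_degree=ppd,
        background_luminance=config.background_luminance,
    )
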