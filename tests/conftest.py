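"""Shared fixtures: synthetic study conditions used across the suite.

Everything is generated programmatically at test time; expensive renders
(40 s blocks at 20 kHz) are session-scoped so detection/sorting tests and
the acceptance suite share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from hdmea.detect import detect_block
from hdmea.layout import BlockConfiguration, RegionOfInterest, build_layout, tile_blocks
from hdmea.merge import GlobalFootprint
from hdmea.simulate import (
    GroundTruthUnit,
    SessionPlan,
    simulate_session,
    spike_shape,
    unit_footprint,
)
from hdmea.sort import BlockFootprint, sort_block


def make_block_footprint(
    unit: GroundTruthUnit,
    layout,
    block: BlockConfiguration,
    label: int = 0,
    template_noise: float = 0.0,
    rng: np.random.Generator | None = None,
    n_spikes: int = 80,
    sample_rate: float = 20_000.0,
) -> BlockFootprint:
    """Ground-truth block footprint (noise-free template + optional noise)."""
    rng = rng or np.random.default_rng(0)
    ids = tuple(block.electrode_ids)
    tpl = unit_footprint(unit, layout, ids, sample_rate)
    if template_noise > 0:
        tpl = tpl + rng.normal(0, template_noise, tpl.shape)
    _, trough = spike_shape(sample_rate, unit.trough_width_ms, unit.overshoot_ratio)
    pos = layout.position(np.asarray(ids))
    core = int(np.asarray(ids)[int(np.argmin(np.hypot(pos[:, 0] - unit.x, pos[:, 1] - unit.y)))])
    return BlockFootprint(
        label=label,
        block_index=block.block_index,
        electrode_ids=ids,
        template=tpl,
        spike_samples=np.arange(n_spikes),
        core_electrode=core,
        sample_rate=sample_rate,
        pre_samples=trough,
    )


def as_global(fp: BlockFootprint, unit_id: int = 0, day: int | None = None) -> GlobalFootprint:
    return GlobalFootprint(unit_id, fp.electrode_ids, fp.template, [fp], day)


@pytest.fixture(scope="session")
def block_layout():
    """One full 18x6 block configuration on its own layout."""
    lay = build_layout(18, 6)
    blocks = tile_blocks(lay, RegionOfInterest.full(lay))
    assert len(blocks) == 1
    return lay, blocks[0]


@pytest.fixture(scope="session")
def three_units():
    """Three spatially overlapping units (pairwise footprint MC < 0.7) at
    SNR >= 10 against the 6 μV noise floor."""
    return [
        GroundTruthUnit(0, x=36, y=126, peak_amplitude=60, spatial_sigma=22, trough_width_ms=0.25),
        GroundTruthUnit(1, x=63, y=144, peak_amplitude=75, spatial_sigma=28, trough_width_ms=0.35, overshoot_ratio=0.45),
        GroundTruthUnit(2, x=54, y=108, peak_amplitude=90, spatial_sigma=18, trough_width_ms=0.30, overshoot_ratio=0.2),
    ]


@pytest.fixture(scope="session")
def three_unit_sort(block_layout, three_units):
    """40 s rendered block with three overlapping units, filtered, detected,
    and sorted once for the whole suite."""
    lay, block = block_layout
    ids = list(block.electrode_ids)
    ses = simulate_session(lay, [block], three_units, SessionPlan(duration_s=40, noise_sigma=6.0), seed=7)
    rec = ses.blocks[0]
    events, sds, filtered = detect_block(rec.traces, ids, rec.sample_rate)
    footprints = sort_block(filtered, ids, rec.sample_rate, seed=2, noise_sd_by_electrode=sds)
    return {
        "layout": lay,
        "block": block,
        "units": three_units,
        "session": ses,
        "events": events,
        "noise_sd": sds,
        "filtered": filtered,
        "footprints": footprints,
    }


@pytest.fixture(scope="session")
def tracking_cohort():
    """10 large stable units in 5 rectangular blocks for day-tracking tests."""
    lay = build_layout(18, 30)
    blocks = [
        BlockConfiguration(
            b, tuple(lay.electrode_at(r, c) for c in range(6 * b, 6 * b + 6) for r in range(18))
        )
        for b in range(5)
    ]
    rng = np.random.default_rng(42)
    units = []
    uid = 0
    for b in range(5):
        for dx, y in ((36, 70), (72, 240)):
            units.append(
                GroundTruthUnit(
                    uid,
                    x=6 * b * 18 + dx + rng.uniform(-5, 5),
                    y=y + rng.uniform(-5, 5),
                    peak_amplitude=float(rng.uniform(150, 300)),
                    spatial_sigma=float(rng.uniform(22, 28)),
                )
            )
            uid += 1
    return lay, blocks, units
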