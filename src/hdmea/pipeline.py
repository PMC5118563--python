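"""End-to-end orchestration: detect -> sort per block -> merge -> track.

A single :class:`PipelineConfig` carries every stage's parameters plus the
seed; it round-trips losslessly through YAML and hashes canonically, so any
output can be traced back to the exact configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .detect import ActivityMap, DetectionParams, activity_map, detect_block
from .layout import ElectrodeLayout, build_layout
from .merge import GlobalFootprint, MergeParams, merge_block_footprints
from .simulate import SessionRecording
from .sort import SortingParams, sort_block
from .track import TrackedUnit, TrackingParams, group_stats, qc_filter, track_days

__all__ = ["PipelineConfig", "SessionResult", "LongitudinalResult", "run_session", "run_longitudinal"]


@dataclass(frozen=True)
class PipelineConfig:
    n_rows: int = 99
    n_cols: int = 111
    pitch: float = 18.0
    max_simultaneous: int = 126
    block_rows: int = 18
    block_cols: int = 6
    overlap_fraction: float = 0.25
    detection: DetectionParams = field(default_factory=DetectionParams)
    sorting: SortingParams = field(default_factory=SortingParams)
    merging: MergeParams = field(default_factory=MergeParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    seed: int = 0

    def layout(self) -> ElectrodeLayout:
        return build_layout(self.n_rows, self.n_cols, self.pitch, self.max_simultaneous)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("detection", "sorting", "merging", "tracking"):
            d[k] = dict(d[k])
        d["sorting"]["k_candidates"] = list(d["sorting"]["k_candidates"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "detection" in d:
            d["detection"] = DetectionParams(**d["detection"])
        if "sorting" in d:
            s = dict(d["sorting"])
            if "k_candidates" in s:
                s["k_candidates"] = tuple(s["k_candidates"])
            d["sorting"] = SortingParams(**s)
        if "merging" in d:
            d["merging"] = MergeParams(**d["merging"])
        if "tracking" in d:
            d["tracking"] = TrackingParams(**d["tracking"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class SessionResult:
    day_index: int
    footprints: list[GlobalFootprint]
    activity: ActivityMap
    report: "object"  # pandas.DataFrame

    @property
    def n_units(self) -> int:
        return len(self.footprints)


def _stage_seed(seed: int, day: int, block: int) -> int:
    return int(np.random.SeedSequence(entropy=(seed & 0x7FFFFFFF, day, block)).generate_state(1)[0] % (2**31 - 1))


def run_session(config: PipelineConfig, session: SessionRecording) -> SessionResult:
    """Detect, sort every block of one day, and merge the block footprints."""
    import pandas as pd

    layout = config.layout()
    all_events: dict[int, list] = {}
    recorded: set[int] = set()
    block_fps = []
    blocks = []
    for rec in session.blocks:
        ids = list(rec.block.electrode_ids)
        bad = [e for e in ids if e >= layout.n_electrodes]
        if bad:
            raise ValueError(f"recording references electrodes outside the layout: {bad[:5]}")
        blocks.append(rec.block)
        recorded.update(ids)
        events, sds, filtered = detect_block(rec.traces, ids, rec.sample_rate, config.detection)
        for e, evs in events.items():
            all_events.setdefault(e, []).extend(evs)
        fps = sort_block(
            filtered, ids, rec.sample_rate, config.sorting, config.detection,
            seed=_stage_seed(config.seed, session.day_index, rec.block.block_index),
            block_index=rec.block.block_index,
            noise_sd_by_electrode=sds,
            day_index=session.day_index,
        )
        block_fps.extend(fps)
    merged = merge_block_footprints(block_fps, blocks, config.merging)
    for fp in merged:
        fp.day_index = session.day_index
    amap = activity_map(all_events, recorded)
    report = pd.DataFrame(
        [
            {
                "day": session.day_index,
                "unit_id": fp.unit_id,
                "n_spikes": fp.n_spikes,
                "n_electrodes": len(fp.electrode_ids),
                "blocks": ",".join(map(str, fp.block_indices)),
                "core_electrode": fp.core_electrode,
                "cf_amplitude_uV": float(-fp.template.min()),
            }
            for fp in merged
        ]
    )
    return SessionResult(session.day_index, merged, amap, report)


@dataclass
class LongitudinalResult:
    sessions: list[SessionResult]
    retained_units: list[TrackedUnit]
    all_chains: list[TrackedUnit]
    stats: "object"  # pandas.DataFrame


def run_longitudinal(config: PipelineConfig, sessions: Sequence[SessionRecording]) -> LongitudinalResult:
    """Per-day sessions, consecutive-day tracking, QC, and group statistics."""
    if len(sessions) < 2:
        raise ValueError("longitudinal analysis needs at least two days")
    layout = config.layout()
    results = [run_session(config, s) for s in sessions]
    by_day = {r.day_index: r.footprints for r in results}
    recorded = {
        s.day_index: {e for b in s.blocks for e in b.block.electrode_ids} for s in sessions
    }
    retained, chains = track_days(by_day, config.tracking)
    for unit in chains:
        qc_filter(unit, layout, config.tracking, recorded_electrodes_by_day=recorded)
    stats = group_stats(retained)
    return LongitudinalResult(results, retained, chains, stats)
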