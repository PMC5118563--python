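"""HDF5 containers for recordings and footprint stores, plus CSV reports.

Recording file layout::

    /day_<d>/block_<b>/traces          float32 (electrodes x samples) μV
    /day_<d>/block_<b>/electrode_ids   int
    /day_<d>/block_<b>/carried_ids     int
    /day_<d>/block_<b>@sample_rate, @t_start, @block_index
    /day_<d>@day_index

Footprint stores mirror the structure with one group per unit holding the
template, electrode ids, spike samples and provenance attributes.
"""

from __future__ import annotations

import json
from typing import Sequence

import h5py
import numpy as np

from .layout import BlockConfiguration
from .merge import GlobalFootprint
from .simulate import RecordingBlockData, SessionPlan, SessionRecording, GroundTruthEventLog
from .sort import BlockFootprint

__all__ = [
    "write_recording",
    "read_recording",
    "write_footprints",
    "read_footprints",
]


def write_recording(path, sessions: Sequence[SessionRecording], attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
        for ses in sessions:
            g = f.create_group(f"day_{ses.day_index}")
            g.attrs["day_index"] = ses.day_index
            g.attrs["noise_sigma"] = ses.plan.noise_sigma
            for rec in ses.blocks:
                b = g.create_group(f"block_{rec.block.block_index}")
                b.create_dataset("traces", data=rec.traces.astype(np.float32), compression="gzip")
                b.create_dataset("electrode_ids", data=np.asarray(rec.block.electrode_ids, dtype=np.int64))
                b.create_dataset("carried_ids", data=np.asarray(rec.block.carried_ids, dtype=np.int64))
                b.attrs["sample_rate"] = rec.sample_rate
                b.attrs["t_start"] = rec.t_start
                b.attrs["block_index"] = rec.block.block_index
            if ses.truth.spikes:
                t = g.create_group("truth")
                for (u, bi), s in ses.truth.spikes.items():
                    tg = t.create_group(f"unit_{u}_block_{bi}")
                    tg.create_dataset("spike_samples", data=np.asarray(s, dtype=np.int64))
                    amp = ses.truth.peak_amplitudes.get((u, bi), {})
                    tg.attrs["unit_id"] = u
                    tg.attrs["block_index"] = bi
                    tg.attrs["peak_amplitudes"] = json.dumps(amp)


def read_recording(path) -> list[SessionRecording]:
    sessions = []
    with h5py.File(path, "r") as f:
        for day_name in sorted(f, key=lambda n: int(n.split("_")[1])):
            g = f[day_name]
            day = int(g.attrs["day_index"])
            blocks = []
            sample_rate = 20000.0
            for bname in sorted((n for n in g if n.startswith("block_")), key=lambda n: int(n.split("_")[1])):
                b = g[bname]
                cfg = BlockConfiguration(
                    int(b.attrs["block_index"]),
                    tuple(int(e) for e in b["electrode_ids"][()]),
                    tuple(int(e) for e in b["carried_ids"][()]),
                )
                sample_rate = float(b.attrs["sample_rate"])
                blocks.append(
                    RecordingBlockData(cfg, b["traces"][()], sample_rate, float(b.attrs["t_start"]))
                )
            truth = GroundTruthEventLog()
            if "truth" in g:
                for tname in g["truth"]:
                    tg = g["truth"][tname]
                    key = (int(tg.attrs["unit_id"]), int(tg.attrs["block_index"]))
                    truth.spikes[key] = tg["spike_samples"][()]
                    truth.peak_amplitudes[key] = {
                        int(k): float(v) for k, v in json.loads(tg.attrs["peak_amplitudes"]).items()
                    }
            plan = SessionPlan(
                day_index=day,
                duration_s=blocks[0].n_samples / sample_rate if blocks else 40.0,
                sample_rate=sample_rate,
                noise_sigma=float(g.attrs.get("noise_sigma", 0.0)),
            )
            sessions.append(SessionRecording(day, blocks, truth, plan))
    return sessions


def write_footprints(path, footprints: Sequence[GlobalFootprint], attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        for k, v in (attrs or {}).items():
            f.attrs[k] = v
        for fp in footprints:
            g = f.create_group(f"unit_{fp.unit_id}")
            g.attrs["unit_id"] = fp.unit_id
            if fp.day_index is not None:
                g.attrs["day_index"] = fp.day_index
            g.create_dataset("template", data=fp.template)
            g.create_dataset("electrode_ids", data=np.asarray(fp.electrode_ids, dtype=np.int64))
            for ci, c in enumerate(fp.contributors):
                cg = g.create_group(f"contrib_{ci}")
                cg.attrs["block_index"] = c.block_index
                cg.attrs["label"] = c.label
                cg.attrs["core_electrode"] = c.core_electrode
                cg.attrs["sample_rate"] = c.sample_rate
                cg.attrs["pre_samples"] = c.pre_samples
                if c.day_index is not None:
                    cg.attrs["day_index"] = c.day_index
                cg.create_dataset("template", data=c.template)
                cg.create_dataset("electrode_ids", data=np.asarray(c.electrode_ids, dtype=np.int64))
                cg.create_dataset("spike_samples", data=np.asarray(c.spike_samples, dtype=np.int64))


def read_footprints(path) -> list[GlobalFootprint]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted((n for n in f if n.startswith("unit_")), key=lambda n: int(n.split("_")[1])):
            g = f[name]
            contribs = []
            for cname in sorted((n for n in g if n.startswith("contrib_")), key=lambda n: int(n.split("_")[1])):
                cg = g[cname]
                contribs.append(
                    BlockFootprint(
                        label=int(cg.attrs["label"]),
                        block_index=int(cg.attrs["block_index"]),
                        electrode_ids=tuple(int(e) for e in cg["electrode_ids"][()]),
                        template=cg["template"][()],
                        spike_samples=cg["spike_samples"][()],
                        core_electrode=int(cg.attrs["core_electrode"]),
                        sample_rate=float(cg.attrs["sample_rate"]),
                        pre_samples=int(cg.attrs["pre_samples"]),
                        day_index=int(cg.attrs["day_index"]) if "day_index" in cg.attrs else None,
                    )
                )
            out.append(
                GlobalFootprint(
                    unit_id=int(g.attrs["unit_id"]),
                    electrode_ids=tuple(int(e) for e in g["electrode_ids"][()]),
                    template=g["template"][()],
                    contributors=contribs,
                    day_index=int(g.attrs["day_index"]) if "day_index" in g.attrs else None,
                )
            )
    return out
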