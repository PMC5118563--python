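"""Multi-day single-unit tracking and central-footprint (CF) metrics.

Footprints from the same block configuration are compared between
consecutive recording days; pairs with matching coefficient above 0.85 are
linked one-to-one (greedy, by descending MC) and assembled into chains.
Chains traceable for at least ``min_tracked_days`` (7) recording days make
up the reported set.  Per day and unit the central footprint is quantified:

* CF amplitude — |largest negative spike amplitude| within the footprint;
* CF location — position of that peak on the negative-peak amplitude map,
  cubic-interpolated to a 2 μm grid (sub-electrode resolution);
* CF area — electrode count of the 8-connected supra-threshold region
  (amplitudes above 50% of the CF amplitude) around the core electrode,
  times the 324 μm^2 electrode cell of an 18 μm pitch grid;
* movement distance — Euclidean distance between the CF locations of
  consecutive days.

Quality control mirrors the manual evaluation criteria: days with CF
amplitude below 50 μV are excluded, units whose supra-threshold set splits
into several connected components (multiple footprint centers) are
excluded, and a footprint partially missing because its unit was silent
while a block was scanned is only excluded when the missing electrodes
touch the central footprint area itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline

from .layout import ElectrodeLayout
from .merge import GlobalFootprint, NoCommonElectrodesError, matching_coefficient

__all__ = [
    "TrackingParams",
    "CFMetrics",
    "TrackedUnit",
    "cf_amplitude",
    "cf_location",
    "cf_area",
    "movement_distance",
    "compute_cf_metrics",
    "track_days",
    "qc_filter",
    "group_stats",
]


@dataclass(frozen=True)
class TrackingParams:
    mc_track: float = 0.85
    min_tracked_days: int = 7
    min_cf_amplitude: float = 50.0
    cf_area_fraction: float = 0.5
    interp_grid_step: float = 2.0
    max_window_halfwidth: int = 4  # electrodes, for the interpolation patch

    def __post_init__(self):
        if self.mc_track <= 0 or self.min_cf_amplitude <= 0 or self.interp_grid_step <= 0:
            raise ValueError("tracking thresholds must be positive")


@dataclass
class CFMetrics:
    day_index: int
    amplitude: float  # μV
    location: tuple[float, float]  # μm
    area_um2: float
    n_centers: int = 1
    location_fallback: bool = False
    movement_um: float | None = None  # vs previous tracked day


@dataclass
class TrackedUnit:
    chain_id: int
    footprints: dict[int, GlobalFootprint] = field(default_factory=dict)  # day -> footprint
    metrics: dict[int, CFMetrics] = field(default_factory=dict)
    excluded: bool = False
    exclusion_reason: str | None = None
    low_amplitude_days: set[int] = field(default_factory=set)
    artifact_days: set[int] = field(default_factory=set)

    @property
    def days(self) -> list[int]:
        return sorted(self.footprints)

    @property
    def span(self) -> int:
        return len(self.footprints)


def _peak_map(fp: GlobalFootprint) -> dict[int, float]:
    """Per-electrode negative-peak magnitude (0 where the waveform never
    goes negative)."""
    mins = fp.template.min(axis=1)
    return {e: float(max(0.0, -m)) for e, m in zip(fp.electrode_ids, mins)}


def cf_amplitude(fp: GlobalFootprint) -> float:
    """|global minimum| of the footprint (μV)."""
    if fp.template.size == 0:
        raise ValueError("empty footprint")
    return float(-fp.template.min())


def _grid_patch(fp: GlobalFootprint, layout: ElectrodeLayout, half: int):
    """Largest all-covered rectangular electrode patch around the core,
    grown greedily one grid line at a time up to ``half`` in each direction.
    Returns (rows, cols, amplitude matrix) or None if smaller than 4x4."""
    amp = _peak_map(fp)
    covered = {layout.rowcol(e) for e in fp.electrode_ids}
    covered = {(int(r), int(c)) for r, c in covered}
    cr, cc = (int(v) for v in layout.rowcol(fp.core_electrode))
    r0 = r1 = cr
    c0 = c1 = cc

    def full_line(rr0, rr1, cc0, cc1):
        return all((r, c) in covered for r in range(rr0, rr1 + 1) for c in range(cc0, cc1 + 1))

    grown = True
    while grown:
        grown = False
        if cr - r0 < half and r0 > 0 and full_line(r0 - 1, r0 - 1, c0, c1):
            r0 -= 1; grown = True
        if r1 - cr < half and r1 < layout.n_rows - 1 and full_line(r1 + 1, r1 + 1, c0, c1):
            r1 += 1; grown = True
        if cc - c0 < half and c0 > 0 and full_line(r0, r1, c0 - 1, c0 - 1):
            c0 -= 1; grown = True
        if c1 - cc < half and c1 < layout.n_cols - 1 and full_line(r0, r1, c1 + 1, c1 + 1):
            c1 += 1; grown = True
    if r1 - r0 < 3 or c1 - c0 < 3:
        return None
    rows = np.arange(r0, r1 + 1)
    cols = np.arange(c0, c1 + 1)
    A = np.array([[amp[layout.electrode_at(r, c)] for c in cols] for r in rows])
    return rows, cols, A


def cf_location(
    fp: GlobalFootprint, layout: ElectrodeLayout, params: TrackingParams | None = None
) -> tuple[tuple[float, float], bool]:
    """CF location on the cubic-interpolated amplitude surface.

    Returns ``((x, y) μm, fallback)``; ``fallback`` is True when the core
    electrode lacks the 4x4 covered neighborhood cubic interpolation needs,
    in which case the core electrode position itself is returned.
    """
    params = params or TrackingParams()
    patch = _grid_patch(fp, layout, params.max_window_halfwidth)
    core_xy = layout.position(fp.core_electrode)
    if patch is None:
        return (float(core_xy[0]), float(core_xy[1])), True
    rows, cols, A = patch
    ys = rows * layout.pitch
    xs = cols * layout.pitch
    spline = RectBivariateSpline(ys, xs, A, kx=3, ky=3)
    step = params.interp_grid_step
    yf = np.arange(ys[0], ys[-1] + step / 2, step)
    xf = np.arange(xs[0], xs[-1] + step / 2, step)
    surface = spline(yf, xf)
    i, j = np.unravel_index(np.argmax(surface), surface.shape)
    return (float(xf[j]), float(yf[i])), False


def cf_area(
    fp: GlobalFootprint, layout: ElectrodeLayout, params: TrackingParams | None = None
) -> tuple[float, int, list[int]]:
    """CF area and footprint-center count.

    Electrodes whose negative-peak magnitude exceeds ``cf_area_fraction``
    (50%) of the CF amplitude are thresholded; the 8-connected component
    containing the core electrode defines the central footprint area
    (count x pitch^2 μm^2).  Additional disconnected supra-threshold
    components are reported through ``n_centers`` (> 1 flags a multi-center
    footprint).
    """
    params = params or TrackingParams()
    amp = _peak_map(fp)
    thr = params.cf_area_fraction * cf_amplitude(fp)
    supra = [e for e, v in amp.items() if v > thr]
    rows, cols = zip(*[(int(layout.rowcol(e)[0]), int(layout.rowcol(e)[1])) for e in supra])
    r0, c0 = min(rows), min(cols)
    mask = np.zeros((max(rows) - r0 + 1, max(cols) - c0 + 1), dtype=bool)
    for r, c in zip(rows, cols):
        mask[r - r0, c - c0] = True
    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    cr, cc = (int(v) for v in layout.rowcol(fp.core_electrode))
    core_label = labels[cr - r0, cc - c0]
    members = [
        e for e in supra
        if labels[int(layout.rowcol(e)[0]) - r0, int(layout.rowcol(e)[1]) - c0] == core_label
    ]
    area = len(members) * layout.pitch**2
    return float(area), int(n_comp), members


def movement_distance(loc_i: tuple[float, float], loc_prev: tuple[float, float]) -> float:
    """Euclidean CF-location displacement between consecutive days (μm)."""
    if loc_i is None or loc_prev is None:
        raise ValueError("movement undefined without both locations")
    return float(np.hypot(loc_i[0] - loc_prev[0], loc_i[1] - loc_prev[1]))


def compute_cf_metrics(
    fp: GlobalFootprint, layout: ElectrodeLayout, params: TrackingParams | None = None
) -> CFMetrics:
    params = params or TrackingParams()
    amp = cf_amplitude(fp)
    loc, fb = cf_location(fp, layout, params)
    area, n_centers, _ = cf_area(fp, layout, params)
    return CFMetrics(
        day_index=fp.day_index if fp.day_index is not None else -1,
        amplitude=amp,
        location=loc,
        area_um2=area,
        n_centers=n_centers,
        location_fallback=fb,
    )


def _link_mc(a: GlobalFootprint, b: GlobalFootprint) -> float | None:
    """Best same-block matching coefficient between two units' contributor
    footprints (None if they share no block)."""
    best = None
    for fa in a.contributors:
        for fb in b.contributors:
            if fa.block_index != fb.block_index:
                continue
            try:
                mc = matching_coefficient(fa, fb)
            except NoCommonElectrodesError:  # pragma: no cover - same block always shares
                continue
            best = mc if best is None else max(best, mc)
    return best


def track_days(
    footprints_by_day: Mapping[int, Sequence[GlobalFootprint]],
    params: TrackingParams | None = None,
) -> tuple[list[TrackedUnit], list[TrackedUnit]]:
    """Chain same-neuron footprints across consecutive recording days.

    Candidate links between day d and the next recorded day are same-block
    footprint pairs with MC above ``mc_track``; links are assigned
    one-to-one greedily by descending MC (ties by unit order).  Returns
    ``(retained, all_chains)`` where retained chains span at least
    ``min_tracked_days`` days.
    """
    params = params or TrackingParams()
    days = sorted(footprints_by_day)
    if len(days) < 2:
        raise ValueError("tracking needs footprints from at least two days")

    chain_of: dict[tuple[int, int], TrackedUnit] = {}
    chains: list[TrackedUnit] = []

    def chain_for(day: int, idx: int, fp: GlobalFootprint) -> TrackedUnit:
        key = (day, idx)
        if key not in chain_of:
            unit = TrackedUnit(chain_id=len(chains))
            unit.footprints[day] = fp
            chains.append(unit)
            chain_of[key] = unit
        return chain_of[key]

    for d0, d1 in zip(days[:-1], days[1:]):
        prev = list(footprints_by_day[d0])
        curr = list(footprints_by_day[d1])
        candidates = []
        for i, a in enumerate(prev):
            for j, b in enumerate(curr):
                mc = _link_mc(a, b)
                if mc is not None and mc > params.mc_track:
                    candidates.append((-mc, i, j))
        candidates.sort()
        used_i: set[int] = set()
        used_j: set[int] = set()
        for negmc, i, j in candidates:
            if i in used_i or j in used_j:
                continue
            used_i.add(i)
            used_j.add(j)
            unit = chain_for(d0, i, prev[i])
            unit.footprints[d1] = curr[j]
            chain_of[(d1, j)] = unit
        for j, b in enumerate(curr):
            chain_for(d1, j, b)  # start fresh chains for unmatched units

    retained = [u for u in chains if u.span >= params.min_tracked_days]
    return retained, chains


def qc_filter(
    unit: TrackedUnit,
    layout: ElectrodeLayout,
    params: TrackingParams | None = None,
    recorded_electrodes_by_day: Mapping[int, set[int]] | None = None,
) -> TrackedUnit:
    """Compute CF metrics for a chain and apply the evaluation criteria.

    Days with CF amplitude below ``min_cf_amplitude`` are flagged and their
    metrics excluded from group statistics.  A unit with multiple footprint
    centers on any retained day is excluded outright.  When the electrode
    set recorded on a day is supplied, days whose footprint misses recorded
    coverage are flagged as silent-block artifacts; the unit is excluded
    only if a missing electrode borders the central footprint area.
    """
    params = params or TrackingParams()
    prev_day = None
    for day in unit.days:
        fp = unit.footprints[day]
        m = compute_cf_metrics(fp, layout, params)
        m.day_index = day
        if m.amplitude < params.min_cf_amplitude:
            unit.low_amplitude_days.add(day)
        else:
            if m.n_centers > 1:
                unit.excluded = True
                unit.exclusion_reason = "multiple footprint centers"
            if prev_day is not None and prev_day == day - 1 and prev_day in unit.metrics:
                pm = unit.metrics[prev_day]
                if prev_day not in unit.low_amplitude_days:
                    m.movement_um = movement_distance(m.location, pm.location)
        if recorded_electrodes_by_day and day in recorded_electrodes_by_day:
            missing = recorded_electrodes_by_day[day] - set(fp.electrode_ids)
            if missing:
                unit.artifact_days.add(day)
                _, _, central = cf_area(fp, layout, params)
                central_rc = {tuple(int(v) for v in layout.rowcol(e)) for e in central}
                for e in missing:
                    r, c = (int(v) for v in layout.rowcol(e))
                    if any(abs(r - rr) <= 1 and abs(c - cc) <= 1 for rr, cc in central_rc):
                        unit.excluded = True
                        unit.exclusion_reason = "central footprint area incomplete"
                        break
        unit.metrics[day] = m
        prev_day = day
    return unit


def group_stats(units: Sequence[TrackedUnit], day_range: Sequence[int] | None = None):
    """Per-day group summaries as a DataFrame.

    Median movement (the group statistic for CF-location dynamics) and mean
    CF amplitude / CF area, each with the standard error of the mean
    (SD/sqrt(n) over units).  Excluded units and low-amplitude days do not
    contribute; empty days are omitted with a warning.
    """
    import pandas as pd

    usable = [u for u in units if not u.excluded]
    if day_range is None:
        day_range = sorted({d for u in usable for d in u.metrics})
    rows = []
    for day in day_range:
        amps, areas, moves = [], [], []
        for u in usable:
            if day in u.metrics and day not in u.low_amplitude_days:
                m = u.metrics[day]
                amps.append(m.amplitude)
                areas.append(m.area_um2)
                if m.movement_um is not None:
                    moves.append(m.movement_um)
        if not amps:
            warnings.warn(f"no usable units on day {day}; omitted", stacklevel=2)
            continue

        def sem(v):
            return float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0

        rows.append(
            {
                "day": day,
                "n_units": len(amps),
                "movement_median_um": float(np.median(moves)) if moves else np.nan,
                "movement_sem_um": sem(moves) if moves else np.nan,
                "amplitude_mean_uV": float(np.mean(amps)),
                "amplitude_sem_uV": sem(amps),
                "area_mean_um2": float(np.mean(areas)),
                "area_sem_um2": sem(areas),
            }
        )
    return pd.DataFrame(rows).set_index("day") if rows else pd.DataFrame()
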