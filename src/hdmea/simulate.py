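"""Ground-truth simulator for block-scanned HD-MEA recordings.

Synthetic units have a soma position on (or between) the electrodes, a
biphasic extracellular waveform whose trough amplitude decays as a Gaussian
of distance from the soma, Poisson spike trains thinned by an absolute
refractory period, and i.i.d. Gaussian electrode noise.  Blocks are rendered
independently (sequential acquisition: each block sees its own stretch of
wall-clock time), and multi-day series apply per-day amplitude scaling,
soma drift, unit dropout, and forced silence of a unit during chosen blocks
(the "silent-block" artifact of scanned acquisitions).

Every inserted spike is logged, so the simulator doubles as the oracle for
detection/sorting/tracking recovery tests: subtracting all logged insertions
from a noise-free rendering leaves exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .layout import BlockConfiguration, ElectrodeLayout

__all__ = [
    "GroundTruthUnit",
    "UnitDayState",
    "SessionPlan",
    "RecordingBlockData",
    "GroundTruthEventLog",
    "SessionRecording",
    "spike_shape",
    "unit_footprint",
    "simulate_spike_train",
    "render_block",
    "simulate_session",
    "simulate_longitudinal",
    "synthesize_day_footprints",
    "make_decay_drift_plans",
]

DEFAULT_SAMPLE_RATE = 20_000.0


@dataclass(frozen=True)
class GroundTruthUnit:
    """Simulated neuron with known position, waveform, and statistics.

    ``peak_amplitude`` is the magnitude (μV, positive number) of the negative
    trough at the soma; the trough seen by an electrode at distance d is
    ``-peak_amplitude * exp(-d^2 / (2 spatial_sigma^2))``.
    """

    unit_id: int
    x: float
    y: float
    peak_amplitude: float = 100.0
    spatial_sigma: float = 25.0
    trough_width_ms: float = 0.30
    overshoot_ratio: float = 0.30
    firing_rate: float = 2.0
    refractory_ms: float = 2.0

    def __post_init__(self):
        if self.peak_amplitude <= 0:
            raise ValueError("peak_amplitude must be > 0")
        if self.spatial_sigma <= 0:
            raise ValueError("spatial_sigma must be > 0")
        if self.refractory_ms < 0:
            raise ValueError("refractory_ms must be >= 0")

    def with_state(self, state: "UnitDayState") -> "GroundTruthUnit":
        """Unit as it appears on a given day (scaled amplitude, drifted soma)."""
        return replace(
            self,
            x=self.x + state.offset[0],
            y=self.y + state.offset[1],
            peak_amplitude=self.peak_amplitude * state.amplitude_scale,
        )


@dataclass(frozen=True)
class UnitDayState:
    """Per-day modifier of one unit: absolute soma offset (μm) from the
    nominal position, amplitude scale factor, activity flag, and block
    indices in which the unit is forced silent."""

    amplitude_scale: float = 1.0
    offset: tuple[float, float] = (0.0, 0.0)
    active: bool = True
    silent_blocks: frozenset[int] = frozenset()


@dataclass(frozen=True)
class SessionPlan:
    """One recording day: block scan order is taken from the block list the
    simulator is called with; every block lasts ``duration_s`` seconds."""

    day_index: int = 0
    duration_s: float = 40.0
    sample_rate: float = DEFAULT_SAMPLE_RATE
    noise_sigma: float = 6.0
    modifiers: Mapping[int, UnitDayState] = field(default_factory=dict)

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")

    def state_for(self, unit_id: int) -> UnitDayState:
        return self.modifiers.get(unit_id, UnitDayState())


@dataclass
class RecordingBlockData:
    """Voltage traces (μV, float32, electrodes x samples) of one block."""

    block: BlockConfiguration
    traces: np.ndarray
    sample_rate: float
    t_start: float = 0.0

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]


@dataclass
class GroundTruthEventLog:
    """Inserted spikes: (unit_id, block_index) -> spike sample indices, plus
    the true per-electrode trough magnitudes of each unit that day."""

    spikes: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    peak_amplitudes: dict[tuple[int, int], dict[int, float]] = field(default_factory=dict)

    def spikes_for(self, unit_id: int, block_index: int) -> np.ndarray:
        return self.spikes.get((unit_id, block_index), np.empty(0, dtype=int))

    def units(self) -> set[int]:
        return {u for u, _ in self.spikes}


@dataclass
class SessionRecording:
    day_index: int
    blocks: list[RecordingBlockData]
    truth: GroundTruthEventLog
    plan: SessionPlan


def spike_shape(
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    trough_width_ms: float = 0.30,
    overshoot_ratio: float = 0.30,
    support_ms: float = 3.0,
) -> tuple[np.ndarray, int]:
    """Unit-normalized biphasic waveform (negative trough, positive overshoot).

    Returns ``(shape, trough_index)`` where ``min(shape) == -1`` exactly and
    the trough sits one third into the ``support_ms`` window (so a 1 ms
    pre / 2 ms post cut-out captures the whole waveform).
    """
    n = int(round(support_ms * 1e-3 * sample_rate)) + 1
    t = np.arange(n) / sample_rate * 1e3  # ms
    t0 = support_ms / 3.0
    w = trough_width_ms / 2.3548  # FWHM -> Gaussian sigma
    delay = 1.7 * trough_width_ms
    s = -np.exp(-((t - t0) ** 2) / (2 * w**2)) + overshoot_ratio * np.exp(
        -((t - t0 - delay) ** 2) / (2 * (1.6 * w) ** 2)
    )
    s /= np.abs(s.min())
    return s, int(np.argmin(s))


def unit_footprint(
    unit: GroundTruthUnit,
    layout: ElectrodeLayout,
    electrode_ids: Sequence[int] | None = None,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> np.ndarray:
    """True spatiotemporal template of a unit: (n_electrodes, n_samples).

    Electrode e at distance d_e from the soma receives
    ``-A exp(-d_e^2 / (2 sigma_s^2)) * s(t)`` with s the unit-normalized
    biphasic shape; the trough of the nearest electrode equals -A when the
    soma sits exactly on it.
    """
    if electrode_ids is None:
        electrode_ids = range(layout.n_electrodes)
    ids = np.asarray(list(electrode_ids), dtype=int)
    pos = layout.position(ids)
    d2 = (pos[:, 0] - unit.x) ** 2 + (pos[:, 1] - unit.y) ** 2
    amp = unit.peak_amplitude * np.exp(-d2 / (2 * unit.spatial_sigma**2))
    shape, _ = spike_shape(sample_rate, unit.trough_width_ms, unit.overshoot_ratio)
    return np.outer(amp, shape)


def true_peak_amplitudes(
    unit: GroundTruthUnit, layout: ElectrodeLayout, electrode_ids: Sequence[int]
) -> dict[int, float]:
    ids = np.asarray(list(electrode_ids), dtype=int)
    pos = layout.position(ids)
    d2 = (pos[:, 0] - unit.x) ** 2 + (pos[:, 1] - unit.y) ** 2
    amp = unit.peak_amplitude * np.exp(-d2 / (2 * unit.spatial_sigma**2))
    return {int(e): float(a) for e, a in zip(ids, amp)}


def simulate_spike_train(
    rate: float,
    duration_s: float,
    refractory_ms: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Homogeneous Poisson spike times (s) thinned by absolute refractoriness.

    Events closer than ``refractory_ms`` to the previously *kept* event are
    dropped, so the minimum inter-spike interval of the output is guaranteed.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if duration_s < 0:
        raise ValueError("duration must be >= 0")
    if rate == 0 or duration_s == 0:
        return np.empty(0)
    rng = np.random.default_rng(rng)
    n_exp = int(rate * duration_s + 6 * np.sqrt(rate * duration_s) + 10)
    times = np.cumsum(rng.exponential(1.0 / rate, size=n_exp))
    while times[-1] < duration_s:  # pragma: no cover - astronomically rare
        times = np.concatenate([times, times[-1] + np.cumsum(rng.exponential(1.0 / rate, size=n_exp))])
    times = times[times < duration_s]
    if refractory_ms > 0 and times.size:
        ref = refractory_ms * 1e-3
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= ref:
                kept.append(t)
        times = np.asarray(kept)
    return times


def render_block(
    block: BlockConfiguration,
    layout: ElectrodeLayout,
    units: Sequence[GroundTruthUnit],
    plan: SessionPlan,
    rng: np.random.Generator | int | None = None,
    t_start: float = 0.0,
) -> tuple[RecordingBlockData, GroundTruthEventLog]:
    """Render one block: summed spike insertions plus Gaussian noise.

    Unit modifiers from ``plan`` (scale, drift, dropout, silent blocks) are
    applied before insertion; the event log records every inserted spike and
    the true per-electrode trough magnitudes.
    """
    rng = np.random.default_rng(rng)
    fs = plan.sample_rate
    n_samples = int(round(plan.duration_s * fs))
    ids = np.asarray(block.electrode_ids, dtype=int)
    traces = np.zeros((len(ids), n_samples), dtype=np.float32)
    log = GroundTruthEventLog()

    for unit in units:
        state = plan.state_for(unit.unit_id)
        if not state.active or block.block_index in state.silent_blocks:
            continue
        u = unit.with_state(state)
        train = simulate_spike_train(u.firing_rate, plan.duration_s, u.refractory_ms, rng)
        samples = np.round(train * fs).astype(int)
        samples = samples[(samples >= 0) & (samples < n_samples)]
        if samples.size == 0:
            continue
        fp = unit_footprint(u, layout, ids, fs)
        shape_len = fp.shape[1]
        _, trough = spike_shape(fs, u.trough_width_ms, u.overshoot_ratio)
        for s in samples:
            a = s - trough
            b = a + shape_len
            ca, cb = max(a, 0), min(b, n_samples)
            traces[:, ca:cb] += fp[:, ca - a : shape_len - (b - cb)].astype(np.float32)
        log.spikes[(u.unit_id, block.block_index)] = samples
        log.peak_amplitudes[(u.unit_id, block.block_index)] = true_peak_amplitudes(u, layout, ids)

    if plan.noise_sigma > 0:
        for i in range(len(ids)):  # row-wise to bound peak memory
            traces[i] += rng.normal(0.0, plan.noise_sigma, n_samples).astype(np.float32)
    return RecordingBlockData(block, traces, fs, t_start), log


def simulate_session(
    layout: ElectrodeLayout,
    blocks: Sequence[BlockConfiguration],
    units: Sequence[GroundTruthUnit],
    plan: SessionPlan,
    seed: int | np.random.SeedSequence = 0,
) -> SessionRecording:
    """Render one day's sequential block scan (blocks independent)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child = ss.spawn(len(blocks))
    out_blocks = []
    truth = GroundTruthEventLog()
    for i, block in enumerate(blocks):
        rec, log = render_block(
            block, layout, units, plan, np.random.default_rng(child[i]), t_start=i * plan.duration_s
        )
        out_blocks.append(rec)
        truth.spikes.update(log.spikes)
        truth.peak_amplitudes.update(log.peak_amplitudes)
    return SessionRecording(plan.day_index, out_blocks, truth, plan)


def simulate_longitudinal(
    layout: ElectrodeLayout,
    blocks: Sequence[BlockConfiguration],
    units: Sequence[GroundTruthUnit],
    plans: Sequence[SessionPlan],
    seed: int = 0,
) -> list[SessionRecording]:
    """Render a multi-day series; day d uses the d-th spawned seed stream, so
    a 1-day series reproduces ``simulate_session`` bit for bit."""
    if not plans:
        raise ValueError("at least one day plan required")
    ss = np.random.SeedSequence(seed)
    day_seeds = ss.spawn(len(plans)) if len(plans) > 1 else [ss]
    return [
        simulate_session(layout, blocks, units, plan, day_seeds[d])
        for d, plan in enumerate(plans)
    ]


def synthesize_day_footprints(
    layout: ElectrodeLayout,
    blocks: Sequence[BlockConfiguration],
    units: Sequence[GroundTruthUnit],
    plans: Sequence[SessionPlan],
    template_noise: float = 0.5,
    seed: int = 0,
):
    """Ground-truth *footprint-level* day series (no trace rendering).

    For each day, every active unit contributes one block footprint on its
    home block (the block containing the electrode nearest its soma on day
    one), built from its true template under that day's amplitude scale and
    drift, plus i.i.d. Gaussian template noise emulating the residual noise
    floor of a median over many spikes.  Units silent in their home block
    that day are omitted (the silent-block artifact).  Returns
    ``{day_index: [GlobalFootprint, ...]}`` with ``unit_id`` carrying the
    true identity, footprints shuffled within each day.
    """
    from .merge import GlobalFootprint
    from .sort import BlockFootprint

    rng_master = np.random.default_rng(np.random.SeedSequence(seed))
    block_sets = {b.block_index: np.asarray(b.electrode_ids, dtype=int) for b in blocks}
    home: dict[int, int] = {}
    for u in units:
        best = None
        for bi, ids in sorted(block_sets.items()):
            pos = layout.position(ids)
            d = float(np.min(np.hypot(pos[:, 0] - u.x, pos[:, 1] - u.y)))
            if best is None or d < best[0]:
                best = (d, bi)
        home[u.unit_id] = best[1]

    out: dict[int, list] = {}
    for plan in plans:
        rng = np.random.default_rng(rng_master.integers(2**31 - 1))
        fps = []
        for u in units:
            state = plan.state_for(u.unit_id)
            bi = home[u.unit_id]
            if not state.active or bi in state.silent_blocks:
                continue
            mod = u.with_state(state)
            ids = block_sets[bi]
            tpl = unit_footprint(mod, layout, ids, plan.sample_rate)
            if template_noise > 0:
                tpl = tpl + rng.normal(0.0, template_noise, tpl.shape)
            _, trough = spike_shape(plan.sample_rate, mod.trough_width_ms, mod.overshoot_ratio)
            pos = layout.position(ids)
            core = int(ids[int(np.argmin(np.hypot(pos[:, 0] - mod.x, pos[:, 1] - mod.y)))])
            n_spk = max(1, int(rng.poisson(mod.firing_rate * plan.duration_s)))
            bf = BlockFootprint(
                label=u.unit_id,
                block_index=bi,
                electrode_ids=tuple(int(e) for e in ids),
                template=tpl,
                spike_samples=np.arange(n_spk),
                core_electrode=core,
                sample_rate=plan.sample_rate,
                pre_samples=trough,
                day_index=plan.day_index,
            )
            fps.append(
                GlobalFootprint(u.unit_id, bf.electrode_ids, tpl, [bf], plan.day_index)
            )
        rng.shuffle(fps)
        out[plan.day_index] = fps
    return out


def make_decay_drift_plans(
    n_days: int,
    unit_ids: Sequence[int],
    first_day: int = 13,
    duration_s: float = 40.0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    noise_sigma: float = 6.0,
    amplitude_decay_per_day: float = 0.0,
    drift_um_per_day: tuple[float, float] = (0.0, 0.0),
    dropout_days: Mapping[int, int] | None = None,
    silent: Mapping[int, Mapping[int, Sequence[int]]] | None = None,
) -> list[SessionPlan]:
    """Build day plans with cumulative geometric amplitude decay and linear
    soma drift; ``dropout_days[u]`` is the first day index (0-based offset)
    on which unit u is inactive, ``silent[d][u]`` lists blocks in which unit
    u is forced silent on day offset d."""
    plans = []
    for d in range(n_days):
        mods = {}
        for u in unit_ids:
            active = not (dropout_days and u in dropout_days and d >= dropout_days[u])
            sb = frozenset((silent or {}).get(d, {}).get(u, ()))
            mods[u] = UnitDayState(
                amplitude_scale=(1.0 - amplitude_decay_per_day) ** d,
                offset=(drift_um_per_day[0] * d, drift_um_per_day[1] * d),
                active=active,
                silent_blocks=sb,
            )
        plans.append(
            SessionPlan(
                day_index=first_day + d,
                duration_s=duration_s,
                sample_rate=sample_rate,
                noise_sigma=noise_sigma,
                modifiers=mods,
            )
        )
    return plans
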