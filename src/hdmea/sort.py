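"""Iterative unsupervised spike sorting of one block configuration.

The sorter proceeds core-electrode by core-electrode:

I.   Spike clustering — detect threshold crossings on every electrode, pick
     the electrode with the largest spikes as *core electrode*, cut the
     spike waveforms of the 10 largest-signal electrodes around each core
     spike, up-sample them 6x in time with cubic splines and re-align at the
     interpolated core trough, project the concatenated waveforms onto their
     first principal components, and run k-means for k = 2..5.  The k whose
     mean silhouette value is largest wins; clusters qualify as template
     candidates only if their mean silhouette exceeds 0.5 and their biggest
     spike reaches 80% of the largest spike amplitude on the core electrode.
     If no k yields a mean silhouette above 0.5 the event set is treated as
     one homogeneous cluster (a lone unit produces exactly this signature).
II.  Template matching — the candidate's per-electrode median template is
     temporarily subtracted from *all* core-electrode spikes; the residuals
     are clustered once more (k = 2) in PCA space.  If one residual cluster
     lies at least ``residual_ratio`` (2x) closer to the zero-residual point
     along the first component than the other, only its spikes belong to the
     unit; otherwise the split was spurious and all spikes belong.  The
     footprint is rebuilt from the member spikes and their template is
     permanently subtracted ("peeled") from the traces.
III. The loop repeats on the peeled traces until no electrode retains enough
     supra-threshold events or a unit cap is reached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from .detect import DetectionParams, SpikeEvent, detect_spikes, noise_sd

logger = logging.getLogger(__name__)

__all__ = [
    "SortingParams",
    "WaveformSet",
    "ClusterSolution",
    "BlockFootprint",
    "NoUnitError",
    "select_core_electrode",
    "extract_waveforms",
    "cluster_spikes",
    "accept_clusters",
    "build_template",
    "match_residuals",
    "sort_block",
]


class NoUnitError(RuntimeError):
    """Raised when an operation needs events but none are available."""


@dataclass(frozen=True)
class SortingParams:
    n_assist_electrodes: int = 10
    upsample_factor: int = 6
    k_candidates: tuple[int, ...] = (2, 3, 4, 5)
    silhouette_min: float = 0.5
    amplitude_fraction: float = 0.8
    residual_ratio: float = 2.0
    pre_ms: float = 1.0
    post_ms: float = 2.0
    align_margin_ms: float = 0.25
    n_pca_components: int = 5
    kmeans_restarts: int = 10
    min_cluster_spikes: int = 10
    max_units_per_block: int = 20

    def __post_init__(self):
        if not all(k >= 2 for k in self.k_candidates):
            raise ValueError("k candidates must be >= 2")
        if not 0 < self.amplitude_fraction <= 1:
            raise ValueError("amplitude_fraction must be in (0, 1]")

    def window_samples(self, sample_rate: float) -> tuple[int, int]:
        return (
            int(round(self.pre_ms * 1e-3 * sample_rate)),
            int(round(self.post_ms * 1e-3 * sample_rate)),
        )


@dataclass
class WaveformSet:
    """Aligned, up-sampled spike waveforms on the assist electrodes.

    ``waveforms`` has shape (n_spikes, n_assist, n_up) and is aligned so the
    interpolated core-electrode trough sits at index
    ``pre_ms * upsample_factor * sample_rate``; ``spike_samples`` are the
    trough positions rounded back to raw samples.
    """

    spike_samples: np.ndarray
    spike_times_fine: np.ndarray  # fractional trough positions (raw samples)
    waveforms: np.ndarray
    assist_ids: tuple[int, ...]
    core_electrode: int
    core_amplitudes: np.ndarray  # |trough| per spike on the core electrode
    sample_rate: float
    upsample_factor: int

    @property
    def n_spikes(self) -> int:
        return len(self.spike_samples)

    def features(self) -> np.ndarray:
        return self.waveforms.reshape(self.n_spikes, -1)


@dataclass
class ClusterSolution:
    k: int
    labels: np.ndarray
    silhouette_values: np.ndarray | None  # None for the single-cluster case
    mean_silhouette: float
    per_k_mean: dict[int, float] = field(default_factory=dict)
    fallback: bool = False  # too few spikes to attempt a split

    def cluster_mean_silhouette(self, label: int) -> float:
        if self.silhouette_values is None:
            return float("nan")
        return float(self.silhouette_values[self.labels == label].mean())


@dataclass
class BlockFootprint:
    """Single-unit footprint of one block: per-electrode median template over
    the accepted spikes, aligned at the core-electrode trough."""

    label: int
    block_index: int
    electrode_ids: tuple[int, ...]
    template: np.ndarray  # (n_electrodes, pre + post + 1) μV
    spike_samples: np.ndarray
    core_electrode: int
    sample_rate: float
    pre_samples: int
    day_index: int | None = None
    spike_samples_fine: np.ndarray | None = None  # fractional trough positions

    @property
    def n_spikes(self) -> int:
        return len(self.spike_samples)

    @property
    def trough_index(self) -> tuple[int, int]:
        """(electrode row, sample) of the template's global minimum."""
        i, j = np.unravel_index(np.argmin(self.template), self.template.shape)
        return int(i), int(j)


def select_core_electrode(events_by_electrode: Mapping[int, Sequence[SpikeEvent]]) -> int:
    """Electrode whose largest |negative amplitude| is maximal (ties: lower id)."""
    best: tuple[float, int] | None = None
    for e, evs in events_by_electrode.items():
        if not evs:
            continue
        amp = max(abs(ev.amplitude) for ev in evs)
        key = (-amp, int(e))
        if best is None or key < best:
            best = key
    if best is None:
        raise NoUnitError("no events on any electrode")
    return best[1]


def _rank_assist_electrodes(
    traces: np.ndarray,
    electrode_ids: Sequence[int],
    core_electrode: int,
    spike_samples: np.ndarray,
    sample_rate: float,
    params: SortingParams,
) -> list[int]:
    """Rank block electrodes by their largest negative deflection within
    +-0.5 ms of the core spike times; returns the top ``n_assist`` ids with
    the core electrode guaranteed a slot."""
    w = max(1, int(round(0.5e-3 * sample_rate)))
    n = traces.shape[1]
    amps = []
    for i, e in enumerate(electrode_ids):
        m = 0.0
        for s in spike_samples:
            seg = traces[i, max(0, s - w) : min(n, s + w + 1)]
            if seg.size:
                m = max(m, float(-seg.min()))
        amps.append((-m, int(e)))
    order = [e for _, e in sorted(amps)]
    top = order[: params.n_assist_electrodes]
    if core_electrode not in top:
        top = top[:-1] + [core_electrode]
    return top


def extract_waveforms(
    traces: np.ndarray,
    electrode_ids: Sequence[int],
    core_electrode: int,
    core_events: Sequence[SpikeEvent],
    sample_rate: float,
    params: SortingParams | None = None,
) -> WaveformSet:
    """Cut, up-sample (cubic, 6x) and trough-align spike waveforms.

    Spikes whose window (plus alignment margin) exceeds the trace bounds are
    skipped with a log entry.
    """
    params = params or SortingParams()
    ids = [int(e) for e in electrode_ids]
    pre, post = params.window_samples(sample_rate)
    margin = max(1, int(round(params.align_margin_ms * 1e-3 * sample_rate)))
    n = traces.shape[1]
    samples = np.asarray([ev.sample for ev in core_events], dtype=int)
    keep = (samples - pre - margin >= 0) & (samples + post + margin < n)
    if (~keep).any():
        logger.info("skipped %d edge spikes on electrode %d", int((~keep).sum()), core_electrode)
    samples = samples[keep]
    if samples.size == 0:
        raise NoUnitError("no in-bounds spikes to extract")

    assist = _rank_assist_electrodes(traces, ids, core_electrode, samples, sample_rate, params)
    rows = {e: ids.index(e) for e in assist}
    up = params.upsample_factor
    n_up = (pre + post) * up + 1
    offsets = (np.arange(n_up) - pre * up) / up  # raw-sample units around the trough

    waveforms = np.empty((samples.size, len(assist), n_up))
    core_amp = np.empty(samples.size)
    aligned = np.empty(samples.size, dtype=int)
    fine = np.empty(samples.size)
    core_seg_row = assist.index(core_electrode)
    for si, s in enumerate(samples):
        a, b = s - pre - margin, s + post + margin + 1
        t_raw = np.arange(a, b, dtype=float)
        seg = traces[[rows[e] for e in assist], a:b]
        spl = CubicSpline(t_raw, seg, axis=1)
        # locate the interpolated core trough within +-margin of the event
        t_fine = np.arange((s - margin) * up, (s + margin) * up + 1) / up
        core_fine = spl(t_fine)[core_seg_row]
        t_trough = t_fine[int(np.argmin(core_fine))]
        cut = spl(t_trough + offsets)
        waveforms[si] = cut
        core_amp[si] = -cut[core_seg_row, pre * up]
        aligned[si] = int(round(t_trough))
        fine[si] = t_trough
    return WaveformSet(
        spike_samples=aligned,
        spike_times_fine=fine,
        waveforms=waveforms,
        assist_ids=tuple(assist),
        core_electrode=core_electrode,
        core_amplitudes=core_amp,
        sample_rate=sample_rate,
        upsample_factor=up,
    )


def _seed_int(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence(entropy=(int(seed) & 0x7FFFFFFF, salt)).generate_state(1)[0] % (2**31 - 1))


def _pca_project(X: np.ndarray, n_components: int) -> tuple[np.ndarray, PCA]:
    n_comp = max(1, min(n_components, min(X.shape) - 1))
    pca = PCA(n_components=n_comp, svd_solver="full")
    return pca.fit_transform(X), pca


def cluster_spikes(
    wset: WaveformSet, params: SortingParams | None = None, seed: int = 0
) -> ClusterSolution:
    """PCA + k-means over k candidates; the mean silhouette selects k.

    Returns a single-cluster solution when there are too few spikes to split
    (``fallback=True``) or when no candidate k reaches ``silhouette_min``
    (a homogeneous event set: splitting it would only carve noise).
    """
    params = params or SortingParams()
    n = wset.n_spikes
    single = ClusterSolution(
        k=1, labels=np.zeros(n, dtype=int), silhouette_values=None, mean_silhouette=float("nan")
    )
    if n < 2 * params.min_cluster_spikes:
        single.fallback = True
        return single

    Xp, _ = _pca_project(wset.features(), params.n_pca_components)
    best: ClusterSolution | None = None
    per_k: dict[int, float] = {}
    for k in params.k_candidates:
        if k >= n:
            continue
        km = KMeans(n_clusters=k, n_init=params.kmeans_restarts, random_state=_seed_int(seed, k))
        labels = km.fit_predict(Xp)
        if len(np.unique(labels)) < 2:
            continue
        sil = silhouette_samples(Xp, labels)
        mean = float(sil.mean())
        per_k[k] = mean
        if best is None or mean > best.mean_silhouette:
            best = ClusterSolution(k, labels, sil, mean, per_k)
    if best is None:
        single.fallback = True
        return single
    best.per_k_mean = per_k
    if best.mean_silhouette <= params.silhouette_min:
        single.per_k_mean = per_k
        return single
    return best


def accept_clusters(
    solution: ClusterSolution, wset: WaveformSet, params: SortingParams | None = None
) -> list[np.ndarray]:
    """Template-candidate clusters, largest core amplitude first.

    A k>=2 cluster qualifies if its mean member silhouette exceeds
    ``silhouette_min`` *and* its biggest spike reaches
    ``amplitude_fraction`` (80%) of the largest core-electrode amplitude.
    The single-cluster solution is its own (sole) candidate.
    """
    params = params or SortingParams()
    global_max = float(wset.core_amplitudes.max())
    candidates: list[tuple[float, np.ndarray]] = []
    for lab in np.unique(solution.labels):
        members = np.flatnonzero(solution.labels == lab)
        peak = float(wset.core_amplitudes[members].max())
        if solution.k >= 2:
            if solution.cluster_mean_silhouette(lab) <= params.silhouette_min:
                continue
            if peak < params.amplitude_fraction * global_max:
                continue
        candidates.append((-peak, members))
    candidates.sort(key=lambda t: t[0])
    return [m for _, m in candidates]


def build_template(
    traces: np.ndarray,
    electrode_ids: Sequence[int],
    spike_samples: np.ndarray,
    core_electrode: int,
    sample_rate: float,
    params: SortingParams | None = None,
    label: int = 0,
    block_index: int = 0,
    spike_times_fine: np.ndarray | None = None,
) -> BlockFootprint:
    """Median spike-triggered template on every block electrode.

    With fractional trough positions supplied, each spike window is
    resampled at its sub-sample offset before the median, so alignment
    jitter does not blunt the trough.
    """
    params = params or SortingParams()
    pre, post = params.window_samples(sample_rate)
    n = traces.shape[1]
    samples = np.asarray(spike_samples, dtype=int)
    keep = (samples - pre - 1 >= 0) & (samples + post + 1 < n)
    samples_kept = samples[keep]
    if samples_kept.size == 0:
        raise NoUnitError("no in-bounds spikes for template")
    fine_kept = None if spike_times_fine is None else np.asarray(spike_times_fine)[keep]
    windows = []
    grid = np.arange(-pre, post + 1, dtype=float)
    for i, s in enumerate(samples_kept):
        frac = float(fine_kept[i] - s) if fine_kept is not None else 0.0
        if frac:
            a, b = s - pre - 1, s + post + 2
            spl = CubicSpline(np.arange(a, b, dtype=float), traces[:, a:b], axis=1)
            windows.append(spl(s + frac + grid))
        else:
            windows.append(traces[:, s - pre : s + post + 1])
    template = np.median(np.stack(windows), axis=0)
    return BlockFootprint(
        label=label,
        block_index=block_index,
        electrode_ids=tuple(int(e) for e in electrode_ids),
        template=template,
        spike_samples=samples_kept,
        core_electrode=int(core_electrode),
        sample_rate=sample_rate,
        pre_samples=pre,
        spike_samples_fine=fine_kept,
    )


def match_residuals(
    wset: WaveformSet,
    template_up: np.ndarray,
    params: SortingParams | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Step II membership test; returns a boolean member mask over spikes.

    Residuals (spike - template on the assist electrodes) are projected onto
    principal components and split with 2-means.  The projection of the zero
    residual marks where a spike that *is* the template would land; if one
    centroid lies at least ``residual_ratio`` times closer to that point
    along the first component than the other, only its spikes are members,
    otherwise the whole event set matches the template.  The distance rule
    is only consulted when the residual split is a real cluster structure
    (mean silhouette above ``silhouette_min``): 2-means always cuts even
    pure-noise residuals in half, and an unlucky asymmetric noise cut could
    otherwise pass the ratio test and shed genuine member spikes.  The test
    is applied repeatedly to the surviving member set, so that several
    distinct contaminating populations (more than one neighbor unit firing
    into the core electrode) are shed one split at a time.
    """
    params = params or SortingParams()
    n = wset.n_spikes
    residuals = wset.features() - template_up.reshape(1, -1)
    mask = np.ones(n, dtype=bool)
    if n < 4 or float(np.ptp(residuals)) == 0.0:
        return mask
    for depth in range(8):
        idx = np.flatnonzero(mask)
        if idx.size < 4:
            break
        sub = residuals[idx]
        if float(np.ptp(sub)) == 0.0:
            break
        Xp, pca = _pca_project(sub, params.n_pca_components)
        km = KMeans(n_clusters=2, n_init=params.kmeans_restarts, random_state=_seed_int(seed, 2 + depth))
        labels = km.fit_predict(Xp)
        if len(np.unique(labels)) < 2:
            break
        if float(silhouette_samples(Xp, labels).mean()) <= params.silhouette_min:
            break
        zero_ref = pca.transform(np.zeros((1, sub.shape[1])))[0, 0]
        d = np.abs(km.cluster_centers_[:, 0] - zero_ref)
        lo, hi = int(np.argmin(d)), int(np.argmax(d))
        if d[hi] > 0 and d[lo] * params.residual_ratio <= d[hi]:
            mask[idx[labels != lo]] = False
        else:
            break
    return mask


def _subtract_template(traces: np.ndarray, fp: BlockFootprint) -> None:
    """Peel: subtract the footprint template at every member spike time.

    When fractional trough positions are known the template is shifted by
    the sub-sample offset (cubic interpolation) before subtraction;
    otherwise the residual left by half-sample misalignment scales with the
    trough slope and can itself re-cross the detection threshold.
    """
    pre = fp.pre_samples
    L = fp.template.shape[1]
    n = traces.shape[1]
    spline = CubicSpline(np.arange(L), fp.template, axis=1)
    fine = fp.spike_samples_fine
    for i, s in enumerate(fp.spike_samples):
        frac = float(fine[i] - s) if fine is not None else 0.0
        shifted = spline(np.arange(L) - frac) if frac else fp.template
        a = s - pre
        b = a + L
        ca, cb = max(a, 0), min(b, n)
        traces[:, ca:cb] -= shifted[:, ca - a : L - (b - cb)].astype(traces.dtype)


def sort_block(
    traces: np.ndarray,
    electrode_ids: Sequence[int],
    sample_rate: float,
    params: SortingParams | None = None,
    detection: DetectionParams | None = None,
    seed: int = 0,
    block_index: int = 0,
    noise_sd_by_electrode: Mapping[int, float] | None = None,
    day_index: int | None = None,
) -> list[BlockFootprint]:
    """Steps I-III on one block of *filtered* traces; footprints in discovery
    order.  Noise SDs are estimated once on the input traces (peeling removes
    spikes, not noise) unless supplied."""
    params = params or SortingParams()
    detection = detection or DetectionParams()
    ids = [int(e) for e in electrode_ids]
    work = np.array(traces, dtype=np.float32, copy=True)
    if noise_sd_by_electrode is None:
        noise_sd_by_electrode = {e: noise_sd(work[i]) for i, e in enumerate(ids)}

    units: list[BlockFootprint] = []
    exhausted: set[int] = set()
    iteration = 0
    while len(units) < params.max_units_per_block and iteration < params.max_units_per_block + len(ids):
        iteration += 1
        events = {}
        for i, e in enumerate(ids):
            if e in exhausted:
                continue
            evs = detect_spikes(work[i], noise_sd_by_electrode[e], sample_rate, detection, e)
            if len(evs) >= params.min_cluster_spikes:
                events[e] = evs
        if not events:
            break
        core = select_core_electrode(events)
        try:
            wset = extract_waveforms(work, ids, core, events[core], sample_rate, params)
        except NoUnitError:
            exhausted.add(core)
            continue
        if wset.n_spikes < params.min_cluster_spikes:
            exhausted.add(core)
            continue
        solution = cluster_spikes(wset, params, seed=_seed_int(seed, 100 + iteration))
        placed = False
        for members in accept_clusters(solution, wset, params):
            template_up = np.median(wset.waveforms[members], axis=0)
            member_mask = match_residuals(wset, template_up, params, seed=_seed_int(seed, 200 + iteration))
            member_samples = wset.spike_samples[member_mask]
            if member_samples.size < params.min_cluster_spikes:
                continue
            fp = build_template(
                work, ids, member_samples, core, sample_rate, params,
                label=len(units), block_index=block_index,
                spike_times_fine=wset.spike_times_fine[member_mask],
            )
            fp.day_index = day_index
            _subtract_template(work, fp)
            units.append(fp)
            logger.info(
                "block %d: unit %d on core electrode %d, %d spikes (k=%d, mean silhouette %.3f)",
                block_index, fp.label, core, fp.n_spikes, solution.k, solution.mean_silhouette,
            )
            exhausted.clear()
            placed = True
            break
        if not placed:
            exhausted.add(core)
    return units
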