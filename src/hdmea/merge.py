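"""Step III: waveform matching coefficient and footprint merging.

Two footprints of the same neuron recorded in the same block agree almost
perfectly (matching coefficient, MC > 0.95); footprints recorded in two
*adjacent* blocks see the neuron through partially different electrodes and
a slightly looser MC > 0.85 applies.  The MC of a footprint pair is

    MC = 2 * sum_e sum_t ov(a_et, b_et) / (sum|a| + sum|b|),

computed over the electrodes common to both configurations with both
waveforms aligned at their core trough, where ``ov`` is the sample-wise
shared area: ``min(|a|, |b|)`` where the two waveforms agree in sign and 0
where they do not.  MC is symmetric, equals 1 for identical footprints and
0 for sign-inverted ones.  Footprints whose pairwise MC exceeds the
applicable threshold are joined into connected components and merged into
array-wide global footprints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .layout import BlockConfiguration
from .sort import BlockFootprint

logger = logging.getLogger(__name__)

__all__ = [
    "MergeParams",
    "GlobalFootprint",
    "NoCommonElectrodesError",
    "matching_coefficient",
    "overlap_area_mc",
    "merge_block_footprints",
]


class NoCommonElectrodesError(ValueError):
    """The two footprints share no electrode; their MC is undefined."""


@dataclass(frozen=True)
class MergeParams:
    mc_same_block: float = 0.95
    mc_adjacent_block: float = 0.85

    def __post_init__(self):
        for v in (self.mc_same_block, self.mc_adjacent_block):
            if not 0 < v <= 1:
                raise ValueError("MC thresholds must lie in (0, 1]")


@dataclass
class GlobalFootprint:
    """Array-wide single-unit footprint merged from one or more block
    footprints.  On electrodes covered by several contributors the stored
    waveform is their spike-count-weighted average; electrodes no
    contributing block recorded are absent (missing, not zero)."""

    unit_id: int
    electrode_ids: tuple[int, ...]
    template: np.ndarray  # (n_electrodes, n_samples)
    contributors: list[BlockFootprint] = field(default_factory=list)
    day_index: int | None = None

    @property
    def n_spikes(self) -> int:
        return sum(fp.n_spikes for fp in self.contributors)

    @property
    def block_indices(self) -> tuple[int, ...]:
        return tuple(sorted({fp.block_index for fp in self.contributors}))

    @property
    def core_electrode(self) -> int:
        row, _ = np.unravel_index(np.argmin(self.template), self.template.shape)
        return int(self.electrode_ids[int(row)])

    def electrode_row(self, electrode_id: int) -> int:
        return self.electrode_ids.index(int(electrode_id))


def overlap_area_mc(a: np.ndarray, b: np.ndarray) -> float:
    """MC of two already-aligned equal-shape waveform arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("aligned waveform arrays must have equal shapes")
    agree = (a * b) > 0
    ov = np.where(agree, np.minimum(np.abs(a), np.abs(b)), 0.0)
    denom = np.abs(a).sum() + np.abs(b).sum()
    if denom == 0:
        return 1.0  # two identically silent footprints
    return float(2.0 * ov.sum() / denom)


def _aligned_common(fpA: BlockFootprint | GlobalFootprint, fpB: BlockFootprint | GlobalFootprint):
    common = sorted(set(fpA.electrode_ids) & set(fpB.electrode_ids))
    if not common:
        raise NoCommonElectrodesError("footprints share no electrode")
    rowsA = [fpA.electrode_ids.index(e) for e in common]
    rowsB = [fpB.electrode_ids.index(e) for e in common]
    tA, tB = fpA.template[rowsA], fpB.template[rowsB]
    # align at each footprint's global trough time
    ja = int(np.unravel_index(np.argmin(fpA.template), fpA.template.shape)[1])
    jb = int(np.unravel_index(np.argmin(fpB.template), fpB.template.shape)[1])
    left = min(ja, jb)
    right = min(tA.shape[1] - ja, tB.shape[1] - jb)
    return tA[:, ja - left : ja + right], tB[:, jb - left : jb + right]


def matching_coefficient(
    fpA: BlockFootprint | GlobalFootprint, fpB: BlockFootprint | GlobalFootprint
) -> float:
    """MC of two footprints on their common electrodes, trough-aligned.

    Raises :class:`NoCommonElectrodesError` when the configurations share no
    electrode (an undefined comparison, deliberately not reported as 0).
    """
    tA, tB = _aligned_common(fpA, fpB)
    return overlap_area_mc(tA, tB)


def _block_adjacency(blocks: Sequence[BlockConfiguration]) -> set[frozenset[int]]:
    adj: set[frozenset[int]] = set()
    sets = {b.block_index: set(b.electrode_ids) for b in blocks}
    idx = sorted(sets)
    for i, bi in enumerate(idx):
        for bj in idx[i + 1 :]:
            if sets[bi] & sets[bj]:
                adj.add(frozenset((bi, bj)))
    return adj


def _merge_component(fps: list[BlockFootprint], unit_id: int) -> GlobalFootprint:
    # common aligned window length across contributors
    troughs = [int(np.unravel_index(np.argmin(fp.template), fp.template.shape)[1]) for fp in fps]
    left = min(troughs)
    right = min(fp.template.shape[1] - j for fp, j in zip(fps, troughs))
    electrodes = sorted(set().union(*(fp.electrode_ids for fp in fps)))
    tpl = np.zeros((len(electrodes), left + right))
    wsum = np.zeros(len(electrodes))
    for fp, j in zip(fps, troughs):
        cut = fp.template[:, j - left : j + right]
        for row, e in enumerate(fp.electrode_ids):
            g = electrodes.index(e)
            tpl[g] += fp.n_spikes * cut[row]
            wsum[g] += fp.n_spikes
    tpl /= np.maximum(wsum, 1)[:, None]
    day = fps[0].day_index
    return GlobalFootprint(
        unit_id=unit_id,
        electrode_ids=tuple(electrodes),
        template=tpl,
        contributors=list(fps),
        day_index=day,
    )


def merge_block_footprints(
    footprints: Sequence[BlockFootprint],
    blocks: Sequence[BlockConfiguration],
    params: MergeParams | None = None,
) -> list[GlobalFootprint]:
    """Merge block footprints into global footprints.

    Same-block pairs merge at MC > ``mc_same_block`` (0.95), adjacent-block
    pairs (blocks sharing at least one electrode) at MC > ``mc_adjacent_block``
    (0.85); non-adjacent pairs are never compared.  Connected components of
    the resulting graph become :class:`GlobalFootprint` objects; the total
    accepted spike count is conserved.  Output order is deterministic
    regardless of input order (sorted by block index, then label).
    """
    params = params or MergeParams()
    fps = sorted(footprints, key=lambda fp: (fp.block_index, fp.label, -fp.n_spikes))
    adjacency = _block_adjacency(blocks)

    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(fps)))
    for i in range(len(fps)):
        for j in range(i + 1, len(fps)):
            bi, bj = fps[i].block_index, fps[j].block_index
            if bi == bj:
                thr = params.mc_same_block
            elif frozenset((bi, bj)) in adjacency:
                thr = params.mc_adjacent_block
            else:
                continue
            try:
                mc = matching_coefficient(fps[i], fps[j])
            except NoCommonElectrodesError:
                continue
            if mc > thr:
                g.add_edge(i, j, mc=mc)

    merged = []
    comps = sorted(nx.connected_components(g), key=min)
    for unit_id, comp in enumerate(comps):
        members = [fps[i] for i in sorted(comp)]
        if len(members) > 1:
            # audit: same-block pairs pulled together only transitively
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    if members[a].block_index == members[b].block_index:
                        mc = matching_coefficient(members[a], members[b])
                        if mc <= params.mc_same_block:
                            logger.warning(
                                "transitive same-block merge with MC %.3f (blocks %d/%d)",
                                mc, members[a].block_index, members[b].block_index,
                            )
        merged.append(_merge_component(members, unit_id))
    return merged
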