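"""Iterative block sorter: core selection, waveform extraction, clustering,
acceptance rules, template building, residual matching, and peeling."""

import numpy as np
import pytest

from hdmea.detect import SpikeEvent, detect_block
from hdmea.merge import matching_coefficient
from hdmea.simulate import GroundTruthUnit, SessionPlan, simulate_session, unit_footprint
from hdmea.sort import (
    ClusterSolution,
    NoUnitError,
    SortingParams,
    accept_clusters,
    build_template,
    cluster_spikes,
    extract_waveforms,
    match_residuals,
    select_core_electrode,
    sort_block,
)

FS = 20_000.0


class TestSelectCoreElectrode:
    def test_largest_amplitude_wins(self):
        ev = {1: [SpikeEvent(1, 5, -90.0)], 2: [SpikeEvent(2, 9, -120.0)]}
        assert select_core_electrode(ev) == 2

    def test_single_active_electrode(self):
        assert select_core_electrode({4: [SpikeEvent(4, 0, -30.0)]}) == 4

    def test_tie_broken_by_lower_id(self):
        ev = {9: [SpikeEvent(9, 1, -50.0)], 3: [SpikeEvent(3, 2, -50.0)]}
        assert select_core_electrode(ev) == 3

    def test_no_events_raises(self):
        with pytest.raises(NoUnitError):
            select_core_electrode({1: []})

    def test_core_is_electrode_nearest_soma(self, three_unit_sort):
        lay = three_unit_sort["layout"]
        events = three_unit_sort["events"]
        core = select_core_electrode(events)
        ids = np.asarray(three_unit_sort["block"].electrode_ids)
        pos = lay.position(ids)
        # largest-amplitude unit is unit 2 (90 μV)
        u = three_unit_sort["units"][2]
        assert core == int(ids[int(np.argmin(np.hypot(pos[:, 0] - u.x, pos[:, 1] - u.y)))])


@pytest.fixture(scope="module")
def clean_single_unit(block_layout):
    """Noise-free 10 s block with one unit, with detected events."""
    lay, block = block_layout
    u = GroundTruthUnit(0, x=45, y=126, peak_amplitude=90, spatial_sigma=25, firing_rate=3.0)
    ses = simulate_session(lay, [block], [u], SessionPlan(duration_s=10.0, noise_sigma=0.0), seed=5)
    traces = ses.blocks[0].traces.astype(np.float64)
    ids = list(block.electrode_ids)
    truth = ses.truth.spikes_for(0, 0)
    core = lay.electrode_at(7, 2)  # nearest electrode to (45, 126)
    events = [SpikeEvent(core, int(s), float(traces[ids.index(core), s])) for s in truth]
    return lay, block, u, traces, ids, core, events, truth


class TestExtractWaveforms:
    def test_noise_free_waveforms_match_inserted_template(self, clean_single_unit):
        lay, block, u, traces, ids, core, events, _ = clean_single_unit
        ws = extract_waveforms(traces, ids, core, events, FS)
        ref = np.median(ws.waveforms, axis=0)
        dev = np.abs(ws.waveforms - ref).max()
        assert dev < 0.01 * 90  # identical up to interpolation tolerance

    def test_upsampled_length_is_six_fold(self, clean_single_unit):
        lay, block, u, traces, ids, core, events, _ = clean_single_unit
        p = SortingParams()
        ws = extract_waveforms(traces, ids, core, events, FS, p)
        pre, post = p.window_samples(FS)
        assert ws.waveforms.shape[2] == (pre + post) * p.upsample_factor + 1
        assert ws.waveforms.shape[1] == p.n_assist_electrodes

    def test_edge_spike_is_skipped(self, clean_single_unit):
        lay, block, u, traces, ids, core, events, _ = clean_single_unit
        early = [SpikeEvent(core, 3, -90.0)] + events
        ws = extract_waveforms(traces, ids, core, early, FS)
        assert ws.n_spikes == len(events)

    def test_core_amplitude_is_trough_magnitude(self, clean_single_unit):
        lay, block, u, traces, ids, core, events, _ = clean_single_unit
        ws = extract_waveforms(traces, ids, core, events, FS)
        assert np.all(ws.core_amplitudes > 0)
        # soma sits 9 μm off the core electrode: Gaussian weight applies
        expected = 90.0 * np.exp(-(9.0**2) / (2 * 25.0**2))
        assert ws.core_amplitudes.mean() == pytest.approx(expected, rel=0.02)


class TestClusterSpikes:
    def _waveset(self, templates, counts, noise, seed=0):
        """Synthetic WaveformSet from per-unit assist-electrode templates."""
        from hdmea.sort import WaveformSet

        rng = np.random.default_rng(seed)
        w, labels = [], []
        for t, (tpl, n) in enumerate(zip(templates, counts)):
            w.append(tpl[None] + rng.normal(0, noise, (n,) + tpl.shape))
            labels += [t] * n
        w = np.concatenate(w)
        order = rng.permutation(len(w))
        amps = -w[:, 0].min(axis=1)
        return (
            WaveformSet(np.arange(len(w))[order] * 100 + 500, (np.arange(len(w))[order] * 100 + 500).astype(float),
                        w[order], tuple(range(w.shape[1])), 0, amps[order], FS, 6),
            np.asarray(labels)[order],
        )

    def _two_templates(self):
        t = np.linspace(0, 3, 361)
        s1 = -np.exp(-((t - 1.0) ** 2) / 0.02)
        s2 = -np.exp(-((t - 1.0) ** 2) / 0.08) + 0.4 * np.exp(-((t - 1.7) ** 2) / 0.05)
        a1 = 80 * np.exp(-np.arange(10) / 3.0)
        a2 = 70 * np.exp(-np.arange(10)[::-1] / 4.0)
        return np.outer(a1, s1), np.outer(a2, s2)

    def test_distinct_units_split_with_k_two(self):
        tpl1, tpl2 = self._two_templates()
        ws, truth = self._waveset([tpl1, tpl2], [60, 60], noise=2.0)
        sol = cluster_spikes(ws, seed=1)
        assert sol.k == 2
        agree = max(
            (sol.labels == truth).mean(), (sol.labels != truth).mean()
        )
        assert agree >= 0.95
        assert sol.silhouette_values.min() >= -1 and sol.silhouette_values.max() <= 1

    def test_homogeneous_spikes_yield_no_acceptable_split(self):
        tpl1, _ = self._two_templates()
        ws, _ = self._waveset([tpl1], [80], noise=2.0)
        sol = cluster_spikes(ws, seed=1)
        assert sol.k == 1
        assert all(v <= 0.5 for v in sol.per_k_mean.values())

    def test_too_few_spikes_fall_back_flagged(self):
        tpl1, _ = self._two_templates()
        ws, _ = self._waveset([tpl1], [12], noise=1.0)
        sol = cluster_spikes(ws, SortingParams(min_cluster_spikes=10), seed=1)
        assert sol.k == 1 and sol.fallback


class TestAcceptClusters:
    def _solution(self, labels, sils):
        labels = np.asarray(labels)
        sils = np.asarray(sils, dtype=float)
        return ClusterSolution(len(np.unique(labels)), labels, sils, float(sils.mean()))

    def _wset(self, amps):
        from hdmea.sort import WaveformSet

        amps = np.asarray(amps, dtype=float)
        w = -amps[:, None, None] * np.ones((1, 1, 5))
        return WaveformSet(np.arange(amps.size), np.arange(amps.size).astype(float),
                           w, (0,), 0, amps, FS, 6)

    def test_small_amplitude_cluster_rejected(self):
        ws = self._wset([100, 100, 50, 50])
        sol = self._solution([0, 0, 1, 1], [0.9, 0.9, 0.9, 0.9])
        accepted = accept_clusters(sol, ws)
        assert len(accepted) == 1
        assert set(accepted[0]) == {0, 1}

    def test_low_silhouette_cluster_rejected(self):
        ws = self._wset([100, 100, 95, 95])
        sol = self._solution([0, 0, 1, 1], [0.9, 0.9, 0.4, 0.4])
        accepted = accept_clusters(sol, ws)
        assert len(accepted) == 1
        assert set(accepted[0]) == {0, 1}

    def test_candidates_ordered_by_amplitude(self):
        ws = self._wset([90, 90, 100, 100])
        sol = self._solution([0, 0, 1, 1], [0.9] * 4)
        accepted = accept_clusters(sol, ws)
        assert [set(a) for a in accepted] == [{2, 3}, {0, 1}]


class TestBuildTemplate:
    def test_noise_free_template_equals_inserted_footprint(self, clean_single_unit):
        lay, block, u, traces, ids, core, events, truth = clean_single_unit
        fp = build_template(traces, ids, truth, core, FS)
        true_fp = unit_footprint(u, lay, ids)
        trough = int(np.argmin(true_fp.min(axis=0)))
        pre = fp.pre_samples
        L = min(pre, trough)
        R = min(fp.template.shape[1] - pre, true_fp.shape[1] - trough)
        dev = np.abs(fp.template[:, pre - L : pre + R] - true_fp[:, trough - L : trough + R]).max()
        assert dev < 1e-3
        r, c = fp.trough_index
        assert fp.electrode_ids[r] == core

    def test_single_spike_template_is_that_window(self, clean_single_unit):
        lay, block, u, traces, ids, core, events, truth = clean_single_unit
        s = int(truth[1])
        fp = build_template(traces, ids, [s], core, FS)
        pre, post = SortingParams().window_samples(FS)
        np.testing.assert_allclose(fp.template, traces[:, s - pre : s + post + 1])

    def test_median_error_shrinks_with_spike_count(self):
        """Monte-Carlo: template error scales roughly as 1/sqrt(n)."""
        rng = np.random.default_rng(6)
        truth = -80 * np.exp(-((np.linspace(0, 3, 61) - 1.0) ** 2) / 0.02)

        def err(n):
            spikes = truth[None] + rng.normal(0, 6.0, (n, 61))
            return np.abs(np.median(spikes, axis=0) - truth).mean()

        e50 = np.mean([err(50) for _ in range(20)])
        e500 = np.mean([err(500) for _ in range(20)])
        assert e500 < e50 / 2.0  # expect ~ 1/sqrt(10) ≈ 0.32


class TestMatchResiduals:
    def _wset_from(self, arrs):
        from hdmea.sort import WaveformSet

        w = np.stack(arrs)
        amps = -w[:, 0].min(axis=1)
        n = len(arrs)
        return WaveformSet(np.arange(n), np.arange(n).astype(float), w,
                           tuple(range(w.shape[1])), 0, amps, FS, 6)

    def test_template_spikes_all_members(self):
        rng = np.random.default_rng(2)
        tpl = np.outer(80 * np.exp(-np.arange(10) / 3), -np.exp(-((np.linspace(0, 3, 361) - 1) ** 2) / 0.02))
        ws = self._wset_from([tpl + rng.normal(0, 2.0, tpl.shape) for _ in range(60)])
        assert match_residuals(ws, tpl, seed=3).all()

    def test_exact_template_spikes_all_members(self):
        tpl = np.outer([50.0, 30.0], -np.exp(-((np.linspace(0, 3, 361) - 1) ** 2) / 0.02))
        ws = self._wset_from([tpl.copy() for _ in range(20)])
        assert match_residuals(ws, tpl, seed=3).all()

    def test_contaminating_unit_excluded(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0, 3, 361)
        tpl = np.outer(80 * np.exp(-np.arange(10) / 3), -np.exp(-((t - 1) ** 2) / 0.02))
        other = np.outer(60 * np.exp(-np.arange(10)[::-1] / 2), -np.exp(-((t - 1) ** 2) / 0.09) + 0.4 * np.exp(-((t - 1.8) ** 2) / 0.04))
        arrs = [tpl + rng.normal(0, 2, tpl.shape) for _ in range(50)]
        arrs += [other + rng.normal(0, 2, tpl.shape) for _ in range(50)]
        ws = self._wset_from(arrs)
        mask = match_residuals(ws, tpl, seed=3)
        truth = np.array([True] * 50 + [False] * 50)
        assert (mask == truth).mean() >= 0.95


class TestSortBlock:
    def test_noise_free_single_unit_fully_peeled(self, clean_single_unit):
        lay, block, u, traces, ids, core, events, truth = clean_single_unit
        sd = {e: 1.0 for e in ids}  # nominal 1 μV floor for thresholding
        fps = sort_block(traces, ids, FS, seed=1, noise_sd_by_electrode=sd)
        assert len(fps) == 1
        assert fps[0].n_spikes == truth.size
        assert fps[0].core_electrode == core

    def test_pure_noise_block_yields_nothing(self, block_layout):
        lay, block = block_layout
        ses = simulate_session(lay, [block], [], SessionPlan(duration_s=10.0, noise_sigma=6.0), seed=21)
        ids = list(block.electrode_ids)
        _, sds, filtered = detect_block(ses.blocks[0].traces, ids, FS)
        assert sort_block(filtered, ids, FS, seed=1, noise_sd_by_electrode=sds) == []

    def test_fixed_seed_is_reproducible(self, three_unit_sort):
        fps1 = three_unit_sort["footprints"]
        fps2 = sort_block(
            three_unit_sort["filtered"],
            list(three_unit_sort["block"].electrode_ids),
            FS,
            seed=2,
            noise_sd_by_electrode=three_unit_sort["noise_sd"],
        )
        assert len(fps1) == len(fps2)
        for a, b in zip(fps1, fps2):
            assert np.array_equal(a.template, b.template)
            assert np.array_equal(a.spike_samples, b.spike_samples)

    def test_three_overlapping_units_recovered(self, three_unit_sort):
        """The acceptance-grade scenario, checked at module level too."""
        fps = three_unit_sort["footprints"]
        assert len(fps) == 3
        ses = three_unit_sort["session"]
        filtered = three_unit_sort["filtered"]
        ids = list(three_unit_sort["block"].electrode_ids)
        oracles = [
            build_template(filtered, ids, ses.truth.spikes_for(u, 0), 0, FS) for u in range(3)
        ]
        matched = set()
        for fp in fps:
            mcs = [matching_coefficient(fp, o) for o in oracles]
            best = int(np.argmax(mcs))
            matched.add(best)
            assert max(mcs) >= 0.9
        assert matched == {0, 1, 2}

    def test_no_duplicate_of_peeled_unit(self, three_unit_sort):
        """Re-sorting already-peeled traces finds no copy of a removed unit
        (the over-sorting guard)."""
        fps = three_unit_sort["footprints"]
        filtered = np.array(three_unit_sort["filtered"], copy=True)
        from hdmea.sort import _subtract_template

        for fp in fps:
            _subtract_template(filtered, fp)
        ids = list(three_unit_sort["block"].electrode_ids)
        again = sort_block(filtered, ids, FS, seed=2, noise_sd_by_electrode=three_unit_sort["noise_sd"])
        for fp in again:
            assert all(matching_coefficient(fp, old) < 0.9 for old in fps)
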