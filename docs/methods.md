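# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `hdmea`. It is the package's own account; every empirical
statement here is computed by the test suite or by `scripts/acceptance.py`.

## Array model and block tiling

The array is a regular rectangular grid (pitch 18 μm, row-major 0-based ids,
origin top-left, y increasing downward) with a readout constraint of 126
simultaneous channels. A region of interest is scanned with 6 × 18-electrode
blocks (≈ 90 × 306 μm, within the readout budget) at 25% electrode overlap.

Exact 25% overlap is impossible with rigid rectangular window shifts
(27 electrodes is not a whole number of 6-wide columns or 18-tall rows), so
blocks after the first are electrode *sets*: the next
⌈0.75·B⌉ = 81 uncovered electrodes in scan order — bands of 18 rows, columns
left to right, rows top to bottom within a column, i.e. the acquisition
order "smaller y, then larger x" — plus the ⌊0.25·B⌋ = 27 electrodes of the
previous block closest (Euclidean; ties by ascending electrode id, for
determinism) to the centroid of the new electrodes. Interior blocks
therefore hold exactly 108 electrodes and consecutive blocks share exactly
27. The tiling is deterministic and covers the region.

A pure 18 μm rectangular grid cannot reproduce an 11,011-electrode
floor plan over 2 × 1.75 mm²; the synthetic 99 × 111 default (10,989
electrodes over 1980 × 1764 μm) approximates the density and makes no claim
to match an exact commercial electrode count.

## Synthetic recordings

A ground-truth unit is a point soma at (x, y) with:

* **spatial decay** — the trough seen by an electrode at distance d is
  `-A·exp(-d²/(2σ_s²))`; defaults A ∈ [60 … 300] μV depending on scenario,
  σ_s ≈ 20–28 μm (chosen so that 50%-threshold footprint areas land in the
  few-thousand μm² range typical of somatic footprints on such arrays);
* **waveform** — a unit-normalized biphasic shape over 3 ms: a Gaussian
  trough (FWHM = `trough_width_ms`, default 0.3 ms) followed by a positive
  overshoot (default ratio 0.3, delayed by 1.7 × the trough width), min
  exactly −1 after normalization, trough one third into the support so a
  1 ms pre / 2 ms post window captures it;
* **firing** — homogeneous Poisson (default 2 Hz) thinned by an absolute
  refractory period (default 2 ms); thinning keeps the first event of any
  too-close pair, so the minimum inter-spike interval is guaranteed;
* **noise** — i.i.d. Gaussian per electrode sample (default σ = 6 μV).

Blocks are rendered independently (they are recorded sequentially in
reality, so they share no noise and each gets its own spike train). Every
inserted spike is logged with its sample index and true per-electrode trough
magnitudes; subtracting all logged insertions from a noise-free rendering
leaves exactly zero, which the suite asserts. All randomness flows from
`numpy.random.SeedSequence` spawning, so a fixed seed reproduces bit-identical
output and a one-day series equals a single-session render.

Multi-day series apply per-day modifiers: geometric amplitude decay
(`(1-r)^d`), linear soma drift, dropout, and forced silence of chosen units
during chosen blocks — the *silent-block artifact* of scanned acquisition,
where a neuron that happened not to fire while its block was recorded is
missing from the merged footprint.

`synthesize_day_footprints` additionally produces *footprint-level* day
series without trace rendering: each unit contributes its true template on
its home block plus i.i.d. template noise (default 0.4 μV/sample,
the residual noise floor of a median over ~80 spikes of 2.75 μV filtered
noise: 1.2533·σ_f/√n). This is what the merge- and tracking-level tests run
on; the sorter itself is exercised on full renders.

What the simulator does **not** emulate: spatially correlated or
non-Gaussian noise, bursting and rate non-stationarity, waveform changes
with bursting, electrode-to-electrode gain differences, temporally
overlapping spike *shapes* beyond linear summation, and dendritic/axonal
footprint structure (the Gaussian is radially symmetric). Passing tests
therefore demonstrate algorithmic correctness under the stated model, not
performance on tissue data.

## Detection

Traces are band-pass filtered 500–3000 Hz with a 2nd-order Butterworth
applied forward–backward (zero phase, so trough timing is unbiased — later
stages align waveforms at the trough sample). The per-electrode noise SD is
the MAD estimate `median(|x|)/0.6745`, which a 1% contamination of large
spikes barely moves (asserted at < 5% bias in the suite). Events are local
minima of excursions below −5.5 × noise SD with a 1 ms per-electrode dead
time (the dead time is not specified by the published parameter set; it
prevents double-counting multi-sample excursions). The event time is the
negative peak, not the threshold crossing, because peak alignment is what
waveform averaging needs. The noise SD is per-electrode; whether the
original analysis used a per-electrode or global estimate is unknowable from
the published description, and per-electrode is the safer choice on
heterogeneous arrays.

Note that white noise of σ = 6 μV has ≈ 2.75 μV SD inside the 500–3000 Hz
band, so the effective threshold on rendered data is ≈ 15 μV.

The activity map records, per *recorded* electrode, the largest magnitude
among negative event amplitudes (0 if silent); electrodes never recorded are
missing, not zero. Day-level activity counts use a 50 μV display floor.

## Block sorting

One iteration of the sorter:

1. **Core electrode** — the electrode whose largest negative event amplitude
   is maximal (ties to the lower id).
2. **Waveforms** — for each core event, windows of 1 ms pre / 2 ms post
   (plus a 0.25 ms alignment margin) are cut on the 10 electrodes with the
   largest negative deflections at the core spike times (core included),
   cubic-spline up-sampled ×6 and re-aligned at the interpolated core
   trough. Fractional trough positions are kept for sub-sample work later.
3. **Clustering** — concatenated waveforms are projected onto the first 5
   principal components and k-means (10 restarts, seeded) is run for
   k ∈ {2, 3, 4, 5}; the k with the largest mean silhouette value wins.
   If no k reaches a mean silhouette above 0.5, the event set is treated as
   one homogeneous cluster: a lone unit produces exactly this signature
   (forced splits of its noise carry silhouettes ≈ 0.2), and without this
   rule no isolated unit could ever be accepted.
4. **Acceptance** — a cluster is a template candidate if its members' mean
   silhouette exceeds 0.5 *and* its biggest spike reaches 80% of the
   largest core-electrode amplitude; candidates are processed
   largest-amplitude first.
5. **Residual matching** — the candidate's median template (on the assist
   electrodes, up-sampled domain) is subtracted from *all* core-electrode
   spikes; residuals are PCA-projected and split with 2-means. The
   projection of the zero residual marks where a spike identical to the
   template lands. If one centroid is at least 2× closer to that point
   along the first component, only its spikes are members; otherwise the
   split was spurious and all spikes match. Two robustness refinements,
   both documented design choices of this implementation: (a) the distance
   rule is consulted only when the residual split itself is genuine
   (mean silhouette > 0.5) — 2-means always cuts even pure-noise residuals
   in half, and an unlucky asymmetric noise cut can pass the ratio test and
   shed real member spikes; (b) the test is applied recursively to the
   surviving member set, shedding one contaminant population per pass,
   because a single k=2 split cannot isolate the template unit when *two*
   neighbor units fire into the same core electrode.
6. **Footprint & peeling** — the footprint is rebuilt from the member
   spikes as the per-electrode median over all block electrodes, each
   window resampled at its fractional trough offset (sub-sample alignment;
   without it the residual of a peeled spike scales with trough slope ×
   half-sample jitter and can re-cross threshold, spawning spurious
   remnant units). The template, shifted per spike by its fractional
   offset, is permanently subtracted from the traces.

The loop repeats until no electrode retains ≥ 10 supra-threshold events
(`min_cluster_spikes`, a stopping floor absent from the published
description; it also suppresses clusters of chance noise crossings) or 20
units were found (`max_units_per_block`, a loop bound). A core electrode
that yields no acceptable candidate is marked exhausted until the next
successful peel changes the landscape; every iteration either removes ≥ 10
events or exhausts an electrode, so termination is guaranteed. Noise SDs
are estimated once on the input traces and reused across iterations —
peeling removes spikes, not noise. With a fixed seed the entire sort is
bit-reproducible.

Known limitation: spikes of two units overlapping *in time* sum linearly,
match neither template, and are shed by residual matching; template peeling
does not re-resolve them. At the default 2 Hz rates such collisions are a
few per 40 s block and remain below the 10-spike cluster floor; at several
Hz per unit they can accumulate into small low-MC remnant clusters.

## Matching coefficient and merging

`MC = 2·Σ ov / (Σ|a| + Σ|b|)` over the electrodes common to both footprints
and their trough-aligned overlapping samples, where `ov = min(|a|,|b|)`
where the signs agree and 0 otherwise (opposite-polarity content must not
count as shared area). MC is symmetric, 1 for identical footprints, 0 for
sign-inverted ones; a pair with no common electrode is an *undefined*
comparison and raises, never returns 0. The implementation is verified
against a brute-force sample-wise oracle to 1e-9 on 1,000 random pairs.

Footprints from the same block merge at MC > 0.95, footprints from adjacent
blocks (sharing ≥ 1 electrode — the 25% overlap is the comparison substrate)
at MC > 0.85; non-adjacent blocks are never compared. Connected components
of that graph become global footprints; on shared electrodes contributors
are combined by spike-count-weighted averaging (the combination rule is not
prescribed anywhere; weighting by evidence is the natural choice), total
spike counts are conserved, and electrodes no contributor recorded stay
missing. Same-block pairs joined only transitively at MC ≤ 0.95 are kept
merged but logged as conflicts. Output is deterministic under input
permutation (components ordered by their smallest contributor).

Because MC's denominator integrates |waveform| over *all* common electrodes
and samples, the independent noise floors of two templates depress MC
roughly by the ratio of noise area to signal area. Footprints built from
many spikes of large units (≥ 150 μV) keep same-unit MC comfortably above
0.85–0.95; for ~80 μV units with ~0.4 μV template noise the same comparison
hovers near the threshold. This is a real property of the statistic, not an
implementation artifact, and drives the amplitude range chosen for the
tracking study below.

## Day tracking and CF metrics

Footprints generated from the same block configuration are compared between
consecutive recording days; pairs with MC > 0.85 are candidate links,
assigned one-to-one greedily by descending MC (ties by unit order — the
assignment rule is unspecified in the published description and greedy is
deterministic). When a unit spans several blocks, the link MC is the best
same-block contributor pair. Chains are assembled transitively; a missing
day ends the chain (no gap bridging), and only chains spanning ≥ 7 recording
days enter the reported set (shorter chains remain available raw).

Per day and unit:

* **CF amplitude** — |global minimum| of the footprint (μV).
* **CF location** — the per-electrode negative-peak amplitude map is
  cubic-spline interpolated (`RectBivariateSpline`) on the largest fully
  covered electrode patch around the core (grown greedily up to ±4
  electrodes; at least 4 × 4 is required, else the electrode position is
  returned with a fallback flag) and evaluated on a 2 μm grid; the argmax is
  the CF location. The stated spatial resolution (2 μm) wins over a literal
  "up-sampling by a factor of 100" of an 18 μm pitch, which would give
  0.18 μm and contradict it.
* **CF area** — electrodes above 50% of the CF amplitude, restricted to the
  8-connected component containing the core electrode, × pitch² = 324 μm²
  per electrode (electrode-count based, not interpolated-surface area,
  following the electrode-set definition of the area). Additional
  disconnected supra-threshold components raise the multi-center count.
* **Movement distance** — Euclidean distance between CF locations of
  consecutive days ("abs of the location difference" read as the planar
  norm); undefined, not zero, without a previous day.

Quality control mirrors the manual evaluation criteria: days with CF
amplitude < 50 μV are excluded from statistics; units with multiple
footprint centers are excluded; when the recorded electrode set of a day is
known, a footprint missing recorded coverage is flagged as a silent-block
artifact and the unit is excluded only if a missing electrode is 8-adjacent
to the CF-area component (the operational reading of "the central footprint
area was partially missing" — adjacency is the weakest condition under
which the area estimate itself could be truncated). The published
criterion (1), "different heat-map shapes", is subsumed by the MC > 0.85
link rule and not re-implemented as a separate visual check.

Group statistics per day: *median* movement and *mean* CF amplitude and CF
area (matching the group statistics used for each quantity), each with
SEM = SD/√n over units.

## Problem sizes and study conditions

The suite and the acceptance script use desk-scale conditions chosen once:

* detection/sorting: one 108-electrode block, 40 s at 20 kHz, σ = 6 μV;
  three overlapping units at 60/75/90 μV (SNR ≥ 10, pairwise true-footprint
  MC 0.36–0.48) with default 2 Hz firing;
* sorting scores compare each recovered footprint against the *truth-log
  oracle template* — the median spike-triggered window at the true spike
  times of the same filtered traces — the fair reference for a
  spike-triggered estimate, and one that is independent of the sorter's
  own assignments;
* merging/tracking: footprint-level series (see above); the tracking cohort
  is 10 fixed units, two per block across five 18 × 6 blocks, amplitudes
  150–300 μV, σ_s 22–28 μm, 10 days of 3%/day decay and 2 μm/day drift.
  The cohort is a fixed study condition; the seed varies only template
  noise and spike counts. The weakest cohort member sits at the 0.85 MC
  threshold and reliably breaks once, giving a stable 9/10 full-span
  tracking across seeds — an intentional illustration of the retention
  boundary rather than a failure;
* the drift-free control uses noiseless templates, isolating grid
  quantization: movements are then exactly 0.

## Numerical choices

* float32 traces (memory); float64 everywhere above the trace level.
* Cubic splines for temporal up-sampling and template shifting; cubic
  bivariate splines for spatial interpolation.
* k-means seeded via `SeedSequence(entropy=(seed, salt))`, silhouette on the
  PCA projection with Euclidean distance.
* MC of two all-zero footprints is defined as 1 (identical silence).
* Ties: core electrode and carried-electrode selection by ascending id;
  candidate clusters by descending amplitude; day links by descending MC.

## Known limitations

* No within-session drift correction, no resolution of temporally
  overlapping spikes beyond peeling, no line-noise removal, no
  spatially correlated noise model by default.
* Tracking links only consecutive recorded days; a unit silent for a whole
  day restarts as a new chain.
* The MC noise-floor sensitivity discussed above makes sub-100 μV units
  hard to track at the 0.85 threshold under this simulator's conditions.
* Real-data effect sizes (population activity decline, unit-count decline,
  absolute CF-area distributions) are properties of tissue recordings and
  are not reproduced, though the simulator can emulate the trends
  qualitatively.
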