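# Methods

## Chamber and activation model

The chamber is a flat rectangular sheet of atrial tissue, 6 × 4 cm with a
0.1 cm node lattice, standing in for an unfolded atrium.  Every analysis
in the package is local or angular (clique-scale vector fits, sector
angles, segment coherence), so the flattening preserves the quantities of
interest while keeping geometry exactly testable.

Activation is kinematic, not reaction–diffusion: each beat is a surface of
local activation times (LAT) generated at a fixed conduction velocity.
Beat onsets advance by the cycle length plus Gaussian jitter.  Patterns:

* **focal** — `lat = onset + dist(node, center)/cv`; the LAT minimum sits
  at the source.
* **planar** — LAT affine in position along the wave normal.
* **rotor** — Archimedean-spiral phase map with one rotation per cycle
  length (wavelength `cv · CL`).
* **chaotic** — per beat, `n_wavelets` (default 4) point sources are
  re-drawn at random, plus 0–2 straight lines of conduction block; LAT is
  the earliest arrival on an 8-neighbour lattice graph with blocked edges
  removed (Dijkstra), i.e. wavefronts detour around the lines.  Wavelet
  positions are sampled from the sheet extended by a 2 cm margin so
  wavefronts also enter across the sheet edges; without the margin, edge
  regions would see systematically inward-travelling waves and two
  independent chaotic maps would agree there far above chance, which
  contradicts the very property (poor reproducibility) the pattern is
  meant to exhibit.  If block lines isolate a region from every source,
  its LAT falls back to straight-line conduction so LAT stays finite.

The chaotic generator is a behavioural stand-in: no quantitative model of
disorganized AF is implied beyond per-beat spatial decorrelation.

## Electrogram synthesis

Unipolar electrograms are a difference-of-Gaussians biphasic template
(lobe σ = 2 ms, lobe offset 2.5 ms, total width ≈ 10 ms) normalized to the
configured peak-to-peak amplitude (default 1 mV).  The positive (R) lobe
weight equals the *local context* — the fraction of tissue within 3 mm
already activated when the wavefront arrives — and the negative (S) lobe
weight its complement.  An electrode on a focal origin has local context
0 and therefore records a monophasic negative (QS) complex; mid-wave
electrodes record symmetric biphasic complexes.  A wide (σ = 10 ms)
low-frequency ventricular far-field template is superposed every 800 ms at
0.5× the atrial amplitude, and white noise (default sd 0.02 mV) is added.
Far-field timing, not morphology, is what the downstream ventricular score
exploits, so the template only needs to be broad and periodic.

A recording session moves a 4×4 grid catheter (3 mm equidistant pitch,
matching the commercial layout) through an itinerary of poses; LAT at each
electrode is bilinear-interpolated from the node lattice.  The canonical
study itinerary is a dense 9 × 5 tiling (45 poses, 0.6 s dwell each,
1 kHz sampling) whose clique footprints overlap, emulating continuous
chamber-wide acquisition; this leaves no coverage gaps (one-sided coverage
otherwise produces spurious half-ring centrifugal patterns at coverage
boundaries) and accumulates a few thousand used points per map, the same
order as clinical per-map counts.  Two stationary appendage channels (LAA,
RAA) record for the whole session.  All randomness flows from a single
session seed; fixed seed ⇒ bit-identical sessions.

## Annotation

Reference detection runs on the B2–C2 bipole of the roving grid.  The
sensitivity threshold applies to a deflection's local peak-to-peak
amplitude (a symmetric biphasic of P-P `v` has rectified lobes of only
`v/2`); auto-sensitivity uses 0.3 × the median 200 ms-windowed P-P,
floored at 0.02 mV.  Detections respect a 90 ms refractory period (about
half the shortest AF cycle length of interest; the larger peak wins a
conflict).  When a wavefront travels parallel to the B2–C2 axis the bipole
cancels; the pipeline then falls back to the B2 unipolar with the same
configuration and logs the fallback.  The far-field leaks into that
unipolar reference, which is exactly what the ventricular score is for.

Beats are accepted when their interval to the previous annotation is
within ±50 ms (inclusive) of the median cycle length; the first beat is
judged by its following interval.  The ±30 ms window of interest widens in
10 ms steps while supra-threshold signal (0.1 mV) is present within one
step beyond either edge, capped at `min(150 ms, median CL / 2)` —
contiguous activity is chased, isolated far deflections are not.  The
ventricular score is `1 − 2·exp(−Δ/τ)` with Δ the distance to the nearest
ventricular event and τ = 25 ms; only its sign behaviour is constrained by
the protocol (coincident → −1, distant → +1, zero at Δ = τ·ln 2), the
exponential form is this package's choice.  AFCL is the mean of ten
consecutive appendage inter-annotation intervals, starting at the first
stable annotation (all ten intervals within tolerance of the median) so a
missed detection cannot double an interval into the mean.

## Omnipolar vector estimation

Each interior 2×2 cell of the grid yields four right-triangle cliques (one
per omitted corner), 36 per pose.  Per clique and beat:

* activation time per electrode = steepest negative unipolar slope in the
  WOI, refined to sub-sample precision by a parabolic fit of the
  derivative trough (at 1 kHz the raw 1 ms quantization would alone exceed
  the 5° direction budget across a 3 mm clique);
* direction and speed from the exact plane fit `t = a + g·x` over the
  three (position, time) pairs: direction `g/|g|` (later activation
  downstream), speed `1/|g|`;
* an E-field loop from the two leg bipoles scaled by inverse edge length.
  The legs sense the wavefront at midpoints about half a pitch apart,
  which lags one component against the other; the lag is compensated by
  cross-correlation alignment (±12 ms search) so a travelling plane wave
  produces the linearly polarized loop the continuum E-field would show.
  Without compensation the loop ellipticity grows as conduction slows and
  certainty collapses for perfectly clean slow waves.

**Certainty** = planarity × fit quality, clipped to [0, 1]: planarity is
`1 − λ2/λ1` of the loop covariance; fit quality is `exp(−residual/1 ms)`
where the residual is the RMS disagreement between the observed activation
times and the times predicted by projecting the clique positions onto the
loop's principal axis at the fitted speed.  A plane through three points
has zero residual by construction, so the residual is defined across the
two routes (unipolar timing vs bipolar loop) rather than within the fit;
the two must agree for the vector to be trusted.  Clean plane waves score
> 0.9 at typical atrial velocities; white-noise cliques average < 0.05
because the two routes disagree.  Near-simultaneous activation (time
spread ≤ 1 sample) is flagged indeterminate with certainty 0.  Zero-energy
loops score 0.

Acceptance requires certainty ≥ 0.5, peak-to-peak ≥ 0.3 mV (nominal; the
duplicate-resolution criterion uses 0.5), and beat score ≥ 0, all
inclusive at equality; the rejection reason names the first failed filter.

## Map assembly and analysis

Duplicate resolution merges vectors within 1 mm *across poses* (revisits),
keeping the highest certainty, then higher voltage, then earlier beat;
repeated beats of one clique within a single pose are independent samples
of local propagation and are retained.  The procedure is greedy in that
priority order, hence idempotent and input-order invariant.  The chamber
is partitioned into 18 equal rectangles (6 × 3 on the default sheet).

FVS: vectors within a 4 mm-radius ROI (circle inscribed in the printed
~0.8 × 0.8 cm² footprint; the radius is configurable) are binned into
eight 45° sectors anchored at +x.  A vector is centrifugal when its
direction lies within 45° of the outward radial at its position,
centripetal within 45° of the inward radial, perpendicular otherwise;
sector scores are +1/−1 for a strict >60% majority, else 0.  Candidates
need at least 8 vectors in the ROI *and all eight sectors populated* —
one-sided coverage (sheet boundary, coverage edge) cannot witness a
centrifugal pattern and otherwise yields spurious FVS ≥ 3 from downstream
sectors alone.  Detection scans a 2 mm candidate lattice; accepted
candidates with overlapping ROIs are merged by non-maximum suppression
(highest FVS, then mean ROI certainty).

Organization: per segment, the coherent fraction is the share of vectors
within 45° of the segment's circular-mean direction; organized requires
strictly >70%, and segments with fewer than 5 vectors count as not
organized.  The chamber is organized at strictly >70% of segments, i.e.
≥ 13 of 18.

Concordance between two maps is evaluated per mapped location: each map is
first reduced to its most trustworthy vector per distinct position (beats
of one clique share a position and would otherwise make nearest-neighbour
matching ambiguous — a map compared with itself must score 100%), then
each location of map A is matched to the nearest location of map B within
2 mm and counted concordant at ≤ 45° angular difference.  Classes: low
< 30%, high > 70%, both boundaries moderate.  For circular-uniform
direction fields the expected concordance is 25% (the 90°/360° cone),
which is why decorrelated chaotic maps classify low.

QS detection: the positive-lobe fraction of the windowed unipolar
peak-to-peak; QS at < 0.1.

## Numerical and design choices

* Time in ms, voltage in mV, distance in cm, speed in m/s (1 m/s =
  0.1 cm/ms); 0-based samples; times relative to session start.
* Thresholds are inclusive at exact equality except where the printed rule
  is strict (>60%, >70%); boundary semantics are unit-tested exhaustively.
* Tie-breaks are always total (certainty → vpp → beat → pose → position)
  so assembly and suppression are deterministic.
* "Ten consecutive electrograms" is read as ten intervals.
* The ambiguous duplicate setting "certainty / P-P 0.5 (nominal 0.3)" is
  resolved as certainty threshold 0.5 and duplicate P-P criterion 0.5 mV
  (nominal 0.3 mV), both configurable.
* The plane-wave oracle harness uses single-pose sessions with 0.8 s
  dwell: at 0.3 m/s a wavefront needs up to ~200 ms to cross the sheet, so
  three full beats only fit the trace with a margin beyond three cycle
  lengths.
* Degenerate inputs: empty maps, flat traces, all-zero reference signals,
  sub-3-detection references, and non-overlapping map pairs raise explicit
  errors; candidate centers coinciding with a vector position classify
  that vector perpendicular with a warning.

## Problem sizes

The test suite and the results script use desk-scale problem sizes chosen
to make every stochastic claim measurable in minutes: 50 seeded sessions
per activation pattern in the behavioural suite (20 in
`scripts/acceptance.py`), 100 (40) random plane-wave trials, 20 map pairs
per reproducibility class (10), and 20 QS seeds.  A canonical session is
45 poses × 0.6 s at 1 kHz (~27 s of signal, ~2,600 used points per map).

## What the simulation does and does not show

The generator reproduces the *mechanisms* the mapping rules rely on:
radial vector convergence at focal origins, QS unipolar morphology there,
coherent propagation domains for organized rhythms, beat-to-beat spatial
decorrelation for chaotic ones, far-field contamination separable by
timing, and cycle-length statistics.  It does not model ionic dynamics,
fibrosis, anisotropy, 3-D geometry, catheter contact or motion artifact,
fractionated multi-component electrograms, or true AF nonstationarity.
Passing tests therefore validate the implementation of the mapping and
scoring rules under controlled conditions — not clinical performance of
the method on human atria.  Clinical outcome statistics (termination or
inducibility rates, survival analyses) depend on patient data and are out
of scope.  Optional VTK/HDF5 exports are not implemented; all artifacts
are diff-able CSV/JSON.
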