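# Methods

This note documents the models, conventions and numerical choices behind
`pairedval`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, and what the synthetic generator does and does not
emulate.

## Manipulator co-registration (`coreg`)

A dual-probe rig drives a juxtacellular pipette with a reference
manipulator whose axes are squared to the stereotaxic frame, and an
extracellular polytrode with a second manipulator tilted about the
anterior-posterior (Y) axis by its approach angle θ (48.2° on the rig this
package models). Converting the tilted manipulator's native readings into
the reference frame is the planar rotation

    x_ref =  cos θ · z + sin θ · x
    y_ref =  y
    z_ref = −sin θ · z + cos θ · x

The matrix is orthogonal (in fact symmetric), so norms are preserved and
the inverse is the same matrix. Sign convention: the physical tilt is
−48.2° from horizontal; we store θ = +48.2° and use the rotation exactly as
written — negating θ transposes it. One convention is used everywhere.

Residual mechanical misalignment is absorbed by an affine map
`reference = A·p + b` fitted by ordinary least squares to pairs of
coordinates observed at the same physical point in both frames. Design
choices:

* **Translation included.** Zeroing errors behave like constant offsets; a
  bare 3×3 matrix cannot absorb them, so the fit is affine with an explicit
  offset `b`.
* **Fit after the tilt transform**, not on raw axis counts: the rotation is
  known geometry, the fit only mops up what mechanics left over.
* **Plain least squares** on the homogeneous design `[p | 1]` (12
  parameters). n is small (~15) and errors are near-Gaussian; no robust
  loss. The design must have affine rank 4 (≥ 4 non-coplanar points), and
  rank deficiency raises a named error rather than a silent pseudo-inverse.
* **Calibration points** are a seeded subsample of a 5×5×5 mm lattice in
  1 mm steps (216 nodes), redrawn until the subset has full affine rank.
  The physical sessions this emulates used 15 such positions; their exact
  locations are not tabulated anywhere, so a seeded subsample stands in.

With 15 points and 3 μm-per-axis readout noise, the expected post-fit mean
Euclidean residual is ≈ σ·√(3·(1 − 4/15))·√2·Γ(2)/Γ(3/2) ≈ 4.1 μm — the
acceptance script measures ~4.2 μm over 100 sessions, comfortably inside
the 10.5 μm software-corrected rig error it is compared against.

## Probe geometry and raw I/O (`probe_io`)

Two probe layouts ship as factories. The 32-channel "poly3" staggered
3-column probe: 12 center-column sites at 25 μm axial spacing (275 μm
span), flanked by two 10-site columns offset half a period axially and
18.5 μm laterally, giving staggered nearest-neighbour distances of
≈22.3 μm — inside the probe family's 22–25 μm pitch band. The published
figures show but do not tabulate exact coordinates, so the stagger and the
site numbering (center column top-to-bottom, then left, then right) are
package conventions, fixed and serialized via `write_geometry`. The
128-channel probe is a regular grid at 22.5 μm pitch with 20×20 μm sites.

Raw recordings are flat binary int16, **sample-major** (channel-interleaved:
frame = one sample of every channel), little-endian, 30 kHz. Conversion to
μV uses a configurable amplifier step defaulting to 0.195 μV/bit (the step
of the amplifier family used for such recordings; it is configuration, not
a constant). Axial coordinates increase with depth, 0 at the top site.

## Filtering and noise (`signal`)

All spike-band work uses a third-order Butterworth band-pass applied
forward-backward (zero phase), as second-order sections for numerical
stability. Bands: 100–14,250 Hz for waveform analysis (the upper edge is
95% of Nyquist at 30 kHz), 500–14,250 Hz for event detection, and
100–5,000 Hz as an alternative for recordings with high-frequency noise.
Edge handling is odd-reflection padding of length 3× the recursion order;
traces shorter than the padding raise an explicit error, and filtering is
applied to whole recordings, never to extracted windows. Designs whose
upper edge reaches 95% of Nyquist are checked for pole stability and a
warning is logged.

Noise σ defaults to the plain standard deviation; a MAD-scaled robust
variant exists (off by default) because heavy spiking inflates the plain
SD.

## Ground-truth analyses (`ground_truth`)

* **Juxtacellular spike detection**: one event per contiguous
  supra-threshold excursion, aligned on the extremum — the maximum for the
  canonical positive-before-negative loose-patch waveform, the minimum for
  the two known negative-first pairs (polarity is per-pair metadata).
  "Well-isolated" is operationalized as no second excursion extremum within
  ±1 ms; both members of a closer pair are rejected. Thresholds are always
  explicit inputs (the per-pair values used in the source dataset live in
  its supplementary table, not here).
* **JTA**: per-channel mean of ±2 ms windows around each juxtacellular
  peak. Events whose window clips a recording edge are excluded and
  counted, not zero-padded — simpler statistics at a negligible cost in n.
* **Footprint**: per-channel peak-to-peak within ±1 ms of the alignment
  time; spatial map by piecewise-linear interpolation on a Delaunay
  triangulation of the sites (1 μm default grid), exact at sites and exact
  for linear fields.
* **Amplitude–distance**: max-over-channels p2p per pair versus
  tip-to-nearest-site distance (uncertainty ±10.5 μm from the rig
  calibration). Amplitudes below a 5 μV floor are flagged as possible
  electronics cross-talk rather than neural signal. `fit_amplitude_decay`
  fits `A₀·exp(−d/λ) + c`; the additive floor `c` absorbs the
  noise/artifact baseline that would otherwise bias λ upward.
* **Propagation velocity**: inter-site distance divided by the delay
  between negative peaks, with the argmin refined by 3-point parabolic
  interpolation — at 30 kHz the 33 μs sample step would otherwise dominate
  delays across a 22.5 μm pitch. Positive velocity means later arrival at
  the second site; the estimate is antisymmetric under swapping sites.

## Flood-fill detection and scoring (`detection`)

Detection follows the dual-threshold flood-fill scheme for dense probes:
per-channel σ on the full filtered trace, strong threshold 4.5σ seeds an
event, weak threshold 2σ grows it over the graph whose nodes are
(channel, sample) entries of the weak mask, connected when within ±1 sample
in time and on the same or a neighbouring channel (inter-site distance ≤
adjacency radius, default 30 μm — covering nearest neighbours on both
probe layouts). Components without a strong sample are discarded; each
survivor yields one event at its largest deflection (ties broken by
earliest sample then lowest channel, so results are order-independent);
events with peaks closer than 0.5 ms on overlapping channel sets are
merged. Polarity is negative-only by default (extracellular somatic spikes
are negative-first); a both-polarities flag exists. This is the package's
own documented variant of the scheme, not a byte-exact port of any
existing detector.

Scoring against the juxtacellular train uses a PETH in 1 ms bins aligned
so 0 ms is a bin center, and greedy nearest-neighbour matching within
±0.5 ms (each detected event matches at most one reference spike; hits +
misses = n_reference). Greedy was chosen over optimal assignment for
transparency; the test suite checks it against a maximum-matching oracle
in the sparse regime where they provably coincide. Note the 0-centered
bins mean a 2× bin refinement is not nested; refinement invariants hold
for odd factors (3× is tested).

## The synthetic generator (`synth`)

The generator emulates the *statistics* a paired-recording rig observes,
not the biophysics:

* **Amplitude decay**: `A(d) = A₀·exp(−d/λ)` with λ = 100/ln(38/5) ≈
  49.3 μm and A₀ = 38·e^(50/λ) ≈ 104.8 μV, the unique exponential through
  38 μV at 50 μm and 5 μV at 150 μm — the amplitude range reported for
  neurons in that distance band. Exponential (rather than power-law) decay
  is a model choice: two anchor points determine it uniquely and it
  respects the observation that only sub-50 μm neurons leave large
  signatures. Tests treat λ as the generator's truth, not an empirical
  claim.
* **Templates**: Gaussian-lobe biphasic/triphasic waveforms, peak-to-peak
  normalized; juxtacellular spikes are positive-before-negative and scaled
  to ~4 mV p2p, extracellular ones negative-first.
* **Propagation**: per-site delay = axial offset / velocity (default
  0.55 m/s, literature-scale backpropagation ~0.67 m/s also used in
  tests).
* **Spike times**: Poisson with a 1 ms absolute refractory period.
  Background units (uniform in a 200 μm slab, 0.5–5 Hz, default density
  50,000/mm³ — the middle of the cortical 40–60k range) are available via
  `place_background_neurons`.
* **Cross-talk**: an optional common-mode copy of the juxtacellular
  waveform, identical on all channels, capped below 5 μV — the magnitude
  of the artifact such rigs exhibit.
* **Noise** is white Gaussian. Real recordings have 1/f and spatially
  correlated noise, electrode drift, bursting, and waveform
  non-stationarity; none are modelled. Passing tests therefore demonstrate
  the *analysis chain* is correct and calibrated against a known truth,
  not that it is robust to everything real tissue does.
* **Reproducibility**: all randomness flows from one seed through named
  substreams (spikes, noise, placement, misalignment), so components can
  be regenerated in isolation and identical configs are bit-identical.

Problem sizes in tests and examples are scaled to desk conditions: e.g.
the 51 μm footprint-recovery scenario uses ~7.4 Hz × 60 s (≈440 spikes)
rather than a 1 Hz neuron recorded for seven minutes, preserving the event
count that matters for the standard error.

## Sensitivity-volume estimate (`estimates`)

Expected neurons per electrode = density × (2/3)πr³ with r in mm — a
*half*-sphere because the probe shank occupies the other half-space.
Rounding is to the nearest integer and the unrounded value is always
reported alongside. For 40,000–60,000 neurons/mm³ and r = 50 μm this gives
10.5–15.7, i.e. ~10–15 neurons per site.

## Known limitations

* The flood-fill detector is deliberately minimal: no alignment
  refinement, deduplication across shanks, or amplitude-based splitting;
  spike sorting is out of scope.
* The generator's exponential decay is isotropic; real EAPs are elongated
  along the apical-dendrite axis, which is exactly why distant neurons can
  occasionally be visible over hundreds of micrometres.
* Velocity estimation assumes a single propagating negative peak per
  channel; multi-phasic or non-propagating signatures need explicit site
  choices by the user.
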