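# Methods

This note documents the models, parameter choices, and numerical decisions
behind `remoterep`, and states precisely what the synthetic-session generator
does and does not emulate.

## Track geometry and linearization

The Y-maze is linearized onto three straight segments meeting at a junction:
a box segment (default 50 cm) and two arms (default 120 cm each, 30° to
either side of "forward"). The linear axis concatenates box, arm 1, arm 2;
all intervals are half-open and region masks are defined by bin-center
membership with a 5 cm default bin (regions of 5/15/25 cm land exactly on bin
edges). The center reward port sits *inside* the box, 25 cm from the
junction: the feedback phase is spent at the port, and a port at the junction
would make local (current-location) spiking decode partly into the arm bases,
contaminating arm-content statistics. Positions farther than 10 cm from the
skeleton are snapped and flagged; callers carry the last valid position
forward. Along-track distances between segments run through the junction.

## Clusterless decoder

* Kernels: spherical Gaussian in mark space (bandwidth 20 µV over the 4
  channels) and Gaussian in along-track position (6 cm), both configurable;
  the source experiment fixes neither, and these are standard values in the
  clusterless-decoding literature.
* Amplitude threshold: 100 µV on the maximum channel.
* Occupancy: speed-filtered (>4 cm/s) exploration histogram, Gaussian-
  smoothed *within* each segment (smoothing across the junction would leak
  occupancy between arm bases), normalized. Bins below 1e-5 of total mass
  receive zero likelihood; the division is floored there to avoid blow-ups.
* Each 6 ms bin is decoded independently (log-space product of per-spike
  likelihoods, renormalized in float64; informative bins sum to 1 within
  1e-9). No state-transition prior: the only temporal smoothing is the causal
  30 ms running average, which averages the informative bins among the last
  five and marks windows with fewer than two informative constituents
  ineligible.
* Tetrodes with fewer than 50 encoding spikes are excluded with a warning
  (configurable, so miniature test instances can keep all spikes).
* "Spatially specific spike": likelihood peak above 3× the uniform level,
  configurable. This operationalizes an undefined term; it excludes noise
  spikes with flat likelihoods.

## Detection

Trigger logic follows the stated criteria verbatim with strict inequalities
(>0.40 target-end mass, <0.20 opposite arm, <0.20 box, ≥2 spatially specific
tetrodes in the 30 ms window, port distance <17 cm). A single averaged bin
qualifying triggers the tone (the 30 ms average is itself the persistence
mechanism); an unstated inter-tone lockout defaults to 5 s, longer than the
3 s nosepoke window. Sessions truncate at 75 rewards or 30 minutes. The
head-direction condition ramps its angular tolerance linearly in reward count
from ±20° (reward 0) to ±3° (reward 25); only the endpoints are given by the
task description, the linear shape is an assumption.

## Classification

The segment is the detection bin plus the 90 ms before it (16 six-ms bins;
the window does not extend past detection). Trajectory categories are tested
first — a full sweep also satisfies the jump mass criterion, and the
categories must be mutually exclusive — via OLS of the posterior-mass-
weighted mean target-arm position against time over informative bins with
≥0.2 arm mass; "covering" is the range of fitted values, and significance is
p<0.05 on the slope. Then jump-and-arm-base (>0.4 end mass plus >0.2 mass in
the proximal 15 cm in a pre-detection bin), then jump, then other. Peripheral
flags use a 0.2 mass threshold in the first/last 5 cm of the arm (no
threshold is stated for "representation of" those regions). The jump distance
is the along-track distance from the animal to the posterior mode of the
first bin exceeding the end-mass criterion.

## Prevalence

Eligible bins are informative feedback-phase bins with the animal strictly
within 17 cm of the port; qualifying bins carry >0.40 region mass. "Tone-
triggering representation removed" excises the detection-triggering 30 ms
window plus the preceding 90 ms (the exact span is unstated). The
Mann-Whitney test is implemented from the rank formula with tie correction
(normal approximation) and by exhaustive enumeration for groups of ≤8;
longitudinal trends are OLS on optionally z-scored prevalence with the
slope t-test, with the convention (0, 1) for constant series. Grouped
mixed-effects inference is intentionally out of scope.

## Assemblies

Counts in 30 ms bins, per-unit z-scored (silent units dropped). The number
of assemblies is the count of correlation-matrix eigenvalues above the
Marchenko-Pastur upper edge (1+√(N/B))². At finite sizes the top noise
eigenvalue fluctuates above the asymptotic edge on the Tracy-Widom scale
(B^{-2/3}(1+√q)^{4/3}q^{-1/6}, q=N/B) and crosses it in roughly 15% of
realizations at N=60, B=20000, so the significance threshold adds twice that
scale (~99th percentile); `tw_constant=0` restores the bare bound. ICA
(FastICA, seeded) runs on the projection onto the significant eigenspace;
weight vectors are unit-norm with the largest-magnitude weight positive.
Activation strength is the zero-diagonal quadratic form, computed as
(wᵀz)² − Σᵢwᵢ²zᵢ². High-weight units are those above mean + 2 SD of an
assembly's weights; an assembly is labeled *target* iff the weight-weighted
place-map mass of its high-weight units in the target arm end exceeds that
of every other equal-length candidate region (opposite end, both arm bases,
far 25 cm of the box). Activation ratios compare mean strength at detection
bins to random near-port bins; in synthetic sessions the stillness baseline
is nearly silent, so the denominator is close to zero and the ratio is large
and scale-unstable across seeds (orders of magnitude) — only its sign and
the accompanying rank test are comparable across sessions.

## Brain state

Ripples: 150–250 Hz band-pass, analytic-signal envelope smoothed 4 ms,
events above mean + 3.5 SD for ≥15 ms, extended to mean + 1 SD and merged
across <10 ms gaps. The exact parameters of the source's cited detection
method are not restated there; 3.5 SD was chosen, within the conventional
3–5 SD range, because the extreme values of the smoothed Gaussian-noise
envelope cross 3 SD for 15 ms about once per minute, which would contaminate
a ripple-free recording (all parameters configurable). States per 6 ms bin:
SWR (overlapping a detected ripple), else moving (>4 cm/s), else still.
Theta phase is the analytic phase of the 6–10 Hz band with 0 at the trough
(the convention is reported, since "late theta" depends on it); the Rayleigh
test uses Z = nR̄² with the standard series correction, clipped to [0, 1],
and warns below n = 10. Composition tables use the chi-square test with
two-proportion z-tests post hoc and flag expected counts below 5.

## Synthetic sessions: what is and is not emulated

The generator's defaults are the study conditions: 60 cells on 8 tetrodes,
exactly 12 cued visits per arm during exploration (box dwell between visits
is scaled so the phase lasts ≈15 min), a feedback phase capped at 30 min
spent ≥80% within 17 cm of the port with stillness bouts, ~8 Hz theta during
movement, and ripples injected during stillness.

* Place fields are unimodal Gaussians (σ = 6 cm, peak 30 Hz, baseline
  0.1 Hz), confined to the segment holding their center — a linear-position
  bell does not wrap around the junction, and real fields at choice points
  are shaped by the trajectory rather than spreading symmetrically into
  three segments. Centers tile the track (stratified placement) outside the
  two designated end regions, with a fraction (default 0.2 per arm) placed
  in each arm's distal 25 cm, and keep 12 cm from the junction.
* During stillness, spiking collapses to a scaled local component (15% of
  the tuning rate at the current position) plus a 0.02 Hz out-of-field
  floor, reflecting the near-silence of CA1 cells outside their field during
  immobility. Without this, coincident out-of-field spikes from end cells
  generate frequent spurious remote detections that no real recording shows
  at that rate.
* Marks: cell-specific cluster means on a 4-D lattice with 80 µV separation
  and 20 µV spherical spread, base amplitude 150 µV.
* Injected events run at 5× the movement rate. Three times was tried first;
  at a 60-cell population it yields ~1 spike per 6 ms bin during events —
  far sparser than the real system, which decoded on the order of a million
  spikes per session — and single-spike posteriors are too noisy for the
  trajectory regression. Five times brings event bins to 2–3 spikes,
  matching the real per-bin regime.
* Event shapes: jumps hold a jittered position mid-end; jump-and-arm-base
  events alternate base and end content in 12 ms blocks (so base mass
  appears in distinct decode bins at any grid alignment, without a monotone
  progression); trajectories sweep at replay speeds (7–10.5 m/s) to a hold
  point just inside the end region. Default sweep spans (52 cm medium, 78 cm
  long) are sized so the span *visible in the 90 ms before the trigger* —
  which fires a few bins after the representation enters the end region —
  lands inside each category's coverage window; spans, speeds, and rates are
  all configurable.
* LFP: white-noise floor (15 µV), movement-gated theta, 200 Hz Hann-windowed
  ripple bursts of 60–120 ms calibrated so their envelope peaks 6 SD above
  the baseline envelope mean.

What passing tests therefore do **not** show about real data: real
recordings have non-Gaussian, spatially drifting fields, theta phase
precession, correlated noise and shared noise across tetrodes, cluster drift
and overlap in mark space, pink-spectrum LFP, and replay content that is not
generated from the same tuning curves the decoder estimates. The synthetic
sessions validate the *computation* — that each stage implements its
definition and recovers known ground truth — not decoding performance on
biological signals.

### Known limitations

* The medium-trajectory category (fitted coverage in [35, 45) cm) sits
  within the coverage noise of the synthetic decoder (~5 cm SD): per-kind
  recovery is ≈0.99 for jumps, ≈0.9 for jump-and-arm-base, ≈0.85–0.95 for
  long trajectories, but only ≈0.6–0.8 for medium trajectories, which spill
  into the jump (undershoot) or long (overshoot) categories. Aggregated over
  the realistic jump-dominated event mix, recovery exceeds 0.9.
* The assembly activation ratio is scale-unstable on synthetic stillness
  (see above).
* The SWR detector's null is not exactly zero: about one false detection per
  10 minutes of ripple-free synthetic LFP at the default operating point.

## Problem sizes

Default sessions decode ~60–80 k spikes over ~45 min of session time in
about a minute on one CPU; the test suite uses shortened sessions (2.5–6 min
exploration, 4–12 min feedback) everywhere except the acceptance checks,
which run the default session once.
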