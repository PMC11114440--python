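# Methods

This note records the model behind each pipeline stage, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
data can and cannot establish.

## Signal model and preprocessing

Input is 16-channel 10-20 EEG (Fp1…O2, linked-earlobe reference) sampled
at 200 Hz, assumed already acquisition-filtered to 1.5–60 Hz and
artifact-free; the package performs no artifact rejection and no
re-referencing. Five analysis bands are used: delta 2–4, theta 4–8,
alpha 8–13, beta 13–30, gamma 30–60 Hz.

Each band is isolated with a 4000th-order (4001-tap) type-I FIR bandpass
designed by the window method with a Hamming window. The taps are exactly
symmetric, so phase is exactly linear; the group delay of 2000 samples is
compensated, and edges are computed against reflection padding so the
filtered record is full-length and time-aligned. Because all channels
pass through the identical filter, any residual phase response cancels in
cross-channel phase differences — a property the tests check directly.

**Filtering order.** The continuous record is filtered once per band and
then epoched. Filtering a 1000-sample epoch with a 4001-tap kernel would
be ill-posed, so continuous-first is the only coherent ordering; dropping
the first and last epochs further suppresses any residual edge transient.
Epochs are contiguous, non-overlapping 5-s windows (1000 samples): long
enough to resolve slow rhythms, short enough that epoch-averaged PLI is
not washed out, and a 600-s record yields 120 − 2 = 118 of them.

An optional 58–62 Hz FIR band-stop can be applied before band filtering
for mains-contaminated recordings; it is off by default since synthetic
data contains no line interference. Note the gamma band is implemented
as printed (30–60 Hz), with no carve-out at 60 Hz.

## Phase lag index

Per epoch, instantaneous phase is the argument of the Hilbert analytic
signal computed over that epoch. For a channel pair with phase
difference Δφ(t_k), k = 1…T,

    PLI = | (1/T) Σ_k sign Δφ(t_k) |,   Δφ wrapped to the principal interval.

The printed statistic ranges over [0, 1]; the absolute value makes the
sign of the lag irrelevant. A consistently positive (or negative) lag
gives 1; independent phases give ≈ 0 (sampling error ~ T^(-1/2)); and a
phase difference concentrated at exactly 0 or π gives ≈ 0, because signs
cancel around the symmetric concentration point. Exact 0 and exact π
differences contribute sign 0 — both encode lag-free coupling, which the
index deliberately discounts; this is what makes PLI robust to
instantaneous volume conduction of a common source. Per-epoch values are
averaged into one symmetric 16 × 16 matrix per subject and band
(diagonal fixed at 0).

Averaging PLI over epochs *before* graph construction (rather than
averaging per-epoch betweenness) is the conventional reading of
"network from connectivity, then centrality" and is the package default;
computing per-epoch betweenness would require the alternative order and
is deliberately not offered, to keep one well-defined estimand.

Implementation note: the subject-level estimator works on the analytic
signal via sign(Im z_a z̄_b) ≡ sign(sin Δφ) in a compiled kernel; tests
pin it to the literal per-epoch formula at 1e-12.

## Betweenness hubs

A subject's band matrix defines a weighted undirected graph on the 16
electrodes with edge length 1/PLI (stronger coupling = shorter path); a
zero PLI removes the edge. Normalized betweenness centrality of node i is

    b_i = [ Σ over ordered pairs (h, j), h ≠ j, both ≠ i, of ρ_hj(i)/ρ_hj ]
          / ((n − 1)(n − 2))

with ρ_hj the number of shortest h→j paths and ρ_hj(i) those through i.
The ordered-pair index set with the (n−1)(n−2) normalization maps a star
center to exactly 1 and tree leaves to 0. Betweenness is computed on the
whole weighted graph — no minimum-spanning-tree backbone, whose pruning
discards exactly the weak links that shape global detours.

Shortest paths use Dijkstra with Brandes' dependency accumulation.
Co-minimal paths split credit by path counting (never arbitrary
tie-breaks); two path lengths are considered tied at a relative
tolerance of 1e-12. Unreachable ordered pairs (possible when a PLI is
exactly 0) contribute no paths; the pipeline counts and reports such
disconnected-graph occurrences in its manifest because they silently
change shortest-path structure.

## Statistics

Per band, on the subjects × 16 betweenness table:

* **Group comparison** — mixed (split-plot) ANOVA, group between, node
  within. Sums of squares use the weighted (Type II) decomposition,
  which is exact for this design and matches common repeated-measures
  software for unbalanced groups (e.g. 31 vs 21). Greenhouse–Geisser ε
  is estimated from the *pooled within-group* covariance of the node
  values (double-centered trace formula, clipped to [1/(k−1), 1]) and
  applied to the within effects (node, group × node); the between-group
  effect keeps uncorrected df. Effect size is partial η² — the common
  default of repeated-measures software when η² is printed unqualified.
* **Treatment comparison** — two-way fully-within ANOVA
  (treatment × node) on paired session tables; each effect is tested
  against its interaction with subjects; ε is 1 for the 2-level
  treatment factor, and comes from the session-mean and session-
  difference covariances for the node and interaction effects.
* **Gating and FDR** — post hoc per-electrode t-tests (independent for
  group, paired for treatment) run only in bands whose main or
  interaction effect reaches P < 0.05 (GG-corrected); p-values are
  BH-corrected across the 16 electrodes within the band and thresholded
  at q < 0.05, with the sign of the group (or session) difference
  reported. Interaction p-values are additionally BH-corrected *across
  the five bands* and reported in a separate column: two correction
  scopes, separately labeled, never conflated.
* **Correlations** — Pearson r (two-sided p via the t transform) between
  BC at the sites of interest and the clinical score (patients) or age
  (all subjects). A paired t-test utility covers pre/post score
  comparisons; a zero-variance nonzero difference reports t = ±inf
  rather than NaN, and genuinely degenerate ANOVA inputs (zero error
  variance with a nonzero effect) raise errors.
* **Top edges** — for display tables, the strongest ⌈0.2 · 120⌉ = 24
  edges of a group-mean PLI matrix, ties broken lexicographically so the
  selection is deterministic.

## Synthetic cohorts

The generator emulates the study-shaped data the pipeline expects:
16 channels, 200 Hz, 600-s records by default, two groups of 31 and 21
subjects. A subject's signal is the sum of:

* **Background oscillators** — per band and channel, a constant-amplitude
  cosine whose phase performs a biased random walk: step mean advances
  the band-center frequency; step jitter is sized to spread the
  Lorentzian linewidth over a quarter of the bandwidth. Pure sinusoids
  would make every phase statistic degenerate (PLI exactly 0 or 1);
  wandering phase yields interior PLI values and epoch-to-epoch
  variability. Band amplitudes default to typical eyes-closed resting
  values (delta 20, theta 10, alpha 15, beta 5, gamma 2 µV).
* **Planted hubs** — a hub electrode's band oscillation is mixed into
  each target channel as (1 − c)·own + c·hub-at-lag, with lag π/4 by
  default. At c = 1 the pair is perfectly lag-locked (PLI → 1); at c = 0
  independent. A 0 or π lag is rejected when c > 0, since PLI cannot see
  it by construction. Injection at a fixed lag (rather than
  bidirectional dynamical coupling) gives direct control of the planted
  lag for an undirected statistic. Overlapping hubs multiply their
  (1 − c) shares.
* **Common source** — one pink-noise trace added identically to all
  channels (gain × 5 µV RMS): high amplitude correlation, zero lag,
  hence invisible to PLI — the volume-conduction control.
* **Channel noise** — independent pink (1/f) noise, gain × 5 µV RMS.

The default group contrast plants strong hubs (c = 0.85) at Fz-beta and
Pz-gamma in controls and a strong O1-gamma hub in patients, weak
(c = 0.15) elsewhere — the qualitative pattern the pipeline should
recover (patient BC lower at Fz-beta and Pz-gamma, higher at O1-gamma).
The strong/weak values were calibrated once so that planted hubs
dominate shortest-path structure and the contrast is recoverable with
high power at the replicate-study cohort sizes; they are not tuned per
experiment. Each subject's couplings are scaled by a latent trait
(multiplier 1 + 0.15·u, u ~ N(0,1), clipped), and patients' BPRS scores
are built from the same latent with a configurable target correlation
(default mean 50, sd 12, ρ = 0 — no score–coupling relation unless
requested). Every subject draws from an independent substream keyed by
(seed, group, subject index), so cohorts are bit-reproducible and stable
under subject-count changes. Signals are generated in float32 —
comfortably beyond the 16-bit precision of EDF storage.

What the generator does **not** model: realistic head-volume conduction
(a single equal-gain common source stands in for it), artifacts (blinks,
EMG, electrode pops), non-stationary amplitude dynamics, 1/f slope
differences between groups, or any directed/lagged network dynamics
beyond fixed-lag injection. Passing tests therefore demonstrate that the
pipeline recovers the structure it is designed to detect and stays
calibrated under a fair null — not that it is robust to every artifact
of clinical recordings.

## Replicate-study problem sizes

The calibration and power studies run the full pipeline (generation →
filtering → PLI → betweenness → gated statistics) on many replicate
cohorts; to keep them desk-scale they use 15 + 15 subjects and 60-s
records (10 analysis epochs): 200 null cohorts for the false-flag rate
(bound 8%: nominal 5% plus simulation error), 50 recovery cohorts for
the ≥ 80% all-three-contrasts power check. The acceptance script uses
100 and 25 replicates for the same quantities, and a single 31-vs-21,
120-s demonstration cohort for the study-shaped statistics.

## Known limitations

* PLI discards genuinely zero-lag physiological coupling along with
  volume conduction; weighted/directed PLI variants are out of scope.
* The gamma band runs to 60 Hz; recordings with strong mains residue
  there need the optional notch, and no high/low-gamma split is offered.
* The ANOVA layer assumes complete tables (no missing electrodes);
  subjects with missing cells must be dropped by the caller.
* Betweenness on 16 nodes is exact but its sampling variability across
  epochs is not propagated into the group tests; the subject is the unit
  of analysis, as in the standard design.
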