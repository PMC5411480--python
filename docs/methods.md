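# Methods

## Model

`tonebind` treats a trial as a sequence of chords, each a set of
simultaneous pure-tone components described only by log-frequency (in
semitones, st(f) = 12·log₂(f/1 Hz)) and duration. Amplitude never enters
the model; the spectral envelope exists only for audio rendering.

**Generative picture.** Every component belongs to a latent *track* with
centre frequency μᵢ. Component log-frequencies are Gaussian about the
centre with variance σ²_track (st²). The sensed log-frequency of each
component is further corrupted by independent Gaussian sensory noise of
variance σ²_sense·d₀/d for tone duration d, with d₀ = 150 ms the
reference duration — precision grows with duration. σ²_track and
σ²_sense are the only free parameters.

**Filtering.** Inference is mean-field filtering in the factorial hidden
Markov model this implies:

1. *Initialization.* The first (non-intertrial) chord creates one track
   per component, with belief mean at the sensed frequency and variance
   σ²_track + sensory noise.
2. *Attribution.* Each tone j of a later chord is softly assigned to all
   tracks; the responsibility r₍ᵢⱼ₎ is the normalized Gaussian predictive
   density of gⱼ under track i, whose predictive variance is the belief
   variance + σ²_track + sensory noise. Densities are evaluated in log
   space and normalized with the max-subtraction pattern, so a 9-octave
   spread cannot underflow to a zero column.
3. *Update.* Track i absorbs nᵢ = Σⱼ r₍ᵢⱼ₎ effective observations with
   responsibility-weighted mean; the conjugate step adds nᵢ/obs-variance
   to the belief precision. A track with nᵢ = 0 is untouched (and its
   weighted mean is flagged undefined rather than silently 0/0).
4. *Readout.* For the test pair, φᵢ sums oriented shifts gₖ − gⱼ over all
   T1×T2 component pairs weighted by r₍ᵢⱼ₎·r₍ᵢₖ₎; the binary report is
   the sign of Φ = Σᵢ φᵢ, with an exact tie broken by a seeded fair coin
   (ties have measure zero once σ²_sense > 0; the coin only guards
   noiseless unit tests). The percept is computed from T2's attribution
   *before* T2 updates the beliefs; the order cannot change the percept
   but is fixed for determinism.

Track centres may in principle drift; no per-step diffusion term is added
by default (the drift capacity is carried by σ²_track in the predictive
variance), but `ModelParams.diffusion` exposes one. The number of tracks
is fixed by the first chord — no birth/death.

Two implementations share this math: the step-by-step operations
(`sense`, `initialize_tracks`, `attribute`, `update_beliefs`,
`process_trial`) and a batched array path (`simulate_trials`) that groups
trials by chord-role structure, pads component counts under a mask, and
runs the filter for thousands of trials at once. A unit test pins their
noiseless equivalence; the Monte-Carlo-heavy stages (condition
predictions, fitting) use the batched path.

## Stimuli

* Shepard tones: octave-spaced components from a base frequency up to the
  band edge; the audible band is fixed to [30, 22050] Hz for every
  generator. Intertrial complexes use half-octave (√2) spacing.
* **Base-octave folding.** Test bases are drawn uniformly from 60–120 Hz.
  Every *derived* base (T2 at a semitone offset, context tones, probes)
  is folded mod octave back into 60–120 Hz. A Shepard tone's pitch class
  is invariant under this fold; without it, band-edge component-count
  imbalances give the "ambiguous" 6-st pair a systematic ±6 st edge term
  on ~10% of trials and shift its response rate to ~0.64. With folding
  the imbalanced slices shrink to <1% of draws and largely cancel.
* Random spectra: T1 components uniform in log frequency over the band;
  each T2 component exactly at the log midpoint of adjacent T1 components
  (enforced ambiguity); context components confined to the half-gap
  between each T1 component and its bias-side midpoint, so the context
  favours exactly one shift direction.
* Experiment designs reproduce the printed grids and totals: interval
  scan 1–11 st (440 trials), context count 0–10 (440), context duration
  0–320 ms (320; a 0-ms context is the *absence* of the chord, not a
  zero-length observation), silent gap 0.5–64 s (160), random spectra
  with 3–80 components (480), and the probe-sequence design (35-ms probes
  every 250 ms, i.e. 4 Hz). For the probe design only the two printed
  binary factors (context region × probe region) are enumerated, 30
  repetitions each. The single-context interval scan (−5…+6 st in 1-st
  steps) is exposed as a `context_intervals_st` override of the
  context-count design. Whether intertrial complexes used random or fixed
  bases is unspecified; they are drawn uniformly from 60–120 Hz like test
  bases, and they are never fed to the model. Audio rendering uses 5-ms
  raised-cosine ramps (unspecified in the design; a declared default).

## Simulated listeners

A cohort draws per-listener parameters independently: σ²_track
log-uniform on [0.5, 8] st², σ²_sense log-uniform on [0.1, 4] st²
(variances act multiplicatively), lapse uniform on [0, 0.05] (its lower
bound is 0, so log-uniform is unavailable). These bounds make the
simulated psychometric curves span the qualitative range of the
behavioural effects — from moderate to near-complete context bias — and
are configuration, not constants. Responses are *sampled*, not
thresholded probabilities, so downstream statistics see genuine binomial
noise; the lapse replaces the model response by a fair coin.

What the generator does **not** emulate: idiosyncratic per-listener
tritone biases (cancelled in the designs by randomizing absolute
frequency, and therefore also absent here), attention lapses correlated
in time, learning across blocks, and any memory decay over silent gaps.
Consequently the gap design shows a flat bias profile in simulation —
passing tests demonstrate the pipeline's correctness on data satisfying
the model's assumptions, not that human gap or density profiles are
reproduced.

## Fitting

Per listener, the two variances are estimated by maximizing the binomial
likelihood of per-cell response counts, where a cell is (experiment,
condition, bias direction) — conditioning on bias direction keeps cells
homogeneous when a design randomizes the context region. Cell
probabilities come from Monte-Carlo simulation; the estimator is a
log-spaced grid search (default 15×15 over [0.05, 20] st²) with one fixed
simulation seed shared by all grid points (common random numbers), since
the Monte-Carlo likelihood is noisy and the optimum broad. The lapse is
fixed (default 0.02), not fitted: it keeps empirical 0/1 cells from
producing −∞ log-likelihoods. Gap and random-spectrum data are excluded
from the objective (they would require model extensions; see above).

**Identifiability.** σ²_sense is well constrained by the psychometric
slope and the duration effect. σ²_track lies on a broad likelihood
ridge: with Shepard-tone tracks 12 st apart, attribution is near-hard for
any σ²_track ≲ 4 st², and predicted response probabilities change by
less than 0.01 across two orders of magnitude. Point estimates of
σ²_track therefore wander along the ridge (only its upper end, ≳ 8 st²,
degrades predictions and is rejected); a recovery study at ~900 trials
per listener pins σ²_sense within a factor of 2 in ~90% of replicates but
cannot do the same for σ²_track. Model predictions are insensitive to
position on the ridge, which is why a single fit still yields stable
predicted curves.

A further property worth knowing: P(T1-higher) is *not* monotone at the
extreme intervals — with any sensory noise, sign flips are most frequent
at the smallest interval (1 st), producing a small uptick there. The
curve is monotone through the central 3–9 st range and crosses 0.5 at the
half-octave.

## Statistics

* Bias summaries: the statistic is the mean over listeners of each
  listener's proportion of bias-consistent responses (or 'up' responses
  where no bias is defined). CIs are percentile bootstraps over
  *listeners* (the cohort, not trials, is the sampling unit) at level
  1 − α/m with m the number of comparisons (Bonferroni); significance is
  the CI excluding 0.5, and levels with fewer than two listeners are
  flagged unreliable.
* Kruskal–Wallis: classical rank H with tie correction; the P value is a
  permutation estimate, P = (1 + #{H* ≥ H}) / (n_perm + 1), with labels
  shuffled within listener when listener ids are given (10,000
  permutations by default). The type-I rate at nominal 5% calibrates to
  [0.03, 0.07] in simulation.
* Probe spectrum: the first 500 ms of each epoch are concatenated in
  trial order and Fourier transformed; window and trial count must place
  a bin exactly at 4 Hz, and the 4-Hz power is read at that bin, never
  integrated over a band. The PRR divides the Context+ 4-Hz power by the
  Context− power. Epoch arrays are synthetic (Gaussian-bump evoked
  responses every 250 ms plus white noise); no sensor-file reader exists
  because no recording format is published, and no sensor preprocessing
  (filtering, channel selection, topography) is modelled.

## Numerical and design choices

* Responsibilities are computed with max-subtracted exponentials;
  normalization is exact to 1e−9 over the full frequency range.
* Posterior variance strictly decreases whenever a track absorbs mass;
  this is asserted as a property test.
* Mean-field vs exact: on 2-track × 2-tone instances the mean-field
  posterior means agree with exhaustive enumeration over hard assignments
  to within 5% of the track separation once tracks are ≥ 4 st apart; the
  approximation tightens as separation grows.
* Pipeline determinism: one root seed feeds named per-stage substreams
  (`SeedSequence.spawn`); re-running a config is bit-identical for every
  CSV, which the manifest's SHA-256 hashes make checkable.
* Problem sizes in the test suite and analysis scripts (e.g. 5000 trials
  for the chance-level check, 800 repetitions per interval for the
  crossing, 3 fitted listeners in the driver script) are chosen so each
  stage's Monte-Carlo error is well below the asserted tolerances.

## Known limitations

* The model omits amplitude, attention, memory decay and adaptive
  generative variance; gap-duration and spectral-density profiles of real
  listeners are out of scope by construction.
* The probe-sequence (MEG-style) analysis operates on synthetic epochs
  only and makes no claim about sensor-level phenomena.
* σ²_track is reported with its ridge caveat above; treat its point
  estimate as a representative of an equivalence class, not a measured
  quantity.
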