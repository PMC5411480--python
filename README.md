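# tonebind

Probabilistic temporal binding of tone sequences: how prior acoustic
context resolves ambiguous pitch-shift judgements.

## The problem

A Shepard tone is a chord of octave-spaced pure tones; between two such
chords a half-octave (6 semitone) step is perfectly ambiguous — the upward
and the downward interpretation involve identical log-frequency distances,
and listeners split 50/50. Presenting even a brief context tone beforehand
almost fully determines the reported direction: the perceived shift passes
through the context's frequency region. `tonebind` implements, end to end
and with simulated listeners only, the computational account of this
effect: successive frequency components are bound into slowly-varying
**tracks**, and the reported pitch shift is read out within tracks.

The package is organised as an analysis project: the library under
`src/tonebind/` holds every computation, the numbered scripts under
`analysis/` run the narrative (build stimuli → simulate cohorts → fit →
statistics → probe spectra) and write tables under `results/`.

## The model

All frequencies live in semitone log-units, st(f) = 12·log₂(f/1 Hz).

* **Generative assumptions.** Each component of a chord arises from a
  track with centre μᵢ; component log-frequencies scatter around the
  centre with variance σ²_track. The sensed frequency of a tone of
  duration *d* carries additional sensory noise of variance
  σ²_sense·d₀/d (d₀ = 150 ms), so longer tones are sensed more precisely.
  σ²_track and σ²_sense are the model's only free parameters.
* **Inference** is mean-field filtering in the corresponding factorial
  hidden Markov model. The first chord initialises one track per
  component (belief variance σ²_track + noise). Each later tone j is
  softly attributed to every track i with responsibility
  r₍ᵢⱼ₎ ∝ N(gⱼ; μᵢ, varᵢ + σ²_track + noise), and each track performs a
  conjugate Gaussian update with nᵢ = Σⱼ r₍ᵢⱼ₎ effective observations.
* **Readout.** For the test pair T1–T2, φᵢ = Σⱼₖ r₍ᵢⱼ₎ r₍ᵢₖ₎ (gₖ − gⱼ)
  sums all oriented component shifts weighted by the probability that both
  belong to track i; the report is the sign of Φ = Σᵢ φᵢ.

Around the model sit the stimulus generators (Shepard tones, half-octave
intertrial complexes, random inharmonic spectra with enforced midpoint
ambiguity, the six experiment designs with their printed trial counts),
simulated-listener cohorts, per-listener grid-search fitting of the two
variances, and the statistics machinery: listener-level bootstrap CIs
(Bonferroni-corrected, tested against 0.5), Kruskal–Wallis H with
permutation P values, and the 4-Hz probe-response spectrum / probe
response ratio (PRR) for synthetic evoked-response epochs.

## Worked example

```python
import numpy as np, json
import tonebind as tb

params = tb.ModelParams(sigma2_track=2.0, sigma2_sense=1.0)

# the ambiguity: 5000 no-context trials at the 6-st interval
trials = tb.build_experiment("exp1", dict(intervals_st=(6,), reps=5000),
                             seed=42)
ups = tb.simulate_trials(trials, params, np.random.default_rng(0))
print(round(ups.mean(), 3))          # 0.5 up to Monte-Carlo error

# its resolution: bias probability vs number of context tones
trials = tb.build_experiment("exp2", seed=3)
table = tb.predict_condition(trials, params, n_sim=25)
table["n"] = [json.loads(c)["n_context"] for c in table.condition]
print(table.sort_values("n").p_response.round(3).tolist())
```

prints (exact values vary with the seed)

```
0.5
[0.491, 0.906, 0.988, 0.989, 0.989, 0.999, 1.0, 1.0, 0.999, 1.0, 1.0]
```

— without context the ambiguous pair is at chance; a single context tone
already drives ~90% of responses through its frequency region, and from
about five tones the bias is essentially complete.

Run the full narrative with
`python analysis/01_build_stimuli.py` … `05_probe_spectrum.py`.

## Scope notes

The silent-gap and random-spectrum designs are generated and simulated but
excluded from fitting: capturing their behavioural profiles would require
memory decay over the gap and adaptive estimation of the generative
variance. See `docs/methods.md` for the model's assumptions, parameter
defaults and known limitations.
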