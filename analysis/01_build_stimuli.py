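#!/usr/bin/env python
"""Build every experiment's trial set and write them as CSV tables.

Generates the six stimulus designs (interval scan, context-count scan,
context-duration scan, silent-gap scan, random spectra, probe-sequence
design), reports the trial counts and condition grids, and renders one
demonstration trial to WAV.
"""

from pathlib import Path

import tonebind as tb

OUT = Path("results/trials")
SEED = 20260923


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for i, exp in enumerate(["exp1", "exp2", "exp4", "exp5", "exp6", "meg"]):
        trials = tb.build_experiment(exp, seed=SEED + i)
        tb.trials_to_csv(trials, OUT / f"trials_{exp}.csv")
        levels = sorted({t.condition_key for t in trials})
        print(f"{exp}: {len(trials)} trials, {len(levels)} condition cells")
    # one audible example: 5 context tones then the ambiguous test pair
    demo = tb.build_experiment(
        "exp2", dict(n_context_levels=(5,), reps=1, n_intertrial=0),
        seed=SEED)[0]
    wave = tb.synthesize_audio(demo, tb.EnvelopeSpec())
    tb.write_wav(OUT / "demo_trial.wav", wave)
    print(f"demo trial rendered to {OUT / 'demo_trial.wav'} "
          f"({len(wave) / 44100:.2f} s)")


if __name__ == "__main__":
    main()
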