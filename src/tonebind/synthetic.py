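"""Simulated-listener data generation.

Stands in for a behavioural cohort: each simulated listener owns a pair of
binding-model variance parameters and a lapse rate, and produces one
sampled binary response per trial (so downstream statistics see genuine
binomial noise).  Also generates the synthetic MEG-like probe-epoch arrays
consumed by the spectral analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding import ModelParams, simulate_trials

#: Default per-listener parameter bounds.  Variances are drawn
#: log-uniformly (they act multiplicatively); the lapse rate, whose lower
#: bound is 0, is drawn uniformly.
DEFAULT_PARAM_BOUNDS = {
    "sigma2_track": (0.5, 8.0),
    "sigma2_sense": (0.1, 4.0),
    "lapse": (0.0, 0.05),
}

RESPONSE_COLUMNS = ("listener_id", "trial_id", "experiment", "condition",
                    "bias_direction", "response",
                    "response_consistent_with_bias")


@dataclass
class SimListener:
    """One simulated participant: identity + true generative parameters."""

    listener_id: str
    params: ModelParams
    seed: int


def make_cohort(n_listeners, param_distribution=None, seed=0):
    """Draw a cohort of simulated listeners.

    Parameters are sampled independently per listener within
    ``param_distribution`` bounds (default :data:`DEFAULT_PARAM_BOUNDS`);
    reproducible given ``seed``.
    """
    if n_listeners < 1:
        raise ValueError("need at least one listener")
    bounds = dict(DEFAULT_PARAM_BOUNDS)
    bounds.update(param_distribution or {})
    for name in ("sigma2_track", "sigma2_sense"):
        lo, hi = bounds[name]
        if not (0 < lo <= hi):
            raise ValueError(f"{name} bounds must be positive and ordered")
    lo, hi = bounds["lapse"]
    if not (0 <= lo <= hi < 0.5):
        raise ValueError("lapse bounds must satisfy 0 <= lo <= hi < 0.5")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    listener_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                      for s in ss.spawn(n_listeners)]
    cohort = []
    for i in range(n_listeners):
        s2t = np.exp(rng.uniform(*np.log(bounds["sigma2_track"])))
        s2s = np.exp(rng.uniform(*np.log(bounds["sigma2_sense"])))
        lapse = rng.uniform(*bounds["lapse"])
        cohort.append(SimListener(
            listener_id=f"L{i:02d}",
            params=ModelParams(float(s2t), float(s2s), lapse=float(lapse),
                               seed=listener_seeds[i]),
            seed=listener_seeds[i]))
    return cohort


def cohort_to_dict(cohort):
    return [{"listener_id": sl.listener_id, "seed": sl.seed,
             "sigma2_track": sl.params.sigma2_track,
             "sigma2_sense": sl.params.sigma2_sense,
             "lapse": sl.params.lapse} for sl in cohort]


def cohort_from_dict(records):
    return [SimListener(r["listener_id"],
                        ModelParams(r["sigma2_track"], r["sigma2_sense"],
                                    lapse=r["lapse"], seed=r["seed"]),
                        r["seed"]) for r in records]


def simulate_responses(cohort, trials) -> pd.DataFrame:
    """One sampled binary response per listener x trial.

    Each listener runs the binding model once per trial with their own
    parameters and seed; with probability ``lapse`` the model response is
    replaced by a fair coin.  Returns a tidy ResponseTable with the
    consistency flag (NA when the trial has no bias direction).
    """
    frames = []
    bias = np.array([tr.bias_direction for tr in trials])
    meta = pd.DataFrame({
        "trial_id": [tr.trial_id for tr in trials],
        "experiment": [tr.experiment for tr in trials],
        "condition": [tr.condition_key for tr in trials],
        "bias_direction": bias,
    })
    for sl in cohort:
        rng = np.random.default_rng(sl.seed)
        up = simulate_trials(trials, sl.params, rng, n_sim=1)[0]
        if sl.params.lapse > 0:
            lapsed = rng.random(len(trials)) < sl.params.lapse
            coin = rng.random(len(trials)) < 0.5
            up = np.where(lapsed, coin, up)
        df = meta.copy()
        df.insert(0, "listener_id", sl.listener_id)
        df["response"] = np.where(up, "up", "down")
        consistent = pd.array(
            np.where(up, bias == "up", bias == "down").astype(int),
            dtype="Int64")
        consistent[bias == "none"] = pd.NA
        df["response_consistent_with_bias"] = consistent
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def responses_to_csv(responses: pd.DataFrame, path):
    responses.to_csv(path, index=False)


def responses_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"condition": str})
    df["response_consistent_with_bias"] = df[
        "response_consistent_with_bias"].astype("Int64")
    return df


def expand_conditions(responses: pd.DataFrame) -> pd.DataFrame:
    """Unpack the JSON condition column into ordinary columns."""
    import json

    cond = pd.DataFrame([json.loads(c) for c in responses["condition"]],
                        index=responses.index)
    return pd.concat([responses, cond], axis=1)


def make_probe_epochs(n_trials, *, epoch_ms=500.0, sample_rate=1000.0,
                      period_ms=250.0, latency_ms=50.0, width_ms=15.0,
                      amplitude=1.0, noise_sd=0.0, seed=0) -> np.ndarray:
    """Synthetic evoked-response epochs for the probe-spectrum analysis.

    Each epoch (one trial) contains an impulse-like Gaussian-bump response
    repeating every ``period_ms`` (default 250 ms, i.e. a 4 Hz presentation
    rate), plus optional white noise.  Emulates the rectified, averaged
    sensor power trace of a steady-state evoked response; it contains no
    background 1/f activity or inter-trial phase drift.
    """
    n_samp = int(round(epoch_ms / 1000.0 * sample_rate))
    t = np.arange(n_samp) / sample_rate * 1000.0  # ms
    sig = np.zeros(n_samp)
    onset = latency_ms
    while onset < epoch_ms:
        sig += np.exp(-0.5 * ((t - onset) / width_ms) ** 2)
        onset += period_ms
    epochs = amplitude * np.tile(sig, (int(n_trials), 1))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        epochs = epochs + rng.normal(0.0, noise_sd, size=epochs.shape)
    return epochs
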