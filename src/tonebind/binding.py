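"""Probabilistic temporal binding of tone components into frequency tracks.

The generative picture: each chord component arises from a latent 'track'
whose centre (log-)frequency drifts slowly; component log-frequencies are
Gaussian around the track centre with variance ``sigma2_track`` (st^2), and
the sensed frequency of each component is further corrupted by sensory
noise with variance ``sigma2_sense * d0 / d`` for a tone of duration ``d``
(longer tones are sensed more precisely).  Inference is mean-field
filtering in the corresponding factorial hidden Markov model: each incoming
tone is softly attributed to every track in proportion to its predictive
density (the 'responsibility'), and each track's Gaussian belief is updated
by a conjugate step using the responsibility-weighted evidence.

The reported percept for a test pair T1-T2 is the sum over tracks of all
oriented component shifts between the two chords, weighted by the
probability that both components belong to that track; its sign is the
binary up/down response.

Two equivalent implementations are provided: dataclass-level operations
(`sense`, `initialize_tracks`, `attribute`, `update_beliefs`,
`process_trial`) that mirror the model description step by step, and a
batched array path (`simulate_trials`) used by the Monte-Carlo heavy
simulation and fitting code.  A unit test pins their equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stimuli import Chord, TrialSpec

#: Reference tone duration for the sensory-noise law, ms.
D0_MS = 150.0


@dataclass
class ModelParams:
    """The two free variance parameters plus simulation controls.

    Parameters
    ----------
    sigma2_track : float
        Variance of component log-frequencies around their track centre,
        st^2.  Controls how wide a frequency range a track 'owns'.
    sigma2_sense : float
        Sensory-noise variance at the reference duration ``d0_ms``, st^2.
        A tone of duration d is sensed with variance sigma2_sense * d0 / d.
    d0_ms : float
        Reference tone duration, 150 ms.
    lapse : float
        Probability of a uniformly random response, in [0, 0.5).
    n_sim : int
        Monte-Carlo repetitions per trial in `predict_condition`.
    seed : int
        Seed for the model's own noise draws when no rng is supplied.
    diffusion : float
        Optional per-step drift variance of track centres, st^2 per chord.
        Defaults to 0: slow-drift capacity is carried by sigma2_track.
    """

    sigma2_track: float
    sigma2_sense: float
    d0_ms: float = D0_MS
    lapse: float = 0.0
    n_sim: int = 100
    seed: int = 0
    diffusion: float = 0.0

    def __post_init__(self):
        if not self.sigma2_track > 0:
            raise ValueError("sigma2_track must be positive")
        if self.sigma2_sense < 0:
            raise ValueError("sigma2_sense must be non-negative")
        if not 0 <= self.lapse < 0.5:
            raise ValueError("lapse must be in [0, 0.5)")
        if not self.d0_ms > 0:
            raise ValueError("d0_ms must be positive")
        if self.diffusion < 0:
            raise ValueError("diffusion must be non-negative")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")


@dataclass
class SensedChord:
    """A chord after sensory corruption: noisy log-frequencies g_j."""

    g: np.ndarray
    noise_variance: float
    source: Chord


@dataclass
class TrackBelief:
    """Gaussian belief about one track's centre frequency (st)."""

    mu: float
    var: float
    track_id: int

    def __post_init__(self):
        if not self.var > 0:
            raise ValueError("belief variance must be positive")


@dataclass
class Attribution:
    """Soft assignment of a chord's tones to the current tracks.

    ``responsibilities[i, j]`` is the posterior probability that tone j of
    the chord was generated by track i; each tone is fully distributed over
    tracks (columns sum to 1).  ``effective_counts[i]`` is the expected
    number of tones attributed to track i and ``weighted_means[i]`` the
    responsibility-weighted mean sensed frequency (NaN and ``defined[i]``
    False when the count is exactly zero).
    """

    responsibilities: np.ndarray
    effective_counts: np.ndarray
    weighted_means: np.ndarray
    defined: np.ndarray


@dataclass
class ShiftPercept:
    """Per-track local shifts phi_i, their sum Phi, and the binary report."""

    phi: np.ndarray
    Phi: float
    response: str  # 'up' or 'down'


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def sense(chord: Chord, params: ModelParams, rng) -> SensedChord:
    """Corrupt a chord's log-frequencies with duration-scaled sensory noise."""
    if not chord.duration_ms > 0:
        raise ValueError("cannot sense a non-positive-duration chord")
    nv = params.sigma2_sense * params.d0_ms / chord.duration_ms
    g = chord.log_components
    if nv > 0:
        g = g + rng.standard_normal(len(g)) * np.sqrt(nv)
    return SensedChord(np.asarray(g, dtype=float), float(nv), chord)


def initialize_tracks(sensed: SensedChord, params: ModelParams):
    """One track per component of the first chord; belief centred on the
    sensed frequency with variance sigma2_track + sensory noise."""
    if len(sensed.g) == 0:
        raise ValueError("cannot initialize tracks from an empty chord")
    var0 = params.sigma2_track + sensed.noise_variance
    return [TrackBelief(float(g), var0, i) for i, g in enumerate(sensed.g)]


def _responsibilities(mu, var, g, obs_var):
    """Soft attribution in log space; columns normalized over tracks."""
    pred_var = var + obs_var  # track predictive variance for a new tone
    diff = g[None, :] - mu[:, None]
    logd = -0.5 * (diff * diff / pred_var[:, None] + np.log(pred_var)[:, None])
    logd -= logd.max(axis=0, keepdims=True)
    r = np.exp(logd)
    r /= r.sum(axis=0, keepdims=True)
    return r


def _observation_variance(params: ModelParams, sensed: SensedChord) -> float:
    # per-tone generative variance seen from a track: component scatter
    # about the centre + sensory noise (+ optional per-step drift)
    return params.sigma2_track + sensed.noise_variance + params.diffusion


def attribute(tracks, sensed: SensedChord, params: ModelParams) -> Attribution:
    """Distribute each tone of a chord over all tracks.

    Responsibility r_ij is proportional to the Gaussian predictive density
    of tone j under track i (belief variance + component scatter + sensory
    noise), normalized over tracks for each tone.
    """
    if len(tracks) == 0:
        raise ValueError("need at least one track")
    mu = np.array([t.mu for t in tracks])
    var = np.array([t.var for t in tracks])
    r = _responsibilities(mu, var, sensed.g, _observation_variance(params, sensed))
    n = r.sum(axis=1)
    s = r @ sensed.g
    defined = n > 0
    gbar = np.full_like(n, np.nan)
    np.divide(s, n, out=gbar, where=defined)
    return Attribution(r, n, gbar, defined)


def update_beliefs(tracks, attribution: Attribution, sensed: SensedChord,
                   params: ModelParams):
    """Conjugate Gaussian update with n_i effective observations.

    Posterior precision adds n_i / obs_var; a track with zero effective
    count is left unchanged.
    """
    mu = np.array([t.mu for t in tracks])
    var = np.array([t.var for t in tracks])
    obs_var = _observation_variance(params, sensed)
    n = attribution.effective_counts
    s = attribution.responsibilities @ sensed.g
    prec = 1.0 / var + n / obs_var
    new_var = 1.0 / prec
    new_mu = new_var * (mu / var + s / obs_var)
    return [TrackBelief(float(m), float(v), t.track_id)
            for m, v, t in zip(new_mu, new_var, tracks)]


def shift_percept(r1, g1, r2, g2, rng) -> ShiftPercept:
    """Sum of oriented shifts between all T1/T2 component pairs, weighted by
    the probability that both belong to the same track.

    phi_i = sum_j sum_k r1[i,j] r2[i,k] (g2[k] - g1[j]); Phi = sum_i phi_i.
    An exact tie (Phi == 0) is broken by a fair coin.
    """
    n1 = r1.sum(axis=1)
    n2 = r2.sum(axis=1)
    phi = (r2 @ g2) * n1 - (r1 @ g1) * n2
    Phi = float(phi.sum())
    if Phi > 0:
        resp = "up"
    elif Phi < 0:
        resp = "down"
    else:
        resp = "up" if rng.random() < 0.5 else "down"
    return ShiftPercept(phi, Phi, resp)


def process_trial(trial: TrialSpec, params: ModelParams, rng) -> ShiftPercept:
    """Run the full filter over one trial and read out the shift percept.

    Tracks are initialized on the first non-intertrial chord (the first
    context tone, or T1 when there is no context); every later chord is
    attributed and used to update the beliefs.  The percept is computed
    from the responsibilities T1 and T2 received *before* T2's update.
    """
    chords = trial.model_chords()
    roles = [c.role for c in chords]
    if "test1" not in roles or "test2" not in roles:
        raise ValueError("trial is missing its test chords")
    r1 = g1 = None
    sensed0 = sense(chords[0], params, rng)
    tracks = initialize_tracks(sensed0, params)
    if roles[0] == "test1":
        # T1 initialized the tracks: each component is its own track
        r1 = np.eye(len(sensed0.g))
        g1 = sensed0.g
    percept = None
    for chord, role in zip(chords[1:], roles[1:]):
        sensed = sense(chord, params, rng)
        att = attribute(tracks, sensed, params)
        if role == "test1":
            r1, g1 = att.responsibilities, sensed.g
        elif role == "test2":
            percept = shift_percept(r1, g1, att.responsibilities, sensed.g, rng)
        tracks = update_beliefs(tracks, att, sensed, params)
    return percept


# ---------------------------------------------------------------------------
# batched simulation
# ---------------------------------------------------------------------------

def _trial_structure(trial: TrialSpec):
    chords = trial.model_chords()
    roles = tuple(c.role for c in chords)
    logf = [c.log_components for c in chords]
    durs = np.array([c.duration_ms for c in chords])
    return roles, logf, durs


def simulate_trials(trials, params: ModelParams, rng=None, n_sim=1) -> np.ndarray:
    """Simulate binary responses for many trials at once.

    Returns a boolean array of shape ``(n_sim, n_trials)`` where True means
    an 'up' response.  Trials are grouped by chord-role structure and padded
    to a common component count so the whole filter runs as array ops; the
    result is identical in distribution to calling :func:`process_trial`
    per trial (and identical deterministically when sigma2_sense = 0).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_sim = int(n_sim)
    out = np.zeros((n_sim, len(trials)), dtype=bool)
    groups: dict = {}
    for idx, tr in enumerate(trials):
        roles, logf, durs = _trial_structure(tr)
        groups.setdefault(roles, []).append((idx, logf, durs))
    for roles, members in groups.items():
        if "test1" not in roles or "test2" not in roles:
            raise ValueError("trial is missing its test chords")
        t1_idx = roles.index("test1")
        t2_idx = roles.index("test2")
        B = len(members)
        T = len(roles)
        idxs = np.array([m[0] for m in members])
        # pad components per chord position
        F, M = [], []
        for t in range(T):
            cmax = max(len(m[1][t]) for m in members)
            f = np.zeros((B, cmax))
            mask = np.zeros((B, cmax), dtype=bool)
            for b, m in enumerate(members):
                k = len(m[1][t])
                f[b, :k] = m[1][t]
                mask[b, :k] = True
            F.append(f)
            M.append(mask)
        durs = np.array([m[2] for m in members])  # (B, T)
        nv = params.sigma2_sense * params.d0_ms / durs  # (B, T)
        obs = params.sigma2_track + nv + params.diffusion
        # replicate the batch across Monte-Carlo draws
        R = B * n_sim
        rep = lambda a: np.repeat(a[None], n_sim, axis=0).reshape((R,) + a.shape[1:])
        Phi = np.zeros(R)
        track_mask = rep(M[0])
        g = rep(F[0])
        if params.sigma2_sense > 0:
            g = g + rep(np.sqrt(nv[:, 0])[:, None] * np.ones_like(F[0])) \
                * rng.standard_normal(g.shape)
        mu = g.copy()
        var = rep(np.broadcast_to((params.sigma2_track + nv[:, 0])[:, None],
                                  F[0].shape)).copy()
        n1 = s1 = None
        if t1_idx == 0:
            n1 = track_mask.astype(float)
            s1 = g * track_mask
        for t in range(1, T):
            Ft, Mt = rep(F[t]), rep(M[t])
            g = Ft
            if params.sigma2_sense > 0:
                g = g + rep(np.sqrt(nv[:, t])[:, None] * np.ones_like(F[t])) \
                    * rng.standard_normal(Ft.shape)
            obs_t = rep(obs[:, t])  # (R,)
            pv = var + obs_t[:, None]  # (R, K)
            diff = g[:, None, :] - mu[:, :, None]  # (R, K, C)
            logd = -0.5 * (diff * diff / pv[:, :, None]
                           + np.log(pv)[:, :, None])
            np.copyto(logd, -np.inf, where=~track_mask[:, :, None])
            logd -= logd.max(axis=1, keepdims=True)
            r = np.exp(logd)
            r /= r.sum(axis=1, keepdims=True)
            r *= Mt[:, None, :]  # padded tones carry no mass
            if t == t1_idx:
                n1 = r.sum(axis=2)
                s1 = np.einsum("rkc,rc->rk", r, g)
            if t == t2_idx:
                n2 = r.sum(axis=2)
                s2 = np.einsum("rkc,rc->rk", r, g)
                Phi = (s2 * n1 - s1 * n2).sum(axis=1)
            n = r.sum(axis=2)
            s = np.einsum("rkc,rc->rk", r, g)
            prec = 1.0 / var + n / obs_t[:, None]
            mu = (mu / var + s / obs_t[:, None]) / prec
            var = 1.0 / prec
        up = Phi > 0
        ties = Phi == 0
        if ties.any():
            up = up | (ties & (rng.random(R) < 0.5))
        out[:, idxs] = up.reshape(n_sim, B)
    return out


def predict_condition(trials, params: ModelParams, rng=None, measure="auto",
                      n_sim=None) -> pd.DataFrame:
    """Monte-Carlo estimate of per-condition response probabilities.

    For each condition level the probability of the measured response
    ('up', or 'bias'-consistent when every trial at the level carries a
    bias direction) is estimated over ``n_sim`` simulated responses per
    trial, then mixed with the lapse rate:
    p = (1 - lapse) * fraction + lapse / 2.

    Returns a DataFrame with columns ``experiment, condition, measure,
    n_trials, n_draws, p_response, mc_se``.
    """
    if len(trials) == 0:
        raise ValueError("no trials supplied")
    if n_sim is None:
        n_sim = params.n_sim
    if rng is None:
        rng = np.random.default_rng(params.seed)
    ups = simulate_trials(trials, params, rng, n_sim)  # (n_sim, N)
    by_level: dict = {}
    for j, tr in enumerate(trials):
        by_level.setdefault((tr.experiment, tr.condition_key), []).append(j)
    rows = []
    for (exp, cond), idxs in sorted(by_level.items()):
        biases = [trials[j].bias_direction for j in idxs]
        use_bias = measure == "bias" or (
            measure == "auto" and all(b != "none" for b in biases))
        vals = []
        for j, b in zip(idxs, biases):
            v = ups[:, j]
            if use_bias:
                v = v if b == "up" else ~v
            vals.append(v)
        frac = float(np.mean(np.concatenate(vals)))
        ndraw = n_sim * len(idxs)
        p = (1 - params.lapse) * frac + params.lapse / 2
        se = (1 - params.lapse) * float(np.sqrt(frac * (1 - frac) / ndraw))
        rows.append({"experiment": exp, "condition": cond,
                     "measure": "bias" if use_bias else "up",
                     "n_trials": len(idxs), "n_draws": ndraw,
                     "p_response": p, "mc_se": se})
    return pd.DataFrame(rows)
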