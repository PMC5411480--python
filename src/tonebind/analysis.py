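"""Behavioural and spectral statistics.

Implements the study's statistics machinery on tabular/array inputs:
per-condition bias proportions with listener-level bootstrap confidence
intervals (Bonferroni-adjusted, tested against the 0.5 chance level),
Kruskal-Wallis H tests with permutation-derived P values (labels shuffled
within listener when listener ids are supplied), and the steady-state
probe-response spectrum with its 4-Hz power and the probe response ratio
(PRR) between Context+ and Context- trial sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import expand_conditions


# ---------------------------------------------------------------------------
# bias summaries
# ---------------------------------------------------------------------------

def summarize_bias(responses: pd.DataFrame, groupby, n_boot=2000, alpha=0.05,
                   n_comparisons=None, seed=0, measure="auto") -> pd.DataFrame:
    """Per-condition response proportions with bootstrap CIs over listeners.

    For each level of ``groupby`` (a condition variable; the JSON condition
    column is expanded automatically) the statistic is the mean over
    listeners of each listener's proportion of bias-consistent responses
    (or of 'up'/T1-lower responses where no bias is defined).  The CI is a
    percentile bootstrap over listeners at level 1 - alpha/n_comparisons
    (Bonferroni; ``n_comparisons`` defaults to the number of levels), and
    significance is the CI excluding the 0.5 chance value.  Levels with
    fewer than 2 listeners are flagged unreliable.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    df = responses
    if groupby not in df.columns:
        df = expand_conditions(df)
        if groupby not in df.columns:
            raise ValueError(f"grouping variable {groupby!r} not found")
    df = df.copy()
    if measure == "auto":
        measure_vals = df["response_consistent_with_bias"].astype("Float64")
        fallback = (df["response"] == "up").astype(float)
        df["_y"] = measure_vals.astype(float).where(
            ~measure_vals.isna().to_numpy(), fallback)
    elif measure == "bias":
        df["_y"] = df["response_consistent_with_bias"].astype(float)
    else:
        df["_y"] = (df["response"] == "up").astype(float)
    rng = np.random.default_rng(seed)
    levels = sorted(df[groupby].dropna().unique().tolist())
    if n_comparisons is None:
        n_comparisons = len(levels)
    conf_alpha = alpha / max(n_comparisons, 1)
    rows = []
    for level in levels:
        sub = df[df[groupby] == level]
        per_listener = sub.groupby("listener_id")["_y"].mean().to_numpy()
        per_listener = per_listener[~np.isnan(per_listener)]
        m = len(per_listener)
        point = float(per_listener.mean()) if m else float("nan")
        boot = per_listener[
            rng.integers(0, m, size=(n_boot, m))].mean(axis=1)
        lo, hi = np.percentile(boot, [100 * conf_alpha / 2,
                                      100 * (1 - conf_alpha / 2)])
        rows.append({
            "level": level, "n_listeners": m, "p": point,
            "ci_low": float(lo), "ci_high": float(hi),
            "significant_vs_chance": bool(lo > 0.5 or hi < 0.5),
            "unreliable": m < 2,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kruskal-Wallis with permutation P value
# ---------------------------------------------------------------------------

@dataclass
class KWResult:
    H: float
    df: int
    p_perm: float
    n_permutations: int


def _h_from_ranks(rank_rows: np.ndarray, group_masks: np.ndarray,
                  group_sizes: np.ndarray, tie_correction: float) -> np.ndarray:
    """Vectorized H over many rank permutations (rows)."""
    N = rank_rows.shape[1]
    R = rank_rows @ group_masks.T  # (P, G) rank sums
    H = 12.0 / (N * (N + 1)) * (R * R / group_sizes).sum(axis=1) - 3 * (N + 1)
    return H / tie_correction


def kruskal_wallis_perm(values, groups, listeners=None, n_permutations=10000,
                        seed=0) -> KWResult:
    """Kruskal-Wallis H with a permutation-estimated P value.

    H uses the classical rank formula with tie correction.  The null
    distribution is built by shuffling group labels — within each
    listener's rows when ``listeners`` is given, otherwise freely — and
    P = (1 + #{H_perm >= H_obs}) / (n_permutations + 1).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have the same length")
    labels = np.unique(groups)
    if len(labels) < 2 or len(values) < 2:
        raise ValueError("need at least 2 groups and 2 observations")
    if np.ptp(values) == 0:
        # all observations identical: H defined as 0, nothing to test
        return KWResult(0.0, len(labels) - 1, 1.0, int(n_permutations))
    ranks = stats.rankdata(values)
    N = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_correction = 1.0 - ((tie_counts ** 3 - tie_counts).sum()
                            / (N ** 3 - N))
    masks = np.stack([groups == g for g in labels]).astype(float)
    sizes = masks.sum(axis=1)
    h_obs = float(_h_from_ranks(ranks[None, :], masks, sizes,
                                tie_correction)[0])
    rng = np.random.default_rng(seed)
    P = int(n_permutations)
    perm_ranks = np.tile(ranks, (P, 1))
    if listeners is None:
        perm_ranks = rng.permuted(perm_ranks, axis=1)
    else:
        listeners = np.asarray(listeners)
        if listeners.shape != values.shape:
            raise ValueError("listeners must align with values")
        for lid in np.unique(listeners):
            idx = np.where(listeners == lid)[0]
            perm_ranks[:, idx] = rng.permuted(perm_ranks[:, idx], axis=1)
    h_perm = _h_from_ranks(perm_ranks, masks, sizes, tie_correction)
    count = int((h_perm >= h_obs - 1e-12).sum())
    p = (1 + count) / (P + 1)
    return KWResult(h_obs, len(labels) - 1, float(p), P)


# ---------------------------------------------------------------------------
# probe spectrum / probe response ratio
# ---------------------------------------------------------------------------

@dataclass
class ProbeSpectrum:
    """Power spectrum of trial-concatenated probe-sequence responses."""

    frequencies: np.ndarray
    power: np.ndarray
    peak_frequency: float
    power_at_4hz: float


@dataclass
class PRRValue:
    """4-Hz probe power on Context+ trials over that on Context- trials."""

    prr: float
    power_plus: float
    power_minus: float


def probe_spectrum(epochs, sample_rate=1000.0, window_ms=500.0) -> ProbeSpectrum:
    """DFT power spectrum of the concatenated first window of each epoch.

    The first ``window_ms`` of every trial epoch are extracted, concatenated
    in trial order, and Fourier transformed.  The frequency grid must place
    a bin exactly at 4 Hz (guaranteed when window_ms * n_trials spans an
    integer number of 250-ms periods), so the 4-Hz power is read at the
    exact bin rather than integrated over a band.  The peak excludes the
    0 Hz (DC) bin.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    n_win = int(round(window_ms / 1000.0 * sample_rate))
    if epochs.shape[1] < n_win:
        raise ValueError(
            f"epochs have {epochs.shape[1]} samples, need {n_win} for a "
            f"{window_ms} ms window")
    concat = epochs[:, :n_win].reshape(-1)
    spec = np.fft.rfft(concat)
    power = (np.abs(spec) ** 2) / len(concat)
    freqs = np.fft.rfftfreq(len(concat), d=1.0 / sample_rate)
    df = freqs[1]
    bin4 = 4.0 / df
    if abs(bin4 - round(bin4)) > 1e-9:
        raise ValueError(
            f"frequency resolution {df} Hz does not place a bin at 4 Hz; "
            "adjust window or trial count")
    peak = float(freqs[1:][np.argmax(power[1:])])
    return ProbeSpectrum(freqs, power, peak, float(power[int(round(bin4))]))


def probe_response_ratio(spectrum_plus: ProbeSpectrum,
                         spectrum_minus: ProbeSpectrum) -> PRRValue:
    """PRR = 4-Hz power (Context+) / 4-Hz power (Context-)."""
    if (len(spectrum_plus.frequencies) != len(spectrum_minus.frequencies)
            or not np.allclose(spectrum_plus.frequencies,
                               spectrum_minus.frequencies)):
        raise ValueError("spectra must share the same frequency grid")
    p_plus, p_minus = spectrum_plus.power_at_4hz, spectrum_minus.power_at_4hz
    if p_minus <= 0 or p_plus <= 0:
        raise ValueError("both 4-Hz powers must be positive")
    return PRRValue(p_plus / p_minus, p_plus, p_minus)


def spectrum_to_frame(spectrum: ProbeSpectrum) -> pd.DataFrame:
    return pd.DataFrame({"frequency_hz": spectrum.frequencies,
                         "power": spectrum.power})
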