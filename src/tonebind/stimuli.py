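"""Stimulus construction for context-dependent pitch-shift experiments.

Builds the frequency-domain objects used throughout the package: Shepard
tones (octave-spaced chords with ambiguous pitch height), half-octave
intertrial complexes, random inharmonic spectra with enforced shift
ambiguity, and the full per-experiment trial sequences (context tones,
test pair, optional probe sequence).  All frequency reasoning is done in
semitone log-frequency units, st(f) = 12 * log2(f / 1 Hz); audio rendering
is an optional last step and the binding model never sees amplitudes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

SEMITONES_PER_OCTAVE = 12.0
#: Audible band applied uniformly to all generators, Hz.
AUDIBLE_BAND_HZ = (30.0, 22050.0)

CHORD_ROLES = ("context", "test1", "test2", "probe", "intertrial")
EXPERIMENTS = ("exp1", "exp2", "exp4", "exp5", "exp6", "meg")


def hz_to_st(f_hz):
    """Semitone log-frequency, st(f) = 12 * log2(f / 1 Hz)."""
    return SEMITONES_PER_OCTAVE * np.log2(np.asarray(f_hz, dtype=float))


def st_to_hz(st):
    """Inverse of :func:`hz_to_st`."""
    return 2.0 ** (np.asarray(st, dtype=float) / SEMITONES_PER_OCTAVE)


@dataclass(frozen=True)
class Chord:
    """A set of simultaneous pure-tone components, the atomic stimulus unit.

    Parameters
    ----------
    components : tuple of float
        Component frequencies in Hz, sorted ascending, all inside the
        audible band.
    duration_ms : float
        Tone duration in milliseconds (> 0).
    onset_ms : float
        Onset relative to trial start.
    role : str
        One of ``context``, ``test1``, ``test2``, ``probe``, ``intertrial``.
    """

    components: tuple
    duration_ms: float
    onset_ms: float = 0.0
    role: str = "context"

    def __post_init__(self):
        comps = tuple(float(c) for c in self.components)
        if len(comps) == 0:
            raise ValueError("chord must have at least one component")
        if any(b < a for a, b in zip(comps, comps[1:])):
            raise ValueError("components must be sorted ascending")
        lo, hi = AUDIBLE_BAND_HZ
        if comps[0] < lo or comps[-1] > hi:
            raise ValueError(
                f"components must lie within [{lo}, {hi}] Hz, got "
                f"[{comps[0]}, {comps[-1]}]"
            )
        if not self.duration_ms > 0:
            raise ValueError("duration must be positive")
        if self.role not in CHORD_ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        object.__setattr__(self, "components", comps)

    @property
    def log_components(self) -> np.ndarray:
        """Components in semitone log-frequency units."""
        return hz_to_st(np.array(self.components))

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms


@dataclass(frozen=True)
class EnvelopeSpec:
    """Spectral amplitude envelope used only for audio rendering."""

    centre_frequency_hz: float = 960.0
    sd_octaves: float = 1.0
    shape: str = "gaussian"  # or "flat"

    def __post_init__(self):
        if self.shape not in ("gaussian", "flat"):
            raise ValueError(f"unknown envelope shape {self.shape!r}")
        if self.shape == "gaussian" and not self.sd_octaves > 0:
            raise ValueError("sd_octaves must be positive for gaussian shape")

    def amplitude(self, f_hz) -> np.ndarray:
        f = np.asarray(f_hz, dtype=float)
        if self.shape == "flat":
            return np.ones_like(f)
        z = np.log2(f / self.centre_frequency_hz) / self.sd_octaves
        return np.exp(-0.5 * z * z)


@dataclass
class TrialSpec:
    """One trial: an ordered chord sequence plus its design condition.

    ``bias_direction`` is the pitch-shift direction a context-consistent
    response would take ('up', 'down', or 'none' when the trial carries no
    context chords).
    """

    trial_id: int
    experiment: str
    condition: dict
    chords: list
    bias_direction: str = "none"
    seed: int = 0

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        roles = [c.role for c in self.chords]
        if roles.count("test1") != 1 or roles.count("test2") != 1:
            raise ValueError("trial must contain exactly one test1 and one test2 chord")
        t1 = next(c for c in self.chords if c.role == "test1")
        t2 = next(c for c in self.chords if c.role == "test2")
        if not t2.onset_ms > t1.onset_ms:
            raise ValueError("test2 must follow test1")
        has_context = any(c.role == "context" for c in self.chords)
        if has_context == (self.bias_direction == "none"):
            raise ValueError(
                "bias_direction must be 'none' exactly when no context chords "
                f"are present (got {self.bias_direction!r}, context={has_context})"
            )
        if self.bias_direction not in ("up", "down", "none"):
            raise ValueError(f"bad bias_direction {self.bias_direction!r}")

    @property
    def condition_key(self) -> str:
        return json.dumps(self.condition, sort_keys=True)

    def model_chords(self) -> list:
        """Chords the binding model processes, in onset order.

        Intertrial chords are carried for audio rendering but never fed to
        the model.
        """
        seq = [c for c in self.chords if c.role != "intertrial"]
        return sorted(seq, key=lambda c: c.onset_ms)


# ---------------------------------------------------------------------------
# chord constructors
# ---------------------------------------------------------------------------

def _geometric_complex(base_frequency_hz, duration_ms, band_hz, spacing_factor,
                       onset_ms=0.0, role="context") -> Chord:
    lo, hi = band_hz
    if not lo <= base_frequency_hz < hi:
        raise ValueError(
            f"base frequency {base_frequency_hz} Hz outside band [{lo}, {hi})"
        )
    comps = []
    f = float(base_frequency_hz)
    while f <= hi * (1 + 1e-12):
        comps.append(f)
        f *= spacing_factor
    return Chord(tuple(comps), duration_ms, onset_ms, role)


def make_shepard_tone(base_frequency_hz, duration_ms=125.0,
                      band_hz=AUDIBLE_BAND_HZ, *, onset_ms=0.0,
                      role="context") -> Chord:
    """Shepard tone: pure tone at the base frequency plus all octave-related
    tones up to the band edge (e.g. up to eight above a 60 Hz base)."""
    return _geometric_complex(base_frequency_hz, duration_ms, band_hz, 2.0,
                              onset_ms, role)


def make_halfoctave_complex(base_frequency_hz, duration_ms=125.0,
                            band_hz=AUDIBLE_BAND_HZ, *, onset_ms=0.0,
                            role="intertrial") -> Chord:
    """Like a Shepard tone but with half-octave (sqrt(2)) component spacing;
    used between trials to flush carry-over context."""
    return _geometric_complex(base_frequency_hz, duration_ms, band_hz,
                              math.sqrt(2.0), onset_ms, role)


def make_random_spectrum_set(n_components, seed, *, n_context=5,
                             bias_direction="up", duration_ms=125.0,
                             band_hz=AUDIBLE_BAND_HZ):
    """Random inharmonic chords with an enforced ambiguous test shift.

    T1 components are drawn uniformly in log frequency over the band.  Each
    T2 component sits exactly at the log-frequency midpoint of two adjacent
    T1 components, so each T2 component is equidistant from its flanking T1
    components and the shift direction is ambiguous.  Context components are
    restricted to the half-gap between each T1 component and its bias-side
    midpoint, so the context favours only one direction of shift.

    Returns ``(t1, t2, context_chords)``.
    """
    n_components = int(n_components)
    if n_components < 2:
        raise ValueError("need at least 2 components to form ambiguous midpoints")
    if bias_direction not in ("up", "down"):
        raise ValueError("bias_direction must be 'up' or 'down'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo_st, hi_st = hz_to_st(band_hz[0]), hz_to_st(band_hz[1])
    t1_st = np.sort(rng.uniform(lo_st, hi_st, size=n_components))
    mid_st = 0.5 * (t1_st[:-1] + t1_st[1:])
    t1 = Chord(tuple(st_to_hz(t1_st)), duration_ms, role="test1")
    t2 = Chord(tuple(st_to_hz(mid_st)), duration_ms, role="test2")
    contexts = []
    for _ in range(int(n_context)):
        if bias_direction == "up":
            # between each T1 component and the midpoint just above it
            c_st = rng.uniform(t1_st[:-1], mid_st)
        else:
            # between each midpoint and the T1 component just above it
            c_st = rng.uniform(mid_st, t1_st[1:])
        contexts.append(Chord(tuple(st_to_hz(np.sort(c_st))), duration_ms,
                              role="context"))
    return t1, t2, contexts


# ---------------------------------------------------------------------------
# experiment builders
# ---------------------------------------------------------------------------

def _child_seeds(seed, n):
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _sequence(chords_spec):
    """Lay out (duration, iti, factory) entries into onset-stamped chords."""
    out, t = [], 0.0
    for duration_ms, iti_ms, make in chords_spec:
        out.append(make(t))
        t += duration_ms + iti_ms
    return out


def _intertrial_head(rng, n_tones, duration_ms=125.0, iti_ms=125.0,
                     gap_after_ms=500.0):
    """Half-octave complexes preceding the main sequence (audio only)."""
    chords = []
    t = 0.0
    for _ in range(int(n_tones)):
        fb = rng.uniform(60.0, 120.0)
        chords.append(make_halfoctave_complex(fb, duration_ms, onset_ms=t,
                                              role="intertrial"))
        t += duration_ms + iti_ms
    return chords, (t + gap_after_ms if n_tones else 0.0)


def wrap_to_base_octave(st, lo_hz=60.0, hi_hz=120.0):
    """Fold a semitone value into the canonical base octave [lo_hz, hi_hz).

    A Shepard tone's pitch class is defined mod octave; every base
    frequency derived by a semitone offset (test-2 tones, context tones)
    is folded back into the octave test bases are drawn from, so chords
    differ only in pitch class, never in band coverage.
    """
    lo = float(hz_to_st(lo_hz))
    return lo + (np.asarray(st, dtype=float) - lo) % SEMITONES_PER_OCTAVE


def _shepard_tone_at(st, duration_ms, onset_ms, role):
    return make_shepard_tone(float(st_to_hz(wrap_to_base_octave(st))),
                             duration_ms, onset_ms=onset_ms, role=role)


def _shepard_pair(st1, interval_st, t_start, duration_ms=125.0, iti_ms=125.0):
    t1 = make_shepard_tone(float(st_to_hz(st1)), duration_ms,
                           onset_ms=t_start, role="test1")
    t2 = _shepard_tone_at(st1 + interval_st, duration_ms,
                          t_start + duration_ms + iti_ms, "test2")
    return [t1, t2]


def _merged(defaults: dict, overrides) -> dict:
    overrides = dict(overrides or {})
    unknown = set(overrides) - set(defaults)
    if unknown:
        raise ValueError(f"unknown design overrides: {sorted(unknown)}")
    out = dict(defaults)
    out.update(overrides)
    return out


def _build_exp1(overrides, seed):
    d = _merged(dict(intervals_st=tuple(range(1, 12)), reps=40,
                     duration_ms=125.0, iti_ms=125.0, n_intertrial=3,
                     fb_range_hz=(60.0, 120.0)), overrides)
    rng = np.random.default_rng(seed)
    cells = [i for i in d["intervals_st"] for _ in range(d["reps"])]
    seeds = _child_seeds(seed, len(cells))
    order = rng.permutation(len(cells))
    trials = []
    for tid, idx in enumerate(order):
        interval = cells[idx]
        head, t0 = _intertrial_head(rng, d["n_intertrial"])
        fb1 = rng.uniform(*d["fb_range_hz"])
        pair = _shepard_pair(hz_to_st(fb1), interval, t0, d["duration_ms"],
                             d["iti_ms"])
        trials.append(TrialSpec(tid, "exp1", {"interval_st": int(interval)},
                                head + pair, "none", seeds[idx]))
    return trials


def _build_exp2(overrides, seed):
    d = _merged(dict(n_context_levels=tuple(range(0, 11)), reps=40,
                     interval_st=6, duration_ms=125.0, iti_ms=125.0,
                     context_test_gap_ms=500.0, n_intertrial=10,
                     fb_range_hz=(60.0, 120.0), region_halfwidth_st=6.0,
                     context_intervals_st=None), overrides)
    rng = np.random.default_rng(seed)
    scan = d["context_intervals_st"]
    if scan is not None:
        # single-context-tone variant: the context interval is the scanned
        # design variable instead of the number of context tones
        cells = [("scan", float(c)) for c in scan for _ in range(d["reps"])]
    else:
        cells = [("count", int(n)) for n in d["n_context_levels"]
                 for _ in range(d["reps"])]
    seeds = _child_seeds(seed, len(cells))
    order = rng.permutation(len(cells))
    trials = []
    for tid, idx in enumerate(order):
        kind, level = cells[idx]
        head, t0 = _intertrial_head(rng, d["n_intertrial"])
        fb1 = rng.uniform(*d["fb_range_hz"])
        st1 = float(hz_to_st(fb1))
        chords = list(head)
        t = t0
        if kind == "scan":
            condition = {"context_interval_st": level}
            bias = "up" if level >= 0 else "down"
            ctx_sts = [st1 + level]
        else:
            condition = {"n_context": level}
            region = rng.choice(["up", "down"])
            bias = region if level > 0 else "none"
            sign = 1.0 if region == "up" else -1.0
            ctx_sts = list(st1 + sign * rng.uniform(
                0.0, d["region_halfwidth_st"], size=level))
        for cst in ctx_sts:
            chords.append(_shepard_tone_at(cst, d["duration_ms"], t, "context"))
            t += d["duration_ms"] + d["iti_ms"]
        if ctx_sts:
            t += d["context_test_gap_ms"] - d["iti_ms"]
        chords += _shepard_pair(st1, d["interval_st"], t, d["duration_ms"],
                                d["iti_ms"])
        trials.append(TrialSpec(tid, "exp2", condition, chords, bias,
                                seeds[idx]))
    return trials


def _build_exp4(overrides, seed):
    d = _merged(dict(durations_ms=(0, 5, 10, 20, 40, 80, 160, 320), reps=40,
                     context_interval_st=3.0, interval_st=6, duration_ms=125.0,
                     n_intertrial=10, fb_range_hz=(60.0, 120.0)), overrides)
    rng = np.random.default_rng(seed)
    cells = [float(dur) for dur in d["durations_ms"] for _ in range(d["reps"])]
    seeds = _child_seeds(seed, len(cells))
    order = rng.permutation(len(cells))
    trials = []
    for tid, idx in enumerate(order):
        dur = cells[idx]
        head, t0 = _intertrial_head(rng, d["n_intertrial"])
        fb1 = rng.uniform(*d["fb_range_hz"])
        st1 = float(hz_to_st(fb1))
        side = rng.choice([1.0, -1.0])
        chords = list(head)
        t = t0
        if dur > 0:
            chords.append(_shepard_tone_at(
                st1 + side * d["context_interval_st"], dur, t, "context"))
            t += dur  # no ITI between context and T1, nor between T1 and T2
            bias = "up" if side > 0 else "down"
        else:
            bias = "none"  # a 0-ms context tone is no context chord at all
        chords += _shepard_pair(st1, d["interval_st"], t, d["duration_ms"],
                                iti_ms=0.0)
        trials.append(TrialSpec(tid, "exp4", {"context_duration_ms": dur},
                                chords, bias, seeds[idx]))
    return trials


def _build_exp5(overrides, seed):
    d = _merged(dict(gaps_s=(0.5, 1, 2, 4, 8, 16, 32, 64), reps=20,
                     n_context=5, interval_st=6, duration_ms=125.0,
                     iti_ms=125.0, n_intertrial=10,
                     fb_range_hz=(60.0, 120.0), region_halfwidth_st=6.0),
                overrides)
    rng = np.random.default_rng(seed)
    cells = [float(g) for g in d["gaps_s"] for _ in range(d["reps"])]
    seeds = _child_seeds(seed, len(cells))
    order = rng.permutation(len(cells))
    trials = []
    for tid, idx in enumerate(order):
        gap_s = cells[idx]
        head, t0 = _intertrial_head(rng, d["n_intertrial"])
        fb1 = rng.uniform(*d["fb_range_hz"])
        st1 = float(hz_to_st(fb1))
        region = rng.choice(["up", "down"])
        sign = 1.0 if region == "up" else -1.0
        chords = list(head)
        t = t0
        for _ in range(int(d["n_context"])):
            cst = st1 + sign * rng.uniform(0.0, d["region_halfwidth_st"])
            chords.append(_shepard_tone_at(cst, d["duration_ms"], t, "context"))
            t += d["duration_ms"] + d["iti_ms"]
        t += gap_s * 1000.0 - d["iti_ms"]
        chords += _shepard_pair(st1, d["interval_st"], t, d["duration_ms"],
                                d["iti_ms"])
        trials.append(TrialSpec(tid, "exp5", {"gap_s": gap_s}, chords, region,
                                seeds[idx]))
    return trials


def _build_exp6(overrides, seed):
    d = _merged(dict(n_components_levels=(3, 5, 10, 20, 40, 80), reps=40,
                     n_context=5, duration_ms=125.0, iti_ms=125.0), overrides)
    rng = np.random.default_rng(seed)
    cells = [(int(n), ctx) for n in d["n_components_levels"]
             for ctx in (True, False) for _ in range(d["reps"])]
    seeds = _child_seeds(seed, len(cells))
    order = rng.permutation(len(cells))
    trials = []
    for tid, idx in enumerate(order):
        n_comp, with_context = cells[idx]
        bias = rng.choice(["up", "down"]) if with_context else "none"
        t1, t2, ctx = make_random_spectrum_set(
            n_comp, rng, n_context=d["n_context"] if with_context else 0,
            bias_direction=bias if with_context else "up",
            duration_ms=d["duration_ms"])
        chords, t = [], 0.0
        for c in ctx:
            chords.append(replace(c, onset_ms=t))
            t += d["duration_ms"] + d["iti_ms"]
        chords.append(replace(t1, onset_ms=t))
        t += d["duration_ms"] + d["iti_ms"]
        chords.append(replace(t2, onset_ms=t))
        trials.append(TrialSpec(
            tid, "exp6",
            {"n_components": n_comp, "context": bool(with_context)},
            chords, bias if with_context else "none", seeds[idx]))
    return trials


def _build_meg(overrides, seed):
    d = _merged(dict(reps=30, n_context=8, n_probe=8, interval_st=6,
                     duration_ms=125.0, iti_ms=125.0, probe_duration_ms=35.0,
                     probe_iti_ms=215.0, fb_range_hz=(60.0, 120.0),
                     region_halfwidth_st=6.0), overrides)
    rng = np.random.default_rng(seed)
    cells = [(region, probe) for region in ("up", "down")
             for probe in ("plus", "minus") for _ in range(d["reps"])]
    seeds = _child_seeds(seed, len(cells))
    order = rng.permutation(len(cells))
    trials = []
    for tid, idx in enumerate(order):
        region, probe_region = cells[idx]
        fb1 = rng.uniform(*d["fb_range_hz"])
        st1 = float(hz_to_st(fb1))
        sign = 1.0 if region == "up" else -1.0
        chords, t = [], 0.0
        for _ in range(int(d["n_context"])):
            cst = st1 + sign * rng.uniform(0.0, d["region_halfwidth_st"])
            chords.append(_shepard_tone_at(cst, d["duration_ms"], t, "context"))
            t += d["duration_ms"] + d["iti_ms"]
        # probe tones at the centre of the context region (Context+) or of
        # the opposite half-octave region (Context-)
        probe_sign = sign if probe_region == "plus" else -sign
        probe_st = st1 + probe_sign * d["region_halfwidth_st"] / 2.0
        for _ in range(int(d["n_probe"])):
            chords.append(_shepard_tone_at(probe_st, d["probe_duration_ms"],
                                           t, "probe"))
            t += d["probe_duration_ms"] + d["probe_iti_ms"]
        chords += _shepard_pair(st1, d["interval_st"], t, d["duration_ms"],
                                d["iti_ms"])
        trials.append(TrialSpec(
            tid, "meg",
            {"context_region": region, "probe_region": probe_region},
            chords, region, seeds[idx]))
    return trials


_BUILDERS = {"exp1": _build_exp1, "exp2": _build_exp2, "exp4": _build_exp4,
             "exp5": _build_exp5, "exp6": _build_exp6, "meg": _build_meg}


def build_experiment(experiment, design_overrides=None, seed=0):
    """Build the full randomized trial list for one experiment design.

    Defaults reproduce the printed designs: exp1 scans the test interval
    1-11 st (440 trials); exp2 varies the number of half-octave-region
    context tones 0-10 (440 trials); exp4 varies a single +/-3 st context
    tone's duration 0-320 ms (320 trials); exp5 varies the context-test
    silent gap 0.5-64 s (160 trials); exp6 uses random spectra with 3-80
    components (480 trials); meg interleaves 4 Hz probe sequences.
    ``design_overrides`` replaces any named default; an unknown key or an
    unknown experiment name raises ``ValueError``.
    """
    if experiment not in _BUILDERS:
        raise ValueError(f"unknown experiment {experiment!r}; "
                         f"known: {sorted(_BUILDERS)}")
    return _BUILDERS[experiment](design_overrides, seed)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def trials_to_frame(trials) -> pd.DataFrame:
    """One row per chord; floats carried at full precision."""
    rows = []
    for tr in trials:
        for ch in sorted(tr.chords, key=lambda c: c.onset_ms):
            rows.append({
                "trial_id": tr.trial_id,
                "experiment": tr.experiment,
                "condition": tr.condition_key,
                "bias_direction": tr.bias_direction,
                "trial_seed": tr.seed,
                "role": ch.role,
                "onset_ms": repr(float(ch.onset_ms)),
                "duration_ms": repr(float(ch.duration_ms)),
                "components_hz": ";".join(repr(float(c))
                                          for c in ch.components),
            })
    return pd.DataFrame(rows)


def trials_to_csv(trials, path):
    trials_to_frame(trials).to_csv(path, index=False)


def trials_from_csv(path) -> list:
    df = pd.read_csv(path, dtype={"condition": str})
    trials = []
    for (tid, exp), grp in df.groupby(["trial_id", "experiment"], sort=True):
        chords = [
            Chord(tuple(float(x) for x in row.components_hz.split(";")),
                  float(row.duration_ms), float(row.onset_ms), row.role)
            for row in grp.itertuples()
        ]
        first = grp.iloc[0]
        trials.append(TrialSpec(int(tid), exp, json.loads(first.condition),
                                chords, first.bias_direction,
                                int(first.trial_seed)))
    trials.sort(key=lambda t: t.trial_id)
    return trials


# ---------------------------------------------------------------------------
# audio rendering
# ---------------------------------------------------------------------------

def synthesize_audio(trial, envelope=EnvelopeSpec(), sample_rate=44100,
                     ramp_ms=5.0) -> np.ndarray:
    """Render a trial as a sum of enveloped sinusoids, peak-normalized.

    Each component's amplitude is the spectral envelope evaluated at the
    component frequency; tones get raised-cosine on/off ramps.  Components
    at or above the Nyquist frequency are rejected.
    """
    chords = sorted(trial.chords, key=lambda c: c.onset_ms)
    nyquist = sample_rate / 2.0
    for ch in chords:
        if max(ch.components) >= nyquist:
            raise ValueError(
                f"component {max(ch.components)} Hz at or above Nyquist "
                f"({nyquist} Hz)")
    n = max(int(round(ch.onset_ms / 1000.0 * sample_rate))
            + int(round(ch.duration_ms / 1000.0 * sample_rate))
            for ch in chords)
    wave = np.zeros(n)
    n_ramp = int(round(ramp_ms / 1000.0 * sample_rate))
    for ch in chords:
        i0 = int(round(ch.onset_ms / 1000.0 * sample_rate))
        nd = int(round(ch.duration_ms / 1000.0 * sample_rate))
        t = np.arange(nd) / sample_rate
        seg = np.zeros(nd)
        amps = envelope.amplitude(np.array(ch.components))
        for f, a in zip(ch.components, amps):
            seg += a * np.sin(2 * np.pi * f * t)
        k = min(n_ramp, nd // 2)
        if k > 0:
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
            seg[:k] *= ramp
            seg[nd - k:] *= ramp[::-1]
        wave[i0:i0 + nd] += seg
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave = 0.95 * wave / peak
    return wave


def write_wav(path, waveform, sample_rate=44100):
    """Write a waveform to 16-bit PCM WAV."""
    data = np.clip(waveform, -1.0, 1.0)
    wavfile.write(path, int(sample_rate), (data * 32767).astype(np.int16))
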