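"""Reproducible end-to-end pipeline: stimuli -> simulated responses ->
fits -> statistics -> figures, driven by a single YAML-serializable
config.  All randomness flows from one root seed through named
per-stage substreams; re-running the same config is bit-identical for
every CSV output (the manifest records file hashes to prove it).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .stimuli import build_experiment, trials_to_csv, trials_from_csv
from .synthetic import (make_cohort, cohort_to_dict, simulate_responses,
                        responses_to_csv)
from .fitting import FitConfig, fit_cohort
from .analysis import summarize_bias

#: Condition variable plotted/grouped per experiment.
GROUP_VARS = {"exp1": "interval_st", "exp2": "n_context",
              "exp4": "context_duration_ms", "exp5": "gap_s",
              "exp6": "n_components", "meg": "probe_region"}

_STAGES = ("stimuli", "cohort", "responses", "fit", "analysis")


@dataclass
class RunConfig:
    """Fully serialized description of one pipeline run."""

    seed: int
    experiments: list = field(default_factory=lambda: ["exp2"])
    n_listeners: int = 3
    cohort_bounds: dict = None
    design_overrides: dict = field(default_factory=dict)
    run_fit: bool = False
    fit: dict = field(default_factory=dict)
    n_boot: int = 1000
    make_figures: bool = True
    out_dir: str = "results/pipeline"

    def __post_init__(self):
        if self.seed is None or not isinstance(self.seed, (int, np.integer)):
            raise ValueError("config must carry an explicit integer seed")
        unknown = set(self.experiments) - set(GROUP_VARS)
        if unknown:
            raise ValueError(f"unknown experiments: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _stage_seeds(root_seed):
    ss = np.random.SeedSequence(root_seed)
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(_STAGES, ss.spawn(len(_STAGES)))}


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = {"tonebind_version": __version__,
                "numpy_version": np.__version__,
                "seed": config.seed, "stage_seeds": seeds, "files": {}}
    artifacts = {}

    def _run(stage, fn):
        try:
            return fn()
        except Exception as exc:  # surface which stage died
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    def _save_csv(name, writer):
        path = out / name
        writer(path)
        manifest["files"][name] = _sha256(path)
        return path

    # --- stimuli ---------------------------------------------------------
    def _stimuli():
        trials = {}
        for i, exp in enumerate(config.experiments):
            tr = build_experiment(exp, config.design_overrides.get(exp),
                                  seed=seeds["stimuli"] + i)
            trials[exp] = tr
            _save_csv(f"trials_{exp}.csv", lambda p, tr=tr: trials_to_csv(tr, p))
        return trials

    trials = _run("stimuli", _stimuli)

    # --- cohort + responses ---------------------------------------------
    def _cohort():
        cohort = make_cohort(config.n_listeners, config.cohort_bounds,
                             seed=seeds["cohort"])
        path = out / "cohort.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(cohort_to_dict(cohort), fh, sort_keys=True)
        manifest["files"]["cohort.yaml"] = _sha256(path)
        return cohort

    cohort = _run("cohort", _cohort)

    def _responses():
        tables = {}
        for exp, tr in trials.items():
            resp = simulate_responses(cohort, tr)
            tables[exp] = resp
            _save_csv(f"responses_{exp}.csv",
                      lambda p, r=resp: responses_to_csv(r, p))
        return tables

    responses = _run("responses", _responses)

    # --- fitting (optional) ---------------------------------------------
    if config.run_fit:
        def _fit():
            fit_cfg = FitConfig(seed=seeds["fit"], **config.fit)
            pooled = pd.concat(responses.values(), ignore_index=True)
            pooled_trials = [t for tr in trials.values() for t in tr]
            fits = fit_cohort(pooled, pooled_trials, fit_cfg)
            _save_csv("fits.csv", lambda p: fits.to_csv(p, index=False))
            return fits

        artifacts["fits"] = _run("fit", _fit)

    # --- analysis --------------------------------------------------------
    def _analysis():
        summaries = {}
        for exp, resp in responses.items():
            var = GROUP_VARS[exp]
            summary = summarize_bias(resp, var, n_boot=config.n_boot,
                                     seed=seeds["analysis"])
            summaries[exp] = summary
            _save_csv(f"bias_{exp}.csv",
                      lambda p, s=summary: s.to_csv(p, index=False))
            if config.make_figures:
                _plot_summary(exp, var, summary, out / f"bias_{exp}.png")
        return summaries

    artifacts["summaries"] = _run("analysis", _analysis)

    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _plot_summary(exp, var, summary, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    x = np.arange(len(summary))
    ax.errorbar(x, summary["p"],
                yerr=[summary["p"] - summary["ci_low"],
                      summary["ci_high"] - summary["p"]],
                fmt="o-", capsize=3)
    ax.axhline(0.5, ls=":", color="grey")
    ax.set_xticks(x, [str(v) for v in summary["level"]])
    ax.set_xlabel(var)
    ax.set_ylabel("P(response)")
    ax.set_ylim(0, 1)
    ax.set_title(exp)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# table validation
# ---------------------------------------------------------------------------

_TRIAL_COLS = {"trial_id", "experiment", "condition", "bias_direction",
               "trial_seed", "role", "onset_ms", "duration_ms",
               "components_hz"}
_RESPONSE_COLS = {"listener_id", "trial_id", "experiment", "condition",
                  "bias_direction", "response",
                  "response_consistent_with_bias"}


def validate_tables(path) -> list:
    """Schema and invariant checks for trial/response CSVs.

    Returns a list of violation dicts (empty means the table is valid),
    each with a ``check`` name, a human-readable ``message`` and where
    possible the offending ``trial_id``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    cols = set(df.columns)
    violations = []
    if _TRIAL_COLS <= cols:
        for (tid, exp), grp in df.groupby(["trial_id", "experiment"]):
            roles = grp["role"].tolist()
            if roles.count("test1") != 1 or roles.count("test2") != 1:
                violations.append({
                    "check": "test_pair", "trial_id": int(tid),
                    "message": f"trial {tid} ({exp}) must contain exactly one "
                               "test1 and one test2 chord"})
                continue
            t1 = float(grp.loc[grp.role == "test1", "onset_ms"].iloc[0])
            t2 = float(grp.loc[grp.role == "test2", "onset_ms"].iloc[0])
            if not t2 > t1:
                violations.append({
                    "check": "test_order", "trial_id": int(tid),
                    "message": f"trial {tid}: test2 must follow test1"})
            if grp["condition"].nunique() > 1 or grp["bias_direction"].nunique() > 1:
                violations.append({
                    "check": "trial_consistency", "trial_id": int(tid),
                    "message": f"trial {tid}: conflicting condition/bias rows"})
            has_ctx = "context" in roles
            bias = grp["bias_direction"].iloc[0]
            if has_ctx == (bias == "none"):
                violations.append({
                    "check": "bias_direction", "trial_id": int(tid),
                    "message": f"trial {tid}: bias_direction '{bias}' "
                               "inconsistent with context presence"})
    elif _RESPONSE_COLS <= cols:
        dup = df.duplicated(["listener_id", "trial_id", "experiment"])
        for tid in df.loc[dup, "trial_id"].unique():
            violations.append({
                "check": "duplicate_rows", "trial_id": int(tid),
                "message": f"duplicated response rows for trial {tid}"})
        bad = ~df["response"].isin(["up", "down"])
        if bad.any():
            violations.append({
                "check": "response_values", "trial_id": None,
                "message": f"{int(bad.sum())} rows with response not in "
                           "{'up','down'}"})
        cons_na = df["response_consistent_with_bias"].isna()
        mismatch = cons_na != (df["bias_direction"] == "none")
        if mismatch.any():
            violations.append({
                "check": "consistency_flag", "trial_id": None,
                "message": f"{int(mismatch.sum())} rows where the consistency "
                           "flag NA-ness disagrees with bias_direction"})
    else:
        violations.append({"check": "schema", "trial_id": None,
                           "message": "unrecognized table schema"})
    return violations
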