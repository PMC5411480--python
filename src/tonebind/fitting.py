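"""Per-listener estimation of the two binding-model variance parameters.

The likelihood is binomial over per-condition response counts, with the
condition probabilities estimated by Monte-Carlo simulation of the binding
model.  Because that likelihood is noisy and the optimum is known to be
broad, estimation is a log-spaced 2-D grid search with a fixed simulation
seed shared across grid points (common random numbers), rather than a
gradient method.  The lapse rate is fixed, not fitted: it guards the
likelihood against 0/1 empirical cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .binding import ModelParams, simulate_trials

#: Experiments whose data enter the fitting objective.  The silent-gap and
#: random-spectrum designs are deliberately excluded: modelling them would
#: need time-dependent sensory decay / adaptive generative variance.
MODELLED_EXPERIMENTS = ("exp1", "exp2", "exp4")


@dataclass
class FitConfig:
    grid_min: float = 0.05
    grid_max: float = 20.0
    n_grid: int = 15
    lapse: float = 0.02
    n_sim: int = 2
    seed: int = 0
    experiments: tuple = MODELLED_EXPERIMENTS

    def grid(self) -> np.ndarray:
        return np.geomspace(self.grid_min, self.grid_max, self.n_grid)


@dataclass
class FitResult:
    """Grid-search maximum-likelihood estimate plus the full surface."""

    listener_id: str
    sigma2_track_hat: float
    sigma2_sense_hat: float
    log_likelihood: float
    surface: pd.DataFrame
    converged: bool
    degenerate: bool
    config: FitConfig


def _observed_counts(responses: pd.DataFrame, trials):
    """Per (condition, bias-direction) cell: number of trials and number of
    'up' responses.  Conditioning on the bias direction keeps cells
    homogeneous when a design randomizes the context region per trial."""
    by_id = {(tr.experiment, tr.trial_id): tr for tr in trials}
    cells: dict = {}
    for row in responses.itertuples():
        tr = by_id.get((row.experiment, row.trial_id))
        if tr is None:
            raise ValueError(
                f"response references unknown trial {row.experiment}/"
                f"{row.trial_id}")
        key = (tr.experiment, tr.condition_key, tr.bias_direction)
        n, k = cells.get(key, (0, 0))
        cells[key] = (n + 1, k + (row.response == "up"))
    return cells


def _predicted_up(trials, s2t, s2s, config: FitConfig):
    """Per-cell model probability of 'up' at one grid point (lapse-mixed)."""
    params = ModelParams(s2t, s2s, lapse=0.0, seed=config.seed)
    rng = np.random.default_rng(config.seed)  # common random numbers
    ups = simulate_trials(trials, params, rng, n_sim=config.n_sim)
    cells: dict = {}
    for j, tr in enumerate(trials):
        key = (tr.experiment, tr.condition_key, tr.bias_direction)
        n, k = cells.get(key, (0, 0))
        cells[key] = (n + ups.shape[0], k + int(ups[:, j].sum()))
    return {key: (1 - config.lapse) * (k / n) + config.lapse / 2
            for key, (n, k) in cells.items()}


def fit_listener(responses: pd.DataFrame, trials, config=None,
                 listener_id=None) -> FitResult:
    """Maximum-likelihood grid search for one listener.

    ``responses`` holds that listener's rows of a ResponseTable; ``trials``
    the TrialSpecs they were collected on.  Only the modelled experiments
    enter the objective.  Returns the argmax, the log-likelihood surface
    (one row per grid point), a convergence flag (False when the optimum
    sits on the grid boundary) and a degeneracy flag (surface flat to
    within 1e-6, e.g. all-identical responses under zero noise).
    """
    config = config or FitConfig()
    if listener_id is None:
        ids = responses["listener_id"].unique()
        if len(ids) != 1:
            raise ValueError(
                "responses must belong to a single listener; pass "
                "listener_id or pre-filter")
        listener_id = ids[0]
    responses = responses[responses["experiment"].isin(config.experiments)]
    trials = [tr for tr in trials if tr.experiment in config.experiments]
    if len(responses) == 0 or len(trials) == 0:
        raise ValueError("no responses/trials in the modelled experiments")
    observed = _observed_counts(responses, trials)
    grid = config.grid()
    rows = []
    for s2t in grid:
        for s2s in grid:
            predicted = _predicted_up(trials, s2t, s2s, config)
            ll = 0.0
            for key, (n, k) in observed.items():
                ll += float(stats.binom.logpmf(k, n, predicted[key]))
            rows.append({"sigma2_track": s2t, "sigma2_sense": s2s,
                         "log_likelihood": ll})
    surface = pd.DataFrame(rows)
    best = surface["log_likelihood"].idxmax()
    s2t_hat = float(surface.loc[best, "sigma2_track"])
    s2s_hat = float(surface.loc[best, "sigma2_sense"])
    ll_hat = float(surface.loc[best, "log_likelihood"])
    on_edge = s2t_hat in (grid[0], grid[-1]) or s2s_hat in (grid[0], grid[-1])
    degenerate = bool(surface["log_likelihood"].max()
                      - surface["log_likelihood"].min() < 1e-6)
    return FitResult(listener_id, s2t_hat, s2s_hat, ll_hat, surface,
                     converged=not on_edge, degenerate=degenerate,
                     config=config)


def fit_cohort(responses: pd.DataFrame, trials, config=None) -> pd.DataFrame:
    """Fit every listener in a ResponseTable; returns one row per listener."""
    rows = []
    for lid, grp in responses.groupby("listener_id", sort=True):
        fr = fit_listener(grp, trials, config, listener_id=lid)
        rows.append({"listener_id": lid,
                     "sigma2_track_hat": fr.sigma2_track_hat,
                     "sigma2_sense_hat": fr.sigma2_sense_hat,
                     "log_likelihood": fr.log_likelihood,
                     "converged": fr.converged,
                     "degenerate": fr.degenerate})
    return pd.DataFrame(rows)


def predict_curves(fit: FitResult, trials, n_sim=200, n_boot=500, alpha=0.05,
                   seed=None) -> pd.DataFrame:
    """Model psychometric curves at the fitted parameters with Monte-Carlo
    confidence intervals (bootstrap over simulation draws)."""
    seed = fit.config.seed if seed is None else seed
    params = ModelParams(fit.sigma2_track_hat, fit.sigma2_sense_hat,
                         lapse=fit.config.lapse, seed=seed)
    rng = np.random.default_rng(seed)
    ups = simulate_trials(trials, params, rng, n_sim=n_sim)  # (n_sim, N)
    by_level: dict = {}
    for j, tr in enumerate(trials):
        by_level.setdefault((tr.experiment, tr.condition_key), []).append(j)
    rows = []
    for (exp, cond), idxs in sorted(by_level.items()):
        biases = [trials[j].bias_direction for j in idxs]
        use_bias = all(b != "none" for b in biases)
        cols = []
        for j, b in zip(idxs, biases):
            v = ups[:, j]
            cols.append(v if (not use_bias or b == "up") else ~v)
        mat = np.column_stack(cols)  # (n_sim, n_trials_in_level)
        per_draw = mat.mean(axis=1)
        boot = rng.choice(per_draw, size=(n_boot, n_sim), replace=True).mean(axis=1)
        mix = lambda p: (1 - params.lapse) * p + params.lapse / 2
        lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        rows.append({"experiment": exp, "condition": cond,
                     "measure": "bias" if use_bias else "up",
                     "p_response": mix(float(per_draw.mean())),
                     "ci_low": mix(float(lo)), "ci_high": mix(float(hi))})
    return pd.DataFrame(rows)
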