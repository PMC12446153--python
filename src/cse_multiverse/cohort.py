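"""Stage-1 cohort simulation.

Samples participant-level random effects from the configured multivariate
normal, generates Gaussian trial RTs and binomial accuracies for the four
condition cells (cC, cI, iC, iI), and aggregates to per-cell summaries — the
(mean RT, RT variance, accuracy) triplets that the EZ transformation consumes.
Stage-1 trial draws are normally not retained; :func:`simulate_stage1_trials`
exposes them for parameter-recovery checks.

Units: parameter profiles are in ms; all tables emitted here use seconds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from .params import EffectModelParams

__all__ = [
    "CELLS",
    "sample_participants",
    "simulate_stage1",
    "simulate_stage1_trials",
]

#: The four condition cells as (prev_congruency, congruency) codes;
#: lowercase = previous trial, uppercase = current trial.
CELLS = (("c", "C"), ("c", "I"), ("i", "C"), ("i", "I"))

_X = {("c", "C"): (0, 0), ("c", "I"): (1, 0), ("i", "C"): (0, 1), ("i", "I"): (1, 1)}


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_participants(params: EffectModelParams, n: int, seed) -> pd.DataFrame:
    """Draw ``n`` participants' random effects.

    RT effects (intercept, congruency slope) come from a zero-mean MVN with
    covariance ``params.re_cov`` (ms); the accuracy intercept from an
    independent N(0, acc_re_sd^2) (logit). Returns columns
    ``participant_id, u_intercept, u_slope, u_acc``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params.validate()
    rng = _as_rng(seed)
    u_rt = rng.multivariate_normal(np.zeros(2), params.re_cov, size=n,
                                   method="cholesky" if _is_pd(params.re_cov) else "svd")
    u_acc = rng.normal(0.0, params.acc_re_sd, size=n) if params.acc_re_sd > 0 else np.zeros(n)
    return pd.DataFrame({
        "participant_id": np.arange(n),
        "u_intercept": u_rt[:, 0],
        "u_slope": u_rt[:, 1],
        "u_acc": u_acc,
    })


def _is_pd(cov: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(cov)
        return True
    except np.linalg.LinAlgError:
        return False


def _cell_means_ms(params: EffectModelParams, effects: pd.DataFrame,
                   x_cur: int, x_prev: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-participant RT cell mean (ms) and accuracy probability."""
    mu = (params.beta_intercept
          + params.beta_congruency * x_cur
          + params.beta_previous * x_prev
          + params.beta_interaction * x_cur * x_prev
          + effects["u_intercept"].to_numpy()
          + effects["u_slope"].to_numpy() * x_cur)
    eta = (params.acc_intercept
           + params.acc_congruency * x_cur
           + params.acc_previous * x_prev
           + params.acc_interaction * x_cur * x_prev
           + effects["u_acc"].to_numpy())
    return mu, expit(eta)


def simulate_stage1(params: EffectModelParams, effects: pd.DataFrame,
                    trials_per_cell: int, seed) -> pd.DataFrame:
    """Generate per-cell summaries from Gaussian trials and binomial accuracy.

    For each participant x cell, draws ``trials_per_cell`` RTs from
    N(cell mean, resid_sd^2) and an accuracy count from
    Binomial(trials_per_cell, inverse-logit of the accuracy predictor), then
    records the sample mean/variance (seconds, ddof=1) and the accuracy
    proportion. Returns 4 rows per participant.
    """
    if trials_per_cell < 2:
        raise ValueError("trials_per_cell must be >= 2 so the cell variance is defined")
    rng = _as_rng(seed)
    n = len(effects)
    rows = []
    for prev, cur in CELLS:
        x_cur, x_prev = _X[(prev, cur)]
        mu_ms, p_acc = _cell_means_ms(params, effects, x_cur, x_prev)
        draws = rng.normal(mu_ms[:, None], params.resid_sd,
                           size=(n, trials_per_cell)) / 1000.0
        k = rng.binomial(trials_per_cell, p_acc)
        rows.append(pd.DataFrame({
            "participant_id": effects["participant_id"].to_numpy(),
            "prev_congruency": prev,
            "congruency": cur,
            "mean_rt": draws.mean(axis=1),
            "var_rt": draws.var(axis=1, ddof=1),
            "accuracy": k / trials_per_cell,
            "n_trials": trials_per_cell,
        }))
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["participant_id", "prev_congruency", "congruency"],
                           ignore_index=True)


def simulate_stage1_trials(params: EffectModelParams, effects: pd.DataFrame,
                           trials_per_cell: int, seed) -> pd.DataFrame:
    """Trial-level stage-1 table (used for mixed-model parameter recovery).

    Same generative model as :func:`simulate_stage1` but the Gaussian trial
    draws are kept. Columns: ``participant_id, prev_congruency, congruency,
    rt_s, correct, trial_index``; correctness is sampled per trial from the
    accuracy model.
    """
    if trials_per_cell < 1:
        raise ValueError("trials_per_cell must be >= 1")
    rng = _as_rng(seed)
    n = len(effects)
    rows = []
    for prev, cur in CELLS:
        x_cur, x_prev = _X[(prev, cur)]
        mu_ms, p_acc = _cell_means_ms(params, effects, x_cur, x_prev)
        draws = rng.normal(mu_ms[:, None], params.resid_sd,
                           size=(n, trials_per_cell)) / 1000.0
        correct = rng.random((n, trials_per_cell)) < p_acc[:, None]
        rows.append(pd.DataFrame({
            "participant_id": np.repeat(effects["participant_id"].to_numpy(),
                                        trials_per_cell),
            "prev_congruency": prev,
            "congruency": cur,
            "rt_s": draws.ravel(),
            "correct": correct.ravel().astype(int),
            "trial_index": np.tile(np.arange(trials_per_cell), n),
        }))
    return pd.concat(rows, ignore_index=True)
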