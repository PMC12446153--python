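"""EZ diffusion closed forms and trial-level Wiener sampling.

Stage 2 of the generator: each participant x condition cell summary
(mean RT, RT variance, accuracy) is mapped to the three parameters of an
unbiased two-boundary Wiener process — drift rate ``v``, boundary separation
``a`` and non-decision time ``Ter`` at fixed scaling ``s`` — via the EZ
closed-form inversion. Trial-level (RT, correctness) pairs are then drawn
from the exact first-passage distribution of that process, and a configurable
share of trials is swapped for uniform "contaminant" RTs emulating
inattention.

With logit L = log(Pc/(1-Pc)) the inversion is::

    v   = sign(Pc - 1/2) * s * [ L (L Pc^2 - L Pc + Pc - 1/2) / VRT ]^(1/4)
    a   = s^2 L / v
    MDT = (a / 2v) * (1 - exp(-va/s^2)) / (1 + exp(-va/s^2))
    Ter = MRT - MDT

and :func:`ez_forward` is its exact inverse (the predicted accuracy, correct-RT
mean and correct-RT variance of the process), used as the round-trip and
moment oracle.

Sampling uses the classical large-time series for the first-passage density.
For an unbiased start (z = a/2) the decision-time distribution is the same at
both boundaries and, in scaled time tau = t s^2 / a^2, forms a one-parameter
family in mu = v a / s^2::

    f(tau) ∝ exp(-mu^2 tau / 2) * S(tau),
    S(tau) = sum_{k odd} (-1)^((k-1)/2) k exp(-k^2 pi^2 tau / 2)

so the boundary series S is precomputed once on a fixed grid and each cell
costs a single inverse-CDF pass. Boundary choice is an exact Bernoulli with
P(correct) = 1 / (1 + exp(-mu)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.special import logit as _logit

__all__ = [
    "DiffusionParams",
    "EZError",
    "edge_correct",
    "ez_inverse",
    "ez_forward",
    "sample_trials",
    "inject_contaminants",
]

DEFAULT_SCALING = 0.1


class EZError(ValueError):
    """Raised when a cell summary cannot be mapped to diffusion parameters."""


@dataclass(frozen=True)
class DiffusionParams:
    """Unbiased Wiener process parameters (evidence units / seconds)."""

    drift_v: float
    boundary_a: float
    ter: float
    scaling_s: float = DEFAULT_SCALING

    def __post_init__(self) -> None:
        if not self.boundary_a > 0:
            raise ValueError("boundary_a must be > 0")
        if self.ter < 0:
            raise ValueError("ter must be >= 0")
        if not self.scaling_s > 0:
            raise ValueError("scaling_s must be > 0")


def edge_correct(accuracy: float, n_trials: int) -> float:
    """Standard EZ edge correction: pull 0/1 accuracies off the boundary.

    A proportion of 1 becomes 1 - 1/(2n) and 0 becomes 1/(2n); anything in
    the open interval is returned unchanged.
    """
    if accuracy >= 1.0:
        return 1.0 - 1.0 / (2 * n_trials)
    if accuracy <= 0.0:
        return 1.0 / (2 * n_trials)
    return float(accuracy)


def ez_inverse(mean_rt: float, var_rt: float, accuracy: float,
               scaling_s: float = DEFAULT_SCALING) -> DiffusionParams:
    """Map a (MRT, VRT, Pc) cell summary to (v, a, Ter).

    ``mean_rt``/``var_rt`` in seconds / seconds^2; ``accuracy`` must already
    be edge-corrected into (0, 1) and away from exactly 0.5, where the drift
    is undefined.
    """
    if not 0.0 < accuracy < 1.0:
        raise EZError(f"accuracy must be in (0, 1) after edge correction, got {accuracy}")
    if accuracy == 0.5:
        raise EZError("drift undefined: accuracy is exactly 0.5 (logit = 0)")
    if not var_rt > 0:
        raise EZError(f"var_rt must be > 0, got {var_rt}")
    s = scaling_s
    pc = float(accuracy)
    L = float(_logit(pc))
    x = L * (L * pc**2 - L * pc + pc - 0.5) / var_rt
    v = float(np.sign(pc - 0.5) * s * x**0.25)
    a = s**2 * L / v
    y = np.exp(-v * a / s**2)
    mdt = (a / (2 * v)) * (1 - y) / (1 + y)
    ter = mean_rt - mdt
    return DiffusionParams(drift_v=v, boundary_a=float(a), ter=float(max(ter, 0.0)),
                           scaling_s=s)


def ez_forward(params: DiffusionParams) -> tuple[float, float, float]:
    """Exact (accuracy, mean correct RT, correct-RT variance) of the process.

    Closed-form companion (and oracle) of :func:`ez_inverse`; errors on zero
    drift, where the EZ inversion itself is undefined.
    """
    v, a, s = params.drift_v, params.boundary_a, params.scaling_s
    if v == 0:
        raise EZError("ez_forward undefined for drift_v = 0")
    L = v * a / s**2  # logit of accuracy
    pc = 1.0 / (1.0 + np.exp(-L))
    y = np.exp(-L)
    mdt = (a / (2 * v)) * (1 - y) / (1 + y)
    vrt = s**4 * L * (L * pc**2 - L * pc + pc - 0.5) / v**4
    return float(pc), float(params.ter + mdt), float(vrt)


# ---------------------------------------------------------------------------
# Exact first-passage sampling (inverse CDF on a precomputed scaled-time grid)

_N_GRID = 8193
_TAU_MAX = 6.0  # slowest mode decays as exp(-pi^2 tau / 2); tail mass < 2e-13
_tau_grid: np.ndarray | None = None
_S_grid: np.ndarray | None = None


def _grids() -> tuple[np.ndarray, np.ndarray]:
    """Scaled-time grid and boundary series S(tau), computed once."""
    global _tau_grid, _S_grid
    if _S_grid is None:
        tau = np.linspace(0.0, _TAU_MAX, _N_GRID)
        S = np.zeros_like(tau)
        k = 1
        while True:
            # series term is negligible everywhere once k^2 pi^2 tau1 / 2 > 45
            cut = int(np.searchsorted(tau, 90.0 / (k**2 * np.pi**2), side="right"))
            if cut <= 1:
                break
            sign = -1.0 if (k - 1) // 2 % 2 else 1.0
            S[:cut] += sign * k * np.exp(-(k**2) * np.pi**2 * tau[:cut] / 2.0)
            k += 2
        np.clip(S, 0.0, None, out=S)  # truncation can leave ~1e-15 negatives
        _tau_grid, _S_grid = tau, S
    return _tau_grid, _S_grid


def sample_trials(params: DiffusionParams, n: int, seed) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` (rt, correct) pairs from the unbiased Wiener process.

    Exact in distribution up to quadrature: the decision-time CDF is built
    from the series density on a dense grid and inverted by interpolation;
    correctness is Bernoulli with the exact absorption probability. RTs are
    decision time + ``ter``, so every RT exceeds ``ter``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    v, a, s = params.drift_v, params.boundary_a, params.scaling_s
    mu = v * a / s**2
    tau, S = _grids()
    dens = np.exp(-(mu**2) * tau / 2.0) * S
    cdf = cumulative_trapezoid(dens, tau, initial=0.0)
    cdf /= cdf[-1]
    t_dec = np.interp(rng.random(n), cdf, tau) * a**2 / s**2
    p_correct = 1.0 / (1.0 + np.exp(-mu))
    correct = (rng.random(n) < p_correct).astype(int)
    return params.ter + t_dec, correct


def inject_contaminants(trials: pd.DataFrame, rate: float, lo: float, hi: float,
                        seed) -> pd.DataFrame:
    """Swap a fixed share of each cell's trials for uniform contaminant RTs.

    Exactly ``round(rate * cell size)`` trials per participant x condition
    cell are replaced: their RT is redrawn from Uniform(lo, hi), correctness
    from a fair Bernoulli (contaminants do not depend on the decision
    process), and ``is_contaminant`` is set. All other rows are unchanged.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = trials.copy()
    if "is_contaminant" not in out.columns:
        out["is_contaminant"] = 0
    if rate == 0.0:
        return out
    rt = out["rt_s"].to_numpy(copy=True)
    correct = out["correct"].to_numpy(copy=True)
    flag = out["is_contaminant"].to_numpy(copy=True)
    for _, idx in out.groupby(["participant_id", "prev_congruency", "congruency"],
                              sort=True).indices.items():
        n_cont = int(np.rint(rate * len(idx)))
        if n_cont == 0:
            continue
        chosen = rng.choice(idx, size=n_cont, replace=False)
        rt[chosen] = rng.uniform(lo, hi, size=n_cont)
        correct[chosen] = (rng.random(n_cont) < 0.5).astype(int)
        flag[chosen] = 1
    out["rt_s"] = rt
    out["correct"] = correct
    out["is_contaminant"] = flag
    return out
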