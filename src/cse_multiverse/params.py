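"""Generative parameter profiles for congruency-sequence-effect simulations.

A profile bundles everything needed to simulate one task: fixed effects for
trial-level reaction times (in ms, under 0/1 dummy coding with congruent = 0
and incongruent = 1 for both the current and the previous trial), a 2x2
random-effect covariance (participant intercept and current-congruency slope),
a residual SD, and logit-scale coefficients for a companion accuracy model.
Under this coding a congruency sequence effect (CSE) appears as a *negative*
interaction coefficient, and the classic raw score (cI - cC) - (iI - iC)
equals minus that coefficient.

Two task profiles ship by default — a large-effect "prime_probe" task
(interaction -20.86 ms) and a small-effect "flanker" task (-14.62 ms) — plus
their nullified twins with the interaction removed. Components that are not
pinned down by the empirical estimates (covariances, residual SD, accuracy
logits) are plausible defaults flagged ``is_default_guess``; every field can
be overridden through the run configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EffectModelParams",
    "MultiversePlan",
    "PROFILE_LABELS",
    "default_params",
    "default_plan",
    "nullify",
]

PROFILE_LABELS = ("prime_probe", "flanker", "prime_probe_null", "flanker_null")

#: Fields whose default values are educated guesses rather than published
#: estimates (the published model fits pin down only the fixed interaction).
DEFAULT_GUESS_FIELDS = (
    "beta_intercept",
    "beta_congruency",
    "beta_previous",
    "re_cov",
    "resid_sd",
    "acc_intercept",
    "acc_congruency",
    "acc_previous",
    "acc_interaction",
    "acc_re_sd",
)

_PSD_TOL = 1e-9


@dataclass
class EffectModelParams:
    """Generative model for one task: RT fixed/random effects + accuracy model.

    RT coefficients are in milliseconds; accuracy coefficients are on the
    logit scale. ``re_cov`` is the (intercept, congruency-slope) covariance in
    ms^2; ``acc_re_sd`` is the SD of the participant random intercept of the
    accuracy model.
    """

    label: str
    beta_intercept: float
    beta_congruency: float
    beta_previous: float
    beta_interaction: float
    re_cov: np.ndarray
    resid_sd: float
    acc_intercept: float
    acc_congruency: float
    acc_previous: float
    acc_interaction: float
    acc_re_sd: float
    is_default_guess: tuple = field(default=DEFAULT_GUESS_FIELDS)

    def __post_init__(self) -> None:
        self.re_cov = np.asarray(self.re_cov, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.re_cov.shape != (2, 2):
            raise ValueError("re_cov must be a 2x2 matrix")
        if not np.allclose(self.re_cov, self.re_cov.T):
            raise ValueError("re_cov must be symmetric")
        if np.linalg.eigvalsh(self.re_cov).min() < -_PSD_TOL:
            raise ValueError("re_cov must be positive semi-definite")
        if not self.resid_sd > 0:
            raise ValueError("resid_sd must be > 0")
        if self.acc_re_sd < 0:
            raise ValueError("acc_re_sd must be >= 0")
        if self.label.endswith("_null") and self.beta_interaction != 0.0:
            raise ValueError("null profiles must have beta_interaction == 0")

    def replace(self, **changes) -> "EffectModelParams":
        return dataclasses.replace(self, **changes)


def _prime_probe() -> EffectModelParams:
    return EffectModelParams(
        label="prime_probe",
        beta_intercept=650.0,
        beta_congruency=80.0,
        beta_previous=5.0,
        beta_interaction=-20.86,
        re_cov=np.array([[80.0**2, 0.3 * 80.0 * 25.0],
                         [0.3 * 80.0 * 25.0, 25.0**2]]),
        resid_sd=150.0,
        acc_intercept=2.9,
        acc_congruency=-0.6,
        acc_previous=-0.1,
        acc_interaction=0.25,
        acc_re_sd=0.5,
    )


def _flanker() -> EffectModelParams:
    return EffectModelParams(
        label="flanker",
        beta_intercept=600.0,
        beta_congruency=65.0,
        beta_previous=5.0,
        beta_interaction=-14.62,
        re_cov=np.array([[75.0**2, 0.3 * 75.0 * 20.0],
                         [0.3 * 75.0 * 20.0, 20.0**2]]),
        resid_sd=140.0,
        acc_intercept=3.0,
        acc_congruency=-0.5,
        acc_previous=-0.1,
        acc_interaction=0.2,
        acc_re_sd=0.5,
    )


def default_params(profile: str) -> EffectModelParams:
    """Return one of the four built-in parameter profiles.

    ``prime_probe`` and ``flanker`` carry the empirical interaction estimates
    (-20.86 and -14.62 ms); the ``*_null`` variants are the same profiles with
    the interaction set to zero (main effects and the accuracy model of the
    true-effect profile are preserved).
    """
    if profile == "prime_probe":
        return _prime_probe()
    if profile == "flanker":
        return _flanker()
    if profile == "prime_probe_null":
        return nullify(_prime_probe())
    if profile == "flanker_null":
        return nullify(_flanker())
    raise ValueError(
        f"unknown profile {profile!r}; valid labels: {', '.join(PROFILE_LABELS)}"
    )


def nullify(params: EffectModelParams) -> EffectModelParams:
    """Remove the CSE: zero the RT interaction, keep everything else.

    Main effects, random-effect structure and the accuracy model are
    untouched, so the nullified profile generates data identical in every
    marginal respect except the sequence effect. Idempotent.
    """
    label = params.label
    if not label.endswith("_null"):
        label = label + "_null"
    return params.replace(label=label, beta_interaction=0.0)


@dataclass
class MultiversePlan:
    """Full factorial simulation plan.

    Defaults reproduce the reference design: 4 effect types x 5 sample sizes
    x 1000 replicates, 100 trials per condition per participant, 10 outlier
    filters x 5 hypothesis tests = 50 decision pathways (20,000 datasets,
    1,000,000 analyses).
    """

    effect_types: tuple = PROFILE_LABELS
    sample_sizes: tuple = (25, 50, 100, 200, 400)
    replicates: int = 1000
    trials_per_cell: int = 100
    filters: tuple = ("sd2", "sd2.5", "sd3", "mad2", "mad2.5", "mad3",
                      "fix1000", "fix1250", "fix1500", "none")
    tests: tuple = ("anova", "lmm", "lmm_cx", "loglmm", "loglmm_cx")
    seed: int = 0
    contaminant_rate: float = 0.05
    contaminant_lo: float = 0.0
    contaminant_hi: float = 3.09

    def __post_init__(self) -> None:
        self.effect_types = tuple(self.effect_types)
        self.sample_sizes = tuple(int(n) for n in self.sample_sizes)
        self.filters = tuple(self.filters)
        self.tests = tuple(self.tests)
        if any(n < 1 for n in self.sample_sizes):
            raise ValueError("sample sizes must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.trials_per_cell < 2:
            raise ValueError("trials_per_cell must be >= 2 (cell variance)")
        if not 0 <= self.contaminant_rate <= 1:
            raise ValueError("contaminant_rate must be in [0, 1]")
        if self.contaminant_hi <= self.contaminant_lo:
            raise ValueError("contaminant_hi must exceed contaminant_lo")

    @property
    def n_datasets(self) -> int:
        return len(self.effect_types) * len(self.sample_sizes) * self.replicates

    @property
    def n_pathways(self) -> int:
        return len(self.filters) * len(self.tests)

    @property
    def n_analyses(self) -> int:
        return self.n_datasets * self.n_pathways


def default_plan(**overrides) -> MultiversePlan:
    """The reference full-scale plan; pass overrides for desk-scale runs."""
    return MultiversePlan(**overrides)
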