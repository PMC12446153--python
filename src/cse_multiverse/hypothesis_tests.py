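"""The five hypothesis-testing models and the composite CSE decision rule.

One aggregate route — the 2x2 repeated-measures ANOVA on per-participant cell
means — and four trial-level mixed models: raw or log RT crossed with a
random-intercept-only ("simple") or random intercept + current-congruency
slope ("complex") structure. Mixed models are fit by maximum likelihood so
that nested fixed-effect structures can be compared with a likelihood-ratio
test and information criteria; the interaction coefficient's significance is
its Wald z test.

The alternative hypothesis (a CSE) is accepted for a mixed model only when
all four hold: dAIC = AIC_null - AIC_alt >= 2 or dBIC >= 6; LRT p < .05;
Wald p < .05; and the interaction estimate is negative (the predicted
direction). The ANOVA accepts when its interaction is significant at .05 and
the per-participant CSE contrast mean is negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.anova import AnovaRM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = ["TestSpec", "TestResult", "DEFAULT_TEST_CODES", "parse_test",
           "default_tests", "exclude_errors", "rm_anova_cse", "fit_lmm_cse",
           "run_test", "decide", "ALPHA"]

ALPHA = 0.05
AIC_THRESHOLD = 2.0
BIC_THRESHOLD = 6.0

KINDS = ("rm_anova", "lmm_simple", "lmm_complex", "lmm_log_simple", "lmm_log_complex")
_CODE_TO_KIND = {"anova": "rm_anova", "lmm": "lmm_simple", "lmm_cx": "lmm_complex",
                 "loglmm": "lmm_log_simple", "loglmm_cx": "lmm_log_complex"}
_KIND_TO_CODE = {v: k for k, v in _CODE_TO_KIND.items()}
DEFAULT_TEST_CODES = tuple(_CODE_TO_KIND)


@dataclass(frozen=True)
class TestSpec:
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown test kind {self.kind!r}; valid: {', '.join(KINDS)}")

    @property
    def code(self) -> str:
        return _KIND_TO_CODE[self.kind]

    @property
    def is_log(self) -> bool:
        return "log" in self.kind

    @property
    def is_complex(self) -> bool:
        return self.kind.endswith("complex")


def parse_test(code: str) -> TestSpec:
    try:
        return TestSpec(_CODE_TO_KIND[code.strip().lower()])
    except KeyError:
        raise ValueError(
            f"unknown test code {code!r}; valid: {', '.join(DEFAULT_TEST_CODES)}"
        ) from None


def default_tests() -> list[TestSpec]:
    return [TestSpec(_CODE_TO_KIND[c]) for c in DEFAULT_TEST_CODES]


@dataclass
class TestResult:
    """Diagnostics of one pathway run; ``interaction_estimate`` is in ms for
    raw-RT models and log-units for log-RT models."""

    kind: str
    converged: bool
    interaction_estimate: float = np.nan
    interaction_p: float = np.nan
    lrt_p: float = np.nan
    delta_aic: float = np.nan
    delta_bic: float = np.nan
    decision: int = 0
    n_participants: int = 0
    n_trials_analyzed: int = 0
    notes: list = field(default_factory=list)


def exclude_errors(trials: pd.DataFrame) -> pd.DataFrame:
    """Keep correct trials only — applied on every pathway before filtering."""
    return trials.loc[trials["correct"] == 1].reset_index(drop=True)


def _cse_scores(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-participant cell means (wide) and CSE contrasts (iI-iC)-(cI-cC), s."""
    means = trials.groupby(["participant_id", "prev_congruency", "congruency"],
                           sort=True)["rt_s"].mean().unstack(["prev_congruency",
                                                              "congruency"])
    complete = means.dropna()
    score = (complete[("i", "I")] - complete[("i", "C")]
             - (complete[("c", "I")] - complete[("c", "C")]))
    return complete, score


def rm_anova_cse(trials: pd.DataFrame) -> TestResult:
    """2x2 repeated-measures ANOVA on per-participant condition means.

    Participants missing any of the four cells are dropped (noted in the
    result). The interaction F has (1, n-1) degrees of freedom and equals the
    squared paired t on the per-participant CSE contrast. A contrast with no
    between-participant variability yields F = 0 and no rejection.
    """
    res = TestResult(kind="rm_anova", converged=True)
    complete, score = _cse_scores(trials)
    dropped = trials["participant_id"].nunique() - len(complete)
    if dropped:
        res.notes.append(f"dropped {dropped} participants with empty cells")
    if len(complete) < 2:
        res.converged = False
        res.notes.append("fewer than 2 complete participants")
        return res
    long = complete.stack(["prev_congruency", "congruency"],
                          future_stack=True).rename("rt_s").reset_index()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = AnovaRM(long, depvar="rt_s", subject="participant_id",
                        within=["prev_congruency", "congruency"]).fit().anova_table
    p = table.loc["prev_congruency:congruency", "Pr > F"]
    if not np.isfinite(p):  # degenerate: zero interaction variability
        p = 1.0
    res.interaction_p = float(p)
    res.interaction_estimate = float(score.mean() * 1000.0)
    res.n_participants = len(complete)
    res.n_trials_analyzed = len(trials)
    res.decision = decide(res, TestSpec("rm_anova"))
    return res


def _design(trials: pd.DataFrame, log_rt: bool) -> tuple[np.ndarray, pd.DataFrame]:
    x_cur = (trials["congruency"] == "I").to_numpy(float)
    x_prev = (trials["prev_congruency"] == "i").to_numpy(float)
    exog = pd.DataFrame({"const": 1.0, "congruency": x_cur, "previous": x_prev,
                         "interaction": x_cur * x_prev}, index=trials.index)
    y = trials["rt_s"].to_numpy(float)
    if log_rt:
        y = np.log(y)
    return y, exog


#: Relative floor for random-effect variances: a diagonal element of the RE
#: covariance below this fraction of the residual variance is a boundary fit.
_BOUNDARY_REL_TOL = 1e-4


def _fit_ml(y, exog, groups, exog_re) -> tuple:
    """One ML mixed fit; returns (llf, params, pvalues, ok, notes).

    statsmodels' own "MLE may be on the boundary" heuristic compares RE
    variances against an absolute 0.01 threshold, which is unit-dependent
    (any healthy fit on second-scaled RTs trips it); boundary detection here
    is relative to the residual variance instead. All other failure signals
    — optimizer non-success, singular covariance, Hessian problems,
    non-finite estimates — mark the fit as non-converged.
    """
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            model = MixedLM(y, exog, groups=groups, exog_re=exog_re)
            fit = model.fit(reml=False, maxiter=200)
        except Exception as exc:  # any optimizer failure counts as non-convergence
            return np.nan, None, None, False, [f"fit error: {exc!r}"]
    ok = bool(fit.converged)
    for w in caught:
        if "may be on the boundary" in str(w.message):
            continue  # replaced by the relative check below
        if issubclass(w.category, (ConvergenceWarning, RuntimeWarning)) or \
                "singular" in str(w.message).lower():
            ok = False
            notes.append(f"{w.category.__name__}: {w.message}")
    if not (np.all(np.isfinite(fit.fe_params)) and np.isfinite(fit.llf)):
        ok = False
        notes.append("non-finite estimates")
    elif np.min(np.diag(fit.cov_re)) < _BOUNDARY_REL_TOL * fit.scale:
        ok = False
        notes.append("random-effect variance on the boundary (~0)")
    return float(fit.llf), fit.fe_params, fit.pvalues, ok, notes


def fit_lmm_cse(trials: pd.DataFrame, spec: TestSpec) -> TestResult:
    """Fit the alternative and null mixed models and assemble diagnostics.

    The alternative model regresses RT (or log RT) on current congruency,
    previous congruency and their interaction; the null model drops only the
    interaction. Random effects: participant intercept, plus a current-
    congruency slope for complex kinds. Both fits use ML; ``delta_aic`` /
    ``delta_bic`` are null minus alternative with a shared parameter-count
    convention, so dAIC = LRT statistic - 2 for the 1-df difference. Any
    optimizer failure, convergence warning or non-finite estimate marks the
    run ``converged=False`` (no exception propagates).
    """
    if spec.kind == "rm_anova":
        raise ValueError("use rm_anova_cse for the ANOVA test")
    res = TestResult(kind=spec.kind, converged=True)
    res.n_participants = trials["participant_id"].nunique()
    res.n_trials_analyzed = len(trials)
    if trials.empty:
        res.converged = False
        res.notes.append("empty table")
        return res
    y, exog = _design(trials, spec.is_log)
    groups = trials["participant_id"].to_numpy()
    exog_re = exog[["const", "congruency"]] if spec.is_complex else exog[["const"]]
    n_re_cov = 3 if spec.is_complex else 1

    llf_alt, fe_alt, pv_alt, ok_alt, notes_alt = _fit_ml(y, exog, groups, exog_re)
    llf_null, _, _, ok_null, notes_null = _fit_ml(
        y, exog[["const", "congruency", "previous"]], groups, exog_re)
    res.notes.extend(notes_alt + notes_null)
    if not (ok_alt and ok_null):
        res.converged = False
        return res

    scale = 1.0 if spec.is_log else 1000.0  # report raw-RT effects in ms
    res.interaction_estimate = float(fe_alt["interaction"] * scale)
    res.interaction_p = float(pv_alt["interaction"])
    lrt = 2.0 * (llf_alt - llf_null)
    res.lrt_p = float(stats.chi2.sf(max(lrt, 0.0), df=1))
    n_obs = len(y)
    k_alt = 4 + n_re_cov + 1  # fixed effects + RE covariance + residual
    k_null = k_alt - 1
    res.delta_aic = float((-2 * llf_null + 2 * k_null) - (-2 * llf_alt + 2 * k_alt))
    res.delta_bic = float((-2 * llf_null + np.log(n_obs) * k_null)
                          - (-2 * llf_alt + np.log(n_obs) * k_alt))
    res.decision = decide(res, spec)
    return res


def run_test(trials: pd.DataFrame, spec: TestSpec) -> TestResult:
    """Dispatch to the ANOVA or mixed-model route for one pathway run."""
    if spec.kind == "rm_anova":
        return rm_anova_cse(trials)
    return fit_lmm_cse(trials, spec)


def decide(result: TestResult, spec: TestSpec) -> int:
    """Composite acceptance rule for the CSE alternative hypothesis.

    Mixed models: (dAIC >= 2 or dBIC >= 6) and LRT p < .05 and Wald p < .05
    and a negative interaction estimate. ANOVA: interaction p < .05 and a
    negative per-participant contrast mean. Undefined for non-converged runs
    (the engine excludes those from rate summaries).
    """
    if not result.converged:
        raise ValueError("decision undefined for non-converged result")
    directional = (np.isfinite(result.interaction_estimate)
                   and result.interaction_estimate < 0)
    significant = np.isfinite(result.interaction_p) and result.interaction_p < ALPHA
    if spec.kind == "rm_anova":
        return int(significant and directional)
    evidence = (result.delta_aic >= AIC_THRESHOLD or result.delta_bic >= BIC_THRESHOLD)
    lrt_sig = np.isfinite(result.lrt_p) and result.lrt_p < ALPHA
    return int(evidence and lrt_sig and significant and directional)
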