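"""Orchestration of the multiverse grid.

Runs the full factorial — effect types x sample sizes x replicates for data
generation, crossed with outlier filters x hypothesis tests for analysis —
under a counter-based seeding scheme: every dataset draws its generator from
``SeedSequence([master, effect index, n, replicate, attempt])`` so that all
50 pathways analyze bit-identical data and any subset of the grid is
reproducible in isolation. Non-converged fits are recorded and excluded from
rate summaries (they do not count as rejections). Rates pool decision counts,
not per-cell rates, and carry Wilson 95% intervals.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import ezdiff, hypothesis_tests as ht
from .ezdiff import EZError
from .cohort import sample_participants, simulate_stage1
from .filters import FilterSpec, apply_filter, parse_filter
from .params import EffectModelParams, MultiversePlan, default_params

__all__ = ["enumerate_pathways", "dataset_rng", "generate_dataset",
           "run_multiverse", "summarize", "wilson_interval"]

log = logging.getLogger(__name__)

MAX_GENERATION_ATTEMPTS = 8


def enumerate_pathways(plan: MultiversePlan) -> list[tuple[FilterSpec, ht.TestSpec]]:
    """Deterministic filter x test product (the decision pathways)."""
    if not plan.filters or not plan.tests:
        raise ValueError("plan needs at least one filter and one test")
    return [(parse_filter(f), ht.parse_test(t))
            for f, t in itertools.product(plan.filters, plan.tests)]


def dataset_rng(master_seed: int, effect_index: int, n_participants: int,
                replicate: int, attempt: int = 0) -> np.random.Generator:
    """Counter-based sub-stream for one dataset of the grid."""
    ss = np.random.SeedSequence(
        [int(master_seed), int(effect_index), int(n_participants),
         int(replicate), int(attempt)])
    return np.random.default_rng(ss)


def _trials_from_cells(cells: pd.DataFrame, trials_per_cell: int,
                       scaling_s: float, rng: np.random.Generator) -> pd.DataFrame:
    """EZ-invert every cell summary and sample its diffusion trials."""
    frames = []
    for row in cells.itertuples(index=False):
        acc = ezdiff.edge_correct(row.accuracy, row.n_trials)
        dp = ezdiff.ez_inverse(row.mean_rt, row.var_rt, acc, scaling_s)
        rt, correct = ezdiff.sample_trials(dp, trials_per_cell, rng)
        frames.append(pd.DataFrame({
            "participant_id": row.participant_id,
            "prev_congruency": row.prev_congruency,
            "congruency": row.congruency,
            "rt_s": rt,
            "correct": correct,
            "is_contaminant": 0,
            "trial_index": np.arange(trials_per_cell),
        }))
    return pd.concat(frames, ignore_index=True)


def generate_dataset(params: EffectModelParams, n_participants: int,
                     trials_per_cell: int, master_seed: int, effect_index: int = 0,
                     replicate: int = 0, contaminant_rate: float = 0.05,
                     contaminant_lo: float = 0.0, contaminant_hi: float = 3.09,
                     scaling_s: float = ezdiff.DEFAULT_SCALING) -> pd.DataFrame:
    """One complete trial-level dataset: stage 1 -> EZ -> diffusion -> contaminants.

    If a stage-1 cell lands exactly on 50% accuracy (where the EZ drift is
    undefined) the replicate is regenerated from a shifted sub-seed; the
    retry is logged. Returns a tidy TrialTable with ``trials_per_cell`` rows
    per participant x cell.
    """
    for attempt in range(MAX_GENERATION_ATTEMPTS):
        rng = dataset_rng(master_seed, effect_index, n_participants, replicate, attempt)
        try:
            effects = sample_participants(params, n_participants, rng)
            cells = simulate_stage1(params, effects, trials_per_cell, rng)
            trials = _trials_from_cells(cells, trials_per_cell, scaling_s, rng)
            return ezdiff.inject_contaminants(trials, contaminant_rate,
                                              contaminant_lo, contaminant_hi, rng)
        except EZError as exc:
            log.warning("regenerating %s replicate %d (attempt %d): %s",
                        params.label, replicate, attempt + 1, exc)
    raise RuntimeError(
        f"dataset generation failed {MAX_GENERATION_ATTEMPTS} times for "
        f"{params.label}, n={n_participants}, replicate={replicate}")


def _resolve_params(plan: MultiversePlan, overrides: dict | None) -> dict:
    overrides = overrides or {}
    out = {}
    for label in plan.effect_types:
        out[label] = overrides.get(label, default_params(label))
    return out


def run_multiverse(plan: MultiversePlan, param_overrides: dict | None = None,
                   keep_runs: bool = False, progress: bool = False
                   ) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Execute the plan and return the PathwayCell count table.

    One row per (effect type, sample size, filter, test) with ``n_runs``,
    ``n_converged``, ``n_decisions_1`` and a ``true_effect`` flag. With
    ``keep_runs=True`` also returns the per-run diagnostics table.
    Individual run failures are recorded as non-converged, never raised.
    """
    pathways = enumerate_pathways(plan)
    profiles = _resolve_params(plan, param_overrides)
    counts: dict[tuple, list] = {}
    runs: list[dict] = []
    grid = list(itertools.product(enumerate(plan.effect_types), plan.sample_sizes,
                                  range(plan.replicates)))
    if progress:
        from tqdm import tqdm
        grid = tqdm(grid, desc="datasets")
    for (ei, label), n, rep in grid:
        params = profiles[label]
        trials = generate_dataset(
            params, n, plan.trials_per_cell, plan.seed, effect_index=ei,
            replicate=rep, contaminant_rate=plan.contaminant_rate,
            contaminant_lo=plan.contaminant_lo, contaminant_hi=plan.contaminant_hi)
        correct_only = ht.exclude_errors(trials)
        for fspec, tspec in pathways:
            filtered, _ledger = apply_filter(correct_only, fspec)
            try:
                result = ht.run_test(filtered, tspec)
            except Exception as exc:  # defensive: a failed run never aborts the grid
                result = ht.TestResult(kind=tspec.kind, converged=False,
                                       notes=[f"run error: {exc!r}"])
            key = (label, n, fspec.code, tspec.code)
            cell = counts.setdefault(key, [0, 0, 0])
            cell[0] += 1
            if result.converged:
                cell[1] += 1
                cell[2] += result.decision
            if keep_runs:
                rec = asdict(result)
                rec.pop("notes")
                rec.update(effect_type=label, n_participants=n, replicate=rep,
                           filter=fspec.code, test=tspec.code)
                runs.append(rec)
    cells = pd.DataFrame(
        [(label, n, f, t, *c) for (label, n, f, t), c in counts.items()],
        columns=["effect_type", "n_participants", "filter", "test",
                 "n_runs", "n_converged", "n_decisions_1"])
    cells["true_effect"] = [profiles[l].beta_interaction != 0
                            for l in cells["effect_type"]]
    if keep_runs:
        return cells, pd.DataFrame(runs)
    return cells


def wilson_interval(count: int, nobs: int, alpha: float = 0.05
                    ) -> tuple[float, float]:
    """Wilson score 95% (by default) interval for a binomial proportion."""
    from statsmodels.stats.proportion import proportion_confint
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def summarize(cells: pd.DataFrame, aggregate_over: tuple[str, ...] = ()
              ) -> pd.DataFrame:
    """Pool decision counts over ``aggregate_over`` fields and attach rates.

    The rate of a pooled cell is summed decisions over summed converged runs
    (never an average of rates), with a Wilson 95% interval on the pooled
    counts. The rate is a TPR where ``true_effect`` holds and an FPR where it
    does not. Pooled cells with no converged runs yield a missing rate.
    """
    if cells.empty:
        raise ValueError("no pathway cells to summarize")
    keys = [c for c in ("effect_type", "n_participants", "filter", "test",
                        "true_effect")
            if c in cells.columns and c not in aggregate_over]
    count_cols = ["n_runs", "n_converged", "n_decisions_1"]
    if keys:
        pooled = cells.groupby(keys, sort=True, as_index=False)[count_cols].sum()
    else:  # everything aggregated: one pooled row
        pooled = cells[count_cols].sum().to_frame().T
    rate, lo, hi = [], [], []
    for row in pooled.itertuples(index=False):
        if row.n_converged == 0:
            log.warning("pooled cell with zero converged runs: %s", row)
            rate.append(np.nan), lo.append(np.nan), hi.append(np.nan)
            continue
        rate.append(row.n_decisions_1 / row.n_converged)
        w = wilson_interval(row.n_decisions_1, row.n_converged)
        lo.append(w[0]), hi.append(w[1])
    pooled["rate"] = rate
    pooled["ci_low"] = lo
    pooled["ci_high"] = hi
    return pooled
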