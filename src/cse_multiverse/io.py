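"""Configuration loading, tidy-table readers/writers, and test fixtures.

Run configurations are TOML files. Every field of the default plan and of
the built-in parameter profiles can be overridden; unknown keys are rejected
with their path so typos cannot silently fall back to defaults. Tables are
UTF-8 CSV with documented column orders (Parquet via pandas/pyarrow works
out of the box for large runs).
"""

from __future__ import annotations

import dataclasses
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ezdiff
from .cohort import CELLS
from .filters import DEFAULT_FILTER_CODES, parse_filter
from .hypothesis_tests import DEFAULT_TEST_CODES, parse_test
from .params import MultiversePlan, default_params

__all__ = ["RunConfig", "load_config", "save_config", "read_trials",
           "write_trials", "make_fixture", "TRIAL_COLUMNS", "CELL_COLUMNS"]

log = logging.getLogger(__name__)

TRIAL_COLUMNS = ["participant_id", "prev_congruency", "congruency", "rt_s",
                 "correct", "is_contaminant", "trial_index"]
CELL_COLUMNS = ["participant_id", "prev_congruency", "congruency", "mean_rt",
                "var_rt", "accuracy", "n_trials"]

_PROFILE_OVERRIDE_KEYS = {
    "beta_intercept", "beta_congruency", "beta_previous", "beta_interaction",
    "re_cov", "resid_sd", "acc_intercept", "acc_congruency", "acc_previous",
    "acc_interaction", "acc_re_sd",
}


@dataclass
class RunConfig:
    """Validated run configuration; defaults reproduce the reference plan."""

    effect_types: tuple = ("prime_probe", "flanker", "prime_probe_null", "flanker_null")
    sample_sizes: tuple = (25, 50, 100, 200, 400)
    replicates: int = 1000
    trials_per_cell: int = 100
    filters: tuple = DEFAULT_FILTER_CODES
    tests: tuple = DEFAULT_TEST_CODES
    seed: int = 0
    contaminant_rate: float = 0.05
    contaminant_lo: float = 0.0
    contaminant_hi: float = 3.09
    filter_center: str = "cell"
    out_dir: str = "multiverse_out"
    log_level: str = "INFO"
    profiles: dict = field(default_factory=dict)  # label -> field overrides

    def to_plan(self) -> MultiversePlan:
        return MultiversePlan(
            effect_types=self.effect_types, sample_sizes=self.sample_sizes,
            replicates=self.replicates, trials_per_cell=self.trials_per_cell,
            filters=self.filters, tests=self.tests, seed=self.seed,
            contaminant_rate=self.contaminant_rate,
            contaminant_lo=self.contaminant_lo, contaminant_hi=self.contaminant_hi)

    def resolve_profiles(self) -> dict:
        """Built-in profiles with any configured overrides applied."""
        out = {}
        for label in self.effect_types:
            params = default_params(label)
            overrides = dict(self.profiles.get(label, {}))
            if overrides:
                if "re_cov" in overrides:
                    overrides["re_cov"] = np.asarray(overrides["re_cov"], float)
                guessed = tuple(f for f in params.is_default_guess
                                if f not in overrides)
                params = params.replace(is_default_guess=guessed, **overrides)
            out[label] = params
        return out


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML run configuration.

    Unknown keys (top-level or inside a profile table) raise with the full
    field path; filter/test codes and profile invariants are validated
    eagerly. An empty file yields the full default plan.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in raw:
        if key not in known:
            raise ValueError(f"unknown config key {key!r}")
    profiles = raw.get("profiles", {})
    for label, overrides in profiles.items():
        for key in overrides:
            if key not in _PROFILE_OVERRIDE_KEYS:
                raise ValueError(f"unknown config key profiles.{label}.{key}")
    cfg = RunConfig(**{k: tuple(v) if isinstance(v, list) and k != "profiles" else v
                       for k, v in raw.items()})
    for code in cfg.filters:
        parse_filter(code)
    for code in cfg.tests:
        parse_test(code)
    if cfg.filter_center not in ("cell", "condition"):
        raise ValueError("filter_center must be 'cell' or 'condition'")
    cfg.to_plan()          # plan invariants
    cfg.resolve_profiles()  # profile invariants (e.g. PSD covariance)
    defaulted = sorted(known - set(raw))
    if defaulted:
        log.info("config %s: defaults applied for %s", path, ", ".join(defaulted))
    return cfg


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_value(x) for x in np.asarray(v).tolist()
                               if True) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    """Write a config as TOML; ``load_config(save_config(c)) == c``."""
    lines = []
    for f in dataclasses.fields(RunConfig):
        if f.name == "profiles":
            continue
        lines.append(f"{f.name} = {_toml_value(getattr(cfg, f.name))}")
    for label, overrides in cfg.profiles.items():
        lines.append(f"\n[profiles.{label}]")
        for key, val in overrides.items():
            lines.append(f"{key} = {_toml_value(val)}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_trials(trials: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    trials[TRIAL_COLUMNS].to_csv(path, index=False)
    return path


def read_trials(path: str | Path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table {path} missing columns: {missing}")
    return trials[TRIAL_COLUMNS]


def make_fixture(kind: str, seed: int, out_dir: str | Path) -> list[Path]:
    """Emit small deterministic CSV fixtures for the test suite.

    ``tiny_dataset``: a 6-participant, 20-trials-per-cell trial table from
    the small-effect profile (480 rows). ``known_moments_cells``: cell
    summaries built with the forward EZ equations from known diffusion
    parameters, so the EZ inversion must recover them exactly.
    ``degenerate_cells``: summaries including accuracy 1.0 and 0.5 cells to
    exercise edge correction and the undefined-drift error path.
    """
    from .engine import generate_dataset  # deferred: engine imports filters/tests

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "tiny_dataset":
        trials = generate_dataset(default_params("flanker"), 6, 20, seed)
        return [write_trials(trials, out_dir / "tiny_dataset.csv")]
    if kind == "known_moments_cells":
        rows = []
        grid = [(0.2, 0.12, 0.25), (0.1, 0.08, 0.3), (0.3, 0.15, 0.2),
                (0.25, 0.11, 0.35)]
        for pid, ((v, a, ter), (prev, cur)) in enumerate(zip(grid, CELLS)):
            acc, mrt, vrt = ezdiff.ez_forward(ezdiff.DiffusionParams(v, a, ter))
            rows.append({"participant_id": pid, "prev_congruency": prev,
                         "congruency": cur, "mean_rt": mrt, "var_rt": vrt,
                         "accuracy": acc, "n_trials": 100,
                         "drift_v": v, "boundary_a": a, "ter": ter})
        path = out_dir / "known_moments_cells.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return [path]
    if kind == "degenerate_cells":
        rows = [
            {"participant_id": 0, "prev_congruency": "c", "congruency": "C",
             "mean_rt": 0.55, "var_rt": 0.02, "accuracy": 1.0, "n_trials": 50},
            {"participant_id": 0, "prev_congruency": "c", "congruency": "I",
             "mean_rt": 0.62, "var_rt": 0.03, "accuracy": 0.5, "n_trials": 50},
            {"participant_id": 0, "prev_congruency": "i", "congruency": "C",
             "mean_rt": 0.56, "var_rt": 0.02, "accuracy": 0.0, "n_trials": 50},
            {"participant_id": 0, "prev_congruency": "i", "congruency": "I",
             "mean_rt": 0.60, "var_rt": 0.025, "accuracy": 0.94, "n_trials": 50},
        ]
        path = out_dir / "degenerate_cells.csv"
        pd.DataFrame(rows)[CELL_COLUMNS].to_csv(path, index=False)
        return [path]
    raise ValueError(
        "unknown fixture kind; valid: tiny_dataset, known_moments_cells, degenerate_cells")
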