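"""The ten outlier-exclusion strategies of the decision tree.

Three SD-based trims (mean +/- k*SD of the participant x condition cell, with
k in {2, 2.5, 3}), three MAD-based trims (median +/- k*MAD, same k grid, MAD
scaled by 1.4826 for normal consistency), three fixed windows (200-1000 ms,
200-1250 ms, 200-1500 ms) and no filtering. Cell statistics are computed on
the table handed in — i.e. after error-trial exclusion and *including*
contaminant trials, which a real analyst cannot identify. All intervals are
closed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = ["FilterSpec", "FilterResult", "DEFAULT_FILTER_CODES", "parse_filter",
           "default_filters", "apply_filter"]

MAD_SCALE = 1.4826  # normal-consistency constant

DEFAULT_FILTER_CODES = ("sd2", "sd2.5", "sd3", "mad2", "mad2.5", "mad3",
                        "fix1000", "fix1250", "fix1500", "none")

_CELL_KEYS = ["participant_id", "prev_congruency", "congruency"]


@dataclass(frozen=True)
class FilterSpec:
    """One outlier-exclusion rule; build from codes via :func:`parse_filter`."""

    family: str  # sd | mad | fixed | none
    k: float | None = None
    lo_ms: float | None = None
    hi_ms: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("sd", "mad", "fixed", "none"):
            raise ValueError(f"unknown filter family {self.family!r}")
        if self.family in ("sd", "mad") and not (self.k and self.k > 0):
            raise ValueError(f"{self.family} filter needs a positive multiplier k")
        if self.family == "fixed":
            if self.lo_ms is None or self.hi_ms is None or self.hi_ms <= self.lo_ms:
                raise ValueError("fixed filter needs lo_ms < hi_ms")

    @property
    def code(self) -> str:
        if self.family == "none":
            return "none"
        if self.family == "fixed":
            return f"fix{int(self.hi_ms)}"
        k = self.k
        return f"{self.family}{int(k) if float(k).is_integer() else k}"


def parse_filter(code: str) -> FilterSpec:
    """Parse a short code like ``sd2.5``, ``mad3``, ``fix1250`` or ``none``."""
    code = code.strip().lower()
    try:
        if code == "none":
            return FilterSpec("none")
        if code.startswith("mad"):
            return FilterSpec("mad", k=float(code[3:]))
        if code.startswith("sd"):
            return FilterSpec("sd", k=float(code[2:]))
        if code.startswith("fix"):
            return FilterSpec("fixed", lo_ms=200.0, hi_ms=float(code[3:]))
    except ValueError:
        pass
    raise ValueError(f"unknown filter code {code!r}; valid: {', '.join(DEFAULT_FILTER_CODES)}")


def default_filters() -> list[FilterSpec]:
    """The ten strategies of the default decision tree, in canonical order."""
    return [parse_filter(c) for c in DEFAULT_FILTER_CODES]


class FilterResult(NamedTuple):
    trials: pd.DataFrame
    ledger: pd.DataFrame  # per cell: n_in, n_kept, n_excluded, emptied


def apply_filter(trials: pd.DataFrame, spec: FilterSpec,
                 center: str = "cell") -> FilterResult:
    """Apply one exclusion rule; returns kept rows plus a per-cell ledger.

    ``center="cell"`` (default) computes SD/MAD statistics within each
    participant x condition cell; ``center="condition"`` pools cells across
    participants, a sensitivity-check mode. Fixed-bound and no-op filters are
    unaffected by ``center``. A cell whose SD (or MAD) is zero has no spread
    to trim against and is kept whole.
    """
    if trials.empty:
        raise ValueError("trials table is empty")
    if center not in ("cell", "condition"):
        raise ValueError("center must be 'cell' or 'condition'")
    rt = trials["rt_s"].to_numpy()
    if spec.family == "none":
        keep = np.ones(len(trials), dtype=bool)
    elif spec.family == "fixed":
        keep = (rt >= spec.lo_ms / 1000.0) & (rt <= spec.hi_ms / 1000.0)
    else:
        keys = _CELL_KEYS if center == "cell" else _CELL_KEYS[1:]
        grp = trials.groupby(keys, sort=False)["rt_s"]
        if spec.family == "sd":
            m = grp.transform("mean").to_numpy()
            s = grp.transform("std").to_numpy()  # ddof=1
            half = spec.k * s
        else:
            med = grp.transform("median").to_numpy()
            mad = MAD_SCALE * (trials["rt_s"] - grp.transform("median")).abs() \
                .groupby([trials[c] for c in keys], sort=False).transform("median").to_numpy()
            m, half = med, spec.k * mad
        keep = np.abs(rt - m) <= half
        keep |= ~(half > 0)  # zero/NaN spread: nothing to trim against
    kept = trials.loc[keep]
    n_in = trials.groupby(_CELL_KEYS, sort=True).size().rename("n_in")
    n_kept = kept.groupby(_CELL_KEYS, sort=True).size().reindex(n_in.index, fill_value=0) \
        .rename("n_kept")
    ledger = pd.concat([n_in, n_kept], axis=1).reset_index()
    ledger["n_excluded"] = ledger["n_in"] - ledger["n_kept"]
    ledger["emptied"] = ledger["n_kept"] == 0
    return FilterResult(kept.reset_index(drop=True), ledger)
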