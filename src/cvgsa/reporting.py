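"""Cross-tabulations of orthogonality rankings.

The benchmark's headline outputs are rank tables — one parameter ranking per
(estimator, sampler) pair — and their robustness summaries: per-parameter
rank ranges across samplers for a fixed estimator (and vice versa), with the
"mean variation of the input set" (the mean of those ranges) quantifying how
much a ranking depends on the choice being varied. A mean variation of 0
means the ranking is perfectly robust to that choice.

Reference rank tables for both models and both measurement types ship as
CSV fixtures (``cvgsa/data``) so the reporting arithmetic is exercisable
without re-running the expensive sensitivity pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .orthogonality import RankVector

__all__ = [
    "RankTable",
    "RangeTable",
    "build_rank_table",
    "range_by_estimator",
    "range_by_sampler",
    "load_reference_ranks",
]


@dataclass(frozen=True)
class RankTable:
    """Integer ranks: rows (estimator, sampler), columns parameters."""

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        if not isinstance(t.index, pd.MultiIndex) or t.index.names != ["estimator", "sampler"]:
            raise ValueError("rank table rows must be indexed by (estimator, sampler)")
        _check_permutation_rows(t, strict=False)

    @property
    def parameters(self) -> list[str]:
        return list(self.table.columns)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def _check_permutation_rows(t: pd.DataFrame, strict: bool) -> None:
    n = t.shape[1]
    want = np.arange(1, n + 1)
    for key, row in t.iterrows():
        if not np.array_equal(np.sort(row.to_numpy()), want):
            msg = f"row {key} is not a permutation of 1..{n}"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, RuntimeWarning)


@dataclass(frozen=True)
class RangeTable:
    """Per-parameter rank ranges across one stratum, plus their mean.

    ``ranges``: strata x parameters (integer max - min rank).
    ``mean_variation``: per-stratum mean of the parameter ranges, reported
    to 2 decimals (half-up rounding, matching the convention of the
    reference tables).
    """

    ranges: pd.DataFrame
    mean_variation: pd.Series

    def __post_init__(self):
        n = self.ranges.shape[1]
        r = self.ranges.to_numpy()
        if r.min() < 0 or r.max() > n - 1:
            raise ValueError("rank ranges must lie in [0, n-1]")


def _round2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


def build_rank_table(runs: dict[tuple[str, str], RankVector | np.ndarray],
                     parameter_names=None, strict: bool = False) -> RankTable:
    """Assemble rankings keyed by (estimator, sampler) into one table.

    The keys must form a complete estimator x sampler grid and every run
    must cover the same parameter set. ``strict`` escalates the
    rows-are-permutations check from a warning to an error.
    """
    if not runs:
        raise ValueError("no runs supplied")
    names = None
    rows = {}
    for key, rv in runs.items():
        if isinstance(rv, RankVector):
            these = rv.parameter_names
            ranks = rv.ranks
        else:
            these = None
            ranks = np.asarray(rv, dtype=int)
        these = tuple(these) if these else None
        if names is None:
            names = these
        elif these is not None and these != names:
            raise ValueError(f"run {key} has a different parameter set")
        rows[key] = ranks
    lengths = {len(r) for r in rows.values()}
    if len(lengths) != 1:
        raise ValueError("runs disagree on the number of parameters")
    if names is None:
        names = tuple(parameter_names) if parameter_names else tuple(
            f"theta{i}" for i in range(lengths.pop()))
    estimators = list(dict.fromkeys(k[0] for k in rows))
    samplers_ = list(dict.fromkeys(k[1] for k in rows))
    missing = [(e, s) for e in estimators for s in samplers_ if (e, s) not in rows]
    if missing:
        raise ValueError(f"incomplete estimator x sampler grid; missing {missing}")
    idx = pd.MultiIndex.from_tuples([(e, s) for e in estimators for s in samplers_],
                                    names=["estimator", "sampler"])
    data = np.array([rows[(e, s)] for e in estimators for s in samplers_])
    t = pd.DataFrame(data, index=idx, columns=list(names))
    if strict:
        _check_permutation_rows(t, strict=True)
    return RankTable(t)


def _ranges_over(table: RankTable, vary: str) -> RangeTable:
    keep = "estimator" if vary == "sampler" else "sampler"
    g = table.table.groupby(level=keep, sort=False)
    ranges = (g.max() - g.min()).astype(int)
    mv = ranges.mean(axis=1).map(_round2)
    mv.name = "mean_variation"
    return RangeTable(ranges, mv)


def range_by_estimator(table: RankTable) -> RangeTable:
    """Per-parameter rank range across samplers, one row per estimator."""
    return _ranges_over(table, vary="sampler")


def range_by_sampler(table: RankTable) -> RangeTable:
    """Per-parameter rank range across estimators, one row per sampler."""
    return _ranges_over(table, vary="estimator")


def load_reference_ranks(model_id: str, measurements: str) -> RankTable:
    """Load a bundled reference ranking table.

    One fixture per (model, measurement type): orthogonality rankings of
    the benchmark study for every estimator x sampler pair.
    """
    fname = f"ranks_{'1ch' if model_id == 'one_chamber' else '2ch'}_{measurements}.csv"
    with resources.files("cvgsa.data").joinpath(fname).open() as fh:
        df = pd.read_csv(fh, index_col=[0, 1])
    df.index.names = ["estimator", "sampler"]
    return RankTable(df.astype(int))
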