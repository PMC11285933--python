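"""Orchestration: sampler -> model evaluations -> total-order indices.

A run is described by a :class:`RunConfig` (model, bounds, sampler,
estimator, sample size N, measurement type, seed). ``run_gsa`` builds the
pick-freeze system, spends the N (n + 2) model evaluations, and returns the
total-order sensitivity matrix — per time point for continuous measurements,
with the variance-weighted time average (TAS) alongside.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field

import numpy as np

from . import models, samplers
from .estimators import (ESTIMATOR_IDS, EvaluationBundle, TotalOrderIndices,
                         total_order_matrix)

__all__ = [
    "RunConfig",
    "GsaResult",
    "TimeAveragedIndices",
    "evaluation_budget",
    "evaluate_pick_freeze",
    "reduce_to_discrete",
    "run_gsa",
    "time_average",
    "write_run",
]

_MEASUREMENTS = ("continuous", "discrete")
OUTPUT_NAMES = ("mean_P_lv", "max_P_art", "max_V_lv")
OUTPUT_NAMES_CONTINUOUS = ("P_lv", "P_art", "V_lv")


def evaluation_budget(N: int, n: int) -> int:
    """Model evaluations needed for first- plus total-order indices: N (n + 2)."""
    if N < 1 or n < 1:
        raise ValueError("require N >= 1 and n >= 1")
    return N * (n + 2)


@dataclass(frozen=True)
class RunConfig:
    """Complete description of one sensitivity run."""

    model_id: str
    sampler: str
    estimator: str
    N: int
    measurements: str = "discrete"
    seed: int | None = 0
    bounds: np.ndarray | None = None
    bootstrap: int = 0
    ci_level: float = 0.95
    constants: models.ModelConstants | None = None
    solver: models.SolverSettings | None = None
    max_failure_fraction: float = 0.05

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("require N >= 2")
        if self.sampler not in samplers.SAMPLER_IDS:
            raise ValueError(f"unknown sampler {self.sampler!r}")
        if self.estimator not in ESTIMATOR_IDS:
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.measurements not in _MEASUREMENTS:
            raise ValueError("measurements must be 'continuous' or 'discrete'")
        if self.bootstrap < 0:
            raise ValueError("bootstrap count must be >= 0")
        if not 0 < self.ci_level < 1:
            raise ValueError("CI level must lie in (0, 1)")
        if self.bounds is not None:
            object.__setattr__(self, "bounds",
                               np.asarray(self.bounds, dtype=float))

    def resolved_bounds(self) -> np.ndarray:
        return (self.bounds if self.bounds is not None
                else models.default_bounds(self.model_id))

    def parameter_names(self) -> tuple[str, ...]:
        return tuple(models.nominal_parameters(self.model_id).names)


@dataclass(frozen=True)
class TimeAveragedIndices:
    """Variance-weighted time average of time-resolved total-order indices."""

    TAS: np.ndarray  # (m, n)
    weights: np.ndarray  # (m, T) per-time output variances used as weights
    parameter_names: tuple[str, ...] | None = None
    output_names: tuple[str, ...] | None = None

    def to_dataframe(self):
        import pandas as pd

        m, n = self.TAS.shape
        outs = self.output_names or tuple(f"y{j}" for j in range(m))
        pars = self.parameter_names or tuple(f"theta{i}" for i in range(n))
        return pd.DataFrame(self.TAS, index=list(outs), columns=list(pars))


def time_average(S_T_t: np.ndarray, var_t: np.ndarray,
                 parameter_names=None, output_names=None) -> TimeAveragedIndices:
    """Average per-time indices with the output variance as weight.

    TAS_T,i = sum_k S_T,i(t_k) Var(Y(t_k)) / sum_k Var(Y(t_k)), channel-wise.
    A channel whose weights sum to zero gets NaN (flagged missing) rather
    than an arbitrary average.
    """
    S = np.asarray(S_T_t, dtype=float)
    w = np.asarray(var_t, dtype=float)
    if S.ndim != 3 or w.shape != (S.shape[0], S.shape[2]):
        raise ValueError("expected S_T_t (m, n, T) and weights (m, T)")
    if np.any(w < 0):
        raise ValueError("variance weights must be >= 0")
    wsum = w.sum(axis=1)  # (m,)
    tas = np.full(S.shape[:2], np.nan)
    good = wsum > 0
    if np.any(good):
        num = np.einsum("mnt,mt->mn", S[good][:, :, :], w[good])
        tas[good] = num / wsum[good, None]
    return TimeAveragedIndices(tas, w, parameter_names, output_names)


def evaluate_pick_freeze(model_id: str, pf: samplers.PickFreezeSet,
                         measurements: str = "discrete",
                         constants: models.ModelConstants | None = None,
                         solver: models.SolverSettings | None = None,
                         ) -> tuple[EvaluationBundle, int]:
    """Run the model on every row of a pick-freeze system.

    Evaluates A, B and all AB_i (the full N (n + 2) budget), reduces
    waveforms to the requested measurement type, and flags failed rows: a
    sample row is masked when its A evaluation or any of its AB_i
    evaluations failed, so deletion stays paired across matrices.
    Returns the bundle and the number of model evaluations performed.
    """
    from . import _kernels

    N, n = pf.n_samples, pf.n_params
    stacked = pf.stacked()  # A, B, AB_1..AB_n
    waves, ok = _kernels.evaluate_batch(model_id, stacked, constants, solver)
    n_eval = stacked.shape[0]

    def block(k):
        return waves[k * N:(k + 1) * N], ok[k * N:(k + 1) * N]

    w_A, ok_A = block(0)
    w_AB = [block(2 + i) for i in range(n)]
    if measurements == "continuous":
        f_A = w_A  # (N, m, T)
        f_AB = np.stack([w[0] for w in w_AB])  # (n, N, m, T)
        out_names = OUTPUT_NAMES_CONTINUOUS
    else:
        f_A = _discrete_reduce(w_A)
        f_AB = np.stack([_discrete_reduce(w[0]) for w in w_AB])
        out_names = OUTPUT_NAMES
    failed = ~ok_A
    for w in w_AB:
        failed |= ~w[1]
    pnames = tuple(models.nominal_parameters(model_id).names)
    bundle = EvaluationBundle(np.nan_to_num(f_A, nan=0.0),
                              np.nan_to_num(f_AB, nan=0.0),
                              failed, pnames, out_names)
    return bundle, n_eval


def _discrete_reduce(waves: np.ndarray) -> np.ndarray:
    """(N, 3, T) waveforms -> (N, 3) scalars: mean P_lv, max P_art, max V_lv."""
    return np.stack([waves[:, 0].mean(axis=1),
                     waves[:, 1].max(axis=1),
                     waves[:, 2].max(axis=1)], axis=1)


def reduce_to_discrete(bundle: EvaluationBundle) -> EvaluationBundle:
    """Turn a continuous (waveform) bundle into its discrete-measurement twin.

    The discrete scalars are reductions of the same waveforms, so a
    continuous evaluation can serve both measurement types without
    re-spending the N (n + 2) model evaluations.
    """
    if bundle.f_A.ndim != 3:
        raise ValueError("expected a time-resolved (continuous) bundle")
    f_A = _discrete_reduce(bundle.f_A)
    f_AB = np.stack([_discrete_reduce(bundle.f_AB[i])
                     for i in range(bundle.n_params)])
    return EvaluationBundle(f_A, f_AB, bundle.failed,
                            bundle.parameter_names, OUTPUT_NAMES)


@dataclass(frozen=True)
class GsaResult:
    """Everything one run produced."""

    config: RunConfig
    bundle: EvaluationBundle
    indices: TotalOrderIndices
    tas: TimeAveragedIndices | None
    n_evaluations: int
    n_failed: int

    @property
    def sensitivity_matrix(self) -> np.ndarray:
        """The (m, n) matrix used downstream for orthogonality: TAS for
        continuous runs, S_T itself for discrete runs."""
        return self.tas.TAS if self.tas is not None else self.indices.S_T


def run_gsa(config: RunConfig) -> GsaResult:
    """Execute one full sensitivity run; deterministic given the seed."""
    n = len(config.parameter_names())
    pf = samplers.pick_freeze_design(config.sampler, config.N, n,
                                     seed=config.seed,
                                     bounds=config.resolved_bounds())
    bundle, n_eval = evaluate_pick_freeze(config.model_id, pf,
                                          config.measurements,
                                          config.constants, config.solver)
    frac_failed = bundle.failed.mean()
    if frac_failed > config.max_failure_fraction:
        raise RuntimeError(
            f"{frac_failed:.1%} of sample rows failed to integrate "
            f"(> {config.max_failure_fraction:.0%}); check bounds "
            f"{config.resolved_bounds().tolist()} for {config.model_id}")
    indices = total_order_matrix(bundle, config.estimator)
    tas = None
    if config.measurements == "continuous":
        f_A = bundle.valid()[0]  # (N, m, T)
        ddof = 0 if config.estimator == "janon" else 1
        var_t = f_A.var(axis=0, ddof=ddof)  # (m, T)
        tas = time_average(indices.S_T, var_t,
                           indices.parameter_names, indices.output_names)
    return GsaResult(config, bundle, indices, tas, n_eval,
                     int(bundle.failed.sum()))


def write_run(result: GsaResult, outdir) -> None:
    """Write indices CSV, TAS CSV (continuous runs) and a run manifest."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    result.indices.to_dataframe(sampler=cfg.sampler).to_csv(
        out / "indices.csv", index=False)
    if result.tas is not None:
        result.tas.to_dataframe().to_csv(out / "tas.csv")
    manifest = {
        "model_id": cfg.model_id,
        "sampler": cfg.sampler,
        "estimator": cfg.estimator,
        "N": cfg.N,
        "measurements": cfg.measurements,
        "seed": cfg.seed,
        "bounds": cfg.resolved_bounds().tolist(),
        "initial_state": list((cfg.constants or
                               models.default_constants(cfg.model_id)).initial_state
                              or models.DEFAULT_STATE[cfg.model_id]),
        "n_evaluations": result.n_evaluations,
        "n_failed": result.n_failed,
        "versions": {"python": platform.python_version(),
                     "numpy": np.__version__},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
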