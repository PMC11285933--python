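"""Bootstrap confidence intervals and convergence declaration.

Uncertainty of a total-order index is quantified by resampling the N sample
rows with replacement — the same row draw applied jointly to f(A) and every
f(AB_i), preserving the pick-freeze pairing — and taking percentile
intervals over B re-estimates.

All four estimators are functions of per-row sufficient statistics
(f(A), f(A)^2 and the per-parameter cross terms with f(AB_i)), so a
bootstrap replicate reduces to a weighted sum of row statistics with
multinomial weights; the B x N resampling is a single matrix product.

A run sequence over an increasing sample-size grid is declared converged at
the smallest N where (a) the parameter ranking stops changing for the rest
of the grid and (b) every index above a floor has a relative CI half-width
within tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import models, pipeline, samplers
from .estimators import ESTIMATOR_IDS, EvaluationBundle, total_order_matrix
from .orthogonality import orthogonality_matrix, rank_by_orthogonality

__all__ = [
    "BootstrapCI",
    "ConvergenceTrace",
    "bootstrap_indices",
    "declare_converged_n",
    "assess_convergence",
]


@dataclass(frozen=True)
class BootstrapCI:
    """Point estimates with percentile bootstrap bounds.

    Arrays are shaped like the index matrix: (m, n) or (m, n, T).
    With B = 0 the bounds are NaN (point estimates only).
    """

    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    B: int
    estimator: str

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def relative_half_width(self, floor: float = 0.0) -> np.ndarray:
        """Half-width over |estimate|; NaN where |estimate| < floor."""
        half = self.width / 2.0
        mag = np.abs(self.estimate)
        return np.where(mag >= max(floor, np.finfo(float).tiny),
                        half / mag, np.nan)


def _row_stats(f_A: np.ndarray, f_AB: np.ndarray):
    """Per-row sufficient statistics, flattened over output (and time) axes."""
    N = f_A.shape[0]
    n = f_AB.shape[0]
    a = f_A.reshape(N, -1)  # (N, d)
    d = a.shape[1]
    ab = f_AB.reshape(n, N, d)
    # columns: a, a^2, then per parameter [ab_i, ab_i^2, a*ab_i]
    cols = [a, a * a]
    for i in range(n):
        cols.extend([ab[i], ab[i] * ab[i], a * ab[i]])
    return np.concatenate(cols, axis=1), d


def _indices_from_sums(sums: np.ndarray, N: int, n: int, d: int,
                       method: str) -> np.ndarray:
    """Index estimates from summed row statistics; sums is (..., (2+3n) d)."""
    lead = sums.shape[:-1]
    s = sums.reshape(*lead, 2 + 3 * n, d)
    s_a, s_a2 = s[..., 0, :], s[..., 1, :]
    f0 = s_a / N
    ey2 = s_a2 / N
    var_std = (s_a2 - N * f0**2) / (N - 1)
    out = np.empty((*lead, n, d))
    for i in range(n):
        s_ab = s[..., 2 + 3 * i, :]
        s_ab2 = s[..., 3 + 3 * i, :]
        s_cross = s[..., 4 + 3 * i, :]
        cross = s_cross / N
        if method == "janon":
            f0p = (s_a + s_ab) / (2 * N)
            m2p = (s_a2 + s_ab2) / (2 * N)
            num = m2p - cross  # == Var - cross + f0^2, cancels exactly
            var = np.maximum(m2p - f0p**2, 0.0)
        elif method == "homma":
            num = var_std - cross + f0**2
            var = var_std
        elif method == "sobol":
            num = ey2 - cross
            var = var_std
        else:  # jansen
            num = (ey2 + s_ab2 / N) / 2.0 - cross
            var = var_std
        with np.errstate(invalid="ignore", divide="ignore"):
            out[..., i, :] = np.where(var > 0, num / var, np.nan)
    return out


def bootstrap_indices(bundle: EvaluationBundle, method: str, B: int = 1000,
                      level: float = 0.95, seed: int | None = None,
                      ) -> BootstrapCI:
    """Percentile bootstrap CIs for every index of a bundle.

    Resamples row indices with replacement, applying the same draw jointly
    to f(A) and every f(AB_i); per (output, parameter) — and per time point
    for time-resolved bundles — the interval spans the level-quantiles of
    the B re-estimates. The point estimate is the full-sample estimate.
    """
    if method not in ESTIMATOR_IDS:
        raise ValueError(f"unknown estimator {method!r}")
    if B < 0:
        raise ValueError("B must be >= 0")
    point = total_order_matrix(bundle, method).S_T  # (m, n[, T])
    if B == 0:
        nanlike = np.full_like(point, np.nan)
        return BootstrapCI(point, nanlike, nanlike, level, 0, method)
    f_A, f_AB = bundle.valid()
    N, n = f_A.shape[0], f_AB.shape[0]
    stats, d = _row_stats(f_A, f_AB)  # (N, (2+3n) d)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(N, np.full(N, 1.0 / N), size=B).astype(float)
    sums = counts @ stats  # (B, (2+3n) d)
    boot = _indices_from_sums(sums, N, n, d, method)  # (B, n, d)
    alpha = (1.0 - level) / 2.0
    import warnings as _warnings

    with _warnings.catch_warnings():
        # all-NaN cells (zero-variance outputs) stay NaN without noise
        _warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanquantile(boot, alpha, axis=0)
        hi = np.nanquantile(boot, 1.0 - alpha, axis=0)

    # reshape (n, d) back to the index layout (m, n[, T])
    def to_index_shape(x):
        x = np.moveaxis(x.reshape(n, *point.shape[:1], *point.shape[2:]), 0, 1)
        return x.reshape(point.shape)

    return BootstrapCI(point, to_index_shape(lo), to_index_shape(hi),
                       level, B, method)


@dataclass(frozen=True)
class ConvergenceTrace:
    """Per-grid-point indices, CIs and rankings over increasing N."""

    N_grid: tuple[int, ...]
    cis: tuple[BootstrapCI, ...]
    rank_vectors: tuple[np.ndarray, ...]
    converged_N: int | None
    tolerance: float
    index_floor: float
    parameter_names: tuple[str, ...] | None = None

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for N, ci, ranks in zip(self.N_grid, self.cis, self.rank_vectors):
            m, n = ci.estimate.shape[:2]
            pars = self.parameter_names or tuple(f"theta{i}" for i in range(n))
            for j in range(m):
                for i in range(n):
                    rows.append({"N": N, "output": j, "parameter": pars[i],
                                 "estimate": ci.estimate[j, i],
                                 "lo": ci.lower[j, i], "hi": ci.upper[j, i],
                                 "rank": int(ranks[i])})
        return pd.DataFrame(rows)


def declare_converged_n(N_grid, rank_vectors, cis, tolerance: float,
                        index_floor: float) -> int | None:
    """Smallest grid N whose ranking equals the previous grid point's and
    every later one's, with relative CI half-widths within tolerance for all
    indices at or above the floor. None if the grid never converges."""
    for k in range(1, len(N_grid)):
        stable = all(np.array_equal(rank_vectors[k - 1], rank_vectors[j])
                     for j in range(k, len(N_grid)))
        if not stable:
            continue
        rhw = cis[k].relative_half_width(floor=index_floor)
        mag = np.abs(cis[k].estimate)
        check = rhw[mag >= index_floor]
        if check.size == 0 or np.nanmax(check) <= tolerance:
            return N_grid[k]
    return None


def _prefix_bundle(bundle: EvaluationBundle, N: int) -> EvaluationBundle:
    return EvaluationBundle(bundle.f_A[:N], bundle.f_AB[:, :N],
                            bundle.failed[:N], bundle.parameter_names,
                            bundle.output_names)


def assess_convergence(model_id: str, sampler: str, estimator: str,
                       N_grid, B: int = 1000, tolerance: float = 0.05,
                       index_floor: float = 0.01, level: float = 0.95,
                       measurements: str = "discrete",
                       bounds: np.ndarray | None = None,
                       seed: int | None = 0,
                       rank_on: str = "orthogonality",
                       constants=None, solver=None) -> ConvergenceTrace:
    """Run the pipeline over an increasing N grid and declare convergence.

    Converged N is the smallest grid point where (a) the parameter ranking
    (mean-orthogonality ranks by default; ``rank_on='influence'`` ranks by
    mean index magnitude instead) equals the previous grid point's and every
    later one's, and (b) the relative CI half-width is within ``tolerance``
    for all indices whose point estimate is at least ``index_floor``.

    Sequence samplers (sobol, golden) evaluate one design at max(N_grid) and
    reuse its prefixes; the lattice is rebuilt per N (its points depend on
    N); Monte Carlo samplers redraw with a per-N seed derived from ``seed``.
    """
    N_grid = tuple(int(N) for N in N_grid)
    if len(N_grid) < 2 or any(b <= a for a, b in zip(N_grid, N_grid[1:])):
        raise ValueError("N grid must be strictly increasing, length >= 2")
    if bounds is None:
        bounds = models.default_bounds(model_id)
    n = len(models.nominal_parameters(model_id).names)
    prefix_ok = sampler in ("sobol", "golden")
    full_bundle = None
    if prefix_ok:
        pf = samplers.pick_freeze_design(sampler, max(N_grid), n, seed=seed,
                                         bounds=bounds)
        full_bundle, _ = pipeline.evaluate_pick_freeze(
            model_id, pf, measurements, constants, solver)
    cis, rank_vecs = [], []
    ss = np.random.SeedSequence(seed)
    boot_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(N_grid))]
    for k, N in enumerate(N_grid):
        if prefix_ok:
            bundle = _prefix_bundle(full_bundle, N)
        else:
            pf = samplers.pick_freeze_design(sampler, N, n, seed=seed,
                                             bounds=bounds)
            bundle, _ = pipeline.evaluate_pick_freeze(
                model_id, pf, measurements, constants, solver)
        ci = bootstrap_indices(bundle, estimator, B, level, seed=boot_seeds[k])
        S = ci.estimate
        if S.ndim == 3:  # continuous: rank on the time-averaged matrix
            f_A = bundle.valid()[0]
            ddof = 0 if estimator == "janon" else 1
            S = pipeline.time_average(S, f_A.var(axis=0, ddof=ddof)).TAS
        if rank_on == "orthogonality":
            ranks = rank_by_orthogonality(orthogonality_matrix(S)).ranks
        elif rank_on == "influence":
            scores = np.abs(S).mean(axis=0)
            order = np.argsort(-scores, kind="stable")
            ranks = np.empty(n, dtype=int)
            ranks[order] = np.arange(1, n + 1)
        else:
            raise ValueError("rank_on must be 'orthogonality' or 'influence'")
        cis.append(ci)
        rank_vecs.append(ranks)
    converged = declare_converged_n(N_grid, rank_vecs, cis, tolerance, index_floor)
    pnames = tuple(models.nominal_parameters(model_id).names)
    return ConvergenceTrace(N_grid, tuple(cis), tuple(map(np.asarray, rank_vecs)),
                            converged, tolerance, index_floor, pnames)
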