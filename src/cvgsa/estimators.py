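"""Total-order Sobol index estimators on pick-freeze model evaluations.

Four classical estimators of the total effect S_T,i from the paired
evaluations f(A) and f(AB_i), each normalised by its own moment convention's
output variance so the index is a variance ratio:

==========  ==================================================  ============
estimator   numerator (l runs over the N sample rows)           moments
==========  ==================================================  ============
``homma``   Var(Y) - (1/N) sum f(A) f(AB_i) + f0^2              standard
``sobol``   (1/N) sum f(A) [f(A) - f(AB_i)]                     standard
``jansen``  (1/2N) sum [f(A) - f(AB_i)]^2                       standard
``janon``   Var(Y) - (1/N) sum f(A) f(AB_i) + f0^2              pooled
==========  ==================================================  ============

Standard moments use the mean of f(A) and the (N-1)-denominator variance;
the pooled (Janon) convention averages f(A) and f(AB_i) together with an
N-denominator variance. With pooled moments the +f0^2 sign makes the Janon
index exactly zero for an inactive parameter (f(AB_i) = f(A)); the
alternative printed "-f0^2" form is available behind ``compat_printed_sign``.

The Jansen and Janon numerators are sums of squares, so those indices are
never negative; Homma and Sobol estimates can go negative at finite N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ESTIMATOR_IDS",
    "EvaluationBundle",
    "Moments",
    "TotalOrderIndices",
    "moments",
    "total_order_index",
    "total_order_matrix",
]

ESTIMATOR_IDS = ("homma", "sobol", "jansen", "janon")


@dataclass(frozen=True)
class EvaluationBundle:
    """Model outputs over a pick-freeze system.

    f_A: (N, m) or (N, m, T) outputs on matrix A.
    f_AB: (n, N, m) or (n, N, m, T) outputs on the hybrids AB_i.
    failed: (N,) rows to exclude jointly from A and every AB_i
    (paired deletion keeps the pick-freeze pairing intact).
    """

    f_A: np.ndarray
    f_AB: np.ndarray
    failed: np.ndarray | None = None
    parameter_names: tuple[str, ...] | None = None
    output_names: tuple[str, ...] | None = None

    def __post_init__(self):
        f_A = np.asarray(self.f_A, dtype=float)
        f_AB = np.asarray(self.f_AB, dtype=float)
        object.__setattr__(self, "f_A", f_A)
        object.__setattr__(self, "f_AB", f_AB)
        if f_AB.shape[1:] != f_A.shape:
            raise ValueError("f_AB must be shaped (n,) + f_A.shape")
        failed = self.failed
        failed = (np.zeros(f_A.shape[0], dtype=bool) if failed is None
                  else np.asarray(failed, dtype=bool))
        if failed.shape != (f_A.shape[0],):
            raise ValueError("failure mask must have one flag per sample row")
        object.__setattr__(self, "failed", failed)

    @property
    def n_params(self) -> int:
        return self.f_AB.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.f_A.shape[1]

    @property
    def n_effective(self) -> int:
        """Sample rows remaining after paired deletion of failed rows."""
        return int((~self.failed).sum())

    def valid(self) -> tuple[np.ndarray, np.ndarray]:
        keep = ~self.failed
        return self.f_A[keep], self.f_AB[:, keep]


@dataclass(frozen=True)
class Moments:
    """Output mean f0 and variance under one convention."""

    f0: np.ndarray
    var: np.ndarray
    convention: str

    def __post_init__(self):
        if self.convention not in ("standard", "janon"):
            raise ValueError("convention must be 'standard' or 'janon'")
        if np.any(np.asarray(self.var) < -1e-12):
            raise ValueError("variance must be >= 0")


def moments(f_A, f_ABi=None, convention: str = "standard") -> Moments:
    """Mean and variance of the outputs under a moment convention.

    ``standard``: f0 = mean of f(A); variance with N-1 denominator.
    ``janon``: f0 and variance pooled over f(A) and f(AB_i), N denominator.
    Arrays reduce along axis 0 (the sample axis).
    """
    f_A = np.asarray(f_A, dtype=float)
    if f_A.shape[0] == 0:
        raise ValueError("empty evaluation set")
    if convention == "standard":
        if f_A.shape[0] < 2:
            raise ValueError("standard variance needs N >= 2 (N - 1 denominator)")
        f0 = f_A.mean(axis=0)
        var = np.sum((f_A - f0) ** 2, axis=0) / (f_A.shape[0] - 1)
    elif convention == "janon":
        if f_ABi is None:
            raise ValueError("janon convention pools f(A) with f(AB_i)")
        f_ABi = np.asarray(f_ABi, dtype=float)
        f0 = (f_A.mean(axis=0) + f_ABi.mean(axis=0)) / 2.0
        var = (np.mean(f_A**2, axis=0) + np.mean(f_ABi**2, axis=0)) / 2.0 - f0**2
        var = np.maximum(var, 0.0)  # guard rounding on near-constant outputs
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return Moments(f0, var, convention)


def _guarded_ratio(num, var):
    """num / var with zero-variance cells flagged as NaN, not zero."""
    num = np.asarray(num, dtype=float)
    var = np.asarray(var, dtype=float)
    out = np.full(np.broadcast(num, var).shape, np.nan)
    good = var > 0
    np.divide(num, var, out=out, where=good)
    return out


def total_order_index(f_A, f_ABi, method: str,
                      compat_printed_sign: bool = False) -> np.ndarray:
    """Total-order index of one parameter, per output (and time point).

    ``f_A`` and ``f_ABi`` are (N, ...) with matching trailing shape; the
    estimate reduces along axis 0. Cells with zero output variance return
    NaN (the index is undefined there, not zero).
    """
    if method not in ESTIMATOR_IDS:
        raise ValueError(f"unknown estimator {method!r}; choose from {ESTIMATOR_IDS}")
    f_A = np.asarray(f_A, dtype=float)
    f_ABi = np.asarray(f_ABi, dtype=float)
    if f_A.shape != f_ABi.shape:
        raise ValueError("f(A) and f(AB_i) must have identical shapes")
    if method == "janon":
        m = moments(f_A, f_ABi, "janon")
        cross = np.mean(f_A * f_ABi, axis=0)
        # numerator written as pooled-second-moment minus cross term: this is
        # Var - cross + f0^2 algebraically, but cancels exactly (index 0, not
        # rounding noise) when the parameter is inactive (f_ABi == f_A)
        m2 = (np.mean(f_A**2, axis=0) + np.mean(f_ABi**2, axis=0)) / 2.0
        num = m2 - cross
        if compat_printed_sign:
            num = num - 2.0 * m.f0**2  # the printed "-f0^2" variant
    else:
        m = moments(f_A, convention="standard")
        if method == "homma":
            num = m.var - np.mean(f_A * f_ABi, axis=0) + m.f0**2
        elif method == "sobol":
            num = np.mean(f_A * (f_A - f_ABi), axis=0)
        else:  # jansen
            num = np.mean((f_A - f_ABi) ** 2, axis=0) / 2.0
    return _guarded_ratio(num, m.var)


@dataclass(frozen=True)
class TotalOrderIndices:
    """S_T matrix: outputs x parameters (x time points), plus provenance."""

    S_T: np.ndarray
    estimator: str
    n_samples: int
    parameter_names: tuple[str, ...] | None = None
    output_names: tuple[str, ...] | None = None

    @property
    def is_time_resolved(self) -> bool:
        return self.S_T.ndim == 3

    def to_dataframe(self, sampler: str | None = None):
        """Long format: (output, parameter[, time_index], estimator, N, index)."""
        import pandas as pd

        m, n = self.S_T.shape[:2]
        outs = self.output_names or tuple(f"y{j}" for j in range(m))
        pars = self.parameter_names or tuple(f"theta{i}" for i in range(n))
        if self.is_time_resolved:
            T = self.S_T.shape[2]
            idx = pd.MultiIndex.from_product([outs, pars, range(T)],
                                             names=["output", "parameter", "time_index"])
            df = pd.DataFrame({"index_value": self.S_T.reshape(-1)}, index=idx)
        else:
            idx = pd.MultiIndex.from_product([outs, pars],
                                             names=["output", "parameter"])
            df = pd.DataFrame({"index_value": self.S_T.reshape(-1)}, index=idx)
        df = df.reset_index()
        df["estimator"] = self.estimator
        df["N"] = self.n_samples
        if sampler is not None:
            df["sampler"] = sampler
        return df


def total_order_matrix(bundle: EvaluationBundle, method: str,
                       compat_printed_sign: bool = False) -> TotalOrderIndices:
    """Apply one estimator to every parameter of an evaluation bundle.

    Returns S_T of shape (m, n) for scalar outputs or (m, n, T) for
    time-resolved outputs. Failed sample rows are deleted jointly from A and
    every AB_i before estimation.
    """
    f_A, f_AB = bundle.valid()
    if f_A.shape[0] == 0:
        raise ValueError("no valid sample rows remain in the bundle")
    cols = [total_order_index(f_A, f_AB[i], method, compat_printed_sign)
            for i in range(bundle.n_params)]
    # each col is (m,) or (m, T); stack as parameter axis 1
    S_T = np.stack(cols, axis=1)
    return TotalOrderIndices(S_T, method, f_A.shape[0],
                             bundle.parameter_names, bundle.output_names)
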