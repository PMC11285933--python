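"""Unit-hypercube experimental designs and pick-freeze matrix systems.

Five design families, two Monte Carlo and three quasi-Monte Carlo:

``uniform``  i.i.d. uniform draws.
``lhs``      Latin hypercube: one point per axis stratum per dimension.
``golden``   additive-recurrence (Kronecker) sequence with generalized
             golden-ratio increments, optionally Cranley-Patterson shifted.
``lattice``  rank-1 lattice frac(i z / N) with a Korobov-form generating
             vector, optionally Cranley-Patterson shifted.
``sobol``    Sobol' low-discrepancy sequence (standard direction numbers,
             leading zero point kept, unscrambled by default).

Designs are generated on [0,1)^n, scaled affinely to parameter bounds, and
assembled into the pick-freeze system (A, B, AB_1..AB_n) whose N(n+2) rows
are the model-evaluation budget of a total-order sensitivity run.
"""

from __future__ import annotations

import functools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

__all__ = [
    "DesignMatrix",
    "PickFreezeSet",
    "SAMPLER_IDS",
    "sample_uniform",
    "sample_lhs",
    "sample_golden",
    "sample_lattice",
    "sample_sobol",
    "sample",
    "scale_to_bounds",
    "build_pick_freeze",
    "pick_freeze_design",
    "save_design",
    "load_design",
]

SAMPLER_IDS = ("uniform", "lhs", "golden", "lattice", "sobol")
_QMC = frozenset({"golden", "lattice", "sobol"})


@dataclass(frozen=True)
class DesignMatrix:
    """An N x n design with its generation metadata."""

    values: np.ndarray
    method: str
    seed: int | None = None
    unit_cube: bool = True
    bounds: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("design must be 2-D (samples x parameters)")
        if self.unit_cube and (v.min() < 0 or v.max() >= 1):
            raise ValueError("unit-cube design has points outside [0, 1)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_params(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PickFreezeSet:
    """Matrices A, B and the n column-substituted hybrids AB_i.

    ``AB[i]`` equals A everywhere except parameter column i, which is taken
    from B. Samples are rows and parameters are columns throughout.
    """

    A: np.ndarray
    B: np.ndarray
    AB: tuple[np.ndarray, ...]

    @property
    def n_samples(self) -> int:
        return self.A.shape[0]

    @property
    def n_params(self) -> int:
        return self.A.shape[1]

    @property
    def n_evaluations(self) -> int:
        """Total rows across A, B and all AB_i: N (n + 2)."""
        return self.n_samples * (self.n_params + 2)

    def stacked(self) -> np.ndarray:
        """All rows as one (N (n+2), n) matrix: A, B, AB_1, ..., AB_n."""
        return np.vstack([self.A, self.B, *self.AB])


def _check_shape(N: int, n: int) -> None:
    if N < 1 or n < 1:
        raise ValueError("require N >= 1 and n >= 1")


def sample_uniform(N: int, n: int, seed: int | None = None) -> DesignMatrix:
    """i.i.d. uniform points on [0,1)^n; reproducible for a fixed seed."""
    _check_shape(N, n)
    rng = np.random.default_rng(seed)
    return DesignMatrix(rng.random((N, n)), "uniform", seed)


def sample_lhs(N: int, n: int, seed: int | None = None) -> DesignMatrix:
    """Latin hypercube: independent stratum permutations per dimension.

    Exactly one point falls in each stratum [(i-1)/N, i/N) of every
    coordinate axis.
    """
    _check_shape(N, n)
    eng = qmc.LatinHypercube(d=n, seed=np.random.default_rng(seed))
    return DesignMatrix(eng.random(N), "lhs", seed)


def _phi_d(d: int) -> float:
    """Generalized golden ratio: the positive root of x**(d+1) = x + 1."""
    x = 2.0
    for _ in range(64):
        x = (1.0 + x) ** (1.0 / (d + 1))
    return x


def sample_golden(N: int, n: int, seed: int | None = None) -> DesignMatrix:
    """Additive-recurrence sequence with golden-ratio increments.

    Point i (i = 1..N) has coordinates frac(i * alpha_j) with
    alpha_j = phi_n**-(j+1) for the generalized golden ratio phi_n; a seed
    applies a Cranley-Patterson rotation (uniform shift modulo 1), leaving
    the low-discrepancy structure intact.
    """
    _check_shape(N, n)
    phi = _phi_d(n)
    alpha = (1.0 / phi) ** np.arange(1, n + 1)
    pts = np.outer(np.arange(1, N + 1), alpha)
    if seed is not None:
        pts = pts + np.random.default_rng(seed).random(n)
    return DesignMatrix(np.mod(pts, 1.0), "golden", seed)


def _b2_weight(x: np.ndarray) -> np.ndarray:
    # 2 pi^2 B_2(x): the shift-invariant kernel of the order-2 Korobov space
    return 2.0 * np.pi**2 * (x * x - x + 1.0 / 6.0)


@functools.lru_cache(maxsize=32)
def korobov_generator(N: int, n: int, n_candidates: int = 128) -> tuple[int, ...]:
    """Korobov-form generating vector (1, a, a^2, ...) mod N for a rank-1 lattice.

    The multiplier ``a`` minimizes the standard shift-invariant P2 squared
    worst-case error over a deterministic candidate set, so the vector is a
    pure function of (N, n).
    """
    if N == 1:
        return (0,) * n
    cand = np.array([a for a in range(1, N) if np.gcd(a, N) == 1])
    if cand.size > n_candidates:
        pick = np.random.default_rng(20240717).choice(cand.size, n_candidates,
                                                      replace=False)
        cand = np.sort(cand[pick])
    i = np.arange(N, dtype=np.int64)
    best_a, best_err = 1, np.inf
    for a in cand:
        z = np.ones(n, dtype=np.int64)
        for j in range(1, n):
            z[j] = (z[j - 1] * a) % N
        prod = np.ones(N)
        for j in range(n):
            prod *= 1.0 + _b2_weight(((i * z[j]) % N) / N)
        err = prod.mean() - 1.0
        if err < best_err:
            best_a, best_err = int(a), err
    z = np.ones(n, dtype=np.int64)
    for j in range(1, n):
        z[j] = (z[j - 1] * best_a) % N
    return tuple(int(v) for v in z)


def sample_lattice(N: int, n: int, generator=None,
                   seed: int | None = None) -> DesignMatrix:
    """Rank-1 lattice: theta_i = frac(i z / N), i = 0..N-1.

    ``generator`` is the integer generating vector z (default: the Korobov
    vector from :func:`korobov_generator`). A seed applies a seeded
    Cranley-Patterson rotation. The construction keeps every point inside
    the unit cube with no rejection step.
    """
    _check_shape(N, n)
    z = np.asarray(generator if generator is not None else korobov_generator(N, n),
                   dtype=np.int64)
    if z.shape != (n,):
        raise ValueError(f"generating vector must have length {n}")
    pts = np.outer(np.arange(N), z) % N / N
    if seed is not None:
        pts = np.mod(pts + np.random.default_rng(seed).random(n), 1.0)
    return DesignMatrix(pts, "lattice", seed)


def sample_sobol(N: int, n: int, seed: int | None = None,
                 scramble: bool = False) -> DesignMatrix:
    """Sobol' sequence points from standard direction numbers.

    Unscrambled by default and starting at the zero point, so the first N
    points of a longer sequence coincide with the N-point design (prefix
    property). ``seed`` only matters when ``scramble`` is set.
    """
    _check_shape(N, n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non power-of-two N
        eng = qmc.Sobol(d=n, scramble=scramble, seed=np.random.default_rng(seed))
        pts = eng.random(N)
    return DesignMatrix(pts, "sobol", seed if scramble else None)


_SAMPLERS = {
    "uniform": sample_uniform,
    "lhs": sample_lhs,
    "golden": sample_golden,
    "lattice": sample_lattice,
    "sobol": sample_sobol,
}


def sample(method: str, N: int, n: int, seed: int | None = None) -> DesignMatrix:
    """Dispatch to one of the five samplers by id."""
    try:
        fn = _SAMPLERS[method]
    except KeyError:
        raise ValueError(f"unknown sampler {method!r}; choose from {SAMPLER_IDS}")
    return fn(N, n, seed=seed)


def scale_to_bounds(design: DesignMatrix, bounds: np.ndarray) -> DesignMatrix:
    """Affinely map a unit-cube design onto per-parameter (lower, upper) bounds."""
    if not design.unit_cube:
        raise ValueError("design is already scaled")
    bounds = np.asarray(bounds, dtype=float)
    if bounds.shape != (design.n_params, 2):
        raise ValueError(f"bounds must be ({design.n_params}, 2)")
    lo, hi = bounds[:, 0], bounds[:, 1]
    if not np.all(np.isfinite(bounds)) or np.any(lo >= hi):
        raise ValueError("require finite lower < upper bounds")
    return DesignMatrix(lo + design.values * (hi - lo), design.method,
                        design.seed, unit_cube=False, bounds=bounds)


def build_pick_freeze(A, B) -> PickFreezeSet:
    """Assemble AB_i hybrids: A with parameter column i replaced from B."""
    A = A.values if isinstance(A, DesignMatrix) else np.asarray(A, dtype=float)
    B = B.values if isinstance(B, DesignMatrix) else np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("A and B must have identical shapes")
    ab = []
    for i in range(A.shape[1]):
        m = A.copy()
        m[:, i] = B[:, i]
        ab.append(m)
    return PickFreezeSet(A, B, tuple(ab))


def pick_freeze_design(method: str, N: int, n: int, seed: int | None = None,
                       bounds: np.ndarray | None = None) -> PickFreezeSet:
    """Generate the full pick-freeze system for one sampler.

    Monte Carlo samplers draw A and B as two independently seeded designs;
    quasi-Monte Carlo samplers draw one 2n-dimensional design and split it
    into A (first n columns) and B (last n columns), so A and B inherit the
    joint low-discrepancy structure without being identical.
    """
    if method in _QMC:
        full = sample(method, N, 2 * n, seed=seed).values
        a, b = full[:, :n], full[:, n:]
    else:
        ss = np.random.SeedSequence(seed)
        s_a, s_b = ss.spawn(2)
        a = sample(method, N, n, seed=np.random.default_rng(s_a).integers(2**31)).values
        b = sample(method, N, n, seed=np.random.default_rng(s_b).integers(2**31)).values
    if bounds is not None:
        bounds = np.asarray(bounds, dtype=float)
        lo, hi = bounds[:, 0], bounds[:, 1]
        a = lo + a * (hi - lo)
        b = lo + b * (hi - lo)
    return build_pick_freeze(a, b)


def save_design(design: DesignMatrix, csv_path) -> None:
    """Write a design as CSV plus a JSON sidecar holding its metadata."""
    np.savetxt(csv_path, design.values, delimiter=",")
    meta = {
        "method": design.method,
        "seed": design.seed,
        "unit_cube": design.unit_cube,
        "bounds": None if design.bounds is None else design.bounds.tolist(),
    }
    with open(str(csv_path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_design(csv_path) -> DesignMatrix:
    values = np.loadtxt(csv_path, delimiter=",", ndmin=2)
    with open(str(csv_path) + ".json") as fh:
        meta = json.load(fh)
    bounds = meta.get("bounds")
    return DesignMatrix(values, meta["method"], meta.get("seed"),
                        unit_cube=meta.get("unit_cube", True),
                        bounds=None if bounds is None else np.asarray(bounds))
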