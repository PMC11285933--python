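"""Parameter orthogonality, ranking, and the identifiability index.

Each parameter i owns the column S_T[:, i] of the total-order sensitivity
matrix (its sensitivity vector over the m outputs; for continuous runs the
variance-weighted time average). The orthogonality of a pair is the sine of
the angle between their sensitivity vectors:

    d_ij = sin(arccos(<S_T,j, S_T,i> / (||S_T,j|| ||S_T,i||)))

so d = 0 marks a collinear (jointly non-identifiable) pair and d = 1 an
orthogonal one. Parameters are ranked by their mean orthogonality to all
other parameters (rank 1 = most orthogonal), and the identifiability index
I_i = E_i * d_i combines a parameter's effect magnitude with its mean
orthogonality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OrthogonalityMatrix",
    "RankVector",
    "orthogonality_matrix",
    "mean_orthogonality",
    "rank_by_orthogonality",
    "identifiability_index",
]


@dataclass(frozen=True)
class OrthogonalityMatrix:
    """Symmetric n x n pairwise orthogonality, zero diagonal, entries in [0,1].

    Columns of the source sensitivity matrix with zero norm give NaN rows /
    columns (flagged missing, excluded from ranking).
    """

    d: np.ndarray
    parameter_names: tuple[str, ...] | None = None

    def pair_values(self) -> np.ndarray:
        """Off-diagonal entries pooled over unordered pairs i < j (the
        histogram-ready view)."""
        iu = np.triu_indices(self.d.shape[0], k=1)
        return self.d[iu]

    def to_dataframe(self):
        import pandas as pd

        names = self.parameter_names or tuple(
            f"theta{i}" for i in range(self.d.shape[0]))
        return pd.DataFrame(self.d, index=list(names), columns=list(names))


@dataclass(frozen=True)
class RankVector:
    """Per-parameter mean orthogonality and 1-based ranks (1 = most orthogonal)."""

    ranks: np.ndarray
    scores: np.ndarray
    parameter_names: tuple[str, ...] | None = None

    def to_dataframe(self):
        import pandas as pd

        names = self.parameter_names or tuple(
            f"theta{i}" for i in range(self.ranks.size))
        return pd.DataFrame({"mean_orthogonality": self.scores,
                             "rank": self.ranks}, index=list(names))


def orthogonality_matrix(S_T: np.ndarray,
                         parameter_names=None) -> OrthogonalityMatrix:
    """Pairwise sine-of-angle orthogonality of the sensitivity columns.

    The cosine is clamped to [-1, 1] before arccos, making d scale-free and
    well-defined even when sensitivity entries are negative (Homma/Sobol
    estimates). Zero-norm columns are flagged NaN with a warning.
    """
    S = np.asarray(S_T, dtype=float)
    if S.ndim != 2:
        raise ValueError("expected a 2-D sensitivity matrix (outputs x parameters)")
    norms = np.linalg.norm(S, axis=0)
    zero = norms == 0
    if np.any(zero):
        warnings.warn("zero-norm sensitivity column(s); their orthogonality "
                      "entries are flagged missing", RuntimeWarning)
    safe = np.where(zero, 1.0, norms)
    cos = (S.T @ S) / np.outer(safe, safe)
    cos = np.clip(cos, -1.0, 1.0)
    d = np.sin(np.arccos(cos))
    d[zero, :] = np.nan
    d[:, zero] = np.nan
    np.fill_diagonal(d, np.where(zero, np.nan, 0.0))
    return OrthogonalityMatrix(d, tuple(parameter_names) if parameter_names else None)


def mean_orthogonality(om: OrthogonalityMatrix | np.ndarray) -> np.ndarray:
    """Mean of d_ij over j != i per parameter (diagonal excluded)."""
    d = om.d if isinstance(om, OrthogonalityMatrix) else np.asarray(om, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two parameters")
    mask = ~np.eye(n, dtype=bool)
    out = np.empty(n)
    for i in range(n):
        row = d[i][mask[i]]
        # entries flagged missing (zero-norm partner columns) are excluded;
        # a fully-flagged parameter gets a NaN score and ranks last
        valid = row[~np.isnan(row)]
        out[i] = valid.mean() if valid.size else np.nan
    return out


def rank_by_orthogonality(om: OrthogonalityMatrix | np.ndarray,
                          parameter_names=None) -> RankVector:
    """Rank parameters by descending mean orthogonality.

    Rank 1 is the most orthogonal parameter. Ties break by parameter
    declaration order (stable sort); NaN scores (zero-norm columns) sort
    last.
    """
    names = (om.parameter_names if isinstance(om, OrthogonalityMatrix)
             and om.parameter_names else parameter_names)
    scores = mean_orthogonality(om)
    # stable ascending sort on the negated scores: descending order with
    # ties resolved by declaration order (NaN scores sort last)
    order = np.argsort(np.where(np.isnan(scores), np.inf, -scores), kind="stable")
    ranks = np.empty(scores.size, dtype=int)
    ranks[order] = np.arange(1, scores.size + 1)
    return RankVector(ranks, scores, tuple(names) if names else None)


def identifiability_index(effect: np.ndarray, d_mean: np.ndarray) -> np.ndarray:
    """Identifiability index I_i = E_i * d_i.

    ``effect`` is a non-negative per-parameter effect magnitude (by default
    callers use the Euclidean norm of the parameter's TAS column) and
    ``d_mean`` its mean orthogonality in [0, 1].
    """
    E = np.asarray(effect, dtype=float)
    d = np.asarray(d_mean, dtype=float)
    if E.shape != d.shape:
        raise ValueError("effect and orthogonality vectors must match in length")
    if np.any(E < 0):
        raise ValueError("effect magnitudes must be >= 0")
    with np.errstate(invalid="ignore"):
        if np.any((d < 0) | (d > 1)):
            raise ValueError("orthogonality scores must lie in [0, 1]")
    return E * d
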