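"""Phylogenetically informed allometry: shape-on-size regression.

Evolutionary allometry is measured by a multivariate regression of
independent contrasts of tangent-space shape coordinates on independent
contrasts of log centroid size.  Contrasts have no intercept, so the
regression runs through the origin; the effect size is the percentage of
total shape (contrast) variance explained, and significance comes from a
permutation test that reshuffles the size contrasts against the shape rows.
When the regression is significant, the contrast-estimated slopes are used
to size-correct the species-level data (two-step phylogenetic size
correction sensu Garland & Ives).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = [
    "fit_allometry",
    "permutation_test",
    "size_correct",
    "PhyloAllometry",
    "PhyloAllometryResults",
]


def _coerce(shape_pics, size_pics) -> tuple[np.ndarray, np.ndarray]:
    S = np.asarray(shape_pics, dtype=float)
    s = np.asarray(size_pics, dtype=float).reshape(-1)
    if S.ndim != 2:
        raise InvalidArgumentError("shape contrasts must be a 2-D array")
    if S.shape[0] != s.shape[0]:
        raise InvalidArgumentError("shape and size contrasts differ in row count")
    return S, s


def fit_allometry(shape_pics, size_pics) -> tuple[np.ndarray, float]:
    """Through-origin multivariate regression of shape on size contrasts.

    Returns the slope vector (one coefficient per shape coordinate) and the
    percentage of total shape variance explained,
    ``100 * ||s b'||_F^2 / ||S||_F^2``.
    """
    S, s = _coerce(shape_pics, size_pics)
    ss = float(s @ s)
    if ss == 0.0:
        raise InvalidArgumentError("size contrasts are all zero")
    b = (S.T @ s) / ss
    total = float((S**2).sum())
    if total == 0.0:
        return b, 0.0
    pct = 100.0 * float(b @ b) * ss / total
    return b, pct


def _pct_for_perms(S: np.ndarray, s: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Vectorised percent-variance statistic for permuted size vectors."""
    ss = float(s @ s)
    total = float((S**2).sum())
    G = S.T @ s[idx].T  # (q, n_perm)
    return 100.0 * (G**2).sum(axis=0) / (ss * total)


def permutation_test(shape_pics, size_pics, n_perm: int = 10000, seed: int = 0) -> float:
    """Permutation p-value for the allometric regression.

    Size contrasts are reshuffled against the shape rows ``n_perm`` times;
    ``p = (1 + #{permutations with percent variance >= observed}) /
    (n_perm + 1)``.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be at least 1")
    S, s = _coerce(shape_pics, size_pics)
    _, obs = fit_allometry(S, s)
    rng = np.random.default_rng(seed)
    n = s.shape[0]
    idx = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    stats = _pct_for_perms(S, s, idx)
    return float((1 + int((stats >= obs).sum())) / (n_perm + 1))


def size_correct(tangent_coords, log_sizes, coefficients) -> np.ndarray:
    """Remove the allometric component from species-level tangent coordinates.

    ``residual = observed - b (log_size - mean log_size)`` applied to the
    original (not contrast) data, reusing the contrast-estimated slopes; the
    mean shape is unchanged.
    """
    X = np.asarray(tangent_coords, dtype=float)
    s = np.asarray(log_sizes, dtype=float).reshape(-1)
    b = np.asarray(coefficients, dtype=float).reshape(-1)
    if X.shape[0] != s.shape[0] or X.shape[1] != b.shape[0]:
        raise InvalidArgumentError("shape mismatch between coordinates, sizes and slopes")
    return X - np.outer(s - s.mean(), b)


class PhyloAllometry:
    """Model object for the contrast regression of shape on size.

    Parameters
    ----------
    shape_contrasts : (m, q) array or DataFrame
        Independent contrasts of tangent-space shape coordinates.
    size_contrasts : (m,) array or Series
        Independent contrasts of log centroid size, row-matched.
    """

    def __init__(self, shape_contrasts, size_contrasts):
        if isinstance(shape_contrasts, pd.DataFrame) and isinstance(size_contrasts, (pd.DataFrame, pd.Series)):
            sc = size_contrasts.squeeze()
            shape_contrasts = shape_contrasts.loc[sc.index]
            size_contrasts = sc
        self.shape_contrasts, self.size_contrasts = _coerce(shape_contrasts, size_contrasts)

    def fit(self, n_permutations: int = 10000, seed: int = 0) -> "PhyloAllometryResults":
        coef, pct = fit_allometry(self.shape_contrasts, self.size_contrasts)
        p = permutation_test(
            self.shape_contrasts, self.size_contrasts, n_perm=n_permutations, seed=seed
        )
        return PhyloAllometryResults(
            model=self,
            coefficients=coef,
            percent_variance=pct,
            p_value=p,
            n_permutations=n_permutations,
            seed=seed,
        )


@dataclass
class PhyloAllometryResults:
    """Fitted allometric regression with permutation inference."""

    model: PhyloAllometry
    coefficients: np.ndarray
    percent_variance: float
    p_value: float
    n_permutations: int
    seed: int
    residuals: np.ndarray | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def size_correct(self, tangent_coords, log_sizes) -> np.ndarray:
        """Species-level size correction with the fitted slopes; the
        residuals are also stored on the results object."""
        self.residuals = size_correct(tangent_coords, log_sizes, self.coefficients)
        return self.residuals

    def summary(self) -> str:
        m, q = self.model.shape_contrasts.shape
        return "\n".join(
            [
                "Phylogenetic allometry (contrast regression through the origin)",
                f"  contrasts: {m}    shape coordinates: {q}",
                f"  % shape variance explained by size: {self.percent_variance:.4f}",
                f"  permutation p ({self.n_permutations} permutations, "
                f"seed {self.seed}): {self.p_value:.6g}",
                f"  significant at 0.05: {self.significant}",
            ]
        )
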