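"""Lability indexes from random skewers on a P-matrix.

Under Lande's equation ``dz = G beta`` the response of a population to a
selection gradient ``beta`` is shaped by the (additive genetic) covariance
matrix ``G``; a phenotypic covariance matrix ``P`` serves as its proxy.
When the true gradient is unknown, average response properties are probed
by "random skewers": unit selection vectors drawn uniformly on the sphere,
responses ``dz = P beta``, and three Monte-Carlo indexes

* respondability ``r_bar`` — mean response length ``||dz||``,
* evolvability ``e_bar`` — mean projection of the response on the
  gradient, ``beta' P beta``,
* flexibility ``f_bar`` — mean cosine between response and gradient.

The P-matrix is built either from reconstructed ancestral shapes at the
internal nodes of the phylogeny (default) or from independent contrasts
(an evolutionary rate matrix), and may be mean-standardized by dividing
every element by the outer product of trait means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InvalidArgumentError

__all__ = [
    "PMatrix",
    "SkewersResult",
    "build_p_matrix",
    "mean_standardize",
    "random_skewers",
    "lability_report",
]

P_SOURCES = ("ancestral_nodes", "contrasts")


@dataclass
class PMatrix:
    """A trait covariance matrix with its standardization bookkeeping."""

    matrix: np.ndarray
    trait_means: np.ndarray
    standardized: bool = False
    source: str = "ancestral_nodes"

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise InvalidArgumentError("P must be square")
        if not np.allclose(M, M.T, atol=1e-10 * max(1.0, float(np.abs(M).max()))):
            raise InvalidArgumentError("P must be symmetric")
        self.matrix = 0.5 * (M + M.T)
        self.trait_means = np.asarray(self.trait_means, dtype=float).reshape(-1)
        if self.trait_means.shape[0] != M.shape[0]:
            raise InvalidArgumentError("trait_means length must match P")
        tr = float(np.trace(self.matrix))
        if tr > 0:
            w = np.linalg.eigvalsh(self.matrix)
            if w.min() < -1e-8 * tr:
                raise InvalidArgumentError("P is not positive semi-definite")

    @property
    def p(self) -> int:
        return int(self.matrix.shape[0])


def build_p_matrix(values, trait_means=None, source: str = "ancestral_nodes") -> PMatrix:
    """Sample covariance of ancestral-node shapes or of independent contrasts.

    Parameters
    ----------
    values : (n, p) array or DataFrame
        Rows are reconstructed internal-node shape vectors
        (``source="ancestral_nodes"``) or independent contrasts
        (``source="contrasts"``; the covariance is then an evolutionary
        rate matrix).
    trait_means : (p,) array, optional
        Standardization means, normally the reconstructed root shape.  If
        omitted and ``values`` is a DataFrame whose ``attrs`` carry a
        ``root_id`` present in the index, that row is used; otherwise the
        column means are used.
    """
    if source not in P_SOURCES:
        raise InvalidArgumentError(f"source must be one of {P_SOURCES}")
    if trait_means is None and isinstance(values, pd.DataFrame):
        root_id = values.attrs.get("root_id")
        if root_id is not None and root_id in values.index:
            trait_means = values.loc[root_id].to_numpy()
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise InvalidArgumentError("need at least 3 rows to estimate a P-matrix")
    M = np.cov(X, rowvar=False, ddof=1)
    M = np.atleast_2d(M)
    if trait_means is None:
        trait_means = X.mean(axis=0)
    return PMatrix(matrix=M, trait_means=trait_means, standardized=False, source=source)


def mean_standardize(P: PMatrix, trait_means=None, epsilon: float = 1e-3) -> PMatrix:
    """Divide every element by the outer product of trait means.

    Mean standardization makes evolvability a proportional, dimensionless
    quantity.  Procrustes tangent coordinates can be arbitrarily close to
    zero (unlike the positive linear measurements the method was designed
    for), so means smaller in magnitude than ``epsilon * ||means||`` are
    floored at that signed bound before dividing.
    """
    means = np.asarray(
        P.trait_means if trait_means is None else trait_means, dtype=float
    ).reshape(-1)
    if means.shape[0] != P.p:
        raise InvalidArgumentError("trait_means length must match P")
    norm = float(np.linalg.norm(means))
    if norm == 0.0:
        raise DegenerateDataError("all trait means are zero; standardization meaningless")
    thr = epsilon * norm
    small = np.abs(means) < thr
    if small.all():
        raise DegenerateDataError(
            "every trait mean is below the epsilon guard; standardization meaningless"
        )
    signs = np.where(means >= 0.0, 1.0, -1.0)
    z = np.where(small, signs * thr, means)
    return PMatrix(
        matrix=P.matrix / np.outer(z, z),
        trait_means=means,
        standardized=True,
        source=P.source,
    )


@dataclass
class SkewersResult:
    """Monte-Carlo lability indexes with their standard errors."""

    respondability: float
    evolvability: float
    flexibility: float
    n_vectors: int
    seed: int
    mc_se: dict = field(default_factory=dict)


def random_skewers(P: PMatrix, n_vectors: int = 1000, seed: int = 0) -> SkewersResult:
    """Probe P with random unit selection gradients.

    Gradients are standard Gaussian vectors normalised to the unit sphere;
    responses are ``dz = P beta``.  Respondability is the mean ``||dz||``,
    evolvability the mean ``beta' P beta``, flexibility the mean
    ``cos(dz, beta)``.  Deterministic given ``seed``.
    """
    if n_vectors < 1:
        raise InvalidArgumentError("n_vectors must be at least 1")
    M = P.matrix
    if M.shape[0] < 2:
        raise InvalidArgumentError("random skewers need at least 2 traits")
    tr = float(np.trace(M))
    if tr <= 0.0:
        raise DegenerateDataError("zero P-matrix: flexibility undefined")
    w = np.linalg.eigvalsh(M)
    if w.min() < -1e-8 * tr:
        raise InvalidArgumentError("P is not positive semi-definite")
    rng = np.random.default_rng(seed)
    beta = rng.standard_normal((n_vectors, M.shape[0]))
    beta /= np.linalg.norm(beta, axis=1, keepdims=True)
    dz = beta @ M  # symmetric, so row convention is immaterial
    lengths = np.linalg.norm(dz, axis=1)
    proj = np.sum(dz * beta, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosine = np.where(lengths > 0, proj / lengths, 0.0)

    def mc(v):
        return float(np.std(v, ddof=1) / np.sqrt(n_vectors)) if n_vectors > 1 else 0.0

    return SkewersResult(
        respondability=float(lengths.mean()),
        evolvability=float(proj.mean()),
        flexibility=float(cosine.mean()),
        n_vectors=n_vectors,
        seed=seed,
        mc_se={
            "respondability": mc(lengths),
            "evolvability": mc(proj),
            "flexibility": mc(cosine),
        },
    )


def lability_report(P: PMatrix, skewers: SkewersResult, region: str) -> dict:
    """One tidy result row for a region's lability analysis."""
    return {
        "region": region,
        "respondability": skewers.respondability,
        "evolvability": skewers.evolvability,
        "flexibility": skewers.flexibility,
        "n_vectors": skewers.n_vectors,
        "seed": skewers.seed,
        "source": P.source,
        "standardized": P.standardized,
    }
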