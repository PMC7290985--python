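"""Principal component analysis of the genotype matrix.

Markers are centred by twice the allele frequency and (by default)
scaled by sqrt(2 p (1 - p)) — the same standardisation the genomic
relationship matrix uses, so PCA and the GRM share one Z matrix.  The
individual x individual covariance is eigendecomposed; scores are
eigenvectors scaled by the square-rooted eigenvalues with a
deterministic sign convention (largest-magnitude entry positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class PCAResult:
    """Scores, eigenvalues and variance proportions of a genotype PCA."""

    scores: pd.DataFrame = field(repr=False)  # individuals x components
    eigenvalues: np.ndarray = field(repr=False)
    proportion_variance: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if (np.diff(self.eigenvalues) > 1e-9 * max(1.0, self.eigenvalues[0])).any():
            raise ValueError("eigenvalues must be non-increasing")
        if ((self.proportion_variance < -1e-12) | (self.proportion_variance > 1 + 1e-12)).any():
            raise ValueError("variance proportions must lie in [0, 1]")

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_genotypes(
    g: GenotypeMatrix,
    n_components: int = 10,
    scale: bool = True,
) -> PCAResult:
    """PCA of a genotype matrix (missing calls mean-imputed per marker).

    Monomorphic markers carry no information and are dropped; an input
    with no polymorphic marker, or with zero total variance (e.g. one
    individual duplicated), is an error.
    """
    if g.n_individuals < 2:
        raise ValueError("PCA needs at least two individuals")
    p = g.allele_frequencies()
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("no polymorphic markers for PCA")
    p = p[poly]
    calls = g.calls[:, poly].astype(float)
    calls = np.where(calls != MISSING, calls, 2.0 * p)
    z = calls - 2.0 * p
    if scale:
        z /= np.sqrt(2.0 * p * (1.0 - p))

    cov = z @ z.T / z.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    eigval, eigvec = eigval[::-1], eigvec[:, ::-1]
    eigval = np.clip(eigval, 0.0, None)
    total = eigval.sum()
    if total <= 1e-12:
        raise ValueError("degenerate input: total variance is zero")

    k = min(n_components, g.n_individuals)
    eigval_k = eigval[:k]
    vec = eigvec[:, :k].copy()
    for c in range(k):
        lead = np.argmax(np.abs(vec[:, c]))
        if vec[lead, c] < 0:
            vec[:, c] *= -1
    scores = vec * np.sqrt(eigval_k)
    frame = pd.DataFrame(
        scores,
        index=pd.Index(g.individual_ids, name="individual_id"),
        columns=[f"PC{c + 1}" for c in range(k)],
    )
    return PCAResult(frame, eigval_k, eigval_k / total)
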