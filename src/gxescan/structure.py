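"""Principal components of the genotype matrix for substructure adjustment.

Standardization follows the GWAS convention: each locus column is centered
by twice its sample allele frequency and scaled by sqrt(p(1-p)), the
binomial standard deviation of a single allele.  Scores are the top-k left
singular directions of the standardized matrix scaled by the singular
values, computed from the eigendecomposition of the n x n genetic
relationship matrix (cheap when loci outnumber samples).  Signs are fixed
so each score vector's largest-magnitude entry is positive, making outputs
reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError


@dataclass
class PCResult:
    scores: np.ndarray               # n x k
    variance_fractions: np.ndarray   # length k, nonincreasing
    loci_used: int

    def validate(self) -> "PCResult":
        k = self.scores.shape[1]
        if self.variance_fractions.shape != (k,):
            raise DataError("variance_fractions length mismatch")
        if (np.diff(self.variance_fractions) > 1e-12).any():
            raise DataError("variance_fractions must be nonincreasing")
        if ((self.variance_fractions < -1e-12)
                | (self.variance_fractions > 1 + 1e-12)).any():
            raise DataError("variance_fractions must lie in [0, 1]")
        gram = self.scores.T @ self.scores
        off = gram - np.diag(np.diag(gram))
        scale = max(np.abs(np.diag(gram)).max(), 1.0)
        if np.abs(off).max() > 1e-8 * scale:
            raise DataError("score columns are not orthogonal")
        return self


def compute_pcs(genotypes: np.ndarray, k: int = 1,
                standardize: bool = True) -> PCResult:
    """Top-k principal components of a 0/1/2 genotype matrix.

    Monomorphic loci (sample allele frequency 0 or 1) are excluded.  With
    ``standardize=False`` columns are centered but not variance-scaled.
    """
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2:
        raise DataError("genotypes must be an n x m matrix")
    n, m = G.shape
    if k < 1:
        raise ConfigError("k must be >= 1")
    phat = np.nanmean(G, axis=0) / 2.0       # per-locus allele frequency
    keep = (phat > 0.0) & (phat < 1.0) & np.isfinite(phat)
    if not keep.any():
        raise DataError("all loci are monomorphic; no PCs can be computed")
    loci_used = int(keep.sum())
    if m < k or loci_used < k:
        raise ConfigError(f"k={k} exceeds the {loci_used} usable loci")
    p = phat[keep]
    Z = G[:, keep] - 2.0 * p[None, :]
    if standardize:
        Z = Z / np.sqrt(p * (1.0 - p))[None, :]
    if np.isnan(Z).any():
        Z = np.where(np.isnan(Z), 0.0, Z)    # missing calls contribute nothing
    K = Z @ Z.T
    vals, vecs = np.linalg.eigh(K)
    vals = vals[::-1]
    vecs = vecs[:, ::-1]
    vals = np.maximum(vals, 0.0)
    total = vals.sum()
    scores = vecs[:, :k] * np.sqrt(vals[:k])[None, :]
    # deterministic sign: largest-magnitude entry of each score is positive
    for j in range(k):
        col = scores[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            scores[:, j] = -col
    fractions = vals[:k] / total if total > 0 else np.zeros(k)
    return PCResult(scores=scores, variance_fractions=fractions,
                    loci_used=loci_used).validate()
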