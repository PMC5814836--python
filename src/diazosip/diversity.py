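"""Beta-diversity helpers for gradient-fraction communities.

SIP studies commonly ordinate the communities of all gradient fractions to
visualise whether the labelled-window fractions drift away from the rest of
the gradient.  This module provides the two pieces used for that check:
Morisita-Horn dissimilarities between fraction communities and classical
principal coordinates analysis (PCoA).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["morisita_horn_matrix", "pcoa"]


def morisita_horn_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Morisita-Horn dissimilarities between samples (rows).

    For samples x, y with totals X, Y:

        d = 1 - 2 * sum(x_i y_i) / ((sum(x_i^2)/X^2 + sum(y_i^2)/Y^2) * X * Y)

    Abundance-weighted, dominated by the common taxa, and insensitive to
    total read depth; values lie in [0, 1] with 0 for proportionally
    identical samples and 1 for disjoint supports.
    """
    arr = np.asarray(counts, dtype=float)
    totals = arr.sum(axis=1)
    if (totals <= 0).any():
        bad = list(np.asarray(counts.index)[totals <= 0])
        raise ValueError(f"zero-sum samples: {bad}")
    simpson = (arr**2).sum(axis=1) / totals**2  # sum x_i^2 / X^2 per sample
    cross = arr @ arr.T
    denom = (simpson[:, None] + simpson[None, :]) * totals[:, None] * totals[None, :]
    sim = 2.0 * cross / denom
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0)
    return pd.DataFrame(d, index=counts.index, columns=counts.index)


def pcoa(dissimilarity: pd.DataFrame, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical principal coordinates analysis (Torgerson scaling).

    Double-centers -0.5 * D^2, eigendecomposes, and returns the top-``k``
    coordinates scaled by the square root of their (positive) eigenvalues,
    along with the full eigenvalue spectrum (descending).  Negative
    eigenvalues — a sign the dissimilarity is not Euclidean-embeddable — are
    reported but never used for coordinates; ``k`` is truncated with a
    warning if fewer positive eigenvalues exist.
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    pos = eigval > max(1e-12, 1e-10 * abs(eigval[0]) if eigval.size else 0.0)
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        k = n_pos
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])[None, :]
    index = dissimilarity.index if isinstance(dissimilarity, pd.DataFrame) else pd.RangeIndex(n)
    frame = pd.DataFrame(coords, index=index, columns=[f"PCo{i + 1}" for i in range(k)])
    return frame, eigval
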