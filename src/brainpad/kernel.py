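"""Feature vectorization and the dot-product similarity (Gram) matrix."""

from __future__ import annotations

import numpy as np

__all__ = ["vectorize_concatenate", "similarity_matrix", "check_psd"]


def vectorize_concatenate(gm_map, wm_map) -> np.ndarray:
    """Concatenate grey- then white-matter voxels into one feature vector.

    Accepts 1-D vectors (one subject) or 2-D ``subjects x voxels`` matrices;
    ordering is deterministic: all GM voxels first, then all WM voxels.
    """
    gm = np.asarray(gm_map, float)
    wm = np.asarray(wm_map, float)
    if gm.size == 0 or wm.size == 0:
        raise ValueError("tissue maps must be non-empty")
    if gm.ndim != wm.ndim:
        raise ValueError("gm and wm maps must have matching dimensionality")
    axis = gm.ndim - 1
    return np.concatenate([gm, wm], axis=axis)


def similarity_matrix(X, X2=None, scale_by_dim: bool = True) -> np.ndarray:
    """Pairwise dot-product similarity.

    With one argument returns the square ``n x n`` Gram matrix of the rows of
    ``X``; with two, the rectangular ``n1 x n2`` cross-similarity used for
    out-of-sample prediction. ``scale_by_dim`` divides by the feature count
    so hyperparameters stay comparable across voxel resolutions.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X2 is None:
        K = X @ X.T
        p = X.shape[1]
    else:
        X2 = np.atleast_2d(np.asarray(X2, float))
        if X.shape[1] != X2.shape[1]:
            raise ValueError(
                f"feature dimension mismatch: {X.shape[1]} vs {X2.shape[1]}"
            )
        K = X @ X2.T
        p = X.shape[1]
    if scale_by_dim and p > 0:
        K = K / p
    return K


def check_psd(K, rel_tol: float = 1e-8) -> bool:
    """True when ``K`` is symmetric and PSD up to ``rel_tol * trace``."""
    K = np.asarray(K, float)
    if K.shape[0] != K.shape[1] or not np.allclose(K, K.T, atol=1e-8 * (1 + np.abs(K).max())):
        return False
    w = np.linalg.eigvalsh(K)
    return bool(w.min() >= -rel_tol * max(np.trace(K), 1e-30))
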