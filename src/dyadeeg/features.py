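"""PCA dimensionality reduction of tick feature vectors.

The windowed tick vectors are high-dimensional (61 samples x n electrodes,
e.g. 1159 for 19 electrodes).  A PCA fitted on the pooled vectors reduces
them to the top ``keep_fraction`` of dimensions — the rounding is ceil, so
19 electrodes give k = ceil(1159/2) = 580 and 64 electrodes k = 1952.

Two fitting scopes are exposed: the default pools vectors from all games
(train and test alike), which mirrors the original analysis pipeline and
leaks no label information but does share unsupervised structure across
folds; ``strict`` callers simply pass training-game vectors only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import h5py
import numpy as np
from sklearn.decomposition import PCA

__all__ = ["PCAModel", "n_components_kept", "fit_pca", "project"]


def n_components_kept(d: int, keep_fraction: float = 0.5) -> int:
    """Number of leading components kept from ``d`` input dimensions."""
    if d < 1:
        raise ValueError("d must be >= 1")
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must be in (0, 1]")
    return math.ceil(keep_fraction * d)


@dataclass
class PCAModel:
    """Fitted projection: training mean, orthonormal components (k x d),
    per-component variances, and the fraction of variance retained."""

    mean: np.ndarray
    components: np.ndarray
    variances: np.ndarray
    k: int
    retained_variance: float

    @property
    def d(self) -> int:
        return self.components.shape[1]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("mean", data=self.mean)
            f.create_dataset("components", data=self.components)
            f.create_dataset("variances", data=self.variances)
            f.attrs["k"] = self.k
            f.attrs["retained_variance"] = self.retained_variance

    @staticmethod
    def load(path) -> "PCAModel":
        with h5py.File(path, "r") as f:
            return PCAModel(
                mean=f["mean"][()],
                components=f["components"][()],
                variances=f["variances"][()],
                k=int(f.attrs["k"]),
                retained_variance=float(f.attrs["retained_variance"]),
            )


def fit_pca(vectors: np.ndarray, keep_fraction: float = 0.5) -> PCAModel:
    """Fit PCA on (n, d) vectors, keeping ``ceil(keep_fraction * d)``
    components (SVD of the centered matrix; no covariance is formed).

    Requires at least k + 1 vectors so every kept component is estimated;
    all-identical input is degenerate and rejected.
    """
    vectors = np.asarray(vectors)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    n, d = vectors.shape
    k = n_components_kept(d, keep_fraction)
    if np.allclose(vectors, vectors[0]):
        raise ValueError("degenerate input: all vectors identical")
    if n <= k:
        raise ValueError(f"need more than {k} vectors to estimate {k} components")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(vectors.astype(np.float64, copy=False))
    return PCAModel(
        mean=pca.mean_,
        components=pca.components_,
        variances=pca.explained_variance_,
        k=k,
        retained_variance=float(np.sum(pca.explained_variance_ratio_)),
    )


def project(model: PCAModel, vectors: np.ndarray, dtype=np.float32) -> np.ndarray:
    """Center ``vectors`` on the training mean and project onto the kept
    components.  Returns (n, k)."""
    vectors = np.asarray(vectors)
    squeeze = vectors.ndim == 1
    if squeeze:
        vectors = vectors[None, :]
    if vectors.shape[1] != model.d:
        raise ValueError(f"vectors have {vectors.shape[1]} dims, model expects {model.d}")
    comps = model.components.astype(dtype)
    out = (vectors.astype(dtype) - model.mean.astype(dtype)) @ comps.T
    return out[0] if squeeze else out
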