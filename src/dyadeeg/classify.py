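"""Class-conditional Gaussian tick models, two-player fusion, thresholding.

Each tick's (PCA-reduced) feature vector is scored under four
class-conditional multivariate normal densities — Kill, Shooter Death,
Bait Death, Null — sharing a single pooled covariance (linear-discriminant
structure).  Densities are estimated from training games under one of two
regimes: *within-team* (other games of the same pair) or *between-team*
(games of other pairs, same role).  The two players' per-tick conditional
densities are fused multiplicatively and renormalized over classes:

    C_j(i) = P(Shooter_j | i) P(Bait_j | i) / sum_i' P(Shooter_j | i') P(Bait_j | i')

All arithmetic is carried out in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg
from scipy.special import logsumexp

from .montage import ROLES
from .preprocess import NULL, TICK_CLASSES

__all__ = [
    "GaussianEventModel",
    "TickLikelihoods",
    "GameFeatures",
    "fit_gaussian_model",
    "tick_likelihoods",
    "fuse",
    "classify_by_ratio",
    "posterior_equality_threshold",
    "subsample_nulls",
    "run_regime",
]


@dataclass
class GaussianEventModel:
    """Per-class means with one pooled, diagonally-shrunk covariance."""

    classes: tuple[str, ...]
    means: np.ndarray            # (C, k)
    covariance: np.ndarray       # (k, k), after shrinkage
    shrinkage: float
    priors: np.ndarray           # training-fold class frequencies, (C,)
    regime: str = ""
    _chol: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        C, k = self.means.shape
        if C != len(self.classes):
            raise ValueError("one mean required per class")
        if self.covariance.shape != (k, k):
            raise ValueError("covariance shape mismatch")

    @property
    def k(self) -> int:
        return self.means.shape[1]

    def cholesky(self) -> np.ndarray:
        if self._chol is None:
            self._chol = linalg.cholesky(self.covariance, lower=True)
        return self._chol

    def class_index(self, cls: str) -> int:
        return self.classes.index(cls)


@dataclass
class TickLikelihoods:
    """Per-tick, per-class log conditional densities from one source.

    For the ``Combined`` source the rows are fused log posteriors and
    exponentiate to a distribution over classes.
    """

    ticks: np.ndarray        # (n,)
    classes: tuple[str, ...]
    loglik: np.ndarray       # (n, C)
    source: str              # "Shooter" | "Bait" | "Combined"

    def __post_init__(self) -> None:
        if self.loglik.shape != (len(self.ticks), len(self.classes)):
            raise ValueError("loglik shape mismatch")
        if not np.all(np.isfinite(self.loglik)):
            raise ValueError("non-finite log-likelihoods")

    def column(self, cls: str) -> np.ndarray:
        return self.loglik[:, self.classes.index(cls)]

    def llr(self, cls_a: str, cls_b: str) -> np.ndarray:
        """Per-tick log-likelihood ratio log P(E|a) - log P(E|b)."""
        return self.column(cls_a) - self.column(cls_b)


def fit_gaussian_model(
    vectors: np.ndarray,
    labels: np.ndarray,
    classes: Sequence[str] = TICK_CLASSES,
    shrinkage: float = 0.05,
    regime: str = "",
) -> GaussianEventModel:
    """Estimate class means and the pooled within-class covariance.

    The covariance is the within-class scatter summed over all classes,
    divided by N - #classes, then shrunk toward its own diagonal:
    ``(1 - lambda) S + lambda diag(S)``.  Raises if a class is missing
    from the training labels or the shrunk covariance is not positive
    definite (remedy: raise ``shrinkage``).
    """
    vectors = np.asarray(vectors)
    labels = np.asarray(labels)
    if not (0.0 <= shrinkage <= 1.0):
        raise ValueError("shrinkage must be in [0, 1]")
    N, k = vectors.shape
    classes = tuple(classes)
    means = np.empty((len(classes), k))
    scatter = np.zeros((k, k))
    counts = np.empty(len(classes))
    for i, cls in enumerate(classes):
        sel = labels == cls
        counts[i] = sel.sum()
        if counts[i] == 0:
            raise ValueError(f"class {cls!r} absent from training data")
        X = vectors[sel].astype(np.float64, copy=False)
        means[i] = X.mean(axis=0)
        Xc = X - means[i]
        scatter += Xc.T @ Xc
    cov = scatter / (N - len(classes))
    cov = (1.0 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))
    try:
        chol = linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError as e:
        raise ValueError(
            "pooled covariance not positive definite; raise shrinkage"
        ) from e
    return GaussianEventModel(
        classes=classes,
        means=means,
        covariance=cov,
        shrinkage=shrinkage,
        priors=counts / N,
        regime=regime,
        _chol=chol,
    )


def tick_likelihoods(
    model: GaussianEventModel,
    vectors: np.ndarray,
    ticks: np.ndarray | None = None,
    source: str = "",
) -> TickLikelihoods:
    """Exact multivariate-normal log-densities of each vector under every
    class.  With the shared covariance the quadratic term is computed once
    per vector; class terms are affine in the feature vector.  float32
    input is evaluated in float32 (the large-matrix fast path), anything
    else in float64."""
    X = np.asarray(vectors)
    dtype = np.float32 if X.dtype == np.float32 else np.float64
    X = X.astype(dtype, copy=False)
    if X.ndim != 2 or X.shape[1] != model.k:
        raise ValueError(f"expected (n, {model.k}) feature matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    n, k = X.shape
    L = model.cholesky()
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    const = -0.5 * (k * np.log(2.0 * np.pi) + logdet)
    # x' S^-1 x once per vector; cross terms via precomputed S^-1 mu_c
    Y = linalg.solve_triangular(L.astype(dtype), X.T, lower=True)
    quad = np.einsum("ij,ij->j", Y, Y)
    W = linalg.cho_solve((L, True), model.means.T).astype(dtype)  # (k, C)
    cross = X @ W                                                 # (n, C)
    mquad = np.einsum("ck,kc->c", model.means.astype(dtype), W)   # (C,)
    loglik = (
        const - 0.5 * (quad[:, None] - 2.0 * cross + mquad[None, :])
    ).astype(np.float64)
    if ticks is None:
        ticks = np.arange(n)
    return TickLikelihoods(
        ticks=np.asarray(ticks), classes=model.classes, loglik=loglik, source=source
    )


def fuse(shooter: TickLikelihoods, bait: TickLikelihoods) -> TickLikelihoods:
    """Combine the two players' conditional densities per tick.

    Log-space product followed by log-sum-exp renormalization over
    classes; the result exponentiates to the fused class distribution.
    """
    if not np.array_equal(shooter.ticks, bait.ticks):
        raise ValueError("tick misalignment between sources")
    if shooter.classes != bait.classes:
        raise ValueError("class order differs between sources")
    joint = shooter.loglik + bait.loglik
    joint = joint - logsumexp(joint, axis=1, keepdims=True)
    return TickLikelihoods(
        ticks=shooter.ticks, classes=shooter.classes, loglik=joint, source="Combined"
    )


def classify_by_ratio(
    loglik_a: np.ndarray, loglik_b: np.ndarray, threshold: float = 1.0
) -> np.ndarray:
    """Label a tick class A iff P(E|A)/P(E|B) > threshold (strict; ties go
    to B, the Null-favoring convention).  Returns a boolean array."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return (np.asarray(loglik_a) - np.asarray(loglik_b)) > np.log(threshold)


def posterior_equality_threshold(
    priors: Mapping[str, float] | np.ndarray,
    cls_a: str,
    cls_b: str = NULL,
    classes: Sequence[str] = TICK_CLASSES,
) -> float:
    """Likelihood-ratio threshold at which the posteriors of ``cls_a`` and
    ``cls_b`` are equal, given training-fold class priors:
    theta = prior(B) / prior(A)."""
    if isinstance(priors, Mapping):
        pa, pb = priors[cls_a], priors[cls_b]
    else:
        classes = tuple(classes)
        pa = priors[classes.index(cls_a)]
        pb = priors[classes.index(cls_b)]
    if pa <= 0 or pb <= 0:
        raise ValueError("priors must be positive")
    return float(pb / pa)


# ---------------------------------------------------------------------------
# Training regimes over a per-game feature dataset
# ---------------------------------------------------------------------------


@dataclass
class GameFeatures:
    """PCA-space features for one game: per-role (n, k) matrices over the
    same interior ticks, with per-tick class labels."""

    team_id: int
    game_id: int
    ticks: np.ndarray
    labels: np.ndarray                 # (n,) strings
    features: dict[str, np.ndarray]    # role -> (n, k)


def subsample_nulls(
    labels: np.ndarray, cap: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices keeping every event tick and at most ``cap`` Null ticks
    (cap <= 0 keeps all), in original order."""
    labels = np.asarray(labels)
    null_idx = np.flatnonzero(labels == NULL)
    event_idx = np.flatnonzero(labels != NULL)
    if cap > 0 and null_idx.size > cap:
        null_idx = rng.choice(null_idx, size=cap, replace=False)
    return np.sort(np.concatenate([event_idx, null_idx]))


def run_regime(
    dataset: Sequence[GameFeatures],
    regime: str,
    target: GameFeatures,
    shrinkage: float = 0.05,
    null_cap: int = 50_000,
    seed: int = 0,
) -> dict[str, TickLikelihoods]:
    """Fit per-role Gaussian models under a training regime and score the
    target game's ticks.

    ``within_team`` trains on the target team's other games (leave one
    game out); ``between_team`` trains on all games of other teams.  Each
    role's model sees only that role's recordings.  The target game never
    contributes to its own training set.
    """
    if regime == "within_team":
        train = [
            g for g in dataset
            if g.team_id == target.team_id and g.game_id != target.game_id
        ]
        if not train:
            raise ValueError("within_team regime needs >= 2 games for the team")
    elif regime == "between_team":
        train = [g for g in dataset if g.team_id != target.team_id]
        if not train:
            raise ValueError("between_team regime needs >= 2 teams")
    else:
        raise ValueError(f"unknown regime {regime!r}")

    rng = np.random.default_rng(seed)
    out: dict[str, TickLikelihoods] = {}
    for role in ROLES:
        X = np.concatenate([g.features[role] for g in train])
        y = np.concatenate([g.labels for g in train])
        keep = subsample_nulls(y, null_cap, rng)
        model = fit_gaussian_model(
            X[keep], y[keep], shrinkage=shrinkage, regime=regime
        )
        out[role] = tick_likelihoods(
            model, target.features[role], ticks=target.ticks, source=role
        )
    return out
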