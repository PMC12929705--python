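"""The integrated phenotype: PCA trait space, axis significance, functional clusters.

PCA on the standardised per-event traits defines a reduced trait space (the
"integrated phenotype").  Axis significance is assessed by a permutation
null (each trait column permuted independently); treatment-replicate mean
trait profiles are clustered by k-means with the number of clusters chosen
by the elbow (maximum second difference of the within-cluster
sum-of-squares curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .traits import TraitMatrix

__all__ = [
    "PhenotypeSpace",
    "FunctionalClusterSolution",
    "fit_pca",
    "test_axes_significance",
    "treatment_profile_heatmap",
    "functional_clusters",
]


@dataclass
class PhenotypeSpace:
    """PCA loadings/scores/variance fractions of the trait space."""

    trait_names: list[str]
    loadings: np.ndarray        # traits x axes, orthonormal columns
    scores: np.ndarray          # events x axes
    variance_fraction: np.ndarray
    mean: np.ndarray            # per-trait centring offsets
    significant_axes: list[int] = field(default_factory=list)
    fitted_on: list[str] = field(default_factory=list)

    @property
    def n_axes(self) -> int:
        return self.loadings.shape[1]

    def project(self, values: np.ndarray) -> np.ndarray:
        """Scores of new standardised trait rows in the fitted space."""
        return (np.asarray(values, float) - self.mean) @ self.loadings

    def to_dict(self) -> dict:
        return {
            "trait_names": list(self.trait_names),
            "loadings": self.loadings.tolist(),
            "variance_fraction": self.variance_fraction.tolist(),
            "mean": self.mean.tolist(),
            "significant_axes": list(self.significant_axes),
            "fitted_on": list(self.fitted_on),
        }


@dataclass
class FunctionalClusterSolution:
    k: int
    assignments: pd.Series          # profile label -> cluster id
    within_ss_by_k: dict[int, float]
    note: str = ""


def _eigvals(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    return s ** 2 / (X.shape[0] - 1)


def fit_pca(traits: TraitMatrix | np.ndarray, trait_names=None,
            fitted_on=None) -> PhenotypeSpace:
    """PCA of standardised traits; axes ordered by decreasing variance.

    Sign convention: the largest-magnitude loading of each axis is positive.
    Rank-deficient inputs are fine; axes beyond the rank carry (numerically)
    zero variance fraction.
    """
    if isinstance(traits, TraitMatrix):
        if not traits.standardized:
            raise ValueError("fit_pca expects standardised traits")
        X = traits.values
        trait_names = list(traits.trait_names)
        fitted_on = fitted_on or [traits.sample_id]
    else:
        X = np.asarray(traits, float)
        trait_names = list(trait_names or [f"t{i}" for i in range(X.shape[1])])
        fitted_on = list(fitted_on or [])
    n, d = X.shape
    if n < d:
        raise ValueError("PCA needs at least as many events as traits")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt.T
    # fix signs: largest |loading| per axis positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            U[:, j] *= -1.0
    scores = U * s
    var = s ** 2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    return PhenotypeSpace(
        trait_names=trait_names,
        loadings=loadings,
        scores=scores,
        variance_fraction=frac,
        mean=mean,
        fitted_on=fitted_on,
    )


def test_axes_significance(
    traits: TraitMatrix | np.ndarray,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[int]:
    """Axes whose eigenvalue exceeds the (1-alpha) quantile of its permutation null.

    The null is built by permuting each trait column independently, which
    destroys trait-trait correlation while keeping marginals.
    """
    X = traits.values if isinstance(traits, TraitMatrix) else np.asarray(traits, float)
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if alpha < 1.0 / (n_perm + 1):
        raise ValueError(
            f"alpha={alpha} unresolvable with n_perm={n_perm}; "
            "need alpha >= 1/(n_perm + 1)"
        )
    rng = np.random.default_rng(seed)
    obs = _eigvals(X)
    null = np.empty((n_perm, len(obs)))
    Xp = X.copy()
    for b in range(n_perm):
        for j in range(X.shape[1]):
            Xp[:, j] = X[rng.permutation(X.shape[0]), j]
        null[b] = _eigvals(Xp)
    thresh = np.quantile(null, 1.0 - alpha, axis=0)
    return [int(j) for j in range(len(obs)) if obs[j] > thresh[j]]


def treatment_profile_heatmap(groups: list[TraitMatrix]) -> pd.DataFrame:
    """Per-replicate mean of each standardised trait.

    Rows are treatment-replicate profiles, columns the eight traits: the
    numeric content of the mean-response heatmap.
    """
    rows, index = [], []
    for tm in groups:
        if tm.treatment is None:
            raise ValueError("every TraitMatrix needs a treatment label")
        rep = tm.replicate if tm.replicate is not None else 0
        rows.append(tm.values.mean(axis=0))
        index.append((tm.treatment, rep))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["treatment", "replicate"]),
        columns=groups[0].trait_names,
    )


def functional_clusters(
    profiles: pd.DataFrame | np.ndarray, k_max: int = 8, seed: int = 0
) -> FunctionalClusterSolution:
    """k-means over trait profiles; k chosen by the elbow rule.

    The elbow is the k maximising the second difference of the
    within-cluster sum of squares curve over k = 2..k_max-1.  Identical
    profiles collapse to k = 1.
    """
    if isinstance(profiles, pd.DataFrame):
        X = profiles.to_numpy(float)
        index = profiles.index
    else:
        X = np.asarray(profiles, float)
        index = pd.RangeIndex(X.shape[0])
    n = X.shape[0]
    if k_max > n:
        raise ValueError("k_max cannot exceed the number of profiles")
    if np.allclose(X, X[0]):
        return FunctionalClusterSolution(
            k=1,
            assignments=pd.Series(np.zeros(n, int), index=index),
            within_ss_by_k={1: 0.0},
            note="identical profiles; k = 1",
        )
    wss: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        wss[k] = float(km.inertia_)
        fits[k] = km.labels_
    if k_max >= 3:
        candidates = range(2, k_max)
        k_best = max(
            candidates, key=lambda k: wss[k - 1] - 2.0 * wss[k] + wss[k + 1]
        )
    else:
        k_best = k_max
    return FunctionalClusterSolution(
        k=k_best,
        assignments=pd.Series(fits[k_best], index=index),
        within_ss_by_k=wss,
    )
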