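"""Gaussian-KDE n-dimensional hypervolumes and kernel functional diversity indices.

A hypervolume is the highest-density region of a product-Gaussian kernel
density estimate of the PCA scores that carries 95% (by default) of the
density mass evaluated at the data points.  Per-dimension bandwidths follow
Silverman's rule.  The region is represented by support points that are
uniformly distributed inside it (rejection sampling from the KDE mixture
followed by an inverse-density thinning), and its volume is given by the
inverse-density importance estimator

    volume ~= (accepted/proposed) * (1/m) * sum_accepted 1 / f_hat(x),

where accepted/proposed estimates the KDE probability mass of the region.

The functional diversity indices are richness (the volume), evenness (the
overlap between the region-restricted KDE and the uniform density on the
region, in [0, 1]) and dispersion (mean distance of support points to their
centroid).  Overlap between two hypervolumes is summarised by the Jaccard
index on volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Hypervolume",
    "FDIndices",
    "estimate_bandwidth",
    "kde_density",
    "build_hypervolume",
    "richness",
    "evenness",
    "dispersion",
    "jaccard",
    "indices",
    "fd_per_replicate",
]


def estimate_bandwidth(scores: np.ndarray) -> np.ndarray:
    """Silverman's rule per dimension: h_j = sigma_j * (4 / ((d+2) n))**(1/(d+4))."""
    X = np.atleast_2d(np.asarray(scores, float))
    n, d = X.shape
    if n < 10:
        raise ValueError("bandwidth estimation needs n >= 10 points")
    sigma = X.std(axis=0, ddof=1)
    if np.any(sigma <= 0):
        raise ValueError(f"zero-variance dimension {int(np.argmax(sigma <= 0))}")
    return sigma * (4.0 / ((d + 2.0) * n)) ** (1.0 / (d + 4.0))


def kde_density(
    points: np.ndarray, data: np.ndarray, bandwidths: np.ndarray,
    chunk: int = 1024,
) -> np.ndarray:
    """Product-Gaussian KDE of ``data`` evaluated at ``points`` (chunked)."""
    P = np.atleast_2d(np.asarray(points, float))
    D = np.atleast_2d(np.asarray(data, float))
    h = np.asarray(bandwidths, float)
    n, d = D.shape
    norm = n * (2.0 * np.pi) ** (d / 2.0) * np.prod(h)
    out = np.empty(P.shape[0])
    for start in range(0, P.shape[0], chunk):
        block = P[start : start + chunk]
        z = np.zeros((block.shape[0], n))
        for j in range(d):
            z += ((block[:, j, None] - D[None, :, j]) / h[j]) ** 2
        out[start : start + chunk] = np.exp(-0.5 * z).sum(axis=1) / norm
    return out


@dataclass
class Hypervolume:
    """KDE-delineated trait-space region for one sample."""

    data_points: np.ndarray       # n x d scores the KDE is built on
    bandwidths: np.ndarray        # per-dimension h
    threshold_density: float
    support_points: np.ndarray    # m x d uniform-weight points inside the region
    support_density: np.ndarray   # KDE density at the support points
    volume: float                 # trait-space units**d
    quantile: float
    mass: float                   # estimated KDE probability mass of the region
    seed: int

    @property
    def dims(self) -> int:
        return self.data_points.shape[1]

    def density(self, points: np.ndarray) -> np.ndarray:
        return kde_density(points, self.data_points, self.bandwidths)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Whether points fall inside the thresholded region."""
        return self.density(points) >= self.threshold_density

    def centroid(self) -> np.ndarray:
        return self.support_points.mean(axis=0)


@dataclass
class FDIndices:
    richness: float
    evenness: float
    dispersion: float


def _threshold_from_data_mass(f_data: np.ndarray, q: float) -> float:
    """Density value delineating the region that carries fraction q of the
    KDE probability mass.

    The data points are (approximately) a sample from the KDE itself, each
    carrying mass 1/n, so the threshold is the density of the lowest-density
    point among the ceil(q*n) highest-density points: the region
    {f >= threshold} then encloses ~q of the probability mass.
    """
    n = f_data.size
    k = min(int(np.ceil(q * n)), n) - 1
    return float(np.sort(f_data)[::-1][k])


def build_hypervolume(
    scores: np.ndarray,
    q: float = 0.95,
    n_support: int | None = None,
    seed: int = 0,
) -> Hypervolume:
    """Construct the q-mass highest-density region of the Gaussian KDE.

    Proposals are drawn from the KDE mixture (random data point plus
    per-dimension Gaussian noise of bandwidth h) and rejected below the
    threshold density; the surviving KDE-distributed points drive the
    inverse-density volume estimator and are then thinned to ``n_support``
    (default 500 * d) exactly uniform support points inside the region.
    """
    X = np.atleast_2d(np.asarray(scores, float))
    n, d = X.shape
    if not 0.0 < q < 1.0:
        raise ValueError("quantile q must lie in (0, 1)")
    if n_support is None:
        n_support = 500 * d
    h = estimate_bandwidth(X)
    f_data = kde_density(X, X, h)
    threshold = _threshold_from_data_mass(f_data, q)

    # Stage 1: rejection sampling from the KDE mixture, keeping proposals
    # above the threshold; these points follow the KDE restricted to the
    # region and feed the inverse-density volume estimator.
    # Stage 2: thin stage-1 points with probability threshold / f_hat(x),
    # which makes the retained support cloud exactly uniform inside the
    # region ("uniformly weighted" support points).
    rng = np.random.default_rng(seed)
    restricted_f: list[np.ndarray] = []
    uniform_pts: list[np.ndarray] = []
    uniform_f: list[np.ndarray] = []
    n_unif = 0
    n_prop = 0
    max_prop = max(int(n_support / 1e-4), 100_000)
    batch = max(2 * n_support, 1000)
    while n_unif < n_support:
        idx = rng.integers(n, size=batch)
        prop = X[idx] + rng.standard_normal((batch, d)) * h
        f_prop = kde_density(prop, X, h)
        keep = f_prop >= threshold
        pts, f_kept = prop[keep], f_prop[keep]
        restricted_f.append(f_kept)
        thin = rng.uniform(size=f_kept.size) < threshold / f_kept
        uniform_pts.append(pts[thin])
        uniform_f.append(f_kept[thin])
        n_unif += int(thin.sum())
        n_prop += batch
        if n_prop >= max_prop and n_unif < n_support:
            raise ValueError(
                "hypervolume rejection sampling acceptance rate < 1e-4; "
                "increase q or the bandwidth"
            )
    support = np.vstack(uniform_pts)[:n_support]
    f_support = np.concatenate(uniform_f)[:n_support]
    f_restricted = np.concatenate(restricted_f)
    # accepted/proposed estimates the KDE mass of the region; together with
    # the inverse-density mean this gives an unbiased volume:
    #   E[1/f | x ~ f|R] = vol(R)/P(R),  P(R) ~= accepted/proposed
    mass = f_restricted.size / n_prop
    volume = mass * float(np.mean(1.0 / f_restricted))
    return Hypervolume(
        data_points=X,
        bandwidths=h,
        threshold_density=threshold,
        support_points=support,
        support_density=f_support,
        volume=volume,
        quantile=q,
        mass=mass,
        seed=seed,
    )


def richness(hv: Hypervolume) -> float:
    """Functional richness: the volume of the occupied trait-space region."""
    return float(hv.volume)


def evenness(hv: Hypervolume) -> float:
    """Overlap of the region-restricted KDE with the uniform density on the region.

    Monte-Carlo over the uniform support points x ~ U(region):
        evenness = integral of min(f_R, u) = volume * E_U[min(f_R, u)]
                 = E_U[min(f_hat(x) * volume / mass, 1)],
    with u = 1/volume the uniform density and f_R = f_hat/mass the
    restricted, renormalised KDE.  1 means perfectly uniform occupancy;
    values near 0 mean tight clumps and gaps.
    """
    ratio = hv.support_density * hv.volume / hv.mass
    return float(np.mean(np.minimum(ratio, 1.0)))


def dispersion(hv: Hypervolume) -> float:
    """Mean Euclidean distance of the support points to their centroid."""
    c = hv.centroid()
    return float(np.mean(np.linalg.norm(hv.support_points - c, axis=1)))


def jaccard(hv_a: Hypervolume, hv_b: Hypervolume) -> float:
    """Jaccard similarity of two hypervolumes: intersection / union of volumes.

    The intersection volume is estimated symmetrically from the fraction of
    each hypervolume's support points falling inside the other's region.
    """
    if hv_a.dims != hv_b.dims:
        raise ValueError("hypervolume dimensionality mismatch")
    frac_a_in_b = float(np.mean(hv_b.contains(hv_a.support_points)))
    frac_b_in_a = float(np.mean(hv_a.contains(hv_b.support_points)))
    inter = 0.5 * (hv_a.volume * frac_a_in_b + hv_b.volume * frac_b_in_a)
    union = hv_a.volume + hv_b.volume - inter
    if union <= 0:
        return 0.0
    return float(np.clip(inter / union, 0.0, 1.0))


def indices(hv: Hypervolume) -> FDIndices:
    return FDIndices(
        richness=richness(hv), evenness=evenness(hv), dispersion=dispersion(hv)
    )


def fd_per_replicate(
    groups: dict[tuple[str, int], np.ndarray],
    q: float = 0.95,
    n_support: int | None = None,
    seed: int = 0,
    min_events: int = 10,
) -> tuple[pd.DataFrame, dict[tuple[str, int], Hypervolume]]:
    """One hypervolume + FD indices per treatment-replicate, in a shared space.

    ``groups`` maps (treatment, replicate) to that replicate's PCA scores.
    Replicates with fewer than ``min_events`` events are skipped with a
    warning.  Returns the tidy index table and the hypervolumes.
    """
    rows = []
    hvs: dict[tuple[str, int], Hypervolume] = {}
    for i, key in enumerate(sorted(groups)):
        treatment, replicate = key
        scores = np.atleast_2d(groups[key])
        if scores.shape[0] < min_events:
            warnings.warn(
                f"replicate {key} has {scores.shape[0]} events (< {min_events}); skipped",
                stacklevel=2,
            )
            continue
        child_seed = int(
            np.random.SeedSequence([seed, i]).generate_state(1)[0] & 0x7FFFFFFF
        )
        hv = build_hypervolume(scores, q=q, n_support=n_support, seed=child_seed)
        hvs[key] = hv
        rows.append(
            {
                "treatment": treatment,
                "replicate": replicate,
                "n_events": scores.shape[0],
                "richness": richness(hv),
                "evenness": evenness(hv),
                "dispersion": dispersion(hv),
            }
        )
    return pd.DataFrame(rows), hvs
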