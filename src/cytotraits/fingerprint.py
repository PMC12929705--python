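"""Projection of natural-community samples onto laboratory treatment fingerprints.

Culture and field events are standardised together (log10 + z on the pooled
set by default) and embedded in one joint PCA space.  Each field sample's
centroid in that space is assigned to the nearest treatment fingerprint
(the treatment's culture centroid), hypervolume membership is reported
alongside, and centroid coordinates are rank-correlated with the samples'
total-nitrogen : light covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .traits import TraitMatrix, StandardizationModel, standardize
from .phenospace import PhenotypeSpace, fit_pca
from .hypervolume import Hypervolume

__all__ = [
    "FieldMetadata",
    "FingerprintReport",
    "joint_space",
    "sample_centroids",
    "assign_fingerprint",
    "gradient_association",
]


@dataclass
class FieldMetadata:
    """Environmental covariates of one field sample (units as supplied)."""

    sample_id: str
    date: str | None = None
    tn: float | None = None     # total nitrogen
    tp: float | None = None     # total phosphorus
    light: float | None = None  # umol photons m-2 s-1

    @property
    def tn_light_ratio(self) -> float | None:
        if self.tn is None or self.light is None or self.light <= 0:
            return None
        return self.tn / self.light

    @property
    def tn_tp_ratio(self) -> float | None:
        if self.tn is None or self.tp is None or self.tp <= 0:
            return None
        return self.tn / self.tp


@dataclass
class FingerprintReport:
    sample_id: str
    centroid: np.ndarray
    nearest_treatment: str
    distances: dict[str, float]
    inside_hypervolume: dict[str, bool]
    gradient_value: float | None = None
    tied: bool = False

    def to_row(self) -> dict:
        row = {
            "sample_id": self.sample_id,
            "nearest_treatment": self.nearest_treatment,
            "gradient_value": self.gradient_value,
            "tied": self.tied,
        }
        for i, c in enumerate(self.centroid):
            row[f"axis{i + 1}"] = float(c)
        for t, dist in self.distances.items():
            row[f"dist_{t}"] = dist
        for t, flag in self.inside_hypervolume.items():
            row[f"inside_{t}"] = flag
        return row


def joint_space(
    culture_traits: list[TraitMatrix],
    field_traits: list[TraitMatrix],
    culture_anchored: bool = False,
) -> tuple[PhenotypeSpace, StandardizationModel, pd.DataFrame]:
    """One PCA fitted on the concatenated culture + field trait matrix.

    Inputs are unstandardised trait matrices.  By default the log10/z model
    is fitted on the pooled data; with ``culture_anchored`` the model is
    fitted on culture events only and applied unchanged to the field.
    Returns the space, the standardisation model, and a provenance frame
    (origin, sample_id, treatment) aligned with the score rows.
    """
    if not culture_traits:
        raise ValueError("culture trait matrices are required")
    ref_names = list(culture_traits[0].trait_names)
    for tm in culture_traits + field_traits:
        if list(tm.trait_names) != ref_names:
            raise ValueError(
                "trait-set mismatch: "
                f"{sorted(set(tm.trait_names) ^ set(ref_names))}"
            )

    def _stack(matrices: list[TraitMatrix]) -> np.ndarray:
        return (
            np.vstack([tm.values for tm in matrices])
            if matrices else np.empty((0, len(ref_names)))
        )

    culture_vals = _stack(culture_traits)
    field_vals = _stack(field_traits)

    fit_vals = culture_vals if culture_anchored else np.vstack(
        [culture_vals, field_vals]
    ) if field_vals.size else culture_vals
    fit_tm = TraitMatrix("pooled", ref_names, fit_vals)
    _, model = standardize(fit_tm)

    def _z(vals: np.ndarray) -> np.ndarray:
        return (np.log10(vals) - model.mean) / model.sd

    z_all = np.vstack([_z(culture_vals)] + ([_z(field_vals)] if field_vals.size else []))
    prov_rows = []
    for origin, matrices in (("culture", culture_traits), ("field", field_traits)):
        for tm in matrices:
            prov_rows.extend(
                {"origin": origin, "sample_id": tm.sample_id,
                 "treatment": tm.treatment}
                for _ in range(tm.n_events)
            )
    provenance = pd.DataFrame(prov_rows)

    space = fit_pca(
        z_all, trait_names=ref_names,
        fitted_on=sorted({r["sample_id"] for r in prov_rows}),
    )
    return space, model, provenance


def sample_centroids(
    scores: np.ndarray,
    sample_ids: np.ndarray | pd.Series,
    axes: list[int] | None = None,
    min_events: int = 10,
) -> pd.DataFrame:
    """Mean score vector per sample over the chosen axes."""
    scores = np.atleast_2d(scores)
    sample_ids = np.asarray(sample_ids)
    axes = list(axes) if axes is not None else list(range(scores.shape[1]))
    rows = {}
    for sid in pd.unique(sample_ids):
        sub = scores[sample_ids == sid][:, axes]
        if sub.shape[0] < min_events:
            warnings.warn(
                f"sample {sid!r} has {sub.shape[0]} events (< {min_events}); skipped",
                stacklevel=2,
            )
            continue
        rows[sid] = sub.mean(axis=0)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"axis{a + 1}" for a in axes]
    )


def assign_fingerprint(
    field_centroid: np.ndarray,
    treatment_centroids: pd.DataFrame,
    treatment_hypervolumes: dict[str, Hypervolume] | None = None,
    metadata: FieldMetadata | None = None,
    sample_id: str = "",
) -> FingerprintReport:
    """Nearest-treatment assignment of one field centroid.

    Euclidean distances to the culture treatment centroids; exact ties are
    broken by treatment label order and flagged.  Hypervolume membership
    (density above each treatment's threshold) is reported alongside.
    """
    c = np.asarray(field_centroid, float)
    distances = {
        str(t): float(np.linalg.norm(c - treatment_centroids.loc[t].to_numpy()))
        for t in treatment_centroids.index
    }
    best = min(distances.values())
    winners = sorted(t for t, d in distances.items() if d == best)
    inside = {}
    if treatment_hypervolumes:
        for t, hv in treatment_hypervolumes.items():
            inside[str(t)] = bool(hv.contains(c[None, : hv.dims])[0])
    gradient = metadata.tn_light_ratio if metadata is not None else None
    return FingerprintReport(
        sample_id=sample_id or (metadata.sample_id if metadata else ""),
        centroid=c,
        nearest_treatment=winners[0],
        distances=distances,
        inside_hypervolume=inside,
        gradient_value=gradient,
        tied=len(winners) > 1,
    )


def gradient_association(reports: list[FingerprintReport]) -> pd.DataFrame:
    """Spearman rank correlation of centroid coordinates with TN:light, per axis."""
    usable = [r for r in reports if r.gradient_value is not None]
    if len(usable) < 5:
        raise ValueError("gradient association needs >= 5 samples with gradient values")
    grad = np.array([r.gradient_value for r in usable])
    if np.all(grad == grad[0]):
        raise ValueError("constant gradient; association undefined")
    coords = np.vstack([r.centroid for r in usable])
    rows = []
    for j in range(coords.shape[1]):
        rho, p = stats.spearmanr(grad, coords[:, j])
        rows.append({"axis": j + 1, "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows)
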