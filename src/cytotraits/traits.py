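"""Functional traits from gated optical channels.

Eight traits are derived per event: cell size (FSC), granularity (SSC), gas
vesicle fraction (cell-volume proxy divided by granularity), phycocyanin and
chlorophyll-a fluorescence, both pigments normalised to size, and the
phycocyanin:chlorophyll-a ratio.  The cell-volume proxy is FSC**beta with a
configurable exponent (default 1, i.e. a pure FSC/SSC ratio), since no
optical sizing model is assumed.

Traits are log10-transformed and z-standardised before multivariate
analysis; the standardisation model can be stored and re-applied so field
samples are projected with the culture-derived reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gating import GatedPopulation

__all__ = [
    "TRAIT_NAMES",
    "TraitMatrix",
    "StandardizationModel",
    "derive_traits",
    "collinearity_filter",
    "standardize",
    "unstandardize",
    "anova_per_trait",
]

TRAIT_NAMES = [
    "cell_size",
    "granularity",
    "gas_vesicle",
    "phycocyanin",
    "chlorophyll_a",
    "pc_per_size",
    "chla_per_size",
    "pc_chla",
]


@dataclass
class TraitMatrix:
    """Per-event functional trait values for one sample."""

    sample_id: str
    trait_names: list[str]
    values: np.ndarray  # events x traits
    treatment: str | None = None
    replicate: int | None = None
    standardized: bool = False
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.trait_names):
            raise ValueError("trait count does not match value columns")
        if not self.standardized and not np.all(
            np.isfinite(self.values) & (self.values > 0)
        ):
            raise ValueError("unstandardised traits must be finite and positive")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.trait_names)
        df.insert(0, "sample_id", self.sample_id)
        return df


@dataclass
class StandardizationModel:
    """Per-trait mean and sd on the log10 scale (population sd, ddof=0)."""

    trait_names: list[str]
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float)
        self.sd = np.asarray(self.sd, float)
        if np.any(self.sd <= 0):
            bad = self.trait_names[int(np.argmax(self.sd <= 0))]
            raise ValueError(f"standardisation sd must be > 0 (trait {bad!r})")

    def to_dict(self) -> dict:
        return {
            "trait_names": list(self.trait_names),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationModel":
        return cls(d["trait_names"], np.array(d["mean"]), np.array(d["sd"]))


def derive_traits(
    gated: GatedPopulation, volume_exponent: float = 1.0
) -> TraitMatrix:
    """Compute the eight functional traits from FSC, SSC, FL670 and FL692.

    Events with a zero in a denominator channel (FSC, SSC or FL692) are
    dropped; the drop count is reported on the returned matrix.
    """
    table = gated.parent
    for ch in ("FSC", "SSC", "FL670", "FL692"):
        if ch not in table.channels:
            raise ValueError(f"required channel {ch!r} missing")
    vals = gated.member_values()
    fsc = vals[:, table.channels.index("FSC")]
    ssc = vals[:, table.channels.index("SSC")]
    pc = vals[:, table.channels.index("FL670")]
    chla = vals[:, table.channels.index("FL692")]

    ok = (fsc > 0) & (ssc > 0) & (chla > 0) & (pc > 0)
    n_dropped = int(np.sum(~ok))
    fsc, ssc, pc, chla = fsc[ok], ssc[ok], pc[ok], chla[ok]

    traits = np.column_stack(
        [
            fsc,                                 # cell_size
            ssc,                                 # granularity
            fsc ** volume_exponent / ssc,        # gas_vesicle
            pc,                                  # phycocyanin
            chla,                                # chlorophyll_a
            pc / fsc,                            # pc_per_size
            chla / fsc,                          # chla_per_size
            pc / chla,                           # pc_chla
        ]
    )
    return TraitMatrix(
        sample_id=table.sample_id,
        trait_names=list(TRAIT_NAMES),
        values=traits,
        n_dropped=n_dropped,
    )


def collinearity_filter(
    candidates: pd.DataFrame | np.ndarray,
    r_threshold: float = 0.8,
    keep_list: list[str] | None = None,
    labels: list[str] | None = None,
) -> list[str]:
    """Greedy pruning of collinear optical traits on |Pearson r| of log10 values.

    While any unprotected pair exceeds the threshold, the member of the
    worst offending pair with the larger mean |r| to all remaining traits is
    dropped, unless it is on ``keep_list`` (the ecological-relevance
    override: strongly correlated traits with distinct meanings, such as the
    two pigment fluorescences, are kept).  Deterministic given input order.
    """
    if isinstance(candidates, pd.DataFrame):
        labels = list(candidates.columns)
        X = candidates.to_numpy(float)
    else:
        X = np.asarray(candidates, float)
        if labels is None:
            labels = [f"c{i}" for i in range(X.shape[1])]
    if X.shape[1] < 2:
        raise ValueError("collinearity filter needs >= 2 candidates")
    if not 0 < r_threshold < 1:
        raise ValueError("r_threshold must lie in (0, 1)")
    keep_list = list(keep_list or [])
    missing = [k for k in keep_list if k not in labels]
    if missing:
        raise ValueError(f"keep_list entries not among candidates: {missing}")

    logX = np.log10(np.clip(X, 1e-300, None))
    retained = list(labels)

    def corr(sub: list[str]) -> np.ndarray:
        idx = [labels.index(s) for s in sub]
        with np.errstate(invalid="ignore"):
            R = np.corrcoef(logX[:, idx], rowvar=False)
        R = np.nan_to_num(np.atleast_2d(R), nan=0.0)
        np.fill_diagonal(R, 0.0)
        return np.abs(R)

    while len(retained) > 1:
        R = corr(retained)
        protected = np.array([s in keep_list for s in retained])
        # pairs over threshold where at least one member is droppable
        over = np.argwhere(np.triu(R, 1) > r_threshold)
        over = [
            (i, j) for i, j in over if not (protected[i] and protected[j])
        ]
        if not over:
            break
        i, j = max(over, key=lambda p: R[p[0], p[1]])
        mean_r = R.mean(axis=1)
        if protected[i]:
            drop = j
        elif protected[j]:
            drop = i
        else:
            drop = i if mean_r[i] >= mean_r[j] else j
        retained.pop(drop)
    return retained


def standardize(
    traits: TraitMatrix, model: StandardizationModel | None = None
) -> tuple[TraitMatrix, StandardizationModel]:
    """log10-transform and z-standardise; fit the model if none is given."""
    if traits.standardized:
        raise ValueError("traits are already standardised")
    logv = np.log10(traits.values)
    if model is None:
        mean = logv.mean(axis=0)
        sd = logv.std(axis=0, ddof=0)
        if np.any(sd <= 0):
            bad = traits.trait_names[int(np.argmax(sd <= 0))]
            raise ValueError(f"trait {bad!r} is constant; cannot standardise")
        model = StandardizationModel(list(traits.trait_names), mean, sd)
    else:
        if list(model.trait_names) != list(traits.trait_names):
            raise ValueError("standardisation model trait set mismatch")
    z = (logv - model.mean) / model.sd
    out = TraitMatrix(
        sample_id=traits.sample_id,
        trait_names=list(traits.trait_names),
        values=z,
        treatment=traits.treatment,
        replicate=traits.replicate,
        standardized=True,
        n_dropped=traits.n_dropped,
    )
    return out, model


def unstandardize(traits: TraitMatrix, model: StandardizationModel) -> TraitMatrix:
    """Invert :func:`standardize` with a stored model."""
    if not traits.standardized:
        raise ValueError("traits are not standardised")
    logv = traits.values * model.sd + model.mean
    return TraitMatrix(
        sample_id=traits.sample_id,
        trait_names=list(traits.trait_names),
        values=10.0 ** logv,
        treatment=traits.treatment,
        replicate=traits.replicate,
        standardized=False,
        n_dropped=traits.n_dropped,
    )


def anova_per_trait(groups: list[TraitMatrix]) -> pd.DataFrame:
    """Classical one-way ANOVA of each trait across treatment groups.

    ``groups`` carries one TraitMatrix per sample with its ``treatment``
    label set; events are pooled by treatment.
    """
    by_treatment: dict[str, list[np.ndarray]] = {}
    for tm in groups:
        if tm.treatment is None:
            raise ValueError("every TraitMatrix needs a treatment label")
        by_treatment.setdefault(tm.treatment, []).append(tm.values)
    if len(by_treatment) < 2:
        raise ValueError("ANOVA needs >= 2 treatment groups")
    stacked = {t: np.vstack(v) for t, v in by_treatment.items()}
    if any(v.shape[0] < 2 for v in stacked.values()):
        raise ValueError("every group needs >= 2 events")
    names = groups[0].trait_names
    rows = []
    for k, trait in enumerate(names):
        samples = [v[:, k] for v in stacked.values()]
        F, p = stats.f_oneway(*samples)
        rows.append({"trait": trait, "F": float(F), "p": float(p)})
    return pd.DataFrame(rows)
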