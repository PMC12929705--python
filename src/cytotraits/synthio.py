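"""Synthetic flow-cytometry data with the statistical structure the pipeline assumes.

The generator emulates a resource-limitation culture experiment on a
bloom-forming cyanobacterium (5 treatments x 4 replicates) plus a lake field
series, bead size standards and nutrient-addition bioassays:

* optical channels are lognormal (right-skewed, as real peak-height data),
  with the two pigment channels correlated on the log scale and a handful of
  redundant "distractor" filters correlated with the informative ones so the
  collinearity pruning stage has realistic input;
* each treatment multiplies channel medians by an effect factor whose sign
  pattern mirrors the culture experiment (nitrogen limitation depresses
  pigments and granularity while cell size rises; light limitation raises
  pigments; phosphorus limitation raises phycocyanin but lowers
  chlorophyll-a; high pCO2 is close to the control);
* each treatment also scales the log-scale spread of its events, so the
  treatments occupy hypervolumes of designed relative size (nitrogen
  limitation narrowest, phosphorus limitation widest);
* a debris fraction of events is drawn from a broad low-intensity cloud;
* field samples interpolate geometrically between the low-light and
  low-nitrogen effect rows along a planted monotone covariate that the
  metadata reports as a TN:light ratio.

All outputs are pure functions of (config, seed, indices).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gating import EventTable
from .fingerprint import FieldMetadata

__all__ = [
    "SynthConfig",
    "INFORMATIVE_CHANNELS",
    "DEFAULT_CHANNELS",
    "generate_culture_events",
    "generate_field_series",
    "generate_beads",
    "generate_bioassay",
]

INFORMATIVE_CHANNELS = ["FSC", "SSC", "FL670", "FL692"]

#: 14 distractor filters; several are deliberately collinear with the
#: informative channels (same pigment seen through a neighbouring filter).
DISTRACTOR_CHANNELS = [
    "FL455_355", "FL530_488", "FL580_488", "FL610_532", "FL660_532",
    "FL710_488", "FL750_640", "FSC_W", "SSC_W", "FL460_355", "FL520_457",
    "FL545_532", "FL620_640", "FL695_532",
]

DEFAULT_CHANNELS = INFORMATIVE_CHANNELS + DISTRACTOR_CHANNELS

#: log-scale correlation of a distractor with its informative parent channel
_DISTRACTOR_PARENT = {
    "FL660_532": ("FL670", 0.90),
    "FL750_640": ("FL670", 0.85),
    "FL710_488": ("FL692", 0.90),
    "FL695_532": ("FL692", 0.88),
    "FSC_W": ("FSC", 0.92),
    "SSC_W": ("SSC", 0.90),
}

_DEFAULT_BASELINES = {
    "FSC": 5000.0, "SSC": 2000.0, "FL670": 8000.0, "FL692": 6000.0,
    "FL455_355": 300.0, "FL530_488": 450.0, "FL580_488": 380.0,
    "FL610_532": 520.0, "FL660_532": 2400.0, "FL710_488": 1800.0,
    "FL750_640": 2600.0, "FSC_W": 5200.0, "SSC_W": 2100.0,
    "FL460_355": 260.0, "FL520_457": 410.0, "FL545_532": 350.0,
    "FL620_640": 600.0, "FL695_532": 1700.0,
}

_DEFAULT_EFFECTS = {
    #             FSC    SSC   FL670  FL692
    "control":   (1.00, 1.00, 1.00, 1.00),
    "high_pCO2": (1.00, 1.10, 1.10, 1.10),
    "low_N":     (1.50, 0.45, 0.30, 0.45),
    "low_P":     (0.80, 1.30, 1.30, 0.85),
    "low_L":     (0.80, 1.40, 2.00, 1.70),
}

#: per-treatment multiplier on the log-scale spread; sets the designed rank
#: order of hypervolume richness: low_N < low_L < control < high_pCO2 < low_P
_DEFAULT_SPREAD = {
    "control": 1.00, "high_pCO2": 1.20, "low_N": 0.55,
    "low_P": 1.40, "low_L": 0.90,
}


@dataclass
class SynthConfig:
    """Parameters of the synthetic experiment and field campaign."""

    n_events_per_sample: int = 2000
    treatments: list[str] = field(
        default_factory=lambda: ["control", "high_pCO2", "low_N", "low_P", "low_L"]
    )
    n_replicates: int = 4
    channels: list[str] = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    baseline_medians: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASELINES)
    )
    effect_matrix: dict[str, dict[str, float]] = None  # treatment -> channel -> factor
    cv: dict[str, float] = None  # per-channel lognormal coefficient of variation
    spread_factors: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SPREAD)
    )
    pigment_rho: float = 0.8  # log-scale correlation FL670 <-> FL692
    debris_fraction: float = 0.10
    n_field_samples: int = 28
    gradient: Sequence[float] | None = None  # per-field-sample TN:light index in [0,1]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events_per_sample < 1:
            raise ValueError("n_events_per_sample must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if not 0 <= self.debris_fraction < 1:
            raise ValueError("debris_fraction must be in [0, 1)")
        if self.effect_matrix is None:
            self.effect_matrix = {
                t: {
                    ch: (_DEFAULT_EFFECTS[t][INFORMATIVE_CHANNELS.index(ch)]
                         if ch in INFORMATIVE_CHANNELS else 1.0)
                    for ch in self.channels
                }
                for t in self.treatments
                if t in _DEFAULT_EFFECTS
            }
            for t in self.treatments:
                if t not in self.effect_matrix:
                    self.effect_matrix[t] = {ch: 1.0 for ch in self.channels}
        if self.cv is None:
            self.cv = {
                ch: (0.5 if ch in INFORMATIVE_CHANNELS else 0.4)
                for ch in self.channels
            }
        for t, row in self.effect_matrix.items():
            if any(f <= 0 for f in row.values()):
                raise ValueError(f"effect factors must be > 0 (treatment {t!r})")
        control = self.effect_matrix.get("control")
        if control is not None and any(f != 1.0 for f in control.values()):
            raise ValueError("control row of effect_matrix must be all ones")
        if self.gradient is None:
            self.gradient = (
                list(np.linspace(0.0, 1.0, self.n_field_samples))
                if self.n_field_samples > 0 else []
            )

    def log_sigmas(self) -> np.ndarray:
        """Natural-log-scale standard deviation per channel (median-preserving)."""
        return np.array(
            [np.sqrt(np.log1p(self.cv[ch] ** 2)) for ch in self.channels]
        )

    def log_correlation(self) -> np.ndarray:
        """Channel-channel correlation matrix on the log scale."""
        chans = self.channels
        C = np.eye(len(chans))

        def _set(a: str, b: str, rho: float) -> None:
            if a in chans and b in chans:
                i, j = chans.index(a), chans.index(b)
                C[i, j] = C[j, i] = rho

        _set("FL670", "FL692", self.pigment_rho)
        for child, (parent, rho) in _DISTRACTOR_PARENT.items():
            _set(child, parent, rho)
        # nearest-PSD repair in case configured correlations conflict
        w, V = np.linalg.eigh(C)
        if w.min() < 1e-10:
            w = np.clip(w, 1e-10, None)
            C = V @ np.diag(w) @ V.T
            d = np.sqrt(np.diag(C))
            C = C / np.outer(d, d)
        return C


def _rng(config: SynthConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, *stream])
    )


def _draw_events(
    config: SynthConfig,
    effect: dict[str, float],
    spread: float,
    rng: np.random.Generator,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (values, truth) with truth 1 = target, 0 = debris."""
    chans = config.channels
    n_debris = int(round(config.debris_fraction * n))
    n_target = n - n_debris

    mu = np.array(
        [np.log(config.baseline_medians[ch] * effect[ch]) for ch in chans]
    )
    sig = spread * config.log_sigmas()
    cov = np.outer(sig, sig) * config.log_correlation()
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(chans)))
    target = np.exp(mu + rng.standard_normal((n_target, len(chans))) @ L.T)

    # debris: broad, uniform on the log scale, well below the target medians
    lo = np.zeros(len(chans))
    hi = np.array(
        [np.log10(max(config.baseline_medians[ch] / 20.0, 10.0)) for ch in chans]
    )
    debris = 10.0 ** (rng.uniform(lo, hi, size=(n_debris, len(chans))))

    values = np.vstack([target, debris])
    truth = np.concatenate([np.ones(n_target, int), np.zeros(n_debris, int)])
    order = rng.permutation(n)
    return values[order], truth[order]


def generate_culture_events(
    config: SynthConfig,
    treatment: str,
    replicate: int,
    return_truth: bool = False,
):
    """Simulate one culture replicate; deterministic in (seed, treatment, replicate)."""
    if treatment not in config.treatments:
        raise ValueError(
            f"unknown treatment {treatment!r}; expected one of {config.treatments}"
        )
    if not 0 <= replicate < config.n_replicates:
        raise ValueError(f"replicate index {replicate} out of range")
    t_idx = config.treatments.index(treatment)
    rng = _rng(config, 1, t_idx, replicate)
    values, truth = _draw_events(
        config,
        config.effect_matrix[treatment],
        config.spread_factors.get(treatment, 1.0),
        rng,
        config.n_events_per_sample,
    )
    table = EventTable(
        sample_id=f"{treatment}_R{replicate + 1}",
        channels=list(config.channels),
        values=values,
    )
    return (table, truth) if return_truth else table


def _interp_effect(config: SynthConfig, w: float) -> dict[str, float]:
    """Geometric (log-linear) interpolation between low_L (w=0) and low_N (w=1)."""
    lo_l, lo_n = config.effect_matrix["low_L"], config.effect_matrix["low_N"]
    return {ch: lo_l[ch] ** (1.0 - w) * lo_n[ch] ** w for ch in config.channels}


def generate_field_series(
    config: SynthConfig, return_truth: bool = False
) -> list[tuple[EventTable, FieldMetadata]]:
    """Simulate the lake series: one sample per gradient value.

    Each sample's effect vector interpolates geometrically between the
    low-light (gradient 0) and low-nitrogen (gradient 1) culture effect
    rows, and the metadata TN:light ratio increases monotonically with the
    gradient so downstream rank associations can be checked against the
    planted monotone trend.
    """
    gradient = list(config.gradient)
    if len(gradient) == 0:
        raise ValueError("field series requires a nonempty gradient list")
    out = []
    sp_l = config.spread_factors.get("low_L", 1.0)
    sp_n = config.spread_factors.get("low_N", 1.0)
    for i, g in enumerate(gradient):
        w = float(np.clip(g, 0.0, 1.0))
        rng = _rng(config, 2, i)
        spread = sp_l ** (1.0 - w) * sp_n ** w
        values, truth = _draw_events(
            config, _interp_effect(config, w), spread, rng,
            config.n_events_per_sample,
        )
        table = EventTable(
            sample_id=f"field_{i + 1:02d}",
            channels=list(config.channels),
            values=values,
        )
        meta = FieldMetadata(
            sample_id=table.sample_id,
            date=f"2023-W{i + 15:02d}",
            tn=50.0 + 950.0 * w,        # umol/L, rises along the planted gradient
            tp=8.0 + 4.0 * float(rng.uniform()),
            light=30.0 - 25.0 * w,      # umol photons m-2 s-1
        )
        out.append((table, meta, truth) if return_truth else (table, meta))
    return out


def generate_beads(sizes_um: Sequence[float], config: SynthConfig) -> EventTable:
    """Bead size standards: tight FSC modes increasing with bead size."""
    sizes = [float(s) for s in sizes_um]
    if len(sizes) < 2 or len(set(sizes)) < 2:
        raise ValueError("bead calibration needs >= 2 distinct sizes")
    rng = _rng(config, 3)
    n_per = 500
    chans = config.channels
    rows = []
    for s in sorted(sizes):
        fsc_median = 100.0 * s ** 2  # scatter tracks cross-section
        sigma = np.sqrt(np.log1p(0.03 ** 2))  # ~3% CV: tight calibration modes
        block = np.full((n_per, len(chans)), 50.0)
        block *= np.exp(rng.standard_normal((n_per, len(chans))) * sigma)
        fsc_col = chans.index("FSC")
        block[:, fsc_col] = fsc_median * np.exp(
            rng.standard_normal(n_per) * sigma
        )
        rows.append(block)
    return EventTable(
        sample_id="beads", channels=list(chans), values=np.vstack(rows)
    )


def generate_bioassay(config: SynthConfig, limiting: str | None) -> pd.DataFrame:
    """Nutrient-addition bioassay: day-0/day-4 fluorescence for 4 treatments x 3 reps.

    The addition matching ``limiting`` ("N", "P", "N+P" or None) gets an
    elevated 4-day growth rate (+0.25 d^-1 over a 0.10 d^-1 base).
    """
    if limiting not in {"N", "P", "N+P", None, "none"}:
        raise ValueError(f"unknown limiting nutrient {limiting!r}")
    if limiting == "none":
        limiting = None
    rng = _rng(config, 4)
    base_g, delta = 0.10, 0.25
    rows = []
    for treatment in ["control", "+N", "+P", "+NP"]:
        if limiting == "N":
            g = base_g + (delta if treatment in {"+N", "+NP"} else 0.0)
        elif limiting == "P":
            g = base_g + (delta if treatment in {"+P", "+NP"} else 0.0)
        elif limiting == "N+P":
            g = base_g + (delta if treatment == "+NP" else 0.0)
        else:
            g = base_g
        for rep in range(3):
            day0 = 100.0 * np.exp(rng.standard_normal() * 0.10)
            day4 = day0 * np.exp(4.0 * g) * np.exp(rng.standard_normal() * 0.08)
            rows.append(
                {"treatment": treatment, "replicate": rep + 1,
                 "day0": day0, "day4": day4}
            )
    return pd.DataFrame(rows)


def write_field_metadata(metas: Sequence[FieldMetadata], path) -> None:
    pd.DataFrame(
        [
            {"sample_id": m.sample_id, "TN": m.tn, "TP": m.tp,
             "light": m.light, "date": m.date}
            for m in metas
        ]
    ).to_csv(path, index=False)
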