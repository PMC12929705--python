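"""Event-table I/O, log transform, density-based population gating and size gating.

A flow cytometer reports one row ("event") per detected particle with one
column per optical channel (forward scatter, sideward scatter, fluorescence
filters).  The target cyanobacterial population is isolated from debris and
background by hierarchical density-based clustering (HDBSCAN) on
log10(x + 1)-transformed channels; field samples are additionally restricted
to a bead-calibrated particle-size window so large colonies and aggregates
are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN

__all__ = [
    "EventTable",
    "GatedPopulation",
    "SizeCalibration",
    "read_events",
    "write_events",
    "log_transform",
    "back_transform",
    "cluster_events",
    "calibrate_size",
    "size_gate",
]

#: default pigment channel used to recognise the cyanobacterial population
PIGMENT_CHANNEL = "FL670"


@dataclass
class EventTable:
    """Per-event optical measurements for one sample.

    values are peak heights in instrument units; every entry must be
    nonnegative and channel names unique.
    """

    sample_id: str
    channels: list[str]
    values: np.ndarray  # events x channels, nonnegative

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D events x channels array")
        if self.values.shape[0] < 1:
            raise ValueError("EventTable needs at least one event")
        if self.values.shape[1] != len(self.channels):
            raise ValueError("channel count does not match value columns")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if np.any(self.values < 0):
            r, c = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at row {r}, channel {self.channels[c]!r}"
            )

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def column(self, channel: str) -> np.ndarray:
        return self.values[:, self.channels.index(channel)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channels)


@dataclass
class GatedPopulation:
    """Subset of an EventTable selected as the target population."""

    parent: EventTable
    member_index: np.ndarray  # indices into parent rows
    cluster_labels: np.ndarray  # per-event labels, -1 = noise

    def __post_init__(self) -> None:
        self.member_index = np.asarray(self.member_index, dtype=int)
        self.cluster_labels = np.asarray(self.cluster_labels, dtype=int)
        n = self.parent.n_events
        if self.member_index.size and (
            self.member_index.min() < 0 or self.member_index.max() >= n
        ):
            raise ValueError("member_index outside parent event range")

    @property
    def n_members(self) -> int:
        return int(self.member_index.size)

    def member_values(self) -> np.ndarray:
        return self.parent.values[self.member_index]

    def member_table(self) -> EventTable:
        return EventTable(
            sample_id=self.parent.sample_id,
            channels=list(self.parent.channels),
            values=self.parent.values[self.member_index],
        )


@dataclass
class SizeCalibration:
    """log10(size um) = intercept + slope * log10(FSC), slope > 0."""

    slope: float
    intercept: float
    fsc_channel: str = "FSC"

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("size calibration slope must be positive")

    def size_um(self, fsc: np.ndarray) -> np.ndarray:
        return 10.0 ** (self.intercept + self.slope * np.log10(np.asarray(fsc, float)))


def read_events(path: str | Path, format: str = "csv") -> EventTable:
    """Read an event table; CSV with a header row of channel names."""
    path = Path(path)
    if format != "csv":
        raise ValueError(f"unknown format {format!r}; only 'csv' is supported")
    df = pd.read_csv(path)
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"{path.name}: negative value at row {r}, channel {df.columns[c]!r}"
        )
    return EventTable(sample_id=path.stem, channels=list(df.columns), values=values)


def write_events(events: EventTable, path: str | Path) -> Path:
    path = Path(path)
    events.to_frame().to_csv(path, index=False)
    return path


def log_transform(events: EventTable) -> EventTable:
    """Replace every value v by log10(v + 1) to reduce right skew."""
    return EventTable(
        sample_id=events.sample_id,
        channels=list(events.channels),
        values=np.log10(events.values + 1.0),
    )


def back_transform(events: EventTable) -> EventTable:
    """Inverse of :func:`log_transform`: v -> 10**v - 1."""
    vals = 10.0 ** events.values - 1.0
    # tiny negative round-off from the inverse is clipped, not an error
    return EventTable(
        sample_id=events.sample_id,
        channels=list(events.channels),
        values=np.clip(vals, 0.0, None),
    )


def cluster_events(
    events: EventTable,
    min_cluster_size: int | None = None,
    min_samples: int = 10,
    pigment_channel: str = PIGMENT_CHANNEL,
    min_cluster_frac: float = 0.01,
    cluster_selection_epsilon: float = 0.15,
) -> GatedPopulation:
    """Isolate the target population with HDBSCAN on log-transformed events.

    Defaults: ``min_cluster_size`` = 1% of events with a floor of 25;
    ``cluster_selection_epsilon`` (in log10 fluorescence units) merges
    sub-clusters closer than ~0.15 decades so a homogeneous population is
    not fragmented into mode-proximal shells.  The
    target is the largest cluster among those whose median pigment
    fluorescence exceeds the global median (cyanobacteria are
    phycocyanin-bright); if no cluster is brighter than the global median,
    the size-qualified cluster with the highest median pigment signal is
    taken instead.
    """
    n = events.n_events
    if min_cluster_size is None:
        min_cluster_size = max(25, int(round(min_cluster_frac * n)))
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")

    labels = HDBSCAN(
        min_cluster_size=min_cluster_size, min_samples=min_samples,
        cluster_selection_epsilon=cluster_selection_epsilon,
        allow_single_cluster=True, copy=True,
    ).fit_predict(events.values)

    cluster_ids = [c for c in np.unique(labels) if c != -1]
    qualified = [
        c for c in cluster_ids if np.sum(labels == c) >= min_cluster_size
    ]
    if not qualified:
        raise ValueError("no target population found")

    pigment = events.column(pigment_channel)
    global_median = float(np.median(pigment))
    bright = [
        c for c in qualified if np.median(pigment[labels == c]) > global_median
    ]
    if bright:
        # largest pigment-bright cluster; ties broken by cluster id for determinism
        target = max(bright, key=lambda c: (np.sum(labels == c), -c))
    else:
        target = max(
            qualified, key=lambda c: (np.median(pigment[labels == c]), -c)
        )
    member_index = np.flatnonzero(labels == target)
    return GatedPopulation(parent=events, member_index=member_index, cluster_labels=labels)


def calibrate_size(beads: EventTable, known_sizes_um: list[float],
                   fsc_channel: str = "FSC") -> SizeCalibration:
    """Fit the log(FSC) <-> log(size) line from bead populations.

    The i-th supplied size pairs with the i-th bead mode in ascending-FSC
    order, so sizes must be supplied strictly increasing; anything else is
    rejected as a non-monotone calibration.
    """
    sizes = [float(s) for s in known_sizes_um]
    if len(sizes) < 2 or len(set(sizes)) < 2:
        raise ValueError("size calibration needs >= 2 distinct bead sizes")
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("bead sizes must be strictly increasing (non-monotone mapping)")

    log_fsc = np.log10(beads.column(fsc_channel) + 1e-12)
    # split the 1-D log-FSC distribution into len(sizes) modes
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=len(sizes), n_init=10, random_state=0).fit(
        log_fsc.reshape(-1, 1)
    )
    medians = np.sort(
        [np.median(log_fsc[km.labels_ == k]) for k in range(len(sizes))]
    )
    if np.any(np.diff(medians) <= 0):
        raise ValueError("bead FSC modes are not separable / non-monotone")
    x, y = medians, np.log10(sizes)
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise ValueError("non-monotone bead calibration (slope <= 0)")
    return SizeCalibration(slope=float(slope), intercept=float(intercept),
                           fsc_channel=fsc_channel)


def size_gate(
    events: EventTable,
    cal: SizeCalibration,
    lo_um: float = 0.5,
    hi_um: float = 10.0,
) -> GatedPopulation:
    """Retain events whose calibrated size lies in the closed window [lo, hi] um."""
    if not lo_um < hi_um:
        raise ValueError("size gate requires lo < hi")
    sizes = cal.size_um(events.column(cal.fsc_channel))
    keep = np.flatnonzero((sizes >= lo_um) & (sizes <= hi_um))
    if keep.size == 0:
        warnings.warn(
            f"size gate [{lo_um}, {hi_um}] um retained no events for "
            f"{events.sample_id!r}",
            stacklevel=2,
        )
    labels = np.full(events.n_events, -1, dtype=int)
    labels[keep] = 0
    return GatedPopulation(parent=events, member_index=keep, cluster_labels=labels)
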