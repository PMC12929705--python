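"""End-to-end orchestration: culture analysis and field fingerprinting.

`run_culture_analysis` turns per-replicate event tables (synthetic by
default) into gated populations, the eight functional traits, the pooled
PCA phenotype space, per-replicate KDE hypervolumes with functional
diversity indices, treatment-level Jaccard overlaps, and the treatment
comparison statistics.  `run_field_assessment` then embeds a field series
in a joint culture+field space and assigns every field sample to its
nearest laboratory treatment fingerprint.

Every stochastic stage receives an explicit child seed derived from the
master seed, so a rerun with the same config reproduces identical numbers.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .synthio import SynthConfig, generate_culture_events, generate_field_series, generate_beads
from .gating import (
    EventTable, GatedPopulation, log_transform, cluster_events,
    calibrate_size, size_gate,
)
from .traits import TraitMatrix, derive_traits, standardize, anova_per_trait
from .phenospace import (
    fit_pca, test_axes_significance, treatment_profile_heatmap, functional_clusters,
)
from .hypervolume import build_hypervolume, fd_per_replicate, jaccard, Hypervolume
from .inference import kruskal_wallis, conover_iman
from .fingerprint import (
    joint_space, sample_centroids, assign_fingerprint, gradient_association,
)

__all__ = ["RunConfig", "CultureResults", "FieldResults",
           "run_culture_analysis", "run_field_assessment"]

FD_INDEX_NAMES = ["richness", "evenness", "dispersion"]


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    synth: SynthConfig = dc_field(default_factory=SynthConfig)
    volume_exponent: float = 1.0
    min_samples: int = 10
    min_cluster_frac: float = 0.01
    q: float = 0.95
    n_support: int | None = None
    n_perm: int = 199
    alpha_axes: float = 0.05
    alpha_pairwise: float = 0.01
    n_axes_max: int = 2
    bead_sizes_um: tuple[float, ...] = (0.5, 2.0, 10.0)
    size_window_um: tuple[float, float] = (0.5, 10.0)
    seed: int = 0
    outdir: str | Path | None = None


def _stage_seed(master: int, stage: int) -> int:
    return int(
        np.random.SeedSequence([master & 0x7FFFFFFF, stage]).generate_state(1)[0]
        & 0x7FFFFFFF
    )


@dataclass
class CultureResults:
    config: RunConfig
    raw_traits: list[TraitMatrix]
    std_traits: list[TraitMatrix]
    std_model: object
    space: object
    axes_used: list[int]
    profiles: pd.DataFrame
    cluster_solution: object
    fd_table: pd.DataFrame
    replicate_hvs: dict
    treatment_hvs: dict[str, Hypervolume]
    jaccard_matrix: pd.DataFrame
    kw: dict[str, tuple[float, float]]
    pairwise: dict[str, pd.DataFrame]
    anova: pd.DataFrame
    manifest: dict


def _gate_sample(events: EventTable, config: RunConfig) -> GatedPopulation:
    """Density gate on log10(x+1) channels; members refer to original values."""
    logged = log_transform(events)
    gated = cluster_events(
        logged,
        min_samples=config.min_samples,
        min_cluster_frac=config.min_cluster_frac,
    )
    return GatedPopulation(
        parent=events,
        member_index=gated.member_index,
        cluster_labels=gated.cluster_labels,
    )


def run_culture_analysis(config: RunConfig) -> CultureResults:
    synth = config.synth
    raw_traits: list[TraitMatrix] = []
    for treatment in synth.treatments:
        for rep in range(synth.n_replicates):
            events = generate_culture_events(synth, treatment, rep)
            gated = _gate_sample(events, config)
            tm = derive_traits(gated, volume_exponent=config.volume_exponent)
            tm.treatment, tm.replicate = treatment, rep
            raw_traits.append(tm)

    pooled = TraitMatrix(
        "culture_pooled", list(raw_traits[0].trait_names),
        np.vstack([tm.values for tm in raw_traits]),
    )
    _, model = standardize(pooled)
    std_traits = []
    for tm in raw_traits:
        z, _ = standardize(tm, model)
        std_traits.append(z)

    z_all = np.vstack([tm.values for tm in std_traits])
    space = fit_pca(
        z_all, trait_names=raw_traits[0].trait_names,
        fitted_on=[tm.sample_id for tm in raw_traits],
    )
    space.significant_axes = test_axes_significance(
        z_all, n_perm=config.n_perm, alpha=config.alpha_axes,
        seed=_stage_seed(config.seed, 10),
    )
    axes_used = [a for a in space.significant_axes if a < config.n_axes_max]
    if not axes_used:
        axes_used = list(range(min(config.n_axes_max, space.n_axes)))

    profiles = treatment_profile_heatmap(std_traits)
    clusters = functional_clusters(
        profiles, k_max=min(8, len(profiles)), seed=_stage_seed(config.seed, 11)
    )

    # per-replicate hypervolumes in the shared culture space
    offsets = np.cumsum([0] + [tm.n_events for tm in std_traits])
    groups = {
        (tm.treatment, tm.replicate): space.scores[
            offsets[i] : offsets[i + 1], axes_used
        ]
        for i, tm in enumerate(std_traits)
    }
    fd_table, replicate_hvs = fd_per_replicate(
        groups, q=config.q, n_support=config.n_support,
        seed=_stage_seed(config.seed, 12),
    )

    # treatment-level (pooled-replicate) hypervolumes and Jaccard overlap
    treatment_hvs: dict[str, Hypervolume] = {}
    for j, treatment in enumerate(synth.treatments):
        scores = np.vstack(
            [groups[k] for k in sorted(groups) if k[0] == treatment]
        )
        treatment_hvs[treatment] = build_hypervolume(
            scores, q=config.q, n_support=config.n_support,
            seed=_stage_seed(config.seed, 100 + j),
        )
    names = list(synth.treatments)
    J = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            val = jaccard(treatment_hvs[a], treatment_hvs[b])
            J.loc[a, b] = J.loc[b, a] = val

    kw = {}
    pairwise = {}
    for index_name in FD_INDEX_NAMES:
        by_t = {
            t: g[index_name].to_numpy()
            for t, g in fd_table.groupby("treatment")
        }
        kw[index_name] = kruskal_wallis(by_t)
        pairwise[index_name] = conover_iman(by_t, alpha=config.alpha_pairwise)

    anova = anova_per_trait(std_traits)

    manifest = {
        "cytotraits": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "n_events_per_sample": synth.n_events_per_sample,
        "treatments": list(synth.treatments),
        "n_replicates": synth.n_replicates,
        "q": config.q,
        "n_perm": config.n_perm,
        "axes_used": [int(a) for a in axes_used],
        "significant_axes": [int(a) for a in space.significant_axes],
    }
    results = CultureResults(
        config=config, raw_traits=raw_traits, std_traits=std_traits,
        std_model=model, space=space, axes_used=axes_used, profiles=profiles,
        cluster_solution=clusters, fd_table=fd_table,
        replicate_hvs=replicate_hvs, treatment_hvs=treatment_hvs,
        jaccard_matrix=J, kw=kw, pairwise=pairwise, anova=anova,
        manifest=manifest,
    )
    if config.outdir is not None:
        _write_culture(results, Path(config.outdir))
    return results


def _write_culture(res: CultureResults, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    res.fd_table.to_csv(outdir / "fd_indices.csv", index=False)
    res.profiles.to_csv(outdir / "trait_profiles.csv")
    res.jaccard_matrix.to_csv(outdir / "jaccard.csv")
    res.anova.to_csv(outdir / "anova_per_trait.csv", index=False)
    kw_df = pd.DataFrame(
        [{"index": k, "H": v[0], "p": v[1]} for k, v in res.kw.items()]
    )
    kw_df.to_csv(outdir / "kruskal_wallis.csv", index=False)
    for index_name, table in res.pairwise.items():
        table.to_csv(outdir / f"conover_{index_name}.csv", index=False)
    with open(outdir / "phenospace.json", "w") as fh:
        json.dump(res.space.to_dict(), fh, indent=2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(res.manifest, fh, indent=2)


@dataclass
class FieldResults:
    reports: list
    report_table: pd.DataFrame
    gradient_table: pd.DataFrame
    joint_space: object
    joint_model: object


def run_field_assessment(config: RunConfig, culture: CultureResults) -> FieldResults:
    if culture is None:
        raise ValueError(
            "culture artefacts missing: run run_culture_analysis first"
        )
    synth = config.synth
    series = generate_field_series(synth)
    beads = generate_beads(list(config.bead_sizes_um), synth)
    cal = calibrate_size(beads, sorted(config.bead_sizes_um))

    field_traits: list[TraitMatrix] = []
    metas = []
    for events, meta in series:
        gated = _gate_sample(events, config)
        member_table = gated.member_table()
        sized = size_gate(member_table, cal, *config.size_window_um)
        if sized.n_members == 0:
            continue
        tm = derive_traits(sized, volume_exponent=config.volume_exponent)
        tm.sample_id = events.sample_id
        field_traits.append(tm)
        metas.append(meta)

    space, model, provenance = joint_space(culture.raw_traits, field_traits)
    # full-rank scores reconstruct the pooled standardised data exactly
    sig = test_axes_significance(
        space.scores @ space.loadings.T + space.mean,
        n_perm=config.n_perm, alpha=config.alpha_axes,
        seed=_stage_seed(config.seed, 20),
    )
    space.significant_axes = sig
    axes_used = [a for a in sig if a < config.n_axes_max]
    if not axes_used:
        axes_used = list(range(min(config.n_axes_max, space.n_axes)))

    is_culture = (provenance["origin"] == "culture").to_numpy()
    culture_scores = space.scores[is_culture][:, axes_used]
    field_scores = space.scores[~is_culture][:, axes_used]

    t_labels = provenance.loc[is_culture, "treatment"].to_numpy()
    t_centroids = pd.DataFrame(
        {t: culture_scores[t_labels == t].mean(axis=0)
         for t in synth.treatments}
    ).T
    t_hvs = {
        t: build_hypervolume(
            culture_scores[t_labels == t], q=config.q,
            n_support=config.n_support,
            seed=_stage_seed(config.seed, 200 + i),
        )
        for i, t in enumerate(synth.treatments)
    }

    field_ids = provenance.loc[~is_culture, "sample_id"].to_numpy()
    centroids = sample_centroids(field_scores, field_ids)
    reports = []
    for meta in metas:
        if meta.sample_id not in centroids.index:
            continue
        reports.append(
            assign_fingerprint(
                centroids.loc[meta.sample_id].to_numpy(),
                t_centroids, t_hvs, meta,
            )
        )
    report_table = pd.DataFrame([r.to_row() for r in reports])
    gradient_table = gradient_association(reports)

    results = FieldResults(
        reports=reports, report_table=report_table,
        gradient_table=gradient_table, joint_space=space, joint_model=model,
    )
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report_table.to_csv(outdir / "fingerprint_reports.csv", index=False)
        gradient_table.to_csv(outdir / "gradient_association.csv", index=False)
    return results
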