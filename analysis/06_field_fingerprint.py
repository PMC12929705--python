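"""Project the field series onto the laboratory treatment fingerprints.

Runs the joint culture+field PCA, assigns each of the 28 field samples to
its nearest treatment fingerprint, and correlates the TN:light covariate
with the position in trait space.  Writes fingerprint_reports.csv and
gradient_association.csv to results/, plus a Figure-5-style map as a
scatter export when matplotlib is available.
"""

from pathlib import Path

from cytotraits.synthio import SynthConfig
from cytotraits.pipeline import RunConfig, run_culture_analysis, run_field_assessment

SEED = 7
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = RunConfig(
        synth=SynthConfig(n_events_per_sample=2000, n_field_samples=28, seed=SEED),
        seed=SEED,
    )
    culture = run_culture_analysis(cfg)
    field = run_field_assessment(cfg, culture)

    field.report_table.to_csv(RESULTS / "fingerprint_reports.csv", index=False)
    field.gradient_table.to_csv(RESULTS / "gradient_association.csv", index=False)

    counts = field.report_table["nearest_treatment"].value_counts()
    print(f"{len(field.report_table)} field samples assigned to fingerprints:")
    print(counts.to_string())
    print("\nSpearman correlation of centroid coordinates with TN:light:")
    print(field.gradient_table.round(3).to_string(index=False))

    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    fig, ax = plt.subplots(figsize=(6, 5))
    t = field.report_table
    sc = ax.scatter(t["axis1"], t["axis2"], c=t["gradient_value"],
                    cmap="Greys", edgecolor="k", s=40, label="field samples")
    for name, hv in culture.treatment_hvs.items():
        c = hv.centroid()
        ax.scatter(*c[:2], s=220, alpha=0.8, label=name)
    fig.colorbar(sc, label="TN : light")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    out = ROOT / "scratch" / "fingerprint_map.png"
    out.parent.mkdir(exist_ok=True)
    fig.savefig(out, dpi=150)
    print(f"\nwrote trait-space map to {out}")


if __name__ == "__main__":
    main()
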