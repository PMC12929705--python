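"""Build the integrated phenotype: PCA space, axis significance, clusters.

Runs the culture stage of the pipeline and reports the PCA variance
fractions, the permutation-significant axes, the treatment-replicate trait
profiles and the k-means elbow solution.  Writes the profile matrix and
the phenotype-space JSON to results/.
"""

import json
from pathlib import Path

import numpy as np

from cytotraits.synthio import SynthConfig
from cytotraits.pipeline import RunConfig, run_culture_analysis

SEED = 7
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = RunConfig(synth=SynthConfig(n_events_per_sample=2000, seed=SEED),
                    seed=SEED)
    res = run_culture_analysis(cfg)

    res.profiles.to_csv(RESULTS / "trait_profiles.csv")
    with open(RESULTS / "phenospace.json", "w") as fh:
        json.dump(res.space.to_dict(), fh, indent=2)

    frac = res.space.variance_fraction
    print("PCA variance fractions (%):",
          ", ".join(f"{100 * v:.1f}" for v in frac[:4]))
    print(f"PC1+PC2 capture {100 * frac[:2].sum():.1f}% of trait variance; "
          f"significant axes (permutation test): "
          f"{[a + 1 for a in res.space.significant_axes]}")
    print(f"k-means elbow on the 20 treatment-replicate profiles: "
          f"k = {res.cluster_solution.k}")
    prof = res.profiles.groupby("treatment").mean()
    print("\nmean standardised trait profile per treatment:")
    print(prof.round(2).to_string())
    print("\nnitrogen limitation sits opposite light limitation on the "
          "pigment traits,\nwith cell size responding in the opposite "
          "direction - the designed contrast.")


if __name__ == "__main__":
    main()
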