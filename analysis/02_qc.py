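#!/usr/bin/env python
"""Site QC, functional prioritization and the population-structure check.

Reads the simulated cohorts, applies the DP/FS/SOR site filters and the
functional-class prioritization to the annotation table, and runs the PCA
structure check on each cohort. Writes the retained panel to
results/analysis/qc.tsv and the PCA summary to results/analysis/pca.tsv.
"""

from pathlib import Path

import pandas as pd

from xassoc import QcThresholds, apply_site_filters, pca_structure_check, prioritize_functional
from xassoc.io import read_cohort

IN = Path("results/analysis/cohorts")
OUT = Path("results/analysis")


def main() -> None:
    disc, anno = read_cohort(IN / "disc")
    val, _ = read_cohort(IN / "val")

    retained, removed = apply_site_filters(anno, QcThresholds())
    prioritized = prioritize_functional(retained)
    prioritized.to_csv(OUT / "qc.tsv", sep="\t", index=False)
    print(
        f"{len(anno)} variants in; removed by rule {removed}; "
        f"{len(retained)} pass site filters; {len(prioritized)} after "
        "functional prioritization"
    )

    rows = []
    for name, cohort in (("discovery", disc), ("validation", val)):
        cohort = cohort.subset_variants(list(prioritized["variant_id"]))
        rep = pca_structure_check(cohort)
        rows.append(
            {
                "cohort": name,
                "pc1_fraction": rep.pc1_fraction,
                "structured": rep.structured,
            }
        )
        print(
            f"{name}: PC1 explains {100 * rep.pc1_fraction:.1f}% of variance "
            f"-> {'STRUCTURED' if rep.structured else 'no substructure'}"
        )
    pd.DataFrame(rows).to_csv(OUT / "pca.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
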