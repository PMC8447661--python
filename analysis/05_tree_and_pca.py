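#!/usr/bin/env python
"""Panel-evaluation ordinations on the discovery cohort: genotype PCA
(per-site mean imputation, centering, SVD) and a neighbor-joining tree
from identity-by-state distances; verifies that the two reference
populations occupy opposite ends with the hybrid generations between.

Reads results/sim/, writes results/structure/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from sikapanel import ancestry, variant_io

BASE = Path(__file__).resolve().parent.parent / "results"
SIM, OUT = BASE / "sim", BASE / "structure"
PER_GROUP = {"sika_ref": 20, "red_ref": 20, "F1": 15, "F2": 15, "F3": 15}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gm, labels = variant_io.read_vcf(SIM / "cohort.vcf", SIM / "labels.tsv")

    coords, explained = ancestry.pca(gm, n_components=5)
    coords = coords.assign(population=labels.reindex(coords.index).to_numpy())
    coords.to_csv(OUT / "pca_coordinates.tsv", sep="\t")
    means = coords.groupby("population")["PC1"].mean()
    order = ["sika_ref", "F3", "F2", "F1", "red_ref"]
    diffs = np.diff(means.loc[order])
    mono = bool((diffs > 0).all() or (diffs < 0).all())
    print(f"PC1 explains {explained[0]:.1%}; group means monotone in red content: {mono}")
    print(means.loc[order].round(2).to_string())

    # NJ tree on a per-group subsample to keep the plot readable
    keep: list[str] = []
    for pop, k in PER_GROUP.items():
        keep.extend(labels.index[labels == pop][:k])
    sub = gm.select_samples(keep)
    dist = ancestry.ibs_distance_matrix(sub)
    newick = ancestry.nj_tree(dist)
    (OUT / "nj_tree.nwk").write_text(newick + "\n")
    dist.to_csv(OUT / "ibs_distances.tsv", sep="\t")
    print(f"NJ tree over {sub.n_samples} individuals written to {OUT / 'nj_tree.nwk'}")


if __name__ == "__main__":
    main()
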