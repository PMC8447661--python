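#!/usr/bin/env python
"""Design the 1 K diagnostic panel from the simulated discovery cohort:
site-level QC (missing rate / depth / quality), per-site Weir-Cockerham
Fst between the two reference populations, the screening filters
(Fst > 0.95, type-II allele pairs only, 50 bp clean flanks, fixed-tier
priority) and the 4x candidate submission with 51-mer probe contexts.

Reads results/sim/, writes results/panel/.
"""

from pathlib import Path

import pandas as pd

from sikapanel import paneldesign, popstats, variant_io

BASE = Path(__file__).resolve().parent.parent / "results"
SIM, OUT = BASE / "sim", BASE / "panel"
TARGET = 1000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gm, labels = variant_io.read_vcf(SIM / "cohort.vcf", SIM / "labels.tsv")
    n_raw = gm.n_sites
    gm = variant_io.filter_sites(gm)
    ref_samples = labels[labels.isin(["sika_ref", "red_ref"])].index.tolist()
    stats = popstats.site_stats(gm.select_samples(ref_samples), labels.reindex(ref_samples))
    result = paneldesign.screen_candidates(stats, target_size=TARGET)

    reference = {name: str(seq) for name, seq in _read_fasta(SIM / "reference.fa").items()}
    panel = paneldesign.add_probe_contexts(result.selected, reference)
    panel.to_csv(OUT / "panel.tsv", sep="\t", index=False)
    stats.to_csv(OUT / "site_stats.tsv", sep="\t", index=False)
    paneldesign.export_candidates(
        result.survivors, reference, OUT / "submission.tsv", target_size=TARGET
    )
    paneldesign.write_probe_fasta(panel, OUT / "panel_probes.fa")

    print("screening attrition (sites remaining after each stage):")
    print(f"  raw VCF records          {n_raw}")
    print(f"  post-QC                  {gm.n_sites}")
    for key in ("fst_above_threshold", "type_ii_pair", "flank_clean", "selected"):
        print(f"  {key:<24} {result.attrition[key]}")
    print(
        f"selected panel: {len(panel)} loci, mean Fst "
        f"{panel['fst'].mean():.4f}, tiers {panel['exclusivity_tier'].value_counts().to_dict()}"
    )


def _read_fasta(path):
    import pyfaidx

    return pyfaidx.Fasta(str(path))


if __name__ == "__main__":
    main()
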