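#!/usr/bin/env python
"""Quantify red-deer genetic content per individual over the selected
panel, summarise the Mendelian dilution across backcross generations
(expected 0.5 / 0.25 / 0.125) and classify each individual's generation
with the nearest-expectation rule; check classification against pedigree
truth.

Reads results/sim/ and results/panel/, writes results/ancestry/.
"""

from pathlib import Path

import pandas as pd

from sikapanel import ancestry, variant_io

BASE = Path(__file__).resolve().parent.parent / "results"
SIM, PANEL, OUT = BASE / "sim", BASE / "panel", BASE / "ancestry"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gm, labels = variant_io.read_vcf(SIM / "cohort.vcf", SIM / "labels.tsv")
    panel = pd.read_csv(PANEL / "panel.tsv", sep="\t")
    report = ancestry.red_allele_proportion(gm, panel, labels=labels)
    report.to_csv(OUT / "ancestry_report.tsv", sep="\t", index=False)
    groups = ancestry.group_summary(report)
    groups.to_csv(OUT / "ancestry_groups.tsv", sep="\t", index=False)
    print("red-allele proportion by generation (mean +/- SD):")
    print(groups.round(4).to_string(index=False))

    truth_class = labels.replace({"sika_ref": "sika", "red_ref": "red"})
    acc = (report["assigned_class"].to_numpy() == truth_class.to_numpy()).mean()
    print(f"generation classification accuracy vs pedigree truth: {acc:.2%}")

    _plot(groups)


def _plot(groups: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [g for g in ("sika_ref", "F3", "F2", "F1", "red_ref") if g in set(groups["population"])]
    g = groups.set_index("population").loc[order]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(g.index, g["mean"], yerr=g["std"].fillna(0), color="#b5651d", capsize=3)
    ax.set_ylabel("red-deer allele proportion")
    ax.set_ylim(0, 1.05)
    for e in (0.125, 0.25, 0.5):
        ax.axhline(e, ls=":", lw=0.8, color="grey")
    fig.tight_layout()
    fig.savefig(OUT / "red_allele_proportion.png", dpi=150)
    print(f"figure written to {OUT / 'red_allele_proportion.png'}")


if __name__ == "__main__":
    main()
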