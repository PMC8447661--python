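"""VCF / label / FASTA I/O and the cohort-level QC filters.

Reading goes through cyvcf2; only biallelic single-base SNPs are kept
(multiallelic or indel records are dropped with a logged count). Writing
emits plain-text VCFv4.2 with unphased diploid GT and "./." for missing.

Filter semantics follow the screening protocol literally: a site is
*removed* when its missing rate is strictly greater than 0.1, its depth
strictly below 5X or its quality strictly below 30 (depth/quality checks
are skipped when the annotation is absent, as for chip-derived matrices);
a sample is removed when its missingness is strictly greater than 10%.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import MISSING, GenotypeMatrix, VariantSite

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# reading


def read_labels(path: str | Path) -> pd.Series:
    """Sample -> population labels from a two-column TSV (with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs columns sample_id, population")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy(), name="population")
    if s.index.has_duplicates:
        dups = s.index[s.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in label file: {dups}")
    return s


def read_vcf(
    path: str | Path, labels_path: str | Path | None = None
) -> tuple[GenotypeMatrix, pd.Series | None]:
    """Load a multi-sample VCF into a genotype matrix of alt-allele counts.

    Non-SNP and multiallelic records are skipped (count logged at INFO).
    If ``labels_path`` is given, every VCF sample must be labelled.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    n_dropped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            n_dropped += 1
            continue
        if variant.REF.upper() not in "ACGT" or variant.ALT[0].upper() not in "ACGT":
            n_dropped += 1
            continue
        dp = variant.INFO.get("DP")
        mean_depth = float(dp) / len(samples) if dp is not None and samples else float("nan")
        qual = float(variant.QUAL) if variant.QUAL is not None else float("nan")
        sites.append(
            VariantSite(
                contig=variant.CHROM,
                pos=variant.POS,
                ref=variant.REF,
                alt=variant.ALT[0],
                qual=qual,
                mean_depth=mean_depth,
            )
        )
        geno = np.asarray(variant.genotypes, dtype=np.int16)[:, :2]
        calls = np.where((geno < 0).any(axis=1), MISSING, geno.clip(min=0).sum(axis=1))
        rows.append(calls.astype(np.int8))
    vcf.close()
    if n_dropped:
        log.info("dropped %d non-SNP/multiallelic records from %s", n_dropped, path)
    calls = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(samples, sites, calls)

    labels = None
    if labels_path is not None:
        labels = read_labels(labels_path)
        unlabelled = sorted(set(samples) - set(labels.index))
        if unlabelled:
            raise ValueError(f"samples missing from label file: {unlabelled}")
        labels = labels.reindex(samples)
    log.info("read %d samples x %d SNP sites from %s", gm.n_samples, gm.n_sites, path)
    return gm, labels


# ---------------------------------------------------------------------------
# writing


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Plain-text VCFv4.2 with diploid unphased GT ("./." for missing)."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    contigs = list(dict.fromkeys(s.contig for s in gm.sites))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, site in enumerate(gm.sites):
            qual = "." if np.isnan(site.qual) else f"{site.qual:g}"
            info = (
                "."
                if np.isnan(site.mean_depth)
                else f"DP={int(round(site.mean_depth * gm.n_samples))}"
            )
            gts = "\t".join(gt_strings[int(g)] for g in gm.calls[:, j])
            fh.write(
                f"{site.contig}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t{qual}\t.\t{info}\tGT\t{gts}\n"
            )


def write_labels(labels: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": labels.index, "population": labels.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def write_fasta(reference: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig, seq in reference.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# filters


def filter_sites(
    gm: GenotypeMatrix,
    max_missing_rate: float = 0.1,
    min_depth: float = 5.0,
    min_qual: float = 30.0,
) -> GenotypeMatrix:
    """Site-level QC: missing rate, locus coverage and locus quality.

    A site survives iff missing rate <= ``max_missing_rate`` AND
    (depth unannotated OR depth >= ``min_depth``) AND (quality
    unannotated OR quality >= ``min_qual``). Boundaries are inclusive on
    the keep side ("greater than 0.1" / "less than 5X" / "less than 30"
    define removal).
    """
    if min(max_missing_rate, min_depth, min_qual) < 0:
        raise ValueError("thresholds must be non-negative")
    missing = gm.site_missing_rate()
    depth = np.array([s.mean_depth for s in gm.sites])
    qual = np.array([s.qual for s in gm.sites])
    keep = (
        (missing <= max_missing_rate)
        & (np.isnan(depth) | (depth >= min_depth))
        & (np.isnan(qual) | (qual >= min_qual))
    )
    out = gm.take_sites(np.flatnonzero(keep))
    log.info("site filter: %d of %d sites survive", out.n_sites, gm.n_sites)
    return out


def filter_samples(gm: GenotypeMatrix, max_sample_missing: float = 0.10) -> GenotypeMatrix:
    """Drop samples whose genotype missingness exceeds the threshold
    (strictly: exactly 10% missing is kept). Sample order is preserved."""
    if not 0.0 <= max_sample_missing <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    keep = gm.sample_missing_rate() <= max_sample_missing
    if not keep.any():
        raise ValueError("sample filter removed every sample")
    out = gm.take_samples(np.flatnonzero(keep))
    log.info("sample filter: %d of %d samples survive", out.n_samples, gm.n_samples)
    return out
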