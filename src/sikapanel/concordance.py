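"""Chip-validation statistics.

Platform agreement between two genotype matrices (e.g. array calls vs
sequencing calls for the same animals), allele-frequency correlation
across sites, replicate consistency, and the Venn-style survivor
accounting for the array QC thresholds (call rate > 95%, MAF > 0.05,
Hardy-Weinberg P >= 0.01 — strict inequalities as in the protocol).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, GenotypeMatrix
from .popstats import hwe_test

log = logging.getLogger(__name__)


def _shared(gm_a: GenotypeMatrix, gm_b: GenotypeMatrix):
    samples = [s for s in gm_a.samples if s in set(gm_b.samples)]
    keys_b = gm_b.site_index()
    sites = [s.key for s in gm_a.sites if s.key in keys_b]
    if not samples:
        raise ValueError("matrices share no samples")
    if not sites:
        raise ValueError("matrices share no sites")
    ia = gm_a.site_index()
    a = gm_a.select_samples(samples).take_sites([ia[k] for k in sites])
    b = gm_b.select_samples(samples).take_sites([keys_b[k] for k in sites])
    return a, b


@dataclass
class ConcordanceReport:
    per_sample: pd.DataFrame  # sample, n_co_called, n_identical, agreement
    mean_agreement: float  # unweighted mean of per-sample agreements
    pooled_agreement: float  # identical cells / co-called cells, pooled


def genotype_agreement(gm_a: GenotypeMatrix, gm_b: GenotypeMatrix) -> ConcordanceReport:
    """Per-individual genotype agreement over cells called on both
    platforms; the headline number is the unweighted mean over samples
    (cell-pooled agreement is reported alongside)."""
    a, b = _shared(gm_a, gm_b)
    co = (a.calls != MISSING) & (b.calls != MISSING)
    same = co & (a.calls == b.calls)
    n_co = co.sum(axis=1)
    n_same = same.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        agreement = np.where(n_co > 0, n_same / n_co, np.nan)
    per_sample = pd.DataFrame(
        {
            "sample": a.samples,
            "n_co_called": n_co,
            "n_identical": n_same,
            "agreement": agreement,
        }
    )
    mean_agreement = float(np.nanmean(agreement)) if len(agreement) else float("nan")
    pooled = float(same.sum() / co.sum()) if co.sum() else float("nan")
    return ConcordanceReport(per_sample, mean_agreement, pooled)


def frequency_correlation(
    gm_a: GenotypeMatrix, gm_b: GenotypeMatrix
) -> tuple[float, float, int]:
    """Pearson correlation of per-site alternate-allele frequencies
    between the two matrices; returns (r, p, n_sites). Zero variance in
    either frequency vector gives r = NaN."""
    a, b = _shared(gm_a, gm_b)

    def freqs(gm: GenotypeMatrix) -> np.ndarray:
        called = gm.calls != MISSING
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(called, gm.calls, 0).sum(axis=0) / (2.0 * n)
        return np.where(n > 0, f, np.nan)

    fa, fb = freqs(a), freqs(b)
    ok = np.isfinite(fa) & np.isfinite(fb)
    fa, fb = fa[ok], fb[ok]
    if len(fa) < 3:
        raise ValueError("need at least 3 shared sites with defined frequencies")
    if np.std(fa) == 0 or np.std(fb) == 0:
        return float("nan"), float("nan"), int(len(fa))
    r, p = stats.pearsonr(fa, fb)
    return float(r), float(p), int(len(fa))


def replicate_consistency(replicates: list[GenotypeMatrix]) -> tuple[float, int, int]:
    """Fraction of loci at which all non-missing replicate calls of the
    same sample agree. Loci with < 2 non-missing calls are excluded.

    ``replicates`` are single-sample (or identically shaped) matrices of
    repeat runs. Returns (consistent_fraction, n_consistent, n_compared).
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    shape = replicates[0].calls.shape
    for gm in replicates[1:]:
        if gm.calls.shape != shape:
            raise ValueError("replicates must have identical shape")
    stack = np.stack([gm.calls for gm in replicates])  # reps x samples x sites
    called = stack != MISSING
    n_called = called.sum(axis=0)
    comparable = n_called >= 2
    lo = np.where(called, stack, np.int8(3)).min(axis=0)
    hi = np.where(called, stack, np.int8(-2)).max(axis=0)
    consistent = comparable & (lo == hi)
    n_compared = int(comparable.sum())
    n_consistent = int(consistent.sum())
    frac = n_consistent / n_compared if n_compared else float("nan")
    return frac, n_consistent, n_compared


@dataclass
class ChipQCReport:
    counts: dict[str, int] = field(default_factory=dict)
    filtered: GenotypeMatrix | None = None


def chip_qc_survivors(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.95,
    hwe_alpha: float = 0.01,
) -> ChipQCReport:
    """Venn-style survivor accounting for the array QC thresholds.

    Counts (over all sites): detected (>= 1 call), polymorphic (both
    alleles observed), pass_maf (MAF strictly > ``maf_min``),
    pass_call_rate (call rate strictly > ``call_rate_min``), pass_both,
    fail_hwe (P < ``hwe_alpha``; monomorphic sites count P = 1), and
    survivors = pass both AND not failing HWE. Returns the matrix
    restricted to the survivors.
    """
    for t in (maf_min, call_rate_min, hwe_alpha):
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    calls = gm.calls
    called = calls != MISSING
    n_called = called.sum(axis=0)
    detected = n_called >= 1
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(called, calls, 0).sum(axis=0) / (2.0 * n_called)
    f = np.where(detected, f, np.nan)
    maf = np.minimum(f, 1.0 - f)
    polymorphic = detected & (maf > 0)
    call_rate = n_called / max(gm.n_samples, 1)
    # a zero threshold disables the corresponding filter entirely
    pass_maf = detected & (maf > maf_min) if maf_min > 0 else detected.copy()
    pass_cr = detected & (call_rate > call_rate_min) if call_rate_min > 0 else detected.copy()
    pass_both = pass_maf & pass_cr

    hwe_p = np.ones(gm.n_sites)
    if detected.any():
        hwe_p[detected] = hwe_test(
            ((calls == 0).sum(axis=0))[detected],
            ((calls == 1).sum(axis=0))[detected],
            ((calls == 2).sum(axis=0))[detected],
        )
    fail_hwe = detected & (hwe_p < hwe_alpha)
    keep = pass_both & ~fail_hwe

    counts = {
        "n_sites": gm.n_sites,
        "detected": int(detected.sum()),
        "polymorphic": int(polymorphic.sum()),
        "pass_maf": int(pass_maf.sum()),
        "pass_call_rate": int(pass_cr.sum()),
        "pass_both": int(pass_both.sum()),
        "fail_hwe": int(fail_hwe.sum()),
        "survivors": int(keep.sum()),
    }
    log.info("chip QC: %s", counts)
    return ChipQCReport(counts, gm.take_sites(np.flatnonzero(keep)))
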