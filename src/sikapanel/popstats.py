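"""Per-site population-genetic statistics.

Allele frequencies per population, minor allele frequency, observed and
expected heterozygosity, call rate, a chi-square Hardy-Weinberg test and
the two-population Weir & Cockerham (1984) per-site Fst estimator theta,
built from the variance components

    a  — among populations,
    b  — among individuals within populations,
    c  — within individuals (h_bar / 2 in the genotype parameterisation),

with theta = a / (a + b + c). theta can be slightly negative (estimator
property) and is undefined when a + b + c = 0, i.e. when both populations
are monomorphic for the same allele; such sites are flagged NaN and are
excluded from panel screening rather than scored 0. A site fixed for
alternative alleles in the two populations gives theta = 1 exactly for
any sample sizes.

Hudson's estimator is available as an alternative but Weir-Cockerham is
the default (it is what VCFtools' per-site weir-fst computes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, GenotypeMatrix


def allele_frequencies(gm: GenotypeMatrix, labels: pd.Series) -> pd.DataFrame:
    """Per site x population: alt-allele frequency, called diploids,
    observed heterozygote frequency.

    Returns a long DataFrame with columns contig, pos, population, freq,
    n_called, het_obs. Populations with zero called genotypes at a site
    get freq/het_obs = NaN.
    """
    labels = labels.reindex(gm.samples)
    if labels.isna().any():
        missing = [s for s, v in labels.items() if pd.isna(v)]
        raise ValueError(f"samples without a population label: {missing}")
    frames = []
    sf = gm.site_frame()
    for pop in pd.unique(labels):
        idx = np.flatnonzero((labels == pop).to_numpy())
        calls = gm.calls[idx, :]
        called = calls != MISSING
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(called, calls, 0).sum(axis=0) / (2.0 * n_called)
            het = (calls == 1).sum(axis=0) / n_called
        freq = np.where(n_called > 0, freq, np.nan)
        het = np.where(n_called > 0, het, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "contig": sf["contig"],
                    "pos": sf["pos"],
                    "population": pop,
                    "freq": freq,
                    "n_called": n_called,
                    "het_obs": het,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def wc_fst(
    p1: np.ndarray,
    p2: np.ndarray,
    h1: np.ndarray,
    h2: np.ndarray,
    n1: np.ndarray,
    n2: np.ndarray,
) -> np.ndarray:
    """Weir & Cockerham (1984) two-population per-site theta.

    Inputs are per-site allele frequencies ``p``, observed heterozygote
    frequencies ``h`` and called diploid counts ``n`` for the two
    populations (arrays broadcast together). Requires n >= 2 in both
    populations; sites failing that, or with a zero denominator, return
    NaN.
    """
    p1, p2, h1, h2, n1, n2 = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (p1, p2, h1, h2, n1, n2))
    )
    r = 2.0
    n_bar = (n1 + n2) / r
    valid = (n1 >= 2) & (n2 >= 2) & np.isfinite(p1) & np.isfinite(p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        inner = p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2
        a = (n_bar / n_c) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (inner - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar)
        c = h_bar / 2.0
        denom = a + b + c
        theta = np.where(valid & (denom != 0), a / denom, np.nan)
    return theta


def hudson_fst(p1, p2, n1, n2) -> np.ndarray:
    """Hudson (1992) estimator as in Bhatia et al. (2013); optional
    alternative to Weir-Cockerham."""
    p1, p2, n1, n2 = np.broadcast_arrays(*(np.asarray(x, dtype=float) for x in (p1, p2, n1, n2)))
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (2 * n1 - 1) - p2 * (1 - p2) / (2 * n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        return np.where(den != 0, num / den, np.nan)


def hwe_test(n_hom_ref, n_het, n_hom_alt) -> np.ndarray:
    """Chi-square (1 df, no continuity correction) Hardy-Weinberg test.

    Expected genotype counts are p^2, 2pq, q^2 at the observed allele
    frequency. Monomorphic sites return p = 1 by convention. Vectorised
    over sites.
    """
    n0, n1, n2 = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (n_hom_ref, n_het, n_hom_alt))
    )
    n = n0 + n1 + n2
    if (n < 1).any():
        raise ValueError("HWE test needs at least one called genotype")
    q = (n1 + 2 * n2) / (2 * n)  # alt-allele frequency
    p = 1.0 - q
    expected = np.stack([n * p**2, n * 2 * p * q, n * q**2])
    observed = np.stack([n0, n1, n2])
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0).sum(axis=0)
    pval = stats.chi2.sf(chi2, df=1)
    monomorphic = (q == 0) | (q == 1)
    return np.where(monomorphic, 1.0, pval)


def site_stats(
    gm: GenotypeMatrix,
    labels: pd.Series | None = None,
    pop_a: str = "sika_ref",
    pop_b: str = "red_ref",
    maf_populations: list[str] | None = None,
) -> pd.DataFrame:
    """One row per site: call_rate, maf, het_obs, het_exp, hwe_p, and —
    when two populations are supplied — per-population frequencies and
    Weir-Cockerham fst.

    MAF scope defaults to all samples (or, if ``maf_populations`` is
    given, the samples of those populations combined). All-missing sites
    get NaN statistics (flagged, not dropped).
    """
    sf = gm.site_frame()
    out = sf[["contig", "pos", "ref", "alt"]].copy()
    calls = gm.calls
    called = calls != MISSING
    n_called = called.sum(axis=0)
    out["call_rate"] = n_called / max(gm.n_samples, 1)

    if maf_populations is not None:
        if labels is None:
            raise ValueError("maf_populations needs labels")
        idx = np.flatnonzero(labels.reindex(gm.samples).isin(maf_populations).to_numpy())
        sub = calls[idx, :]
    else:
        sub = calls
    sub_called = sub != MISSING
    nsub = sub_called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(sub_called, sub, 0).sum(axis=0) / (2.0 * nsub)
        het_obs = (sub == 1).sum(axis=0) / nsub
    f = np.where(nsub > 0, f, np.nan)
    out["alt_freq"] = f
    out["maf"] = np.minimum(f, 1.0 - f)
    out["het_obs"] = np.where(nsub > 0, het_obs, np.nan)
    out["het_exp"] = 2.0 * f * (1.0 - f)

    n0 = ((sub == 0).sum(axis=0)).astype(float)
    n1 = (sub == 1).sum(axis=0).astype(float)
    n2 = (sub == 2).sum(axis=0).astype(float)
    hwe = np.full(gm.n_sites, np.nan)
    has = nsub > 0
    if has.any():
        hwe[has] = hwe_test(n0[has], n1[has], n2[has])
    out["hwe_p"] = hwe

    if labels is not None and {pop_a, pop_b} <= set(labels.reindex(gm.samples)):
        freq = allele_frequencies(gm, labels)
        piv = freq.pivot_table(
            index=["contig", "pos"],
            columns="population",
            values=["freq", "n_called", "het_obs"],
            sort=False,
        )
        key = pd.MultiIndex.from_frame(out[["contig", "pos"]])
        pa = piv.reindex(key)
        out["freq_" + pop_a] = pa[("freq", pop_a)].to_numpy()
        out["freq_" + pop_b] = pa[("freq", pop_b)].to_numpy()
        out["fst"] = wc_fst(
            pa[("freq", pop_a)].to_numpy(),
            pa[("freq", pop_b)].to_numpy(),
            pa[("het_obs", pop_a)].to_numpy(),
            pa[("het_obs", pop_b)].to_numpy(),
            pa[("n_called", pop_a)].to_numpy(),
            pa[("n_called", pop_b)].to_numpy(),
        )
        out["call_rate_" + pop_a] = (
            pa[("n_called", pop_a)].to_numpy()
            / max(int((labels == pop_a).sum()), 1)
        )
        out["call_rate_" + pop_b] = (
            pa[("n_called", pop_b)].to_numpy()
            / max(int((labels == pop_b).sum()), 1)
        )
    return out
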