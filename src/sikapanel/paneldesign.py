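"""Diagnostic-panel screening and probe-context export.

The screening pipeline turns per-site statistics for the two reference
populations into a ranked candidate list:

1. keep sites with a defined Weir-Cockerham Fst strictly above the
   retention threshold (default 0.95);
2. drop strand-ambiguous allele pairs (A/T and C/G; only single-bead
   "type II" pairs A/C, A/G, T/C, T/G are designable);
3. drop sites with another surviving cohort variant within +/-50 bp
   (probe flanking interference);
4. tier the rest: "fixed" when the red-specific allele is at frequency 1
   in red and 0 in sika among called genotypes (with a minimum
   per-population call rate at the site), "high_fst" otherwise;
5. rank: fixed before high_fst, then Fst descending, then combined
   expected heterozygosity ascending, then (contig, pos);
6. truncate to the target panel size.

Filter order only affects attrition counts, never the final set: the
rules are independent per-site predicates (the flanking rule is judged
against the full post-QC cohort variant list, not against screening
survivors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, VariantSite

log = logging.getLogger(__name__)

PANEL_COLUMNS = [
    "contig",
    "pos",
    "ref",
    "alt",
    "red_specific_allele",
    "fst",
    "exclusivity_tier",
    "rank",
]


@dataclass
class ScreenResult:
    """Ranked survivors plus the selected panel head and attrition log."""

    survivors: pd.DataFrame  # all ranked survivors
    selected: pd.DataFrame  # head of length <= target_size
    attrition: dict[str, int] = field(default_factory=dict)


def _ambiguous_pair(ref: pd.Series, alt: pd.Series) -> np.ndarray:
    a = ref.str.upper()
    b = alt.str.upper()
    return (
        ((a == "A") & (b == "T"))
        | ((a == "T") & (b == "A"))
        | ((a == "C") & (b == "G"))
        | ((a == "G") & (b == "C"))
    ).to_numpy()


def flank_clean_mask(
    sites: pd.DataFrame, cohort_sites: pd.DataFrame | None = None, flank_bp: int = 50
) -> np.ndarray:
    """True where no *other* cohort variant lies within ``flank_bp`` on the
    same contig (window inclusive, focal site excluded)."""
    if cohort_sites is None:
        cohort_sites = sites
    clean = np.ones(len(sites), dtype=bool)
    by_contig = {c: np.sort(g["pos"].to_numpy()) for c, g in cohort_sites.groupby("contig")}
    for i, (contig, pos) in enumerate(zip(sites["contig"], sites["pos"])):
        arr = by_contig.get(contig)
        if arr is None:
            continue
        lo = np.searchsorted(arr, pos - flank_bp, side="left")
        hi = np.searchsorted(arr, pos + flank_bp, side="right")
        n_window = hi - lo
        n_self = int(np.searchsorted(arr, pos, "right") - np.searchsorted(arr, pos, "left"))
        if n_window - n_self > 0 or n_self > 1:
            clean[i] = False
    return clean


def screen_candidates(
    stats: pd.DataFrame,
    target_size: int = 1000,
    fst_min: float = 0.95,
    flank_bp: int = 50,
    cohort_sites: pd.DataFrame | None = None,
    pop_a: str = "sika_ref",
    pop_b: str = "red_ref",
    min_fixation_call_rate: float = 0.9,
) -> ScreenResult:
    """Apply the screening pipeline to a ``site_stats`` table.

    ``stats`` must carry contig, pos, ref, alt, fst, freq_<pop_a>,
    freq_<pop_b>, het_exp per site (as produced by
    :func:`sikapanel.popstats.site_stats` with labels). ``cohort_sites``
    is the full post-QC variant list used for the flanking rule; by
    default the stats table itself. Returns every ranked survivor plus the
    head of ``target_size``; fewer survivors than the target is a warning,
    not an error.
    """
    df = stats.reset_index(drop=True).copy()
    attrition: dict[str, int] = {"input": len(df)}

    defined = df["fst"].notna().to_numpy()
    high_fst = defined & (df["fst"].to_numpy() > fst_min)
    attrition["fst_defined"] = int(defined.sum())
    attrition["fst_above_threshold"] = int(high_fst.sum())

    type_ii = ~_ambiguous_pair(df["ref"], df["alt"])
    attrition["type_ii_pair"] = int((high_fst & type_ii).sum())

    flank_ok = flank_clean_mask(df, cohort_sites=cohort_sites, flank_bp=flank_bp)
    keep = high_fst & type_ii & flank_ok
    attrition["flank_clean"] = int(keep.sum())

    sel = df.loc[keep].copy()

    fa = sel["freq_" + pop_a].to_numpy()
    fb = sel["freq_" + pop_b].to_numpy()
    # the red-specific allele is whichever allele is (near-)absent in sika:
    # orient to alt when alt is commoner in red than in sika
    red_is_alt = fb >= fa
    sel["red_specific_allele"] = np.where(red_is_alt, sel["alt"], sel["ref"])
    f_red = np.where(red_is_alt, fb, 1.0 - fb)
    f_sika = np.where(red_is_alt, fa, 1.0 - fa)
    cr_ok = np.ones(len(sel), dtype=bool)
    for pop in (pop_a, pop_b):
        col = "call_rate_" + pop
        if col in sel.columns:
            cr_ok &= sel[col].to_numpy() >= min_fixation_call_rate
    fixed = (f_red == 1.0) & (f_sika == 0.0) & cr_ok
    sel["exclusivity_tier"] = np.where(fixed, "fixed", "high_fst")
    attrition["tier_fixed"] = int(fixed.sum())

    tier_order = sel["exclusivity_tier"].map({"fixed": 0, "high_fst": 1})
    sel = (
        sel.assign(_tier=tier_order)
        .sort_values(
            ["_tier", "fst", "het_exp", "contig", "pos"],
            ascending=[True, False, True, True, True],
            kind="mergesort",
        )
        .drop(columns="_tier")
        .reset_index(drop=True)
    )
    sel["rank"] = np.arange(1, len(sel) + 1)

    if len(sel) < target_size:
        log.warning(
            "only %d survivors for a target panel of %d; returning all", len(sel), target_size
        )
    selected = sel.head(target_size).copy()
    attrition["selected"] = len(selected)
    log.info("screening attrition: %s", attrition)
    return ScreenResult(survivors=sel, selected=selected, attrition=attrition)


# ---------------------------------------------------------------------------
# probe contexts


def extract_probe_context(
    reference: "dict[str, str] | object", site: VariantSite, flank: int = 25
) -> str:
    """51-character sense-strand probe context, variant bracketed.

    The returned string is ``left25 + "[ref/alt]" + right25`` in
    uppercase: the variant occupies position 26 of the unbracketed
    51-mer. ``reference`` is a contig->sequence mapping or a
    pyfaidx.Fasta. Sites within 25 bp of a contig edge raise.
    """
    try:
        seq = reference[site.contig]
    except KeyError as exc:
        raise KeyError(f"contig {site.contig!r} not in reference") from exc
    contig_len = len(seq)
    if site.pos - flank < 1 or site.pos + flank > contig_len:
        raise ValueError(
            f"site {site.contig}:{site.pos} is within {flank} bp of a contig edge"
        )
    left = str(seq[site.pos - flank - 1 : site.pos - 1]).upper()
    base = str(seq[site.pos - 1 : site.pos]).upper()
    right = str(seq[site.pos : site.pos + flank]).upper()
    if base != site.ref.upper():
        raise ValueError(
            f"reference mismatch at {site.contig}:{site.pos}: FASTA has {base}, site says {site.ref}"
        )
    return f"{left}[{site.ref.upper()}/{site.alt.upper()}]{right}"


def add_probe_contexts(records: pd.DataFrame, reference) -> pd.DataFrame:
    out = records.copy()
    out["probe_context"] = [
        extract_probe_context(
            reference, VariantSite(contig=r.contig, pos=int(r.pos), ref=r.ref, alt=r.alt)
        )
        for r in records.itertuples()
    ]
    return out


def export_candidates(
    survivors: pd.DataFrame,
    reference,
    path: str | Path,
    target_size: int = 1000,
    multiplier: int = 4,
) -> pd.DataFrame:
    """Write the top ``multiplier x target_size`` ranked candidates (the
    array vendor receives several-fold the target so attrition during
    probe design still leaves a full panel) as a TSV with probe contexts.
    """
    n = multiplier * target_size
    if len(survivors) < n:
        log.warning("only %d survivors for a %d-candidate submission", len(survivors), n)
    head = survivors.head(n)
    out = add_probe_contexts(head, reference)
    out.to_csv(path, sep="\t", index=False)
    return out


def write_probe_fasta(records: pd.DataFrame, path: str | Path) -> None:
    """Probe contexts as FASTA; the bracketed 51-mer goes in the
    description, the sequence line carries the reference-allele version."""
    with open(path, "w") as fh:
        for r in records.itertuples():
            ctx = r.probe_context
            fh.write(f">{r.contig}_{r.pos} {ctx}\n")
            fh.write(ctx.replace(f"[{r.ref}/{r.alt}]", r.ref) + "\n")


def apply_design_scores(
    records: pd.DataFrame, scores: pd.Series | dict, min_score: float = 0.6
) -> pd.DataFrame:
    """Drop records whose externally supplied designability score falls
    strictly below ``min_score`` (0.6 kept); unscored records pass with a
    flag. Ranks are recomputed."""
    if not isinstance(scores, pd.Series):
        scores = pd.Series(scores)
    key = pd.MultiIndex.from_frame(records[["contig", "pos"]])
    vals = scores.reindex(key).to_numpy(dtype=float)
    out = records.copy()
    out["design_score"] = vals
    out["score_missing"] = np.isnan(vals)
    keep = np.isnan(vals) | (vals >= min_score)
    out = out.loc[keep].reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    log.info("design-score filter: %d of %d records kept", len(out), len(records))
    return out
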