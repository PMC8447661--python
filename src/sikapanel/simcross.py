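"""Synthetic two-population and backcross cohort simulator.

Emulates the study design behind a species-diagnostic SNP panel: a sika
deer and a red deer reference population fixed for alternative alleles at
diagnostic loci, background loci diverged under a Balding-Nichols model,
progressive backcross cohorts (F1 = sika x red, F2 = F1 x sika,
F3 = F2 x sika), and a chip-genotyping noise model (symmetric per-allele
call error plus independent missingness).

Loci are unlinked: each locus segregates independently (no recombination
map, no chromosome-type differences between the species). One master seed
drives named deterministic substreams per stage.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, VariantSite, concat_samples

GENERATIONS = ("sika_ref", "red_ref", "F1", "F2", "F3")

#: reference-allele -> type-II-compatible alternates (keeps the pair in
#: {A/C, A/G, T/C, T/G}); the strand-ambiguous partner is the complement.
_TYPE_II_ALT = {"A": "CG", "C": "AT", "G": "AT", "T": "CG"}
_AMBIGUOUS_ALT = {"A": "T", "T": "A", "C": "G", "G": "C"}

FLANK_BP = 50  # clustering window exercised by the panel flanking filter


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Deterministic per-stage RNG derived from one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode())])
    )


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Cohort sizes default to the resequencing design (250 sika, 206 red,
    23 F1, 20 F2, 20 F3). ``divergence_fst`` parameterises the
    Balding-Nichols beta model for background loci. Diagnostic loci are
    fixed for alternative alleles unless ``residual_polymorphism`` > 0, in
    which case the red-specific allele segregates at frequency
    ``1 - residual_polymorphism`` in red and ``residual_polymorphism`` in
    sika. ``n_ambiguous_diagnostic`` adds diagnostic decoys with A/T or
    C/G allele pairs; ``n_clustered_diagnostic`` (even) adds diagnostic
    decoys placed in pairs < 50 bp apart so each member fails the
    flanking filter and nothing else.
    """

    n_contigs: int = 4
    contig_length: int = 1_000_000
    n_background_sites: int = 2000
    n_diagnostic_sites: int = 1000
    divergence_fst: float = 0.1
    pop_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "sika_ref": 250,
            "red_ref": 206,
            "F1": 23,
            "F2": 20,
            "F3": 20,
        }
    )
    allele_error_rate: float = 0.0
    missing_rate: float = 0.0
    master_seed: int = 0
    n_ambiguous_diagnostic: int = 0
    n_clustered_diagnostic: int = 0
    residual_polymorphism: float = 0.0

    def validate(self) -> None:
        counts = [
            self.n_contigs,
            self.contig_length,
            self.n_background_sites,
            self.n_diagnostic_sites,
            self.n_ambiguous_diagnostic,
            self.n_clustered_diagnostic,
            *self.pop_sizes.values(),
        ]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if not 0.0 < self.divergence_fst < 1.0:
            raise ValueError("divergence_fst must lie in (0, 1)")
        for p in (self.allele_error_rate, self.missing_rate, self.residual_polymorphism):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_clustered_diagnostic % 2:
            raise ValueError("n_clustered_diagnostic must be even (sites are placed in pairs)")
        unknown = set(self.pop_sizes) - set(GENERATIONS)
        if unknown:
            raise ValueError(f"unknown populations in pop_sizes: {sorted(unknown)}")

    @property
    def n_sites(self) -> int:
        return (
            self.n_background_sites
            + self.n_diagnostic_sites
            + self.n_ambiguous_diagnostic
            + self.n_clustered_diagnostic
        )


@dataclass
class TruthTable:
    """Ground truth for a simulated cohort.

    ``sites``: one row per site — category, diagnostic flag, red-specific
    allele and the population frequencies (of the alternate allele) used
    for sampling. ``individuals``: one row per individual — pedigree
    generation and realized red-allele fraction over diagnostic loci.
    """

    sites: pd.DataFrame
    individuals: pd.DataFrame


@dataclass
class ReferenceSim:
    genotypes: GenotypeMatrix  # sika_ref then red_ref rows
    sites: list[VariantSite]
    truth: TruthTable
    reference: dict[str, str]  # contig -> sequence
    labels: pd.Series  # sample -> population


def _place_sites(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Choose site coordinates: unique, >=60 bp from contig edges, and
    > FLANK_BP apart except for deliberately clustered pairs."""
    lo, hi = 61, config.contig_length - 60
    if hi < lo:
        raise ValueError("contig_length too small for probe-context margins")
    capacity = config.n_contigs * max(0, (hi - lo) // (2 * FLANK_BP + 2))
    if config.n_sites > capacity:
        raise ValueError(
            f"{config.n_sites} sites requested but only ~{capacity} positions "
            f"available at the required spacing"
        )
    occupied: dict[int, list[int]] = {c: [] for c in range(config.n_contigs)}

    def is_free(contig: int, pos: int, min_gap: int) -> bool:
        arr = occupied[contig]
        i = np.searchsorted(arr, pos)
        for j in (i - 1, i):
            if 0 <= j < len(arr) and abs(arr[j] - pos) <= min_gap:
                return False
        return True

    def add(contig: int, pos: int) -> None:
        arr = occupied[contig]
        arr.insert(int(np.searchsorted(arr, pos)), pos)

    def draw_isolated() -> tuple[int, int]:
        for _ in range(100_000):
            contig = int(rng.integers(config.n_contigs))
            pos = int(rng.integers(lo, hi + 1))
            if is_free(contig, pos, FLANK_BP):
                add(contig, pos)
                return contig, pos
        raise RuntimeError("failed to place a site; reduce site count or raise contig_length")

    rows: list[tuple[int, int, str]] = []
    for _ in range(config.n_diagnostic_sites):
        rows.append((*draw_isolated(), "diagnostic"))
    for _ in range(config.n_ambiguous_diagnostic):
        rows.append((*draw_isolated(), "diagnostic_ambiguous"))
    for _ in range(config.n_clustered_diagnostic // 2):
        # a pair closer than the flanking window but clear of everyone else
        for _ in range(100_000):
            contig = int(rng.integers(config.n_contigs))
            pos = int(rng.integers(lo, hi - FLANK_BP))
            offset = int(rng.integers(10, FLANK_BP))
            if is_free(contig, pos, 2 * FLANK_BP) and is_free(contig, pos + offset, 2 * FLANK_BP):
                add(contig, pos)
                add(contig, pos + offset)
                rows.append((contig, pos, "diagnostic_clustered"))
                rows.append((contig, pos + offset, "diagnostic_clustered"))
                break
        else:
            raise RuntimeError("failed to place a clustered pair")
    for _ in range(config.n_background_sites):
        rows.append((*draw_isolated(), "background"))

    df = pd.DataFrame(rows, columns=["contig_idx", "pos", "category"])
    df["contig"] = "chr" + (df["contig_idx"] + 1).astype(str)
    return df.sort_values(["contig_idx", "pos"], kind="mergesort").reset_index(drop=True)


def _sample_genotypes(
    rng: np.random.Generator, freqs: np.ndarray, n: int
) -> np.ndarray:
    """Hardy-Weinberg draws: Binomial(2, p) per individual per site."""
    if n == 0:
        return np.zeros((0, len(freqs)), dtype=np.int8)
    return rng.binomial(2, freqs[None, :], size=(n, len(freqs))).astype(np.int8)


def simulate_reference_pops(config: SimulationConfig) -> ReferenceSim:
    """Simulate the two reference populations and the reference sequence.

    Background-site frequencies are drawn per population from a
    Balding-Nichols Beta(p(1-F)/F, (1-p)(1-F)/F) around an ancestral
    frequency p ~ U(0.05, 0.95) with F = ``divergence_fst``. Diagnostic
    sites are fixed (sika frequency ``residual_polymorphism``, red
    ``1 - residual_polymorphism`` for the red-specific alternate allele).
    Genotypes follow Hardy-Weinberg within each population. Deterministic
    given ``master_seed``.
    """
    config.validate()
    seed = config.master_seed

    ref_rng = substream(seed, "reference-sequence")
    reference = {
        f"chr{i + 1}": "".join(
            np.array(list("ACGT"))[ref_rng.integers(0, 4, size=config.contig_length)]
        )
        for i in range(config.n_contigs)
    }

    layout = _place_sites(config, substream(seed, "site-placement"))

    allele_rng = substream(seed, "alleles")
    refs, alts = [], []
    for contig, pos, category in zip(layout["contig"], layout["pos"], layout["category"]):
        ref_base = reference[contig][pos - 1]
        if category == "diagnostic_ambiguous":
            alt = _AMBIGUOUS_ALT[ref_base]
        elif category == "background":
            others = [b for b in "ACGT" if b != ref_base]
            alt = others[int(allele_rng.integers(3))]
        else:  # clean or clustered diagnostic: keep the pair type II
            choices = _TYPE_II_ALT[ref_base]
            alt = choices[int(allele_rng.integers(len(choices)))]
        refs.append(ref_base)
        alts.append(alt)
    layout["ref"] = refs
    layout["alt"] = alts

    freq_rng = substream(seed, "frequencies")
    n_sites = len(layout)
    diagnostic = layout["category"].str.startswith("diagnostic").to_numpy()
    p_sika = np.empty(n_sites)
    p_red = np.empty(n_sites)
    p_sika[diagnostic] = config.residual_polymorphism
    p_red[diagnostic] = 1.0 - config.residual_polymorphism
    n_bg = int((~diagnostic).sum())
    if n_bg:
        F = config.divergence_fst
        p_anc = freq_rng.uniform(0.05, 0.95, size=n_bg)
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_sika[~diagnostic] = freq_rng.beta(a, b)
        p_red[~diagnostic] = freq_rng.beta(a, b)
    layout["p_sika"] = p_sika
    layout["p_red"] = p_red
    layout["diagnostic"] = diagnostic
    layout["red_allele"] = np.where(diagnostic, layout["alt"], "")

    sites = [
        VariantSite(contig=c, pos=int(p), ref=r, alt=a)
        for c, p, r, a in zip(layout["contig"], layout["pos"], layout["ref"], layout["alt"])
    ]

    geno_rng = substream(seed, "reference-genotypes")
    n_sika = config.pop_sizes.get("sika_ref", 0)
    n_red = config.pop_sizes.get("red_ref", 0)
    sika_calls = _sample_genotypes(geno_rng, p_sika, n_sika)
    red_calls = _sample_genotypes(geno_rng, p_red, n_red)

    samples = [f"sika_{i + 1:04d}" for i in range(n_sika)] + [
        f"red_{i + 1:04d}" for i in range(n_red)
    ]
    gm = GenotypeMatrix(samples, sites, np.vstack([sika_calls, red_calls]))
    labels = pd.Series(
        ["sika_ref"] * n_sika + ["red_ref"] * n_red, index=samples, name="population"
    )

    site_truth = layout[
        ["contig", "pos", "ref", "alt", "category", "diagnostic", "red_allele", "p_sika", "p_red"]
    ].copy()
    indiv_truth = _individual_truth(gm, labels, site_truth)
    return ReferenceSim(gm, sites, TruthTable(site_truth, indiv_truth), reference, labels)


def _individual_truth(
    gm: GenotypeMatrix, labels: pd.Series, site_truth: pd.DataFrame
) -> pd.DataFrame:
    """Realized red-allele fraction over diagnostic loci, from genotypes."""
    diag = site_truth["diagnostic"].to_numpy()
    calls = gm.calls[:, diag]
    called = calls != MISSING
    with np.errstate(invalid="ignore"):
        frac = np.where(called, calls, 0).sum(axis=1) / (2 * called.sum(axis=1))
    return pd.DataFrame(
        {
            "sample": gm.samples,
            "generation": labels.reindex(gm.samples).to_numpy(),
            "red_fraction": frac,
        }
    )


def cross(
    parents_a: GenotypeMatrix,
    parents_b: GenotypeMatrix,
    n_offspring: int,
    seed: int | np.random.Generator,
    prefix: str = "off",
) -> GenotypeMatrix:
    """Random mating between two parent pools, loci unlinked.

    Each offspring draws, independently at every locus, one allele from a
    uniformly chosen individual of ``parents_a`` and one from a uniformly
    chosen individual of ``parents_b`` (a fresh parent per locus, i.e. the
    pools are treated as allele reservoirs, not pedigreed parents). When a
    chosen parent is missing at a locus another called parent is drawn.
    """
    if parents_a.n_samples == 0 or parents_b.n_samples == 0:
        raise ValueError("empty parent pool")
    if [s.key for s in parents_a.sites] != [s.key for s in parents_b.sites]:
        raise ValueError("parent matrices must cover identical sites")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sites = parents_a.n_sites

    def gametes(pool: GenotypeMatrix) -> np.ndarray:
        if not pool.called_mask().all():
            # resample per column among called parents
            out = np.empty((n_offspring, n_sites), dtype=np.int8)
            for j in range(n_sites):
                col = pool.calls[:, j]
                called = np.flatnonzero(col != MISSING)
                if called.size == 0:
                    raise ValueError(f"no called parent at site index {j}")
                picks = called[rng.integers(called.size, size=n_offspring)]
                out[:, j] = rng.binomial(1, col[picks] / 2.0)
            return out
        picks = rng.integers(pool.n_samples, size=(n_offspring, n_sites))
        g = pool.calls[picks, np.arange(n_sites)[None, :]]
        return rng.binomial(1, g / 2.0).astype(np.int8)

    calls = (gametes(parents_a) + gametes(parents_b)).astype(np.int8)
    samples = [f"{prefix}_{i + 1:04d}" for i in range(n_offspring)]
    return GenotypeMatrix(samples, list(parents_a.sites), calls)


def apply_genotyping_noise(
    gm: GenotypeMatrix,
    allele_error_rate: float,
    missing_rate: float,
    seed: int | np.random.Generator,
) -> GenotypeMatrix:
    """Chip re-genotyping noise: symmetric per-allele flips + missingness.

    Each of the two allele calls flips to the other allele independently
    with ``allele_error_rate``; each genotype is then set missing
    independently with ``missing_rate``. The input matrix is unmodified.
    """
    for p in (allele_error_rate, missing_rate):
        if not 0.0 <= p <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    calls = gm.calls.copy()
    called = calls != MISSING
    if allele_error_rate > 0 and called.any():
        g = np.where(called, calls, 0)
        # alt alleles that stay alt + ref alleles that flip to alt
        flipped = rng.binomial(g, 1.0 - allele_error_rate) + rng.binomial(
            2 - g, allele_error_rate
        )
        calls = np.where(called, flipped, calls).astype(np.int8)
    if missing_rate > 0:
        drop = rng.random(calls.shape) < missing_rate
        calls = np.where(drop, MISSING, calls).astype(np.int8)
    return GenotypeMatrix(list(gm.samples), list(gm.sites), calls)


@dataclass
class CohortSim:
    """Full five-generation study cohort with truth metadata."""

    genotypes: GenotypeMatrix  # noiseless, all generations
    chip_genotypes: GenotypeMatrix  # after genotyping noise
    labels: pd.Series
    sites: list[VariantSite]
    truth: TruthTable
    reference: dict[str, str]


def simulate_cohort(config: SimulationConfig) -> CohortSim:
    """Reference populations plus progressive backcross generations.

    F1 = sika_ref x red_ref; F2 = F1 x sika_ref; F3 = F2 x sika_ref
    (the study's "F2"/"F3" are successive backcrosses to sika). The chip
    matrix applies the configured noise model to the full cohort.
    """
    ref = simulate_reference_pops(config)
    seed = config.master_seed
    n_sika = config.pop_sizes.get("sika_ref", 0)
    sika = ref.genotypes.take_samples(range(n_sika))
    red = ref.genotypes.take_samples(range(n_sika, ref.genotypes.n_samples))

    f1 = cross(sika, red, config.pop_sizes.get("F1", 0), substream(seed, "cross-F1"), "F1")
    f2 = cross(f1, sika, config.pop_sizes.get("F2", 0), substream(seed, "cross-F2"), "F2")
    f3 = cross(f2, sika, config.pop_sizes.get("F3", 0), substream(seed, "cross-F3"), "F3")

    gm = concat_samples([ref.genotypes, f1, f2, f3])
    labels = pd.concat(
        [
            ref.labels,
            pd.Series("F1", index=f1.samples),
            pd.Series("F2", index=f2.samples),
            pd.Series("F3", index=f3.samples),
        ]
    )
    labels.name = "population"
    chip = apply_genotyping_noise(
        gm, config.allele_error_rate, config.missing_rate, substream(seed, "chip-noise")
    )
    truth = TruthTable(ref.truth.sites, _individual_truth(gm, labels, ref.truth.sites))
    return CohortSim(gm, chip, labels, ref.sites, truth, ref.reference)
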