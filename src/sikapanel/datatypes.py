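"""Core data model: variant sites and the genotype matrix.

Genotypes are stored as counts of the *alternate* allele per diploid
individual, so every call is 0, 1 or 2; ``-1`` encodes a missing call.
Tabular results (per-site statistics, panel manifests, ancestry reports)
are plain :class:`pandas.DataFrame` objects with documented columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: Allele pairs resolvable with a single Illumina bead type ("type II").
#: A/T and C/G pairs are strand-ambiguous and need two bead types.
TYPE_II_PAIRS = frozenset(
    [frozenset("AC"), frozenset("AG"), frozenset("TC"), frozenset("TG")]
)


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNP on the reference assembly (1-based position)."""

    contig: str
    pos: int
    ref: str
    alt: str
    qual: float = float("nan")  # phred-like site quality, NaN if unannotated
    mean_depth: float = float("nan")  # mean per-sample read depth, NaN if unannotated

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if len(allele) != 1 or allele.upper() not in "ACGT":
                raise ValueError(f"not a single-base allele: {allele!r}")
        if self.ref.upper() == self.alt.upper():
            raise ValueError(f"ref and alt alleles are identical at {self.contig}:{self.pos}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig, self.pos)

    def is_strand_ambiguous(self) -> bool:
        """True for A/T and C/G allele pairs (Illumina type I)."""
        return frozenset((self.ref.upper(), self.alt.upper())) not in TYPE_II_PAIRS


@dataclass
class GenotypeMatrix:
    """Individuals x sites matrix of alternate-allele counts.

    ``calls`` has shape ``(n_samples, n_sites)`` with entries in
    {0, 1, 2, MISSING}.
    """

    samples: list[str]
    sites: list[VariantSite]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype calls must be in {0, 1, 2, -1}")

    # -- basic views -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def called_mask(self) -> np.ndarray:
        return self.calls != MISSING

    def site_missing_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_sites)
        return (self.calls == MISSING).mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        if self.n_sites == 0:
            return np.zeros(self.n_samples)
        return (self.calls == MISSING).mean(axis=1)

    def site_frame(self) -> pd.DataFrame:
        """Sites as a DataFrame (contig, pos, ref, alt, qual, mean_depth)."""
        return pd.DataFrame(
            {
                "contig": [s.contig for s in self.sites],
                "pos": [s.pos for s in self.sites],
                "ref": [s.ref for s in self.sites],
                "alt": [s.alt for s in self.sites],
                "qual": [s.qual for s in self.sites],
                "mean_depth": [s.mean_depth for s in self.sites],
            }
        )

    # -- subsetting --------------------------------------------------------

    def take_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            [self.samples[i] for i in idx], list(self.sites), self.calls[idx, :]
        )

    def take_sites(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            list(self.samples), [self.sites[i] for i in idx], self.calls[:, idx]
        )

    def select_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return self.take_samples([lookup[n] for n in names])

    def site_index(self) -> dict[tuple[str, int], int]:
        return {s.key: i for i, s in enumerate(self.sites)}

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), list(self.sites), self.calls.copy())


def concat_samples(matrices: Sequence[GenotypeMatrix]) -> GenotypeMatrix:
    """Stack cohorts that cover the identical site list."""
    if not matrices:
        raise ValueError("no matrices to concatenate")
    sites = matrices[0].sites
    for gm in matrices[1:]:
        if [s.key for s in gm.sites] != [s.key for s in sites]:
            raise ValueError("matrices do not cover identical sites")
    samples: list[str] = []
    for gm in matrices:
        samples.extend(gm.samples)
    calls = np.vstack([gm.calls for gm in matrices])
    return GenotypeMatrix(samples, list(sites), calls)


def red_orientation_counts(
    gm: GenotypeMatrix, red_allele_is_alt: np.ndarray
) -> np.ndarray:
    """Re-orient alternate-allele counts to red-specific-allele counts.

    ``red_allele_is_alt`` is a boolean vector over sites; where False the
    count is flipped (g -> 2 - g). Missing stays missing.
    """
    red_allele_is_alt = np.asarray(red_allele_is_alt, dtype=bool)
    counts = gm.calls.astype(np.int16)
    flipped = np.where(counts == MISSING, MISSING, 2 - counts)
    return np.where(red_allele_is_alt[None, :], counts, flipped)
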