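"""Hybrid-ancestry quantification and panel-evaluation ordinations.

The hybrid index of an individual is the fraction of its called alleles
at panel loci that are the red-deer-specific allele. Under progressive
backcrossing to sika deer the expectation halves each generation:
red 1.0, F1 0.5, first backcross ("F2") 0.25, second backcross ("F3")
0.125, sika 0.0. Generation classification is the deterministic
nearest-expectation rule on that index, with midpoint boundaries and
exact-boundary ties going to the lower-ancestry class.

Also here: genotype PCA (per-site mean imputation, centering, SVD),
identity-by-state distances and a Saitou-Nei neighbor-joining tree with
optional site-resampling bootstrap support.
"""

from __future__ import annotations

from bisect import bisect_left

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix, red_orientation_counts

#: expected red-allele proportion per generation class, in ancestry order
CLASS_EXPECTATIONS = {"sika": 0.0, "F3": 0.125, "F2": 0.25, "F1": 0.5, "red": 1.0}
_CLASSES = list(CLASS_EXPECTATIONS)
#: midpoints between consecutive expectations
_BOUNDARIES = [0.0625, 0.1875, 0.375, 0.75]


def red_allele_proportion(
    gm: GenotypeMatrix,
    panel: pd.DataFrame,
    labels: pd.Series | None = None,
    low_call_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-individual red-allele counts and proportion over panel loci.

    ``panel`` needs contig, pos, red_specific_allele (a panel manifest).
    Missing genotypes are excluded from the denominator; individuals with
    zero called panel loci get NaN. ``low_call`` flags individuals called
    at fewer than ``low_call_fraction`` of the panel.
    """
    index = gm.site_index()
    keys = list(zip(panel["contig"], panel["pos"]))
    missing_sites = [k for k in keys if k not in index]
    if missing_sites:
        raise KeyError(f"panel sites absent from the matrix: {missing_sites[:5]}...")
    cols = [index[k] for k in keys]
    sub = gm.take_sites(cols)
    red_is_alt = np.array(
        [
            r == s.alt
            for r, s in zip(panel["red_specific_allele"], sub.sites)
        ]
    )
    bad = [
        (s.contig, s.pos)
        for r, s in zip(panel["red_specific_allele"], sub.sites)
        if r not in (s.ref, s.alt)
    ]
    if bad:
        raise ValueError(f"red_specific_allele matches neither allele at: {bad[:5]}")
    counts = red_orientation_counts(sub, red_is_alt)
    called = counts != MISSING
    n_called = called.sum(axis=1)
    red_count = np.where(called, counts, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(n_called > 0, red_count / (2.0 * n_called), np.nan)
    out = pd.DataFrame(
        {
            "sample": gm.samples,
            "n_panel_called": n_called,
            "red_allele_count": red_count,
            "proportion": prop,
            "low_call": n_called < low_call_fraction * len(panel),
        }
    )
    out["assigned_class"] = [classify_by_index(p) for p in out["proportion"]]
    if labels is not None:
        out["population"] = labels.reindex(gm.samples).to_numpy()
    return out


def group_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD of the red-allele proportion per labelled population."""
    if "population" not in report.columns:
        raise ValueError("report has no population column (pass labels)")
    return (
        report.groupby("population")["proportion"]
        .agg(["count", "mean", "std"])
        .reset_index()
    )


def classify_by_index(proportion: float) -> str:
    """Nearest-expectation generation class for a red-allele proportion.

    Boundaries are the midpoints 0.0625, 0.1875, 0.375, 0.75; a value
    exactly on a boundary is assigned the lower-ancestry class. NaN maps
    to "unknown".
    """
    if proportion is None or (isinstance(proportion, float) and np.isnan(proportion)):
        return "unknown"
    if not 0.0 <= proportion <= 1.0:
        raise ValueError(f"proportion must lie in [0, 1], got {proportion}")
    return _CLASSES[bisect_left(_BOUNDARIES, proportion)]


# ---------------------------------------------------------------------------
# ordination


def pca(gm: GenotypeMatrix, n_components: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """Genotype PCA: per-site mean imputation, per-site centering (no
    variance scaling), projection onto leading right singular directions.

    Returns (coordinates DataFrame indexed by sample with columns PC1...,
    explained-variance fractions). Component signs are arbitrary. A
    constant matrix yields all-zero coordinates.
    """
    if gm.n_samples < 2 or gm.n_sites < 2:
        raise ValueError("PCA needs at least 2 samples and 2 sites")
    X = gm.calls.astype(float)
    X[X == MISSING] = np.nan
    means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    means = np.where(np.isnan(means), 0.0, means)  # all-missing site -> 0 after centering
    inds = np.where(np.isnan(X))
    X[inds] = means[inds[1]]
    X -= means[None, :]
    n_components = min(n_components, gm.n_samples, gm.n_sites)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    coords = U[:, :n_components] * S[:n_components]
    total = (S**2).sum()
    explained = (S[:n_components] ** 2 / total) if total > 0 else np.zeros(n_components)
    df = pd.DataFrame(
        coords, index=gm.samples, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    return df, explained


def ibs_distance_matrix(gm: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise identity-by-state dissimilarity.

    d(i, j) = mean over co-called sites of |g_i - g_j| / 2, so identical
    genotype vectors are at 0 and opposite homozygotes at 1. Pairs with no
    co-called site get NaN.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    G = gm.calls.astype(float)
    called = G != MISSING
    Gz = np.where(called, G, 0.0)
    C = called.astype(float)
    # sum over co-called sites of |gi - gj| via the expansion of the
    # manhattan distance restricted to the co-called mask
    n_co = C @ C.T
    # |gi-gj| = gi + gj - 2*min(gi,gj); faster: loop over the 3 genotype values
    diff = np.zeros_like(n_co)
    for a in (0.0, 1.0, 2.0):
        for b in (0.0, 1.0, 2.0):
            if a >= b:
                continue
            Ia = (Gz == a) & called
            Ib = (Gz == b) & called
            cross = Ia.astype(float) @ Ib.astype(float).T
            diff += (b - a) * (cross + cross.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = diff / (2.0 * n_co)
    D = np.where(n_co > 0, D, np.nan)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=gm.samples, columns=gm.samples)


# ---------------------------------------------------------------------------
# neighbor joining


class _Node:
    __slots__ = ("name", "children")

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def nj_tree(distances: pd.DataFrame) -> str:
    """Saitou-Nei neighbor joining, returned as an unrooted newick string.

    Standard Q-criterion agglomeration; ties broken deterministically by
    (row, column) order of the current node list. Negative branch lengths
    are clamped to 0 with the deficit moved to the sister branch. Missing
    distances are an error.
    """
    D = distances.to_numpy(dtype=float).copy()
    names = list(distances.index)
    n = len(names)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(D, D.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains missing entries")
    nodes = [_Node(name) for name in names]
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # deterministic tie-break: first (i, j) in row-major order
        i, j = divmod(int(np.argmin(Q)), m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        lj = max(lj, 0.0)
        ai, aj = active[i], active[j]
        new = _Node(children=[(nodes[ai], li), (nodes[aj], lj)])
        # distances from the new node to the remaining taxa
        d_new = 0.5 * (D[ai, :] + D[aj, :] - dij)
        D = np.vstack([D, d_new[None, :]])
        D = np.hstack([D, np.append(d_new, 0.0)[:, None]])
        nodes.append(new)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    a, b = active
    # unrooted: attach the last pair along their connecting edge
    final = _Node(children=[(nodes[a], max(D[a, b], 0.0)), (nodes[b], 0.0)])
    return final.newick() + ";"


def nj_bootstrap_support(
    gm: GenotypeMatrix, n_replicates: int = 100, seed: int = 0
) -> pd.Series:
    """Site-resampling bootstrap support for the bipartitions of the NJ
    tree built from the full IBS matrix. Off by default in the pipeline.

    Returns support fractions keyed by frozenset of taxon names on the
    smaller side of each internal bipartition.
    """
    base = nj_tree(ibs_distance_matrix(gm))
    base_parts = _bipartitions(base, set(gm.samples))
    counts = {p: 0 for p in base_parts}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        idx = rng.integers(gm.n_sites, size=gm.n_sites)
        rep = gm.take_sites(idx)
        parts = _bipartitions(nj_tree(ibs_distance_matrix(rep)), set(gm.samples))
        for p in counts:
            if p in parts:
                counts[p] += 1
    return pd.Series({p: c / n_replicates for p, c in counts.items()})


def _bipartitions(newick: str, all_taxa: set[str]) -> set[frozenset]:
    """Internal-edge bipartitions of a newick tree (smaller side)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    parts = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node.is_leaf() or edge.head_node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in edge.head_node.leaf_iter())
        other = frozenset(all_taxa - side)
        if 1 < len(side) < len(all_taxa) - 1:
            parts.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return parts
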