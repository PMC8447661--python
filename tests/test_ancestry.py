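"""Hybrid index, generation classification, PCA, IBS distances and the
neighbor-joining tree (checked against scikit-bio's NJ as an oracle)."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sikapanel.ancestry import (
    CLASS_EXPECTATIONS,
    classify_by_index,
    group_summary,
    ibs_distance_matrix,
    nj_tree,
    pca,
    red_allele_proportion,
)
from sikapanel.datatypes import MISSING

from conftest import make_gm


def _panel_for(gm, red_allele="alt"):
    sf = gm.site_frame()
    return pd.DataFrame(
        {
            "contig": sf["contig"],
            "pos": sf["pos"],
            "red_specific_allele": sf[red_allele if red_allele in ("ref", "alt") else "alt"],
        }
    )


# ---------------------------------------------------------------------------
# red-allele proportion


def test_proportion_arithmetic():
    calls = np.array(
        [
            [1, 1, 1, 1],  # all het -> 0.5
            [2, 1, 0, MISSING],  # 3 red alleles over 6 called -> 0.5
            [MISSING] * 4,  # nothing called -> NaN, class unknown
        ]
    )
    gm = make_gm(calls)
    rep = red_allele_proportion(gm, _panel_for(gm))
    assert rep.loc[0, "proportion"] == 0.5
    assert rep.loc[1, "proportion"] == 0.5
    assert rep.loc[1, "n_panel_called"] == 3
    assert np.isnan(rep.loc[2, "proportion"])
    assert rep.loc[2, "assigned_class"] == "unknown"
    assert rep.loc[2, "low_call"]


def test_orientation_to_red_specific_allele():
    calls = np.array([[2, 2], [0, 0]])
    gm = make_gm(calls)
    panel = _panel_for(gm, red_allele="ref")  # red allele is the REF base
    rep = red_allele_proportion(gm, panel)
    assert rep.loc[0, "proportion"] == 0.0  # alt homozygote has no red alleles
    assert rep.loc[1, "proportion"] == 1.0


def test_proportions_equal_simulator_truth(small_cohort):
    sim = small_cohort
    diag = sim.truth.sites[sim.truth.sites["diagnostic"]]
    panel = diag.rename(columns={"red_allele": "red_specific_allele"})[
        ["contig", "pos", "red_specific_allele"]
    ]
    rep = red_allele_proportion(sim.genotypes, panel, labels=sim.labels)
    np.testing.assert_allclose(
        rep["proportion"].to_numpy(), sim.truth.individuals["red_fraction"].to_numpy()
    )
    means = group_summary(rep).set_index("population")["mean"]
    assert means["F1"] == pytest.approx(0.5)
    assert means["red_ref"] == 1.0 and means["sika_ref"] == 0.0


# ---------------------------------------------------------------------------
# classification


@pytest.mark.parametrize(
    "p,cls",
    [
        (0.0, "sika"),
        (0.5, "F1"),
        (1.0, "red"),
        (0.30, "F2"),
        (0.10, "F3"),
        (0.0625, "sika"),  # boundary tie -> lower-ancestry class
        (0.1875, "F3"),
        (0.375, "F2"),
        (0.75, "F1"),
    ],
)
def test_classification_rule(p, cls):
    assert classify_by_index(p) == cls


def test_classification_rejects_out_of_range():
    with pytest.raises(ValueError):
        classify_by_index(1.2)
    assert classify_by_index(float("nan")) == "unknown"


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
def test_classifier_is_nearest_expectation(p):
    """Off boundaries the assigned class minimises |p - expectation|; the
    five classes partition [0, 1]."""
    cls = classify_by_index(p)
    assert cls in CLASS_EXPECTATIONS
    best = min(abs(p - e) for e in CLASS_EXPECTATIONS.values())
    assert abs(p - CLASS_EXPECTATIONS[cls]) == pytest.approx(best)


# ---------------------------------------------------------------------------
# PCA


def test_pca_duplicated_samples_get_identical_coordinates():
    rng = np.random.default_rng(13)
    calls = rng.integers(0, 3, (6, 40)).astype(np.int8)
    calls[3] = calls[0]
    coords, _ = pca(make_gm(calls), n_components=3)
    np.testing.assert_allclose(coords.iloc[0], coords.iloc[3], atol=1e-9)


def test_pca_separates_fixed_populations():
    calls = np.vstack([np.zeros((10, 30)), np.full((8, 30), 2)]).astype(np.int8)
    gm = make_gm(calls)
    coords, explained = pca(gm, n_components=2)
    pc1 = coords["PC1"].to_numpy()
    assert max(pc1[:10]) < min(pc1[10:]) or min(pc1[:10]) > max(pc1[10:])
    assert explained[0] == pytest.approx(1.0)


def test_pca_group_means_monotone_in_red_content(small_cohort):
    sim = small_cohort
    coords, _ = pca(sim.genotypes, n_components=2)
    pc1 = coords["PC1"]
    order = ["sika_ref", "F3", "F2", "F1", "red_ref"]
    means = [pc1[sim.labels == g].mean() for g in order]
    diffs = np.diff(means)
    assert (diffs > 0).all() or (diffs < 0).all()


def test_pca_handles_missing_and_constant_input():
    calls = np.array([[0, 1, MISSING], [0, 1, 2], [0, MISSING, 2], [0, 1, 0]])
    coords, _ = pca(make_gm(calls), n_components=2)
    assert np.isfinite(coords.to_numpy()).all()
    const, explained = pca(make_gm(np.ones((3, 4), dtype=np.int8)), n_components=2)
    np.testing.assert_allclose(const.to_numpy(), 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# IBS distances


def test_ibs_reference_values_and_fixture():
    calls = np.array(
        [
            [0, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0, 0],
            [2, 2, 2, 2, 2, 2],
            [1, 2, 0, MISSING, 1, 2],
        ]
    )
    D = ibs_distance_matrix(make_gm(calls)).to_numpy()
    assert D[0, 1] == 0.0
    assert D[0, 2] == 1.0
    # brute force for the mixed row against row 0: diffs |1,2,0,-,1,2| over
    # 5 co-called sites -> (1+2+0+1+2)/(2*5)
    assert D[0, 3] == pytest.approx(6 / 10)
    assert np.allclose(D, D.T)
    assert np.diag(D).sum() == 0


def test_ibs_missing_pair_flagged():
    calls = np.array([[0, MISSING], [MISSING, 2], [1, 1]])
    D = ibs_distance_matrix(make_gm(calls)).to_numpy()
    assert np.isnan(D[0, 1])
    assert np.isfinite(D[0, 2])


def test_ibs_triangle_inequality_on_complete_data():
    rng = np.random.default_rng(14)
    calls = rng.integers(0, 3, (12, 50)).astype(np.int8)
    D = ibs_distance_matrix(make_gm(calls)).to_numpy()
    n = len(D)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


# ---------------------------------------------------------------------------
# neighbor joining


def test_nj_three_taxa_closed_form():
    D = pd.DataFrame(
        [[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]],
        index=list("abc"),
        columns=list("abc"),
    )
    import dendropy

    tree = dendropy.Tree.get(data=nj_tree(D), schema="newick")
    dists = {}
    pdm = tree.phylogenetic_distance_matrix()
    for t1 in tree.taxon_namespace:
        for t2 in tree.taxon_namespace:
            dists[(t1.label, t2.label)] = pdm.patristic_distance(t1, t2)
    # three-point formulas are exact: patristic distances reproduce D
    assert dists[("a", "b")] == pytest.approx(0.3)
    assert dists[("a", "c")] == pytest.approx(0.5)
    assert dists[("b", "c")] == pytest.approx(0.6)


def _pair_clades(newick):
    """Leaf sets of size 2 hanging below some node (enough to identify the
    non-trivial split of a quartet)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    splits = set()
    for node in tree.preorder_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(leaves) == 2:
            splits.add(leaves)
    return splits


def test_nj_recovers_additive_quartet_and_agrees_with_skbio():
    # tree ((a:1,b:2):1,(c:3,d:1)): additive distances
    D = pd.DataFrame(
        [
            [0.0, 3.0, 5.0, 3.0],
            [3.0, 0.0, 6.0, 4.0],
            [5.0, 6.0, 0.0, 4.0],
            [3.0, 4.0, 4.0, 0.0],
        ],
        index=list("abcd"),
        columns=list("abcd"),
    )
    newick = nj_tree(D)
    splits = _pair_clades(newick)
    assert frozenset("ab") in splits or frozenset("cd") in splits
    assert frozenset("ac") not in splits and frozenset("ad") not in splits

    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    ref = skbio_nj(DistanceMatrix(D.to_numpy(), ids=list("abcd")))
    ref_splits = _pair_clades(str(ref).strip())
    assert frozenset("ab") in ref_splits or frozenset("cd") in ref_splits
    # and the patristic distances match the additive input exactly
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i in "abcd":
        for j in "abcd":
            if i < j:
                assert pdm.patristic_distance(taxa[i], taxa[j]) == pytest.approx(D.loc[i, j])


def test_nj_input_validation():
    bad = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=list("ab"), columns=list("ab"))
    with pytest.raises(ValueError, match="at least 3"):
        nj_tree(bad)
    nan = pd.DataFrame(
        [[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]], index=list("abc"), columns=list("abc")
    )
    with pytest.raises(ValueError, match="missing"):
        nj_tree(nan)


def test_nj_clan_separation_of_reference_populations(small_cohort):
    """On the noiseless cohort the sika and red reference animals each
    form a clan (one edge separates them from everything else)."""
    import dendropy

    sim = small_cohort
    # subsample for speed: 8 per reference population, 4 per hybrid group
    keep = []
    for pop, k in (("sika_ref", 8), ("red_ref", 8), ("F1", 4), ("F2", 4), ("F3", 4)):
        keep.extend(sim.labels.index[sim.labels == pop][:k])
    gm = sim.genotypes.select_samples(keep)
    newick = nj_tree(ibs_distance_matrix(gm))
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    labels = sim.labels

    def is_clan(pop):
        members = {s for s in keep if labels[s] == pop}
        for node in tree.preorder_node_iter():
            leaves = {l.taxon.label for l in node.leaf_iter()}
            if leaves == members or leaves == set(keep) - members:
                return True
        return False

    assert is_clan("sika_ref")
    assert is_clan("red_ref")
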