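"""Panel screening against a brute-force oracle, probe-context format,
submission export and designability-score filtering."""

import numpy as np
import pandas as pd
import pytest

from sikapanel.datatypes import VariantSite
from sikapanel.paneldesign import (
    add_probe_contexts,
    apply_design_scores,
    export_candidates,
    extract_probe_context,
    flank_clean_mask,
    screen_candidates,
)
from sikapanel.popstats import site_stats
from sikapanel.simcross import SimulationConfig, simulate_reference_pops


def _stats_row(pos, fst, ref="A", alt="C", fa=0.0, fb=1.0, het_exp=0.0, contig="chr1"):
    return {
        "contig": contig,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "fst": fst,
        "freq_sika_ref": fa,
        "freq_red_ref": fb,
        "het_exp": het_exp,
        "call_rate_sika_ref": 1.0,
        "call_rate_red_ref": 1.0,
    }


@pytest.fixture
def planted_fixture():
    """30 sites: 3 low-Fst, 2 strand-ambiguous, 4 clustered (<50 bp), 21
    clean — with known frequencies and heterozygosities."""
    rows = []
    pos = 1000
    for i in range(21):
        rows.append(_stats_row(pos, 1.0))
        pos += 1000
    for fst in (0.5, 0.8, 0.94):
        rows.append(_stats_row(pos, fst, fa=0.2, fb=0.9, het_exp=0.3))
        pos += 1000
    rows.append(_stats_row(pos, 1.0, ref="A", alt="T"))
    pos += 1000
    rows.append(_stats_row(pos, 1.0, ref="G", alt="C"))
    pos += 1000
    for _ in range(2):  # two clustered pairs, 30 bp apart
        rows.append(_stats_row(pos, 1.0))
        rows.append(_stats_row(pos + 30, 1.0))
        pos += 1000
    return pd.DataFrame(rows)


def brute_force_screen(df, fst_min=0.95, flank_bp=50):
    keep = []
    for i, r in df.iterrows():
        if not (pd.notna(r["fst"]) and r["fst"] > fst_min):
            continue
        if {r["ref"], r["alt"]} in ({"A", "T"}, {"C", "G"}):
            continue
        near = df[
            (df["contig"] == r["contig"])
            & (df.index != i)
            & ((df["pos"] - r["pos"]).abs() <= flank_bp)
        ]
        if len(near):
            continue
        keep.append(i)
    return set(zip(df.loc[keep, "contig"], df.loc[keep, "pos"]))


def test_screen_matches_brute_force_oracle(planted_fixture):
    res = screen_candidates(planted_fixture, target_size=100)
    got = set(zip(res.survivors["contig"], res.survivors["pos"]))
    assert got == brute_force_screen(planted_fixture)
    assert len(res.survivors) == 21
    assert (res.survivors["exclusivity_tier"] == "fixed").all()
    assert res.attrition["selected"] == 21  # fewer than target: all returned


def test_ambiguous_pair_excluded_despite_perfect_fst(planted_fixture):
    res = screen_candidates(planted_fixture, target_size=100)
    kept_pairs = set(zip(res.survivors["ref"], res.survivors["alt"]))
    assert ("A", "T") not in kept_pairs and ("G", "C") not in kept_pairs


def test_screen_is_order_independent(planted_fixture):
    a = screen_candidates(planted_fixture, target_size=10).selected
    shuffled = planted_fixture.sample(frac=1.0, random_state=4)
    b = screen_candidates(shuffled, target_size=10).selected
    pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))


def test_ranking_and_tiering():
    rows = [
        _stats_row(1000, 0.96, fa=0.05, fb=0.97, het_exp=0.2),  # high_fst tier
        _stats_row(3000, 1.0),  # fixed
        _stats_row(5000, 0.97, fa=0.0, fb=1.0, het_exp=0.0),  # fixed, lower fst
    ]
    res = screen_candidates(pd.DataFrame(rows), target_size=2)
    assert list(res.survivors["pos"]) == [3000, 5000, 1000]
    assert list(res.survivors["exclusivity_tier"]) == ["fixed", "fixed", "high_fst"]
    assert list(res.survivors["rank"]) == [1, 2, 3]
    assert list(res.selected["pos"]) == [3000, 5000]
    # red-specific allele oriented to whichever allele is commoner in red
    assert (res.survivors["red_specific_allele"] == res.survivors["alt"]).all()


def test_flank_rule_uses_full_cohort_sites():
    sites = pd.DataFrame([_stats_row(1000, 1.0)])
    cohort = pd.DataFrame([_stats_row(1000, 1.0), _stats_row(1040, 0.1)])
    assert flank_clean_mask(sites, cohort_sites=cohort).tolist() == [False]
    far = pd.DataFrame([_stats_row(1000, 1.0), _stats_row(1051, 0.1)])
    assert flank_clean_mask(sites, cohort_sites=far).tolist() == [True]


def test_noiseless_simulation_selects_only_fixed_tier_with_theta_one():
    cfg = SimulationConfig(
        n_contigs=2,
        contig_length=150_000,
        n_background_sites=0,
        n_diagnostic_sites=150,
        pop_sizes={"sika_ref": 30, "red_ref": 30},
        master_seed=21,
    )
    ref = simulate_reference_pops(cfg)
    stats = site_stats(ref.genotypes, ref.labels)
    res = screen_candidates(stats, target_size=120)
    assert len(res.selected) == 120
    assert (res.selected["exclusivity_tier"] == "fixed").all()
    assert (res.selected["fst"] == 1.0).all()
    # every selected site > 50 bp from every other cohort variant
    allpos = stats.sort_values(["contig", "pos"])
    for _, r in res.selected.iterrows():
        near = allpos[
            (allpos["contig"] == r["contig"])
            & (allpos["pos"] != r["pos"])
            & ((allpos["pos"] - r["pos"]).abs() <= 50)
        ]
        assert near.empty


# ---------------------------------------------------------------------------
# probe contexts


@pytest.fixture
def toy_reference():
    rng = np.random.default_rng(6)
    return {"chrT": "".join("ACGT"[i] for i in rng.integers(0, 4, 4000))}


def test_probe_context_format(toy_reference):
    seq = toy_reference["chrT"]
    pos = 100
    ref_base = seq[pos - 1]
    alt = "A" if ref_base != "A" else "G"
    site = VariantSite("chrT", pos, ref_base, alt)
    ctx = extract_probe_context(toy_reference, site)
    bracket = ctx.index("[")
    assert bracket == 25  # SNP at position 26 of the 51-mer
    unbracketed = ctx[:bracket] + ref_base + ctx[ctx.index("]") + 1 :]
    assert len(unbracketed) == 51
    assert ctx[:25] == seq[pos - 26 : pos - 1].upper()
    assert ctx[ctx.index("]") + 1 :] == seq[pos : pos + 25].upper()


def test_probe_context_edge_and_mismatch_errors(toy_reference):
    seq = toy_reference["chrT"]
    with pytest.raises(ValueError, match="contig edge"):
        extract_probe_context(
            toy_reference, VariantSite("chrT", 10, seq[9], "A" if seq[9] != "A" else "C")
        )
    wrong = "C" if seq[99] != "C" else "G"
    other = "T" if wrong != "T" and seq[99] != "T" else "A"
    with pytest.raises(ValueError, match="mismatch"):
        extract_probe_context(toy_reference, VariantSite("chrT", 100, wrong, other))


def test_export_candidates_multiplier_and_round_trip(tmp_path, toy_reference):
    seq = toy_reference["chrT"]
    rows = []
    for j in range(50):
        pos = 30 + 60 * j
        if pos + 25 > len(seq):
            break
        ref_base = seq[pos - 1]
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref_base]
        rows.append(_stats_row(pos, 1.0, ref=ref_base, alt=alt, contig="chrT"))
    df = pd.DataFrame(rows)
    res = screen_candidates(df, target_size=5)
    out = export_candidates(
        res.survivors, toy_reference, tmp_path / "sub.tsv", target_size=5, multiplier=4
    )
    assert len(out) == 20  # four times the target size
    back = pd.read_csv(tmp_path / "sub.tsv", sep="\t")
    pd.testing.assert_frame_equal(back, out.reset_index(drop=True), check_dtype=False)
    # fewer survivors than the request: export everything
    few = export_candidates(
        res.survivors.head(3), toy_reference, tmp_path / "few.tsv", target_size=5
    )
    assert len(few) == 3


def test_design_score_boundary_and_identity(planted_fixture):
    res = screen_candidates(planted_fixture, target_size=100)
    sel = res.survivors
    key = list(zip(sel["contig"], sel["pos"]))
    scores = pd.Series(1.0, index=pd.MultiIndex.from_tuples(key))
    assert len(apply_design_scores(sel, scores)) == len(sel)  # all pass -> identity
    scores.iloc[0] = 0.59  # strictly below -> removed
    scores.iloc[1] = 0.60  # boundary -> kept
    scores.iloc[2] = np.nan  # unscored -> kept with flag
    out = apply_design_scores(sel, scores)
    assert len(out) == len(sel) - 1
    assert list(out["rank"]) == list(range(1, len(out) + 1))
    assert out["score_missing"].sum() == 1
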