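"""Local branching index, branch ranking, and regional dN/dS enrichment."""

import numpy as np
import pytest

from repevol import coalescent
from repevol.coalescent import SimConfig
from repevol.fitness_dnds import (
    classify_codon_effect,
    codon_effect_single_site,
    lineage_branch_mutations,
    local_branching_index,
    rank_branches_by_fitness_change,
    regional_dnds_enrichment,
    translate_codon,
)
from repevol.genealogy import Genealogy
from repevol.phylo import BranchMutation


def _star_tree(k, b=1.0):
    parent = np.concatenate([np.full(k, k), [-1]]).astype(np.int64)
    blen = np.concatenate([np.full(k, b), [0.0]])
    return Genealogy(parent, blen, k)


def _quadrature_lbi(gen, tau, node, step=1e-4):
    """Independent oracle: integrate exp(-d(x, node)/tau) over every branch
    by brute-force discretization."""
    # distances between nodes via parent walks
    def node_dist(a, b):
        da = {}
        x, d = a, 0.0
        while x >= 0:
            da[x] = d
            d += gen.blen[x]
            x = int(gen.parent[x])
        x, d = b, 0.0
        while x not in da:
            d += gen.blen[x]
            x = int(gen.parent[x])
        return d + da[x]

    total = 0.0
    for v in range(gen.n_nodes):
        if v == gen.root:
            continue
        L = gen.blen[v]
        m = max(1, int(L / step))
        xs = (np.arange(m) + 0.5) * (L / m)
        base = node_dist(v, node)
        # a point at distance x above node v (toward its parent)
        d_through_v = base + xs
        d_through_parent = node_dist(int(gen.parent[v]), node) + (L - xs)
        d = np.minimum(d_through_v, d_through_parent)
        total += np.exp(-d / tau).sum() * (L / m)
    return total


def test_two_leaf_closed_form():
    gen = _star_tree(2, b=0.7)
    tau = 0.3
    ann = local_branching_index(gen, tau=tau)
    e = np.exp(-0.7 / tau)
    expected = tau * (1 - e) + e * tau * (1 - e)
    assert ann.lbi[0] == pytest.approx(expected, rel=1e-12)


def test_lbi_matches_quadrature_on_random_trees():
    rng = np.random.default_rng(3)
    for _ in range(3):
        gen = coalescent.simulate_kingman(SimConfig(n=6, theta=1), rng)
        tau = 0.5
        ann = local_branching_index(gen, tau=tau)
        for node in [0, 3, gen.n_leaves]:
            assert ann.lbi[node] == pytest.approx(
                _quadrature_lbi(gen, tau, node), rel=2e-3
            )


def test_star_tree_leaves_have_equal_lbi():
    gen = _star_tree(6)
    ann = local_branching_index(gen, tau=1.0)
    assert np.allclose(ann.lbi[:6], ann.lbi[0])
    assert np.all(ann.lbi >= 0)


def test_lbi_highest_next_to_bushy_region():
    # caterpillar with a 4-leaf burst at one end: the burst's stem node wins
    #       8
    #      / \
    #     7   5(leaf... build explicitly
    rng = np.random.default_rng(0)
    gen = coalescent.simulate_kingman(SimConfig(n=6, theta=1), rng)
    ann = local_branching_index(gen, tau=0.2)
    below = gen.n_leaves_below()
    # brute-force check: the argmax over all nodes matches quadrature argmax
    vals = [_quadrature_lbi(gen, 0.2, v) for v in range(gen.n_nodes)]
    assert int(np.argmax(ann.lbi)) == int(np.argmax(vals))


def test_lbi_invariant_under_leaf_reordering():
    rng = np.random.default_rng(5)
    gen = coalescent.simulate_kingman(SimConfig(n=8, theta=1), rng)
    ann = local_branching_index(gen, tau=0.4)
    # relabel leaves (labels only; structure unchanged)
    gen2 = Genealogy(gen.parent, gen.blen, gen.n_leaves, leaf_labels=[f"x{i}" for i in range(8)])
    ann2 = local_branching_index(gen2, tau=0.4)
    assert np.allclose(ann.lbi, ann2.lbi)


def test_tau_must_be_positive():
    gen = _star_tree(3)
    with pytest.raises(Exception):
        local_branching_index(gen, tau=-1.0)


# ------------------------------------------------------------------ ranking
def test_dominant_expanding_clade_stem_is_top_ranked():
    # one big recent burst vs scattered singleton leaves
    from repevol.synthetic_data import grafted_sweep_genealogy

    gen = grafted_sweep_genealogy(clade_sizes=(60,), swept_fraction=0.8, rng=1)
    ann = local_branching_index(gen, tau=None)
    top, bottom, flagged = rank_branches_by_fitness_change(gen, ann, k=1)
    below = gen.n_leaves_below()
    assert not flagged
    assert below[top[0]] >= 0.5 * gen.n_leaves  # the swept clade's stem region


def test_rank_ties_broken_deterministically():
    gen = _star_tree(8)
    ann = local_branching_index(gen, tau=1.0)
    t1 = rank_branches_by_fitness_change(gen, ann, k=3)
    t2 = rank_branches_by_fitness_change(gen, ann, k=3)
    assert t1 == t2
    top, bottom, _ = t1
    assert len(top) == len(bottom) == 3


def test_top_and_bottom_disjoint_when_enough_branches():
    rng = np.random.default_rng(6)
    gen = coalescent.simulate_kingman(SimConfig(n=12, theta=1), rng)
    ann = local_branching_index(gen)
    top, bottom, flagged = rank_branches_by_fitness_change(gen, ann, k=3)
    assert not flagged and not (set(top) & set(bottom))


def test_too_few_branches_flagged():
    gen = _star_tree(2)
    ann = local_branching_index(gen, tau=1.0)
    top, bottom, flagged = rank_branches_by_fitness_change(gen, ann, k=3)
    assert flagged


# -------------------------------------------------------------- codon logic
@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("GCT", "GCC", "synonymous"),  # Ala -> Ala
        ("GCT", "GTT", "nonsynonymous"),  # Ala -> Val
        ("GCN", "GTT", "unknown"),
        ("GC-", "GTT", "unknown"),
    ],
)
def test_classify_codon_effect(a, b, expected):
    assert classify_codon_effect(a, b) == expected


def test_single_site_effect_respects_cdr3_boundary(germline_ref):
    g = germline_ref
    lo, hi = g.cdr3_interval
    # a position whose codon overlaps the germline CDR3 segment
    assert codon_effect_single_site(g, lo - 1 if (lo - 1) % 3 != 2 else lo - 2, "A") in (
        "unknown",
        "synonymous",
        "nonsynonymous",
    )
    # positions inside CDR3 always unknown
    assert codon_effect_single_site(g, lo, "A") == "unknown"


def test_translate_codon_matches_standard_code():
    assert translate_codon("ATG") == "M"
    assert translate_codon("TAA") == "*"
    assert translate_codon("ANA") is None


# --------------------------------------------------------------------- dnds
def _muts(region, n_nonsyn, n_syn):
    out = [
        BranchMutation(0, 0, region, "A", "G", "nonsynonymous")
        for _ in range(n_nonsyn)
    ]
    out += [BranchMutation(0, 0, region, "A", "G", "synonymous") for _ in range(n_syn)]
    return out


def test_proportional_distribution_gives_unit_enrichment():
    sets = [_muts("CDR1", 4, 2) + _muts("FWR3", 8, 4) for _ in range(5)]
    res = regional_dnds_enrichment(sets, bootstrap_reps=10, rng=0)
    assert res["CDR1"].enrichment == pytest.approx(1.0)
    assert res["FWR3"].enrichment == pytest.approx(1.0)


def test_cdr_concentrated_nonsynonymous_enriched_fwr_depleted():
    sets = [_muts("CDR1", 9, 1) + _muts("FWR3", 3, 6) for _ in range(6)]
    res = regional_dnds_enrichment(sets, bootstrap_reps=20, rng=0)
    assert res["CDR1"].enrichment > 1
    assert res["FWR3"].enrichment < 1
    assert res["CDR1"].fisher_p < 0.05


def test_zero_synonymous_region_is_undefined():
    sets = [_muts("CDR2", 5, 0) + _muts("FWR1", 2, 3)]
    res = regional_dnds_enrichment(sets, bootstrap_reps=5, rng=0)
    assert np.isnan(res["CDR2"].enrichment)


def test_bootstrap_sd_shrinks_with_more_lineages():
    rng = np.random.default_rng(4)
    def batch(k):
        sets = []
        for _ in range(k):
            sets.append(
                _muts("CDR1", int(rng.integers(2, 8)), int(rng.integers(1, 4)))
                + _muts("FWR3", int(rng.integers(2, 8)), int(rng.integers(1, 4)))
            )
        return regional_dnds_enrichment(sets, bootstrap_reps=60, rng=1)
    sd_small = batch(10)["CDR1"].bootstrap_sd
    sd_big = batch(100)["CDR1"].bootstrap_sd
    assert sd_big < sd_small


def test_lineage_branch_mutation_collection():
    gen = _star_tree(3)
    bm = {0: _muts("CDR1", 1, 0), 1: _muts("FWR1", 0, 1)}
    got = lineage_branch_mutations(gen, bm, [0, 1, 2])
    assert len(got) == 2
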