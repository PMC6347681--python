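"""Alignment anchoring, neighbor joining, germline rooting, Fitch mapping."""

import itertools

import numpy as np
import pytest

from repevol.genealogy import Genealogy
from repevol.phylo import (
    GERMLINE_LABEL,
    align_to_germline,
    build_tree,
    map_mutations_to_branches,
    root_on_germline,
)
from repevol.repertoire_model import Lineage, SequenceRecord, ValidationError
from repevol.synthetic_data import generate_lineage, random_cdr3


@pytest.fixture()
def simple_lineage(germline_ref):
    g = germline_ref
    cdr3 = "TGTGCGAGAGCT"
    base = g.seq[: g.pre_cdr3_len] + cdr3 + g.seq[g.post_cdr3_start :]
    seqs = {"m0": base, "m1": base, "m2": base}
    members = [
        SequenceRecord(k, "S1", "D7", s, g.v_gene, g.j_gene, cdr3)
        for k, s in seqs.items()
    ]
    return Lineage("L1", "S1", members, germline=g)


def _mutate(seq, pos, base=None):
    b = base or ("G" if seq[pos] != "G" else "A")
    return seq[:pos] + b + seq[pos + 1 :]


# ---------------------------------------------------------------- alignment
def test_identical_members_align_as_stacked_rows(simple_lineage):
    aln = align_to_germline(simple_lineage)
    assert len(aln.member_rows) == 3
    assert all(r == aln.germline_row for r in aln.member_rows)


def test_substitutions_appear_at_correct_germline_columns(germline_ref):
    g = germline_ref
    cdr3 = "TGTGCGAGAGCT"
    base = g.seq[: g.pre_cdr3_len] + cdr3 + g.seq[g.post_cdr3_start :]
    mutated = _mutate(_mutate(base, 10), 40)
    members = [
        SequenceRecord("m0", "S1", "D7", base, g.v_gene, g.j_gene, cdr3),
        SequenceRecord("m1", "S1", "D7", mutated, g.v_gene, g.j_gene, cdr3),
    ]
    aln = align_to_germline(Lineage("L1", "S1", members, germline=g))
    diff_cols = [
        c
        for c in range(aln.n_columns)
        if aln.member_rows[1][c] != aln.germline_row[c]
    ]
    assert diff_cols == [10, 40]
    assert [int(aln.column_positions[c]) for c in diff_cols] == [10, 40]


def test_poorly_matching_member_excluded_with_warning(germline_ref):
    g = germline_ref
    cdr3 = "TGTGCGAGAGCT"
    base = g.seq[: g.pre_cdr3_len] + cdr3 + g.seq[g.post_cdr3_start :]
    garbage = ("T" * g.pre_cdr3_len) + cdr3 + ("T" * (len(g.seq) - g.post_cdr3_start))
    members = [
        SequenceRecord("ok", "S1", "D7", base, g.v_gene, g.j_gene, cdr3),
        SequenceRecord("bad", "S1", "D7", garbage, g.v_gene, g.j_gene, cdr3),
    ]
    with pytest.warns(UserWarning, match="bad"):
        aln = align_to_germline(Lineage("L1", "S1", members, germline=g))
    assert aln.member_ids == ["ok"] and aln.excluded == ["bad"]


# --------------------------------------------------------------------- trees
def test_nj_recovers_topology_from_additive_distances(germline_ref):
    """Hand-built additive quartet ((m0,m1),(m2,m3)) with the germline as
    outgroup: the Hamming distances satisfy the four-point condition, so NJ
    must recover both cherries."""
    g = germline_ref
    cdr3 = "TGTGCGAGAGCT"
    base = g.seq[: g.pre_cdr3_len] + cdr3 + g.seq[g.post_cdr3_start :]
    left = base
    for pos in (10, 13, 16, 19, 22):  # shared by the (m0, m1) cherry
        left = _mutate(left, pos)
    right = base
    for pos in (60, 63, 66, 69):  # shared by the (m2, m3) cherry
        right = _mutate(right, pos)
    seqs = [
        _mutate(left, 100),
        _mutate(left, 110),
        _mutate(right, 150),
        _mutate(_mutate(right, 160), 163),
    ]
    g_members = [
        SequenceRecord(f"m{i}", "S1", "D7", s, g.v_gene, g.j_gene, cdr3)
        for i, s in enumerate(seqs)
    ]
    lin = Lineage("L1", "S1", g_members, germline=g)
    tree = root_on_germline(build_tree(align_to_germline(lin), method="nj"))
    clades = [
        frozenset(tree.leaf_labels[u] for u in tree.leaves_below(v))
        for v in range(tree.n_leaves, tree.n_nodes)
    ]
    assert frozenset({"m0", "m1"}) in clades
    assert frozenset({"m2", "m3"}) in clades


def test_identical_sequences_give_zero_member_branches(simple_lineage):
    aln = align_to_germline(simple_lineage)
    tree = build_tree(aln, method="nj")
    assert np.allclose(tree.blen[: tree.n_leaves], 0.0)


def test_import_round_trip_and_orphan_detection(simple_lineage):
    aln = align_to_germline(simple_lineage)
    tree = build_tree(aln, method="nj")
    back = build_tree(aln, method="import", newick=tree.to_newick())
    assert sorted(back.leaf_labels) == sorted(tree.leaf_labels)
    with pytest.raises(ValidationError, match="orphan|match"):
        build_tree(aln, method="import", newick="(a:1,(b:1,c:1):1);")


# ------------------------------------------------------------------- rooting
def test_root_on_germline_makes_germline_child_of_root(simple_lineage, germline_ref, rng):
    lt = generate_lineage("kingman", 6, 4.0, germline_ref, random_cdr3(12, rng), rng=rng)
    aln = align_to_germline(lt.as_lineage(germline_ref))
    tree = build_tree(aln, method="nj")
    rooted = root_on_germline(tree)
    gl = rooted.leaf_labels.index(GERMLINE_LABEL)
    assert int(rooted.parent[gl]) == rooted.root
    assert rooted.n_leaves == tree.n_leaves


def test_root_on_germline_idempotent(simple_lineage):
    aln = align_to_germline(simple_lineage)
    rooted = root_on_germline(build_tree(aln, method="nj"))
    again = root_on_germline(rooted)
    assert np.array_equal(rooted.parent, again.parent)
    assert np.allclose(rooted.blen, again.blen)


def test_missing_germline_raises():
    parent = np.array([2, 2, -1])
    gen = Genealogy(parent, np.ones(3, dtype=float), 2, leaf_labels=["a", "b"])
    with pytest.raises(ValidationError):
        root_on_germline(gen)


# ---------------------------------------------------------------- parsimony
def _tree_and_alignment(germline_ref, seqs, cdr3):
    g = germline_ref
    members = [
        SequenceRecord(f"m{i}", "S1", "D7", s, g.v_gene, g.j_gene, cdr3)
        for i, s in enumerate(seqs)
    ]
    lin = Lineage("L1", "S1", members, germline=g)
    aln = align_to_germline(lin)
    tree = root_on_germline(build_tree(aln, method="nj"))
    return lin, aln, tree


def test_private_mutation_lands_on_terminal_branch(germline_ref):
    g = germline_ref
    cdr3 = "TGTGCGAGAGCT"
    base = g.seq[: g.pre_cdr3_len] + cdr3 + g.seq[g.post_cdr3_start :]
    seqs = [base, base, _mutate(base, 17), _mutate(_mutate(base, 50), 80)]
    lin, aln, tree = _tree_and_alignment(g, seqs, cdr3)
    bm = map_mutations_to_branches(tree, aln, lineage=lin)
    by_leaf = {}
    for v, muts in bm.items():
        for m in muts:
            assert tree.is_leaf(v)
            by_leaf.setdefault(tree.leaf_labels[v], set()).add(m.column)
    assert by_leaf == {"m2": {17}, "m3": {50, 80}}


def test_clade_shared_mutation_on_stem_branch(germline_ref):
    g = germline_ref
    cdr3 = "TGTGCGAGAGCT"
    base = g.seq[: g.pre_cdr3_len] + cdr3 + g.seq[g.post_cdr3_start :]
    shared = _mutate(base, 33)
    # three members carry the shared change plus private ones; three are germline
    seqs = [
        _mutate(shared, 100),
        _mutate(shared, 120),
        _mutate(shared, 140),
        base,
        _mutate(base, 200),
        base,
    ]
    lin, aln, tree = _tree_and_alignment(g, seqs, cdr3)
    bm = map_mutations_to_branches(tree, aln, lineage=lin)
    stem_events = [
        (v, m) for v, muts in bm.items() for m in muts if m.column == 33
    ]
    assert len(stem_events) == 1  # single origin on the clade stem
    v = stem_events[0][0]
    leaves = {tree.leaf_labels[u] for u in tree.leaves_below(v)}
    assert leaves == {"m0", "m1", "m2"}


def test_polymorphic_columns_get_at_least_one_change(germline_ref, rng):
    lt = generate_lineage("kingman", 10, 5.0, germline_ref, random_cdr3(12, rng), rng=rng)
    lin = lt.as_lineage(germline_ref)
    aln = align_to_germline(lin)
    tree = root_on_germline(build_tree(aln, method="nj"))
    bm = map_mutations_to_branches(tree, aln, lineage=lin)
    changed_cols = {m.column for muts in bm.values() for m in muts}
    rows = np.array([np.frombuffer(r.encode(), np.uint8) for r in aln.member_rows])
    germ = np.frombuffer(aln.germline_row.encode(), np.uint8)
    poly = {int(c) for c in range(aln.n_columns) if np.any(rows[:, c] != germ[c])}
    assert poly <= changed_cols


def test_parsimony_reproduces_single_origin_site_counts(germline_ref, rng):
    """When every site has a single origin on the true tree, parsimony on
    the true-tree topology recovers each site exactly once, so per-branch
    counts reproduce the SFS."""
    from repevol.sfs import build_sfs

    lt = generate_lineage("kingman", 12, 4.0, germline_ref, random_cdr3(12, rng), rng=rng)
    lin = lt.as_lineage(germline_ref)
    aln = align_to_germline(lin)
    # import the true genealogy (true topology) instead of NJ
    true = lt.genealogy
    # graft a germline outgroup onto the true tree root
    n = true.n_nodes
    # new leaf 0 = germline, old ids shift by 1, new root at the end
    parent = np.empty(n + 2, dtype=np.int64)
    blen = np.empty(n + 2)
    parent[0] = n + 1
    blen[0] = 0.0
    for v in range(n):
        p = true.parent[v]
        parent[v + 1] = (p + 1) if p >= 0 else (n + 1)
        blen[v + 1] = true.blen[v]
    parent[n + 1] = -1
    blen[n + 1] = 0.0
    labels = [GERMLINE_LABEL] + list(true.leaf_labels)
    grafted = Genealogy(parent, blen, true.n_leaves + 1, labels)
    bm = map_mutations_to_branches(grafted, aln, lineage=lin)
    per_site = {}
    for muts in bm.values():
        for m in muts:
            per_site[(m.column, m.to_base)] = per_site.get((m.column, m.to_base), 0) + 1
    # single origin per site
    assert all(v == 1 for v in per_site.values())
    assert len(per_site) == build_sfs(lin).S + build_sfs(lin).fixed
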