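"""Abundance trajectories, dynamics classification, gene-usage enrichment."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy.special import comb

from repevol.dynamics import (
    AbundanceTrajectory,
    DynamicsThresholds,
    INFINITE,
    abundance_trajectories,
    classify_lineages,
    fold_change,
    fractional_abundance,
    gene_usage_enrichment,
    mutation_density,
    repertoire_totals,
)
from repevol.repertoire_model import Lineage, SequenceRecord, ValidationError


def _rec(i, subj="S1", tp="D0", cdr3="TGTGCGAGAGCT", v="V1", j="J1"):
    seq = "ACG" * 10 + cdr3 + "TTTGGG"
    return SequenceRecord(f"q{i}", subj, tp, seq, v, j, cdr3)


def _traj(counts, fractions):
    return AbundanceTrajectory("L", "S1", counts, fractions)


# ---------------------------------------------------------------- abundance
def test_fractional_abundance_is_count_over_total():
    records = [_rec(i, tp="D7") for i in range(100)]
    lin = Lineage("L1", "S1", records[:5])
    totals = repertoire_totals(records)
    assert fractional_abundance(lin, "D7", totals) == pytest.approx(0.05)


def test_unobserved_lineage_has_zero_abundance():
    records = [_rec(i, tp="D7") for i in range(10)]
    lin = Lineage("L1", "S1", [_rec(99, tp="D0")])
    totals = repertoire_totals(records + [lin.members[0]])
    assert fractional_abundance(lin, "D7", totals) == 0.0


def test_absent_timepoint_raises():
    records = [_rec(0, tp="D7")]
    lin = Lineage("L1", "S1", records)
    with pytest.raises(ValidationError):
        fractional_abundance(lin, "D3", repertoire_totals(records))


def test_fractions_sum_to_one_across_lineages(tiny_bundle):
    from repevol.lineage_clustering import cluster_repertoire

    lins = cluster_repertoire(tiny_bundle.records)
    trajs = abundance_trajectories(lins, tiny_bundle.records)
    totals = repertoire_totals(tiny_bundle.records)
    for subj in {"S1", "S2"}:
        for tp in {t for (s, t) in totals if s == subj}:
            tot = sum(
                t.fraction(tp) for t in trajs.values() if t.subject == subj
            )
            assert tot == pytest.approx(1.0)


# --------------------------------------------------------------- fold change
@pytest.mark.parametrize(
    "f0,f1,expected",
    [(0.001, 0.06, 60.0), (0.01, 0.01, 1.0), (0.01, 0.0, 0.0)],
)
def test_fold_change_finite_cases(f0, f1, expected):
    t = _traj({}, {"D0": f0, "D7": f1})
    assert fold_change(t, "D0", "D7") == pytest.approx(expected)


def test_fold_change_infinite_when_absent_at_baseline():
    t = _traj({}, {"D0": 0.0, "D7": 0.002})
    assert fold_change(t, "D0", "D7") == INFINITE


def test_fold_change_undefined_when_both_zero():
    t = _traj({}, {"D0": 0.0, "D7": 0.0})
    assert math.isnan(fold_change(t, "D0", "D7"))


# ------------------------------------------------------------ classification
def _label_for(f0, f1, d7_count=200):
    t = _traj({"D7": d7_count}, {"D0": f0, "D7": f1})
    return classify_lineages({"L": t})["L"].label


def test_infinite_fc_is_vaccine_responsive():
    assert _label_for(0.0, 0.01) == "vaccine_responsive"


def test_low_fc_high_abundance_is_persistent():
    assert _label_for(0.004 / 1.1, 0.004) == "persistent"


def test_intermediate_fc_is_other():
    assert _label_for(0.0002, 0.002) == "other"


def test_labels_partition_and_are_deterministic(rng):
    trajs = {}
    for i in range(200):
        f0 = float(rng.random() * 0.01) if rng.random() > 0.3 else 0.0
        f1 = float(rng.random() * 0.01)
        trajs[f"L{i}"] = _traj({"D7": 10}, {"D0": f0, "D7": f1})
    labels = classify_lineages(trajs)
    assert set(labels) == set(trajs)
    again = classify_lineages(trajs)
    for k in labels:
        assert labels[k].label == again[k].label
        th = DynamicsThresholds()
        fc = labels[k].fold_change_d0_d7
        if fc > th.responsive_fold:
            assert labels[k].label == "vaccine_responsive"


# ------------------------------------------------------------- fisher oracle
def _fisher_two_sided(a, b, c, d):
    """Exhaustive hypergeometric enumeration of the two-sided exact test."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    def prob(x):
        return (
            comb(col1, x, exact=True)
            * comb(n - col1, row1 - x, exact=True)
            / comb(n, row1, exact=True)
        )
    p_obs = prob(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(p for x in range(lo, hi + 1) if (p := prob(x)) <= p_obs * (1 + 1e-12))


def test_gene_usage_enrichment_matches_hand_enumeration():
    # 3 of 10 in-set lineages use the gene; 10 of 190 background
    lins = []
    for i in range(10):
        lins.append(Lineage(f"in{i}", "S1", [_rec(i, v="Vx" if i < 3 else f"V{i}")]))
    for i in range(190):
        lins.append(
            Lineage(f"bg{i}", "S1", [_rec(100 + i, v="Vx" if i < 10 else f"W{i}")])
        )
    res = gene_usage_enrichment(lins, {f"in{i}" for i in range(10)}, gene="v")
    fold, p = res["Vx"]
    assert fold == pytest.approx((3 / 10) / (10 / 190))
    assert p == pytest.approx(_fisher_two_sided(3, 7, 10, 180), rel=1e-9)


def test_fisher_matches_enumeration_on_small_margins():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a, b, c, d = (int(rng.integers(0, 9)) for _ in range(4))
        if (a + c) == 0 or (a + b) == 0 or (c + d) == 0:
            continue
        from scipy.stats import fisher_exact

        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        assert p == pytest.approx(_fisher_two_sided(a, b, c, d), rel=1e-9)


def test_identical_usage_gives_unit_enrichment():
    lins = [Lineage(f"A{i}", "S1", [_rec(i, v="V1" if i % 2 else "V2")]) for i in range(8)]
    res = gene_usage_enrichment(lins, {"A0", "A1", "A2", "A3"}, gene="v")
    assert res["V1"][0] == pytest.approx(1.0)


def test_gene_absent_from_both_sets_excluded():
    lins = [Lineage(f"A{i}", "S1", [_rec(i, v="V1")]) for i in range(6)]
    res = gene_usage_enrichment(lins, {"A0", "A1"}, gene="v")
    assert set(res) == {"V1"}


# --------------------------------------------------------- mutation density
def test_mutation_density_examples(germline_ref):
    from repevol.synthetic_data import generate_lineage, random_cdr3

    rng = np.random.default_rng(4)
    lt = generate_lineage("kingman", 3, 1e-9, germline_ref, random_cdr3(12, rng), rng=rng)
    rec = lt.records[0]
    assert mutation_density(rec, germline_ref) == 0.0
    # introduce 5 mismatches in the V part
    seq = list(rec.nucleotide_seq)
    for k in range(5):
        pos = 3 * k
        seq[pos] = "A" if seq[pos] != "A" else "C"
    mutated = SequenceRecord(
        "m", rec.subject, rec.timepoint, "".join(seq), rec.v_gene, rec.j_gene, rec.cdr3_nt
    )
    assert mutation_density(mutated, germline_ref) == pytest.approx(
        5 / germline_ref.pre_cdr3_len
    )
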