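"""Domain types and file I/O: round trips, skip accounting, validation."""

import numpy as np
import pytest

from repevol import coalescent
from repevol.genealogy import Genealogy
from repevol.repertoire_model import (
    ConfigurationError,
    GermlineReference,
    Lineage,
    SequenceRecord,
    ValidationError,
    read_germline_fasta,
    read_newick,
    read_repertoire_table,
    write_lineage_fasta,
    write_newick,
    write_repertoire_table,
    write_results_table,
    read_results_table,
)

HEADER = "sequence_id\tsubject\ttimepoint\tsequence\tv_call\tj_call\tjunction\tisotype\n"


def _row(i, cdr3="TGTGCGAGA", iso="IgM", subj="S1", tp="D0"):
    seq = "ACGT" * (8 + i) + cdr3 + "GGGTTT"
    return f"r{i}\t{subj}\t{tp}\t{seq}\t{'V1'}\t{'J1'}\t{cdr3}\t{iso}\n"


def test_empty_table_gives_empty_list_and_zero_skips(tmp_path):
    p = tmp_path / "t.tsv"
    p.write_text(HEADER)
    records, skip = read_repertoire_table(p)
    assert records == []
    assert all(v == 0 for v in skip.values())


def test_well_formed_rows_preserve_fields_verbatim(tmp_path):
    p = tmp_path / "t.tsv"
    p.write_text(HEADER + "".join(_row(i, tp=f"D{i}") for i in range(3)))
    records, skip = read_repertoire_table(p)
    assert len(records) == 3
    r = records[1]
    assert (r.sequence_id, r.subject, r.timepoint) == ("r1", "S1", "D1")
    assert r.v_gene == "V1" and r.j_gene == "J1" and r.isotype == "IgM"
    assert r.cdr3_nt in r.nucleotide_seq


def test_rows_missing_cdr3_are_dropped_and_counted(tmp_path):
    rows = [_row(0), _row(1), _row(2)]
    rows.append("r3\tS1\tD0\tACGTACGT\tV1\tJ1\t\tIgM\n")
    rows.append("r4\tS1\tD0\tACGTACGT\tV1\tJ1\t\tIgM\n")
    p = tmp_path / "t.tsv"
    p.write_text(HEADER + "".join(rows))
    records, skip = read_repertoire_table(p)
    assert len(records) == 3
    assert skip["missing_cdr3"] == 2


def test_skip_counts_plus_records_conserve_row_count(tmp_path):
    rows = [_row(i, tp="D0") for i in range(4)]
    rows.append("x\tS1\tD0\tACGT\tV1\t\tACG\tIgM\n")  # missing J
    rows.append(_row(0))  # duplicate of row 0 (same subject/timepoint/seq)
    p = tmp_path / "t.tsv"
    p.write_text(HEADER + "".join(rows))
    records, skip = read_repertoire_table(p)
    assert len(records) + sum(skip.values()) == 6


def test_missing_required_column_names_the_column(tmp_path):
    p = tmp_path / "t.tsv"
    p.write_text("sequence_id\tsubject\ttimepoint\tsequence\tj_call\tjunction\nx\ta\tb\tACGT\tJ1\tAC\n")
    with pytest.raises(ConfigurationError, match="v_gene"):
        read_repertoire_table(p)


def test_repertoire_table_round_trip(tmp_path, tiny_bundle):
    p = tmp_path / "t.tsv"
    records = tiny_bundle.records[:100]
    write_repertoire_table(records, p)
    back, _ = read_repertoire_table(p, collapse_duplicates=False)
    assert back == records


def test_sequence_record_validation():
    with pytest.raises(ValidationError):
        SequenceRecord("a", "S", "D0", "", "V", "J", "")
    with pytest.raises(ValidationError):
        SequenceRecord("a", "S", "D0", "ACGTX", "V", "J", "")
    with pytest.raises(ValidationError):
        SequenceRecord("a", "S", "D0", "ACGT", "V", "J", "TTT")


# ------------------------------------------------------------------ germline
def _write_germline(tmp_path, v_intervals):
    v = tmp_path / "v.fasta"
    j = tmp_path / "j.fasta"
    bed = tmp_path / "regions.bed"
    v.write_text(">V1\n" + "ACGTAA" * 5 + "\n")  # 30 nt
    j.write_text(">J1\n" + "ACG" * 4 + "\n")  # 12 nt
    lines = [f"V1\t{s}\t{e}\t{r}" for r, s, e in v_intervals]
    lines += ["J1\t0\t3\tCDR3", "J1\t3\t12\tFWR4"]
    bed.write_text("\n".join(lines) + "\n")
    return v, j, bed


def test_germline_region_map_covers_reference(tmp_path):
    ivals = [("FWR1", 0, 10), ("CDR1", 10, 16), ("FWR2", 16, 20),
             ("CDR2", 20, 24), ("FWR3", 24, 27), ("CDR3", 27, 30)]
    v, j, bed = _write_germline(tmp_path, ivals)
    refs = read_germline_fasta(v, j, bed)
    ref = refs[("V1", "J1")]
    assert ref.region_map.size == 42
    assert ref.region_of(0) == "FWR1" and ref.region_of(41) == "FWR4"
    assert ref.cdr3_interval == (27, 33)


def test_overlapping_region_intervals_rejected(tmp_path):
    ivals = [("FWR1", 0, 10), ("CDR1", 9, 30)]
    v, j, bed = _write_germline(tmp_path, ivals)
    with pytest.raises(ValidationError, match="V1"):
        read_germline_fasta(v, j, bed)


def test_gapped_region_intervals_rejected(tmp_path):
    ivals = [("FWR1", 0, 10), ("CDR1", 12, 30)]
    v, j, bed = _write_germline(tmp_path, ivals)
    with pytest.raises(ValidationError, match="gap"):
        read_germline_fasta(v, j, bed)


def test_generated_germline_round_trips_through_write_read(tmp_path, germline_db):
    v, j, bed = tmp_path / "v.fasta", tmp_path / "j.fasta", tmp_path / "r.bed"
    germline_db.write(v, j, bed)
    refs = read_germline_fasta(v, j, bed)
    ref = refs[("SVH01", "SJH01")]
    orig = germline_db.reference("SVH01", "SJH01")
    assert ref.seq == orig.seq
    assert np.array_equal(ref.region_map, orig.region_map)


# ------------------------------------------------------------------- writers
def test_lineage_fasta_has_germline_first(tmp_path, germline_ref, rng):
    from repevol.synthetic_data import generate_lineage, random_cdr3

    lt = generate_lineage("kingman", 4, 2.0, germline_ref, random_cdr3(12, rng), rng=rng)
    lin = lt.as_lineage(germline_ref)
    p = tmp_path / "lin.fasta"
    write_lineage_fasta(lin, p)
    from Bio import SeqIO

    recs = list(SeqIO.parse(str(p), "fasta"))
    assert len(recs) == 5
    assert recs[0].id == "germline"


def test_newick_round_trip_preserves_topology_and_lengths(tmp_path, rng):
    gen = coalescent.simulate_kingman(coalescent.SimConfig(n=5, theta=1), rng)
    p = tmp_path / "t.nwk"
    write_newick(gen, p)
    back = read_newick(p)
    assert sorted(back.leaf_labels) == sorted(gen.leaf_labels)
    # compare leaf-to-leaf path lengths (topology+lengths invariant)
    def dists(g):
        d = g.depths()
        out = {}
        for a in range(g.n_leaves):
            for b in range(a + 1, g.n_leaves):
                # lca via parent walks
                anc = set()
                x = a
                while x >= 0:
                    anc.add(x)
                    x = int(g.parent[x])
                x = b
                while x not in anc:
                    x = int(g.parent[x])
                out[(g.leaf_labels[a], g.leaf_labels[b])] = d[a] + d[b] - 2 * d[x]
        return out
    da, db = dists(gen), dists(back)
    for k, v in da.items():
        kk = k if k in db else (k[1], k[0])
        assert db[kk] == pytest.approx(v, rel=1e-6)


def test_results_table_round_trip(tmp_path):
    rows = [{"a": "1", "b": "x"}, {"a": "2", "b": "y"}]
    p = tmp_path / "r.tsv"
    write_results_table(rows, p)
    assert read_results_table(p) == rows
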