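"""Clonal lineage identification.

Sequences descending from the same naive B-cell ancestor share their V and J
germline genes and their CDR3 length, so clustering proceeds in two stages:
records are first partitioned by the (v_gene, j_gene, CDR3 length) key, and
each group is then split into lineages by single-linkage clustering at a
nucleotide-identity cutoff (default 90%).  Identity can be measured on the
CDR3 alone or on the concatenation of CDR3 and the rest of the variable
region (the default; when both are stated the concatenation is the
implemented reading).  Ties at exactly the cutoff count as linked.

Clustering is exact: all pairs within a group are compared (no k-mer
screening), and the single-linkage components come from a union-find over
the threshold graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .repertoire_model import Lineage, SequenceRecord, ValidationError


@dataclass
class ClusterConfig:
    identity_cutoff: float = 0.90
    metric_scope: str = "cdr3_plus_variable"  # or "cdr3_only"

    def __post_init__(self):
        if not (0 < self.identity_cutoff <= 1):
            raise ValidationError("identity_cutoff must be in (0, 1]")
        if self.metric_scope not in ("cdr3_only", "cdr3_plus_variable"):
            raise ValidationError(f"unknown metric_scope {self.metric_scope!r}")


def partition_by_vj_cdr3len(
    records: list[SequenceRecord],
) -> list[list[SequenceRecord]]:
    """Group records into equivalence classes of (v_gene, j_gene, len(cdr3))."""
    groups: dict[tuple[str, str, int], list[SequenceRecord]] = {}
    for r in records:
        groups.setdefault((r.v_gene, r.j_gene, len(r.cdr3_nt)), []).append(r)
    return [groups[k] for k in sorted(groups)]


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValidationError(
            f"pairwise identity requires equal lengths ({len(a)} vs {len(b)})"
        )
    if len(a) == 0:
        raise ValidationError("empty sequences")
    matches = sum(x == y for x, y in zip(a, b))
    return matches / len(a)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _comparison_string(record: SequenceRecord, scope: str) -> str:
    if scope == "cdr3_only":
        return record.cdr3_nt
    # CDR3 concatenated with the rest of the variable region.  Records in a
    # group share CDR3 length; the non-CDR3 remainder is compared on its
    # common prefix/suffix around the junction so unequal trailing bases do
    # not abort the comparison.
    s = record.nucleotide_seq
    i = s.find(record.cdr3_nt)
    return record.cdr3_nt + s[:i] + s[i + len(record.cdr3_nt) :]


def single_linkage_cluster(
    group: list[SequenceRecord],
    config: ClusterConfig = ClusterConfig(),
    subject: str | None = None,
    lineage_prefix: str = "L",
) -> list[Lineage]:
    """Single-linkage clusters of one (V, J, CDR3-length) group.

    Two records end up in the same lineage iff they are connected by a chain
    of pairs each with identity >= the cutoff on the configured scope.
    """
    if not group:
        return []
    subj = subject if subject is not None else group[0].subject
    strings = [_comparison_string(r, config.metric_scope) for r in group]
    # records whose comparison strings differ in length (ragged non-CDR3
    # parts) are compared on the overlap of their common length
    uf = _UnionFind(len(group))
    arrs = [np.frombuffer(s.encode(), dtype=np.uint8) for s in strings]
    for i in range(len(group)):
        ai = arrs[i]
        for j in range(i + 1, len(group)):
            aj = arrs[j]
            L = min(ai.size, aj.size)
            ident = float(np.count_nonzero(ai[:L] == aj[:L])) / L
            if ident >= config.identity_cutoff:
                uf.union(i, j)
    comps: dict[int, list[SequenceRecord]] = {}
    for i, r in enumerate(group):
        comps.setdefault(uf.find(i), []).append(r)
    key = (group[0].v_gene, group[0].j_gene, len(group[0].cdr3_nt))
    lineages = []
    for c, members in enumerate(sorted(comps.values(), key=lambda ms: ms[0].sequence_id)):
        lid = f"{lineage_prefix}_{subj}_{key[0]}_{key[1]}_{key[2]}_{c}"
        lineages.append(Lineage(lineage_id=lid, subject=subj, members=members))
    return lineages


def cluster_repertoire(
    records: list[SequenceRecord], config: ClusterConfig = ClusterConfig()
) -> list[Lineage]:
    """Full clustering: per subject, partition by germline key then
    single-linkage within each group.  Lineages never cross subjects."""
    by_subject: dict[str, list[SequenceRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject, []).append(r)
    out: list[Lineage] = []
    for subj in sorted(by_subject):
        for group in partition_by_vj_cdr3len(by_subject[subj]):
            out.extend(single_linkage_cluster(group, config, subject=subj))
    return out


def lineage_assignment(lineages: list[Lineage]) -> dict[str, str]:
    """Map sequence_id -> lineage_id (for appending to a repertoire table)."""
    out: dict[str, str] = {}
    for lin in lineages:
        for m in lin.members:
            out[m.sequence_id] = lin.lineage_id
    return out
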