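"""Core domain types and readers/writers for repertoire analyses.

Data model
----------
A repertoire is a table of unique B-cell receptor sequences, one row per
unique sequence observed in one subject at one timepoint, annotated with the
germline V and J gene calls, the CDR3 junction and the isotype — the
AIRR-Rearrangement style of table produced by upstream annotation tools.

The germline coordinate system used throughout the package concatenates the
V gene and the J gene into a single reference axis.  Region labels (FWR1,
CDR1, FWR2, CDR2, FWR3, CDR3, FWR4) tile this axis contiguously; the
germline-encoded CDR3 segment (the V flank followed by the J flank) marks
where each lineage's junction replaces the reference.  In an observed
sequence the lineage-specific CDR3 junction sits between the V part (all
reference positions before the CDR3 region) and the J part (all reference
positions after it).  All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

REGIONS = ("FWR1", "CDR1", "FWR2", "CDR2", "FWR3", "CDR3", "FWR4")
ISOTYPES = ("IgM", "IgD", "IgG", "IgA", "IgE", "unknown")
DNA_ALPHABET = frozenset("ACGTN")

#: Timepoint labels of a pre/post vaccination study design: two
#: pre-vaccination bleeds, the day of vaccination, and five follow-ups.
DEFAULT_TIMEPOINTS = ("D-5", "D-3", "D0", "D1", "D4", "D7", "D9", "D11")


class ConfigurationError(ValueError):
    """A required column or configuration item is missing or inconsistent."""


class ValidationError(ValueError):
    """Input data violates a structural invariant."""


# --------------------------------------------------------------------- types
@dataclass(frozen=True)
class SequenceRecord:
    """One unique observed receptor sequence with its annotations."""

    sequence_id: str
    subject: str
    timepoint: str
    nucleotide_seq: str
    v_gene: str
    j_gene: str
    cdr3_nt: str
    isotype: str = "unknown"

    def __post_init__(self):
        if not self.nucleotide_seq:
            raise ValidationError(f"{self.sequence_id}: empty nucleotide_seq")
        bad = set(self.nucleotide_seq) - DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"{self.sequence_id}: non-ACGTN characters {sorted(bad)}"
            )
        if self.cdr3_nt and self.cdr3_nt not in self.nucleotide_seq:
            raise ValidationError(
                f"{self.sequence_id}: cdr3_nt is not a substring of nucleotide_seq"
            )


@dataclass
class GermlineReference:
    """Personalized germline V+J reference with region annotations.

    ``seq`` is the concatenated V and J gene sequence; ``region_map`` assigns
    one of the seven regions to every position, tiling the axis contiguously
    in order FWR1..FWR4.  ``v_len`` marks where the J gene starts on the axis.
    """

    v_gene: str
    j_gene: str
    v_seq: str
    j_seq: str
    region_map: np.ndarray  # int8 indices into REGIONS, length len(v_seq)+len(j_seq)
    reading_frame: int = 0

    def __post_init__(self):
        self.region_map = np.asarray(self.region_map, dtype=np.int8)
        if self.reading_frame not in (0, 1, 2):
            raise ValidationError("reading_frame must be 0, 1 or 2")
        n = len(self.v_seq) + len(self.j_seq)
        if self.region_map.size != n:
            raise ValidationError(
                f"{self.v_gene}/{self.j_gene}: region_map length {self.region_map.size}"
                f" != reference length {n}"
            )
        # contiguous tiling in REGIONS order
        diffs = np.diff(self.region_map.astype(int))
        if np.any(diffs < 0) or np.any(diffs > 1):
            raise ValidationError(
                f"{self.v_gene}/{self.j_gene}: regions must tile contiguously "
                "in order FWR1..FWR4"
            )

    @property
    def seq(self) -> str:
        return self.v_seq + self.j_seq

    @property
    def v_len(self) -> int:
        return len(self.v_seq)

    def region_of(self, pos: int) -> str:
        return REGIONS[self.region_map[pos]]

    def region_interval(self, region: str) -> tuple[int, int]:
        """0-based half-open interval of a region on the reference axis."""
        idx = REGIONS.index(region)
        where = np.flatnonzero(self.region_map == idx)
        if where.size == 0:
            return (0, 0)
        return (int(where[0]), int(where[-1]) + 1)

    @property
    def cdr3_interval(self) -> tuple[int, int]:
        return self.region_interval("CDR3")

    @property
    def pre_cdr3_len(self) -> int:
        """Length of the reference before the germline CDR3 segment (the V part)."""
        return self.cdr3_interval[0]

    @property
    def post_cdr3_start(self) -> int:
        return self.cdr3_interval[1]


@dataclass
class Lineage:
    """A clonal family: members plus the personalized germline reference."""

    lineage_id: str
    subject: str
    members: list[SequenceRecord]
    germline: GermlineReference | None = None
    v_gene: str = ""
    j_gene: str = ""
    cdr3_length: int = -1

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"{self.lineage_id}: lineage must be nonempty")
        if not self.v_gene:
            self.v_gene = self.members[0].v_gene
        if not self.j_gene:
            self.j_gene = self.members[0].j_gene
        if self.cdr3_length < 0:
            self.cdr3_length = len(self.members[0].cdr3_nt)
        for m in self.members:
            if (
                m.v_gene != self.v_gene
                or m.j_gene != self.j_gene
                or len(m.cdr3_nt) != self.cdr3_length
            ):
                raise ValidationError(
                    f"{self.lineage_id}: member {m.sequence_id} does not share "
                    "the lineage's V/J/CDR3-length key"
                )

    def __len__(self) -> int:
        return len(self.members)

    def germline_with_cdr3(self, cdr3: str | None = None) -> str:
        """Germline sequence with the lineage junction in place of the
        reference CDR3 segment (used as the ancestral sequence for trees).

        By default the lineage's most common member CDR3 is used.
        """
        if self.germline is None:
            raise ValidationError(f"{self.lineage_id}: no germline reference")
        if cdr3 is None:
            counts: dict[str, int] = {}
            for m in self.members:
                counts[m.cdr3_nt] = counts.get(m.cdr3_nt, 0) + 1
            cdr3 = max(sorted(counts), key=lambda c: counts[c])
        g = self.germline
        return g.seq[: g.pre_cdr3_len] + cdr3 + g.seq[g.post_cdr3_start :]


# ------------------------------------------------------------------- readers
#: default mapping from SequenceRecord fields to AIRR-style column names;
#: each value is a tuple of accepted aliases, first match wins.
DEFAULT_COLUMNS: dict[str, tuple[str, ...]] = {
    "sequence_id": ("sequence_id",),
    "subject": ("subject", "subject_id"),
    "timepoint": ("timepoint", "time_point", "sample_time"),
    "nucleotide_seq": ("sequence", "nucleotide_seq"),
    "v_gene": ("v_call", "v_gene"),
    "j_gene": ("j_call", "j_gene"),
    "cdr3_nt": ("junction", "cdr3", "cdr3_nt"),
    "isotype": ("isotype", "c_call"),
}


def read_repertoire_table(
    path: str | os.PathLike,
    column_config: dict[str, str] | None = None,
    collapse_duplicates: bool = True,
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Read an AIRR-Rearrangement-style TSV into SequenceRecords.

    Rows missing a V call, J call or CDR3 are dropped and counted in the
    returned skip report.  When ``collapse_duplicates`` is set, rows with
    identical (subject, timepoint, nucleotide_seq) are merged, keeping the
    first row's id; the number of merged rows is reported under
    ``duplicate_collapsed``.

    Returns
    -------
    (records, skip_report)
    """
    overrides = column_config or {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ConfigurationError(f"{path}: empty file, no header")
        header = set(reader.fieldnames)
        colmap: dict[str, str] = {}
        for fieldname, aliases in DEFAULT_COLUMNS.items():
            if fieldname in overrides:
                cand = (overrides[fieldname],)
            else:
                cand = aliases
            col = next((c for c in cand if c in header), None)
            if col is None:
                if fieldname == "isotype":
                    continue  # optional
                raise ConfigurationError(
                    f"{path}: missing required column for '{fieldname}' "
                    f"(accepted: {', '.join(cand)})"
                )
            colmap[fieldname] = col
        skip = {
            "missing_v_gene": 0,
            "missing_j_gene": 0,
            "missing_cdr3": 0,
            "invalid_sequence": 0,
            "duplicate_collapsed": 0,
        }
        records: list[SequenceRecord] = []
        seen: dict[tuple[str, str, str], int] = {}
        for row in reader:
            v = (row.get(colmap["v_gene"]) or "").strip()
            j = (row.get(colmap["j_gene"]) or "").strip()
            cdr3 = (row.get(colmap["cdr3_nt"]) or "").strip().upper()
            if not v:
                skip["missing_v_gene"] += 1
                continue
            if not j:
                skip["missing_j_gene"] += 1
                continue
            if not cdr3:
                skip["missing_cdr3"] += 1
                continue
            iso = "unknown"
            if "isotype" in colmap:
                iso = (row.get(colmap["isotype"]) or "unknown").strip() or "unknown"
            try:
                rec = SequenceRecord(
                    sequence_id=(row.get(colmap["sequence_id"]) or "").strip(),
                    subject=(row.get(colmap["subject"]) or "").strip(),
                    timepoint=(row.get(colmap["timepoint"]) or "").strip(),
                    nucleotide_seq=(row.get(colmap["nucleotide_seq"]) or "")
                    .strip()
                    .upper(),
                    v_gene=v,
                    j_gene=j,
                    cdr3_nt=cdr3,
                    isotype=iso if iso in ISOTYPES else "unknown",
                )
            except ValidationError:
                skip["invalid_sequence"] += 1
                continue
            if collapse_duplicates:
                key = (rec.subject, rec.timepoint, rec.nucleotide_seq)
                if key in seen:
                    skip["duplicate_collapsed"] += 1
                    continue
                seen[key] = 1
            records.append(rec)
    return records, skip


def write_repertoire_table(records: list[SequenceRecord], path: str | os.PathLike):
    """Write SequenceRecords as an AIRR-style TSV (inverse of the reader)."""
    cols = [
        "sequence_id",
        "subject",
        "timepoint",
        "sequence",
        "v_call",
        "j_call",
        "junction",
        "isotype",
    ]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for r in records:
            w.writerow(
                [
                    r.sequence_id,
                    r.subject,
                    r.timepoint,
                    r.nucleotide_seq,
                    r.v_gene,
                    r.j_gene,
                    r.cdr3_nt,
                    r.isotype,
                ]
            )


def read_region_bed(path: str | os.PathLike) -> dict[str, list[tuple[str, int, int]]]:
    """Read a BED-like file of 0-based half-open region intervals per gene."""
    out: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, start, end, region = line.split("\t")[:4]
            out.setdefault(gene, []).append((region, int(start), int(end)))
    return out


def _build_region_map(
    gene: str, length: int, intervals: list[tuple[str, int, int]]
) -> np.ndarray:
    rmap = np.full(length, -1, dtype=np.int8)
    for region, start, end in intervals:
        if region not in REGIONS:
            raise ValidationError(f"{gene}: unknown region {region}")
        if start < 0 or end > length or start >= end:
            raise ValidationError(f"{gene}: bad interval [{start},{end})")
        if np.any(rmap[start:end] >= 0):
            raise ValidationError(f"{gene}: overlapping region intervals at {region}")
        rmap[start:end] = REGIONS.index(region)
    if np.any(rmap < 0):
        raise ValidationError(f"{gene}: region intervals leave gaps")
    return rmap


def read_germline_fasta(
    v_path: str | os.PathLike,
    j_path: str | os.PathLike,
    region_bed: str | os.PathLike,
) -> dict[tuple[str, str], GermlineReference]:
    """Load germline V and J FASTAs plus region annotations.

    Every (v_gene, j_gene) combination present in the FASTAs yields one
    GermlineReference whose region map covers the concatenated V+J axis.
    Genes without region annotation are rejected.
    """
    regions = read_region_bed(region_bed)
    v_recs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(v_path), "fasta")}
    j_recs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(j_path), "fasta")}
    out: dict[tuple[str, str], GermlineReference] = {}
    for vg, vseq in v_recs.items():
        if vg not in regions:
            raise ValidationError(f"V gene {vg} has no region annotation")
        vmap = _build_region_map(vg, len(vseq), regions[vg])
        for jg, jseq in j_recs.items():
            if jg not in regions:
                raise ValidationError(f"J gene {jg} has no region annotation")
            jmap = _build_region_map(jg, len(jseq), regions[jg])
            out[(vg, jg)] = GermlineReference(
                v_gene=vg,
                j_gene=jg,
                v_seq=vseq,
                j_seq=jseq,
                region_map=np.concatenate([vmap, jmap]),
                reading_frame=0,
            )
    return out


# ------------------------------------------------------------------- writers
def write_lineage_fasta(lineage: Lineage, path: str | os.PathLike) -> None:
    """Write a lineage as FASTA with the germline first (id ``germline``)."""
    recs = []
    if lineage.germline is not None:
        recs.append(
            BioSeqRecord(
                Seq(lineage.germline_with_cdr3()), id="germline", description=""
            )
        )
    for m in lineage.members:
        recs.append(BioSeqRecord(Seq(m.nucleotide_seq), id=m.sequence_id, description=""))
    SeqIO.write(recs, str(path), "fasta")


def write_newick(genealogy, path: str | os.PathLike, precision: int = 10) -> None:
    """Write a genealogy as Newick, branch lengths to >= 6 significant digits."""
    with open(path, "w") as fh:
        fh.write(genealogy.to_newick(precision=max(6, precision)))
        fh.write("\n")


def read_newick(path: str | os.PathLike):
    from .genealogy import Genealogy

    with open(path) as fh:
        return Genealogy.from_newick(fh.read())


def write_results_table(rows: list[dict], path: str | os.PathLike) -> None:
    """Write a list of homogeneous dict rows as a TSV."""
    if not rows:
        with open(path, "w") as fh:
            fh.write("\n")
        return
    cols = list(rows[0].keys())
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols, delimiter="\t", lineterminator="\n")
        w.writeheader()
        for r in rows:
            w.writerow(r)


def read_results_table(path: str | os.PathLike) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
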