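"""Per-lineage alignment, tree building, germline rooting and mutation mapping.

Members of a lineage share their V/J genes and CDR3 length (guaranteed by
clustering), so a full multiple sequence alignment is unnecessary: each
member is anchored to the germline by ungapped alignment of its V and J
segments at their annotated offsets, and CDR3 columns (equal length by
construction) are aligned positionally.  The germline row carries the
lineage consensus CDR3 so that every row has equal length and the row is
gap-free.

Trees are built by neighbor joining on Hamming distances (deterministic and
adequate for clade-level analyses) or imported from user Newick files built
with external maximum-likelihood tools.  Trees are rooted on the germline
leaf, and mutations are placed on branches by Fitch parsimony with the root
state fixed to the germline base, ties broken toward the germline state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genealogy import Genealogy
from .repertoire_model import Lineage, ValidationError

GERMLINE_LABEL = "germline"
_MISSING = frozenset("ACGT")


@dataclass
class LineageAlignment:
    """Column-aligned member sequences plus the germline row.

    ``column_positions[c]`` is the germline-axis coordinate of column ``c``,
    or -1 for CDR3 columns (which have no germline coordinate).
    """

    germline_row: str
    member_ids: list[str]
    member_rows: list[str]
    column_positions: np.ndarray
    excluded: list[str] = field(default_factory=list)
    reading_frame: int = 0

    def __post_init__(self):
        ncol = len(self.germline_row)
        for r in self.member_rows:
            if len(r) != ncol:
                raise ValidationError("alignment rows must have equal length")
        if self.column_positions.size != ncol:
            raise ValidationError("column_positions must cover every column")

    @property
    def n_columns(self) -> int:
        return len(self.germline_row)


def align_to_germline(
    lineage: Lineage, min_anchor_identity: float = 0.5
) -> LineageAlignment:
    """Anchor every member to the germline coordinate system.

    Members whose V/J anchor identity falls below ``min_anchor_identity``
    are excluded with a warning and listed in ``excluded``.
    """
    g = lineage.germline
    if g is None:
        raise ValidationError(f"{lineage.lineage_id}: germline reference required")
    pre = g.pre_cdr3_len
    post_start = g.post_cdr3_start
    post_len = len(g.seq) - post_start
    L = lineage.cdr3_length
    ncol = pre + L + post_len
    germ_row = lineage.germline_with_cdr3()
    assert len(germ_row) == ncol
    col_pos = np.concatenate(
        [
            np.arange(pre),
            np.full(L, -1, dtype=np.int64),
            np.arange(post_start, len(g.seq)),
        ]
    )
    ids: list[str] = []
    rows: list[str] = []
    excluded: list[str] = []
    for m in lineage.members:
        s = m.nucleotide_seq
        i = s.find(m.cdr3_nt)
        mpre, mpost = s[:i], s[i + L :]
        # ungapped anchoring: V part left-anchored at FWR1, J part
        # left-anchored at the junction end; short amplicons leave '-' padding
        row = (
            mpre[:pre].ljust(pre, "-")
            + m.cdr3_nt
            + mpost[:post_len].ljust(post_len, "-")
        )
        aligned = matches = 0
        for c in range(ncol):
            if col_pos[c] < 0:
                continue
            b = row[c]
            if b in ("-", "N"):
                continue
            aligned += 1
            if b == germ_row[c]:
                matches += 1
        if aligned == 0 or matches / aligned < min_anchor_identity:
            warnings.warn(
                f"{lineage.lineage_id}: member {m.sequence_id} anchors at "
                f"{0 if aligned == 0 else matches / aligned:.2f} identity; excluded"
            )
            excluded.append(m.sequence_id)
            continue
        ids.append(m.sequence_id)
        rows.append(row)
    return LineageAlignment(
        germline_row=germ_row,
        member_ids=ids,
        member_rows=rows,
        column_positions=col_pos,
        excluded=excluded,
        reading_frame=g.reading_frame,
    )


# -------------------------------------------------------------------- trees
def _hamming_matrix(rows: list[str]) -> np.ndarray:
    arr = np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])
    missing = (arr == ord("N")) | (arr == ord("-"))
    n = arr.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = arr[i] != arr
        valid = ~(missing[i] | missing)
        num = (diff & valid).sum(axis=1)
        den = valid.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d[i] = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(d, 0.0)
    return d


def build_tree(
    alignment: LineageAlignment,
    method: str = "nj",
    newick: str | None = None,
) -> Genealogy:
    """Build (or import) the lineage tree including the germline leaf.

    ``method="nj"`` runs neighbor joining on Hamming p-distances over the
    alignment columns; negative branch lengths are clamped to 0.
    ``method="import"`` parses a user Newick whose leaf labels must match
    the alignment's member ids plus the germline.
    """
    labels = [GERMLINE_LABEL] + list(alignment.member_ids)
    if method == "import":
        if newick is None:
            raise ValidationError("method='import' requires a newick string")
        gen = Genealogy.from_newick(newick)
        orphans = sorted(set(gen.leaf_labels) ^ set(labels))
        if orphans:
            raise ValidationError(
                f"imported tree labels do not match alignment: {orphans}"
            )
        gen.blen = np.maximum(gen.blen, 0.0)
        return gen
    if method != "nj":
        raise ValidationError(f"unknown tree method {method!r}")
    if len(labels) < 3:
        raise ValidationError("neighbor joining requires >= 3 rows incl. germline")
    from skbio import DistanceMatrix
    from skbio.tree import nj

    rows = [alignment.germline_row] + list(alignment.member_rows)
    dm = DistanceMatrix(_hamming_matrix(rows), ids=labels)
    tree = nj(dm)
    gen = Genealogy.from_newick(str(tree))
    gen.blen = np.maximum(gen.blen, 0.0)
    return gen


def root_on_germline(genealogy: Genealogy) -> Genealogy:
    """Reroot so the germline leaf hangs directly off the root (outgroup)."""
    try:
        leaf = genealogy.leaf_labels.index(GERMLINE_LABEL)
    except ValueError as exc:
        raise ValidationError("tree contains no germline leaf") from exc
    return genealogy.rerooted_above_leaf(leaf).suppress_unifurcations()


# --------------------------------------------------------------- parsimony
@dataclass(frozen=True)
class BranchMutation:
    """A state change assigned to one branch by parsimony."""

    column: int
    position: int  # germline coordinate, -1 for CDR3 columns
    region: str
    from_base: str
    to_base: str
    codon_effect: str = "unknown"


def map_mutations_to_branches(
    genealogy: Genealogy,
    alignment: LineageAlignment,
    lineage: Lineage | None = None,
    include_cdr3: bool = True,
    annotate_codon_effect: bool = True,
) -> dict[int, list[BranchMutation]]:
    """Fitch-parsimony placement of mutations on branches.

    Ancestral states are reconstructed per column with the root state fixed
    to the germline base; each state change is assigned to the branch where
    it occurs, with ties broken toward the germline state.  Codon effects
    use the reconstructed parent haplotype for codon context.

    The genealogy's ``branch_sites`` are populated with per-branch site ids;
    the returned map gives the full mutation annotation per branch.
    """
    from .fitness_dnds import translate_codon

    if GERMLINE_LABEL not in genealogy.leaf_labels:
        raise ValidationError("genealogy must contain the germline leaf")
    row_of = {mid: r for mid, r in zip(alignment.member_ids, alignment.member_rows)}
    row_of[GERMLINE_LABEL] = alignment.germline_row
    missing_leaves = [lab for lab in genealogy.leaf_labels if lab not in row_of]
    if missing_leaves:
        raise ValidationError(f"leaves without alignment rows: {missing_leaves}")
    ncol = alignment.n_columns
    nn = genealogy.n_nodes
    post = genealogy.postorder()
    pre_order = genealogy.preorder()
    children = genealogy.children
    germ = alignment.germline_row
    region_of = _column_regions(alignment, lineage)
    # reconstructed states for all nodes x columns (for codon context)
    states = np.empty((nn, ncol), dtype="U1")
    leaf_rows = [row_of[lab] for lab in genealogy.leaf_labels]
    events: dict[int, list[tuple[int, str, str]]] = {}
    for c in range(ncol):
        if not include_cdr3 and alignment.column_positions[c] < 0:
            states[:, c] = germ[c]
            continue
        # bottom-up Fitch sets
        sets: list[frozenset] = [frozenset()] * nn
        for v in post:
            if genealogy.is_leaf(v):
                b = leaf_rows[v][c]
                sets[v] = _MISSING if b in ("N", "-") else frozenset((b,))
            else:
                inter = None
                uni = frozenset()
                for ch in children[v]:
                    inter = sets[ch] if inter is None else (inter & sets[ch])
                    uni = uni | sets[ch]
                sets[v] = inter if inter else uni
        # top-down assignment, root fixed to germline base
        gb = germ[c]
        for v in pre_order:
            if v == genealogy.root:
                states[v, c] = gb
                continue
            p = genealogy.parent[v]
            ps = states[p, c]
            if genealogy.is_leaf(v):
                b = leaf_rows[v][c]
                sv = ps if b in ("N", "-") else b
            elif ps in sets[v]:
                sv = ps
            elif gb in sets[v]:  # tie toward the germline state
                sv = gb
            else:
                sv = min(sets[v])
            states[v, c] = sv
            if sv != ps:
                events.setdefault(int(v), []).append((c, ps, sv))
    # annotate and register sites
    out: dict[int, list[BranchMutation]] = {}
    branch_sites: dict[int, list[int]] = {}
    site_ids: dict[tuple[int, str], int] = {}
    frame = alignment.reading_frame
    for v, evs in events.items():
        p = int(genealogy.parent[v])
        muts = []
        sids = []
        for c, fb, tb in evs:
            effect = "unknown"
            if annotate_codon_effect:
                c0 = c - ((c - frame) % 3)
                if c0 >= 0 and c0 + 3 <= ncol:
                    parent_codon = "".join(states[p, c0 : c0 + 3])
                    child_codon = list(parent_codon)
                    child_codon[c - c0] = tb
                    child_codon = "".join(child_codon)
                    aa0 = translate_codon(parent_codon)
                    aa1 = translate_codon(child_codon)
                    if aa0 is not None and aa1 is not None:
                        effect = "synonymous" if aa0 == aa1 else "nonsynonymous"
            muts.append(
                BranchMutation(
                    column=c,
                    position=int(alignment.column_positions[c]),
                    region=region_of[c],
                    from_base=fb,
                    to_base=tb,
                    codon_effect=effect,
                )
            )
            key = (c, tb)
            if key not in site_ids:
                site_ids[key] = len(site_ids)
            sids.append(site_ids[key])
        out[v] = muts
        branch_sites[v] = sids
    genealogy.set_branch_sites(branch_sites)
    return out


def _column_regions(alignment: LineageAlignment, lineage: Lineage | None) -> list[str]:
    regions = []
    g = lineage.germline if lineage is not None else None
    for c in range(alignment.n_columns):
        pos = int(alignment.column_positions[c])
        if pos < 0:
            regions.append("CDR3")
        elif g is not None:
            regions.append(g.region_of(pos))
        else:
            regions.append("FWR1")
    return regions
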