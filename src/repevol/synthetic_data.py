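"""Synthetic antibody repertoires with complete ground truth.

The generator emulates the design of a time-resolved vaccination study:
five subjects sampled at eight timepoints (two pre-vaccination bleeds, the
day of vaccination and five follow-ups), each repertoire a mixture of

* vaccine-responsive lineages — absent before vaccination, peaking at day 7
  (>50-fold expansion), heavily mutated, class-switched, with genealogies
  drawn from the Bolthausen–Sznitman (continuous adaptation) coalescent;
* persistent lineages — stable abundance across all timepoints, above 0.1%
  of the repertoire, lightly mutated, mostly IgM, with neutral
  constant-size (Kingman) genealogies;
* other lineages — intermediate expansion, neutral genealogies.

Every lineage receives its own (V, J, CDR3 length) germline key within its
subject, so the generating partition is recoverable by clustering, and its
CDR3 junction is shared by all members (junction positions carry no somatic
mutations, matching the exclusion of CDR3 from mutation calling).

Affinity maturation is emulated at the mutation level: in adaptive
(Bolthausen–Sznitman) lineages, mutations on "winner" branches — branches
subtending a substantial fraction of the lineage — are preferentially
placed in CDR1/CDR2 and forced nonsynonymous, while background mutations
fall uniformly on the V/J axis.  This gives top-fitness branches a designed
CDR enrichment and FWR depletion of nonsynonymous change.

All randomness flows from a single seed; identical seeds give identical
repertoires (byte-identical tables).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from . import coalescent
from .coalescent import SimConfig
from .fitness_dnds import codon_effect_single_site, translate_codon
from .genealogy import Genealogy
from .repertoire_model import (
    DEFAULT_TIMEPOINTS,
    GermlineReference,
    Lineage,
    SequenceRecord,
    write_repertoire_table,
    write_results_table,
)
from .sfs import SFS

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if translate_codon(a + b + c) != "*"
]

#: IMGT-style region tiling of a generated V gene (lengths in nt, in-frame).
V_REGION_LENGTHS = (("FWR1", 78), ("CDR1", 24), ("FWR2", 51), ("CDR2", 24),
                    ("FWR3", 114), ("CDR3", 6))
#: J gene: the tail of CDR3 followed by FWR4.
J_REGION_LENGTHS = (("CDR3", 6), ("FWR4", 45))


# ------------------------------------------------------------------ germline
@dataclass
class GermlineDB:
    """Generated germline V and J genes with region annotations."""

    v_genes: dict[str, str]
    j_genes: dict[str, str]
    regions: dict[str, list[tuple[str, int, int]]]

    def reference(self, v_gene: str, j_gene: str) -> GermlineReference:
        from .repertoire_model import _build_region_map

        vseq = self.v_genes[v_gene]
        jseq = self.j_genes[j_gene]
        vmap = _build_region_map(v_gene, len(vseq), self.regions[v_gene])
        jmap = _build_region_map(j_gene, len(jseq), self.regions[j_gene])
        return GermlineReference(
            v_gene=v_gene, j_gene=j_gene, v_seq=vseq, j_seq=jseq,
            region_map=np.concatenate([vmap, jmap]), reading_frame=0,
        )

    def write(self, v_path, j_path, bed_path) -> None:
        for path, genes in ((v_path, self.v_genes), (j_path, self.j_genes)):
            with open(path, "w") as fh:
                for name in sorted(genes):
                    fh.write(f">{name}\n{genes[name]}\n")
        with open(bed_path, "w") as fh:
            for gene in sorted(self.regions):
                for region, start, end in self.regions[gene]:
                    fh.write(f"{gene}\t{start}\t{end}\t{region}\n")


def _random_orf(n_codons: int, rng) -> str:
    return "".join(
        _SENSE_CODONS[i] for i in rng.integers(len(_SENSE_CODONS), size=n_codons)
    )


def generate_germline_db(n_v: int, n_j: int, seed=0) -> GermlineDB:
    """Random in-frame V (~300 nt) and J (~50 nt) genes with IMGT-style
    region tiling; V genes end inside CDR3, J genes start inside it.
    Deterministic under the seed; germlines contain no stop codons."""
    if n_v < 1 or n_j < 1:
        raise ValueError("need n_v >= 1 and n_j >= 1")
    rng = np.random.default_rng(seed)
    v_genes: dict[str, str] = {}
    j_genes: dict[str, str] = {}
    regions: dict[str, list[tuple[str, int, int]]] = {}
    for i in range(n_v):
        name = f"SVH{i + 1:02d}"  # synthetic V heavy-chain gene
        length = sum(L for _, L in V_REGION_LENGTHS)
        v_genes[name] = _random_orf(length // 3, rng)
        pos, ivals = 0, []
        for region, L in V_REGION_LENGTHS:
            ivals.append((region, pos, pos + L))
            pos += L
        regions[name] = ivals
    for i in range(n_j):
        name = f"SJH{i + 1:02d}"
        length = sum(L for _, L in J_REGION_LENGTHS)
        j_genes[name] = _random_orf(length // 3, rng)
        pos, ivals = 0, []
        for region, L in J_REGION_LENGTHS:
            ivals.append((region, pos, pos + L))
            pos += L
        regions[name] = ivals
    return GermlineDB(v_genes=v_genes, j_genes=j_genes, regions=regions)


def random_cdr3(length: int, rng) -> str:
    if length % 3 or length < 3:
        raise ValueError("CDR3 length must be a positive multiple of 3")
    return _random_orf(length // 3, rng)


# ------------------------------------------------------------------- design
@dataclass
class RepertoireDesign:
    """Study-scale defaults: 5 subjects, 8 timepoints, ~36 vaccine-responsive
    and ~83 persistent lineages per subject."""

    subjects: int = 5
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    n_responsive: int = 36
    n_persistent: int = 83
    n_other: int = 30
    responsive_size_range: tuple[int, int] = (100, 1000)
    persistent_size_range: tuple[int, int] = (200, 800)
    other_size_range: tuple[int, int] = (100, 400)
    regime_map: dict[str, str] = field(
        default_factory=lambda: {
            "vaccine_responsive": "bsz",
            "persistent": "kingman",
            "other": "kingman",
        }
    )
    theta_map: dict[str, float] = field(
        default_factory=lambda: {
            "vaccine_responsive": 8.0,
            "persistent": 3.0,
            "other": 6.0,
        }
    )
    #: per-timepoint relative abundance by class (normalized per lineage);
    #: vaccine-responsive lineages are undetectable before vaccination.
    trajectory_map: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "vaccine_responsive": (0, 0, 0, 0.1, 0.5, 1.0, 0.7, 0.5),
            "persistent": (1, 1, 1, 1, 1, 1, 1, 1),
            "other": (0.2, 0.2, 0.2, 0.3, 0.6, 1.0, 0.8, 0.6),
        }
    )
    isotype_map: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "vaccine_responsive": {"IgG": 0.75, "IgA": 0.20, "IgM": 0.05},
            "persistent": {"IgM": 0.80, "IgD": 0.10, "IgA": 0.10},
            "other": {"IgM": 0.40, "IgG": 0.40, "IgA": 0.20},
        }
    )
    n_v: int = 30
    n_j: int = 6
    cdr3_lengths: tuple[int, ...] = (12, 15, 18, 21, 24)
    #: in adaptive lineages, fraction of winner-branch mutations that are
    #: forced CDR-nonsynonymous (the affinity-maturation emulation)
    winner_cdr_bias: float = 0.8
    winner_min_fraction: float = 0.05
    seed: int = 0

    @classmethod
    def tiny(cls, seed: int = 0) -> "RepertoireDesign":
        """Small profile for fast end-to-end runs and tests."""
        return cls(
            subjects=2,
            n_responsive=3,
            n_persistent=4,
            n_other=3,
            responsive_size_range=(40, 90),
            persistent_size_range=(40, 90),
            other_size_range=(30, 60),
            n_v=10,
            n_j=4,
            seed=seed,
        )


# ------------------------------------------------------------------ lineage
@dataclass
class LineageTruth:
    """Ground truth for one generated lineage."""

    lineage_id: str
    subject: str
    label: str
    regime: str
    theta: float
    n: int
    v_gene: str
    j_gene: str
    cdr3: str
    records: list[SequenceRecord]
    genealogy: Genealogy
    true_sfs: SFS
    #: site id -> (germline position, germline base, derived base, region, effect)
    sites: dict[int, tuple[int, str, str, str, str]]

    def as_lineage(self, germline: GermlineReference) -> Lineage:
        return Lineage(
            lineage_id=self.lineage_id,
            subject=self.subject,
            members=list(self.records),
            germline=germline,
        )

    def branch_mutations(self):
        """True per-branch mutations in the annotation form used by the
        dN/dS machinery (no reconstruction: generator ground truth)."""
        from .phylo import BranchMutation

        out: dict[int, list] = {}
        for v, sids in self.genealogy.branch_sites.items():
            out[v] = [
                BranchMutation(
                    column=-1,
                    position=self.sites[sid][0],
                    region=self.sites[sid][3],
                    from_base=self.sites[sid][1],
                    to_base=self.sites[sid][2],
                    codon_effect=self.sites[sid][4],
                )
                for sid in sids
            ]
        return out


def _eligible_positions(germline: GermlineReference) -> tuple[np.ndarray, np.ndarray]:
    """(CDR1/2 positions, all other non-CDR3 positions) on the germline axis."""
    rm = germline.region_map
    from .repertoire_model import REGIONS

    cdr3 = REGIONS.index("CDR3")
    cdr12 = (rm == REGIONS.index("CDR1")) | (rm == REGIONS.index("CDR2"))
    ok = rm != cdr3
    return np.flatnonzero(cdr12), np.flatnonzero(ok & ~cdr12)


def _nonsyn_base(germline: GermlineReference, pos: int, rng) -> str:
    gbase = germline.seq[pos]
    alts = [b for b in "ACGT" if b != gbase]
    nonsyn = [
        b for b in alts
        if codon_effect_single_site(germline, pos, b) == "nonsynonymous"
    ]
    pool = nonsyn if nonsyn else alts
    return pool[rng.integers(len(pool))]


def _assign_sites(
    gen: Genealogy,
    germline: GermlineReference,
    rng,
    winner_bias: float,
    winner_min_fraction: float,
    lineage_id: str,
) -> dict[int, tuple[int, str, str, str, str]]:
    """Map abstract mutation site ids to (position, derived base) slots.

    Distinct sites must remain distinguishable in the emitted sequences, so
    a germline position can host at most one site per derived base, and two
    sites sharing a position must sit on branches with disjoint leaf sets
    (otherwise a sequence would have to carry two bases at once).  Fresh
    positions are consumed first — big branches first, so that the
    high-frequency sites that define the spectrum always get clean slots.

    With ``winner_bias`` > 0, sites on internal branches subtending at least
    ``winner_min_fraction`` of the leaves are preferentially placed in
    CDR1/CDR2 with a nonsynonymous derived base (the affinity-maturation
    emulation for adaptive lineages).
    """
    below = gen.n_leaves_below()
    # Euler intervals for ancestor/disjointness tests
    tin = np.zeros(gen.n_nodes, dtype=np.int64)
    tout = np.zeros(gen.n_nodes, dtype=np.int64)
    for t, v in enumerate(gen.preorder()):
        tin[v] = t
    for v in gen.postorder():
        tout[v] = max([tout[c] for c in gen.children[v]], default=tin[v])

    def disjoint(a: int, b: int) -> bool:
        return tout[a] < tin[b] or tout[b] < tin[a]

    cdr_fresh, rest_fresh = _eligible_positions(germline)
    cdr_fresh, rest_fresh = list(cdr_fresh), list(rest_fresh)
    rng.shuffle(cdr_fresh)
    rng.shuffle(rest_fresh)
    used: dict[int, list[tuple[int, str]]] = {}  # pos -> [(branch, base)]
    winner_cut = max(2.0, winner_min_fraction * gen.n_leaves)
    sites: dict[int, tuple[int, str, str, str, str]] = {}

    def place(v: int, sid: int, want_cdr_nonsyn: bool) -> None:
        pos = base = None
        if want_cdr_nonsyn and cdr_fresh:
            pos = cdr_fresh.pop()
            base = _nonsyn_base(germline, pos, rng)
        elif rest_fresh or cdr_fresh:
            pool = rest_fresh if rest_fresh else cdr_fresh
            pos = pool.pop()
            gbase = germline.seq[pos]
            alts = [b for b in "ACGT" if b != gbase]
            base = alts[rng.integers(3)]
        else:  # reuse a position on a disjoint branch with a fresh base
            candidates = list(used)
            rng.shuffle(candidates)
            for cand in candidates:
                taken = used[cand]
                if len(taken) >= 3:
                    continue
                if all(disjoint(v, b) for b, _ in taken):
                    gbase = germline.seq[cand]
                    free = [
                        b for b in "ACGT"
                        if b != gbase and all(b != tb for _, tb in taken)
                    ]
                    if free:
                        pos = cand
                        base = free[int(rng.integers(len(free)))]
                        break
            if pos is None:
                raise ValueError(
                    f"{lineage_id}: cannot place mutation {sid} without "
                    "violating site distinguishability (theta too high for "
                    "the germline length)"
                )
        used.setdefault(int(pos), []).append((v, base))
        sites[sid] = (
            int(pos),
            germline.seq[pos],
            base,
            germline.region_of(pos),
            codon_effect_single_site(germline, pos, base),
        )

    # winner branches first, then the rest, big branches first
    branches = sorted(
        gen.branch_sites, key=lambda v: (-int(below[v]), v)
    )
    for v in branches:
        is_winner = (
            winner_bias > 0 and not gen.is_leaf(v) and below[v] >= winner_cut
        )
        for sid in gen.branch_sites[v]:
            want = is_winner and rng.random() < winner_bias
            place(v, sid, want)
    return sites


def generate_lineage(
    regime: str,
    n_cells: int,
    theta: float,
    germline: GermlineReference,
    cdr3: str,
    subject: str = "S1",
    lineage_id: str = "L1",
    timepoints: list[str] | None = None,
    isotypes: dict[str, float] | None = None,
    winner_cdr_bias: float = 0.8,
    winner_min_fraction: float = 0.05,
    label: str = "other",
    rng=None,
) -> LineageTruth:
    """Simulate one lineage: genealogy, infinite-sites mutations mapped to
    germline positions, and emitted member sequences.

    ``timepoints`` assigns one timepoint per leaf (default: all "D7").  The
    emitted records reproduce the true SFS exactly when re-called against
    the germline (one record per leaf; the junction is shared).
    """
    rng = np.random.default_rng(rng)
    cfg = SimConfig(n=n_cells, theta=max(theta, 1e-9), model=regime)
    gen = coalescent.simulate(cfg, rng)
    if theta > 0:
        coalescent.drop_mutations(gen, theta=theta, mode="rate", rng=rng)
    sites = _assign_sites(
        gen, germline, rng,
        winner_bias=(winner_cdr_bias if regime == "bsz" else 0.0),
        winner_min_fraction=winner_min_fraction,
        lineage_id=lineage_id,
    )
    # emit member sequences
    pre = germline.pre_cdr3_len
    post_start = germline.post_cdr3_start
    L = len(cdr3)
    base_seq = germline.seq[:pre] + cdr3 + germline.seq[post_start:]

    def seq_pos(ref_pos: int) -> int:
        return ref_pos if ref_pos < pre else ref_pos - post_start + pre + L

    if timepoints is None:
        timepoints = ["D7"] * n_cells
    if len(timepoints) != n_cells:
        raise ValueError("one timepoint per leaf required")
    iso_names, iso_p = (["unknown"], [1.0])
    if isotypes:
        iso_names = sorted(isotypes)
        iso_p = np.array([isotypes[k] for k in iso_names])
        iso_p = iso_p / iso_p.sum()
    records = []
    for leaf, site_set in enumerate(gen.leaf_site_sets()):
        arr = list(base_seq)
        for sid in site_set:
            pos, _, dbase, _, _ = sites[sid]
            arr[seq_pos(pos)] = dbase
        iso = iso_names[int(rng.choice(len(iso_names), p=iso_p))]
        records.append(
            SequenceRecord(
                sequence_id=f"{lineage_id}.s{leaf}",
                subject=subject,
                timepoint=timepoints[leaf],
                nucleotide_seq="".join(arr),
                v_gene=germline.v_gene,
                j_gene=germline.j_gene,
                cdr3_nt=cdr3,
                isotype=iso,
            )
        )
    gen.leaf_labels = [r.sequence_id for r in records]
    return LineageTruth(
        lineage_id=lineage_id,
        subject=subject,
        label=label,
        regime=regime,
        theta=theta,
        n=n_cells,
        v_gene=germline.v_gene,
        j_gene=germline.j_gene,
        cdr3=cdr3,
        records=records,
        genealogy=gen,
        true_sfs=coalescent.genealogy_to_sfs(gen),
        sites=sites,
    )


# --------------------------------------------------- constructed sweep trees
def grafted_sweep_genealogy(
    clade_sizes: tuple[int, ...] = (450, 450),
    swept_fraction: float = 0.9,
    stem_sites: int = 15,
    shared_sites: int = 4,
    pendant_rate: float = 0.02,
    rng=None,
) -> Genealogy:
    """A lineage genealogy carrying one hard selective sweep per clade.

    Each clade hangs off a common stem (whose ``shared_sites`` mutations are
    carried by every clade, emulating mutations acquired before the clades
    diverged).  Inside a clade, a recently swept haplotype subtends
    ``swept_fraction`` of the clade's leaves as a star; its stem carries
    ``stem_sites`` mutations, which therefore segregate at ~90% frequency
    within the clade — the high-frequency signature of a sweep.  Diversity is
    otherwise purged: leaves carry only rare pendant singletons
    (Poisson(``pendant_rate``) each).

    This is a synthetic stand-in for the top-heavy genealogies of observed
    swept subclones; stationary multiple-merger draws do not concentrate
    high-frequency mass this way.
    """
    rng = np.random.default_rng(rng)
    n = int(sum(clade_sizes))
    ids = iter(range(n, n + 2 + 3 * len(clade_sizes)))
    parent: dict[int, int] = {}
    blen: dict[int, float] = {}
    sites: dict[int, list[int]] = {}
    site_counter = 0

    def new_sites(k: int) -> list[int]:
        nonlocal site_counter
        out = list(range(site_counter, site_counter + k))
        site_counter += k
        return out

    root = next(ids)
    stem = next(ids)
    parent[stem] = root
    blen[stem] = 1.0
    if shared_sites:
        sites[stem] = new_sites(shared_sites)
    leaf = 0
    for m in clade_sizes:
        c = next(ids)
        parent[c] = stem
        blen[c] = 0.5
        swept = next(ids)
        parent[swept] = c
        blen[swept] = 1.0
        sites[swept] = new_sites(stem_sites)
        k = int(round(swept_fraction * m))
        for j in range(m):
            parent[leaf] = swept if j < k else c
            blen[leaf] = 0.05
            p = int(rng.poisson(pendant_rate))
            if p:
                sites[leaf] = new_sites(p)
            leaf += 1
    n_nodes = max(parent.keys() | {root}) + 1
    parr = np.full(n_nodes, -1, dtype=np.int64)
    barr = np.zeros(n_nodes)
    for v, p in parent.items():
        parr[v] = p
        barr[v] = blen[v]
    gen = Genealogy(parr, barr, n)
    gen.set_branch_sites(sites)
    return gen


# --------------------------------------------------------------- repertoire
@dataclass
class RepertoireBundle:
    """A generated repertoire plus everything needed to score the pipeline."""

    design: RepertoireDesign
    germline_db: GermlineDB
    records: list[SequenceRecord]
    lineages: list[LineageTruth]

    def truth_label(self, lineage_id: str) -> str:
        return next(l.label for l in self.lineages if l.lineage_id == lineage_id)

    def membership(self) -> dict[str, str]:
        return {
            r.sequence_id: lt.lineage_id
            for lt in self.lineages
            for r in lt.records
        }

    def write(self, outdir: str | os.PathLike) -> None:
        os.makedirs(outdir, exist_ok=True)
        write_repertoire_table(self.records, os.path.join(outdir, "repertoire.tsv"))
        self.germline_db.write(
            os.path.join(outdir, "germline_v.fasta"),
            os.path.join(outdir, "germline_j.fasta"),
            os.path.join(outdir, "regions.bed"),
        )
        write_results_table(
            [
                {
                    "lineage_id": lt.lineage_id,
                    "subject": lt.subject,
                    "label": lt.label,
                    "regime": lt.regime,
                    "theta": lt.theta,
                    "n": lt.n,
                    "v_gene": lt.v_gene,
                    "j_gene": lt.j_gene,
                    "cdr3": lt.cdr3,
                }
                for lt in self.lineages
            ],
            os.path.join(outdir, "truth_lineages.tsv"),
        )
        write_results_table(
            [
                {"sequence_id": sid, "lineage_id": lid}
                for sid, lid in sorted(self.membership().items())
            ],
            os.path.join(outdir, "truth_membership.tsv"),
        )
        treedir = os.path.join(outdir, "truth_trees")
        os.makedirs(treedir, exist_ok=True)
        for lt in self.lineages:
            with open(os.path.join(treedir, f"{lt.lineage_id}.nwk"), "w") as fh:
                fh.write(lt.genealogy.to_newick() + "\n")


def _assign_timepoints(
    n: int, weights: np.ndarray, timepoints: tuple[str, ...], seqs_hint, rng
) -> list[str]:
    """Assign leaves to timepoints by multinomial allocation.

    Leaves sharing an identical genotype are spread over distinct timepoints
    where possible so that duplicate-row collapsing does not shrink the
    lineage.
    """
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("trajectory weights must have positive mass")
    counts = rng.multinomial(n, w / w.sum())
    slots: list[str] = [
        tp for tp, c in zip(timepoints, counts) for _ in range(c)
    ]
    rng.shuffle(slots)
    assignment = [""] * n
    # group leaves by genotype signature, fill greedily
    groups: dict = {}
    for leaf in range(n):
        groups.setdefault(seqs_hint[leaf], []).append(leaf)
    remaining = {tp: int(c) for tp, c in zip(timepoints, counts)}
    for _, leaves in sorted(groups.items(), key=lambda kv: -len(kv[1])):
        used: set[str] = set()
        for leaf in leaves:
            pick = next(
                (tp for tp in timepoints if remaining.get(tp, 0) > 0 and tp not in used),
                None,
            )
            if pick is None:  # all distinct timepoints used up: reuse one
                pick = next(tp for tp in timepoints if remaining.get(tp, 0) > 0)
            remaining[pick] -= 1
            used.add(pick)
            assignment[leaf] = pick
    return assignment


def generate_repertoire(design: RepertoireDesign) -> RepertoireBundle:
    """Generate a full multi-subject, multi-timepoint repertoire.

    Each lineage gets a unique (V, J, CDR3 length) key within its subject
    (so clustering can recover the generating partition) and a class-specific
    genealogy, mutation load, trajectory and isotype profile.
    """
    rng = np.random.default_rng(design.seed)
    db = generate_germline_db(design.n_v, design.n_j, seed=rng.integers(2**31))
    v_names = sorted(db.v_genes)
    j_names = sorted(db.j_genes)
    all_keys = [
        (v, j, L) for v in v_names for j in j_names for L in design.cdr3_lengths
    ]
    records: list[SequenceRecord] = []
    truths: list[LineageTruth] = []
    classes = (
        ["vaccine_responsive"] * design.n_responsive
        + ["persistent"] * design.n_persistent
        + ["other"] * design.n_other
    )
    size_ranges = {
        "vaccine_responsive": design.responsive_size_range,
        "persistent": design.persistent_size_range,
        "other": design.other_size_range,
    }
    for si in range(design.subjects):
        subject = f"S{si + 1}"
        if len(classes) > len(all_keys):
            raise ValueError("more lineages than distinct germline keys")
        key_idx = rng.choice(len(all_keys), size=len(classes), replace=False)
        for li, (label, ki) in enumerate(zip(classes, key_idx)):
            v, j, L = all_keys[ki]
            germline = db.reference(v, j)
            cdr3 = random_cdr3(L, rng)
            lo, hi = size_ranges[label]
            n = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            regime = design.regime_map[label]
            theta = design.theta_map[label]
            lid = f"T{subject}_{li:03d}"
            # first pass: genotypes, to spread duplicates across timepoints
            lt = generate_lineage(
                regime=regime,
                n_cells=n,
                theta=theta,
                germline=germline,
                cdr3=cdr3,
                subject=subject,
                lineage_id=lid,
                timepoints=None,
                isotypes=design.isotype_map[label],
                winner_cdr_bias=design.winner_cdr_bias,
                winner_min_fraction=design.winner_min_fraction,
                label=label,
                rng=np.random.default_rng(rng.integers(2**31)),
            )
            tps = _assign_timepoints(
                n,
                np.array(design.trajectory_map[label], dtype=float),
                design.timepoints,
                [r.nucleotide_seq for r in lt.records],
                rng,
            )
            lt.records = [replace(r, timepoint=tp) for r, tp in zip(lt.records, tps)]
            truths.append(lt)
            records.extend(lt.records)
    return RepertoireBundle(
        design=design, germline_db=db, records=records, lineages=truths
    )
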