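"""Phylogenetic fitness inference (LBI) and regional dN/dS enrichment.

The local branching index (LBI) of a node is the total tree length in its
neighborhood, exponentially discounted with distance at timescale ``tau``:
nodes sitting next to rapidly branching (recently expanded) parts of the
tree receive high values, making LBI a proxy for fitness.  It is computed
exactly by two message-passing sweeps (rootward then leafward) in closed
form per branch.

Branches are ranked by fitness change (child LBI minus parent LBI); the
mutations on the top- and bottom-ranked branches per lineage, pooled across
lineages, are summarized as per-region dN/dS enrichment: the ratio of
nonsynonymous to synonymous counts in a region, normalized by the same
ratio over all regions within the same branch set.  Uncertainty comes from
bootstrap over lineages (respecting within-lineage correlation), and
per-region two-sided Fisher exact tests compare the region against the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

from .genealogy import Genealogy
from .phylo import BranchMutation
from .repertoire_model import REGIONS, GermlineReference, ValidationError

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

#: LBI neighborhood timescale as a fraction of the mean root-to-leaf
#: distance, the published convention for this statistic.
DEFAULT_TAU_FRACTION = 0.0625


def translate_codon(codon: str) -> str | None:
    """Amino acid for a codon, or None for codons with N/- or wrong length."""
    return _CODON_TABLE.get(codon.upper())


def codon_effect_single_site(
    germline: GermlineReference, pos: int, derived_base: str
) -> str:
    """Synonymous/nonsynonymous call for a single substitution with germline
    codon context.  Codons touching the germline CDR3 segment (whose bases
    are replaced by the lineage junction) and codons containing N are
    ``unknown``."""
    frame = germline.reading_frame
    c0 = pos - ((pos - frame) % 3)
    if c0 < 0 or c0 + 3 > len(germline.seq):
        return "unknown"
    cdr3_lo, cdr3_hi = germline.cdr3_interval
    if cdr3_lo < cdr3_hi and c0 < cdr3_hi and c0 + 3 > cdr3_lo:
        return "unknown"
    codon = germline.seq[c0 : c0 + 3]
    mutated = list(codon)
    mutated[pos - c0] = derived_base
    aa0 = translate_codon(codon)
    aa1 = translate_codon("".join(mutated))
    if aa0 is None or aa1 is None:
        return "unknown"
    return "synonymous" if aa0 == aa1 else "nonsynonymous"


def classify_codon_effect(parent_codon: str, child_codon: str) -> str:
    """Effect of a substitution given the reconstructed parent haplotype's
    codon and the child codon carrying the focal change."""
    aa0 = translate_codon(parent_codon)
    aa1 = translate_codon(child_codon)
    if aa0 is None or aa1 is None:
        return "unknown"
    return "synonymous" if aa0 == aa1 else "nonsynonymous"


# ----------------------------------------------------------------------- LBI
@dataclass
class FitnessAnnotation:
    """Per-node LBI values and per-branch fitness changes."""

    lbi: np.ndarray  # per node
    delta: np.ndarray  # child LBI - parent LBI (NaN at the root)
    tau: float


def local_branching_index(genealogy: Genealogy, tau: float | None = None) -> FitnessAnnotation:
    """Exact LBI by rootward/leafward message passing.

    The rootward message of node ``i`` with branch length ``b`` is
    ``up(i) = tau (1 - e^{-b/tau}) + e^{-b/tau} sum_c up(c)``; the leafward
    message mirrors it with the parent's other messages.  LBI(i) is the sum
    of all messages arriving at ``i``.  ``tau`` defaults to 0.0625 times the
    mean root-to-leaf distance.
    """
    if tau is None:
        depths = genealogy.depths()
        mean_depth = float(depths[: genealogy.n_leaves].mean())
        tau = DEFAULT_TAU_FRACTION * mean_depth
        if tau <= 0:
            tau = 1e-9  # degenerate zero-length tree
    if tau <= 0:
        raise ValidationError("tau must be > 0")
    nn = genealogy.n_nodes
    up = np.zeros(nn)
    down = np.zeros(nn)
    b = genealogy.blen
    decay = np.exp(-b / tau)
    gain = tau * (1.0 - decay)
    children = genealogy.children
    for v in genealogy.postorder():
        s = sum(up[c] for c in children[v])
        up[v] = gain[v] + decay[v] * s
    up_sum = np.zeros(nn)
    for v in range(nn):
        up_sum[v] = sum(up[c] for c in children[v])
    for v in genealogy.preorder():
        if v == genealogy.root:
            down[v] = 0.0
            continue
        p = genealogy.parent[v]
        siblings = up_sum[p] - up[v]
        down[v] = gain[v] + decay[v] * (down[p] + siblings)
    lbi = down + up_sum
    delta = np.full(nn, np.nan)
    nonroot = np.flatnonzero(genealogy.parent >= 0)
    delta[nonroot] = lbi[nonroot] - lbi[genealogy.parent[nonroot]]
    return FitnessAnnotation(lbi=lbi, delta=delta, tau=float(tau))


def rank_branches_by_fitness_change(
    genealogy: Genealogy, annotation: FitnessAnnotation, k: int = 3
) -> tuple[list[int], list[int], bool]:
    """Top-k and bottom-k branches (as child node ids) by LBI change.

    Ties break by clade size (larger first) then node id; deterministic.
    When fewer than 2k branches exist all are returned and the result is
    flagged (third element True).
    """
    below = genealogy.n_leaves_below()
    nodes = [int(v) for v in np.flatnonzero(genealogy.parent >= 0)]
    flagged = len(nodes) < 2 * k
    top = sorted(nodes, key=lambda v: (-annotation.delta[v], -below[v], v))[:k]
    bottom = sorted(nodes, key=lambda v: (annotation.delta[v], -below[v], v))[:k]
    return top, bottom, flagged


# --------------------------------------------------------------------- dN/dS
@dataclass
class RegionalDnds:
    region: str
    nonsynonymous: int
    synonymous: int
    enrichment: float  # NaN when undefined
    bootstrap_sd: float
    fisher_p: float


def _region_counts(mutsets: list[list[BranchMutation]]) -> dict[str, list[int]]:
    counts = {r: [0, 0] for r in REGIONS}  # [nonsyn, syn]
    for muts in mutsets:
        for m in muts:
            if m.codon_effect == "nonsynonymous":
                counts[m.region][0] += 1
            elif m.codon_effect == "synonymous":
                counts[m.region][1] += 1
    return counts


def _enrichment(counts: dict[str, list[int]]) -> dict[str, float]:
    n_tot = sum(c[0] for c in counts.values())
    s_tot = sum(c[1] for c in counts.values())
    out = {}
    for r, (nr, sr) in counts.items():
        if sr == 0 or s_tot == 0 or n_tot == 0:
            out[r] = float("nan")
        else:
            out[r] = (nr / sr) / (n_tot / s_tot)
    return out


def regional_dnds_enrichment(
    branch_mutation_sets: list[list[BranchMutation]],
    bootstrap_reps: int = 100,
    rng=None,
) -> dict[str, RegionalDnds]:
    """Per-region dN/dS enrichment of a pooled branch set.

    ``branch_mutation_sets`` holds, per lineage, the mutations on that
    lineage's chosen branches (e.g. its top-3 fitness-increasing branches).
    Enrichment for region r is (N_r/S_r) / (N_total/S_total) within the
    pooled set; the bootstrap resamples lineages.
    """
    rng = np.random.default_rng(rng)
    counts = _region_counts(branch_mutation_sets)
    enrich = _enrichment(counts)
    n_tot = sum(c[0] for c in counts.values())
    s_tot = sum(c[1] for c in counts.values())
    boots: dict[str, list[float]] = {r: [] for r in REGIONS}
    k = len(branch_mutation_sets)
    for _ in range(bootstrap_reps):
        idx = rng.integers(0, k, size=k)
        bc = _region_counts([branch_mutation_sets[i] for i in idx])
        be = _enrichment(bc)
        for r, v in be.items():
            if np.isfinite(v):
                boots[r].append(v)
    out: dict[str, RegionalDnds] = {}
    for r, (nr, sr) in counts.items():
        if s_tot == 0:
            p = 1.0
        else:
            _, p = stats.fisher_exact(
                [[nr, sr], [n_tot - nr, s_tot - sr]], alternative="two-sided"
            )
        sd = float(np.std(boots[r], ddof=1)) if len(boots[r]) > 1 else float("nan")
        out[r] = RegionalDnds(
            region=r,
            nonsynonymous=nr,
            synonymous=sr,
            enrichment=enrich[r],
            bootstrap_sd=sd,
            fisher_p=float(p),
        )
    return out


def lineage_branch_mutations(
    genealogy: Genealogy,
    branch_mutations: dict[int, list[BranchMutation]],
    branches: list[int],
) -> list[BranchMutation]:
    """Mutations carried by a set of branches of one lineage."""
    out: list[BranchMutation] = []
    for v in branches:
        out.extend(branch_mutations.get(int(v), []))
    return out
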