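"""Somatic mutation calling and site frequency spectra.

For a clonal lineage of ``n`` unique sequences, every somatic point mutation
(relative to the personalized germline V and J genes) defines a segregating
site.  The site frequency spectrum (SFS) counts, for each derived-allele
count ``i`` in ``1..n-1``, the number of sites ``xi_i`` carried by exactly
``i`` of the ``n`` sequences.  CDR3 positions are excluded from mutation
calling because the ancestral state of the junction cannot be established
from the germline.

Sites are keyed by (germline position, derived base): two different derived
bases at one position are independent sites, the infinite-sites reading of
point mutations.  Sites carried by all ``n`` members are fixed differences
and are reported separately, not in the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .repertoire_model import REGIONS, Lineage, ValidationError

#: default frequency bin edges for binned spectra: roughly log-spaced at low
#: frequency, with a dedicated (0.99, 1) top bin so that mass above 99%
#: frequency (diagnostic of sweeps) is visible.
DEFAULT_BIN_EDGES = np.array(
    [0.02, 0.05, 0.10, 0.20, 0.35, 0.50, 0.65, 0.80, 0.90, 0.99]
)


@dataclass(frozen=True)
class Mutation:
    """A somatic point mutation on the germline coordinate axis."""

    position: int
    germline_base: str
    derived_base: str
    region: str = "FWR1"
    codon_effect: str = "unknown"  # synonymous / nonsynonymous / unknown

    def __post_init__(self):
        if self.germline_base == self.derived_base:
            raise ValidationError(
                f"mutation at {self.position}: germline and derived base equal"
            )


@dataclass
class SFS:
    """Site frequency spectrum of one lineage (or one simulated genealogy)."""

    n: int
    xi: dict[int, int] = field(default_factory=dict)
    fixed: int = 0  # sites carried by all n members

    def __post_init__(self):
        for i, c in self.xi.items():
            if not (1 <= i <= self.n - 1):
                raise ValidationError(f"derived count {i} outside [1, n-1]")
            if c < 0:
                raise ValidationError("negative site count")

    @property
    def S(self) -> int:
        """Total number of segregating sites."""
        return int(sum(self.xi.values()))

    def counts_array(self) -> np.ndarray:
        """xi as a dense array indexed 1..n-1 (position 0 unused)."""
        out = np.zeros(self.n, dtype=np.int64)
        for i, c in self.xi.items():
            out[i] = c
        return out

    def frequencies(self) -> np.ndarray:
        """Array of derived-allele frequencies i/n, one entry per site."""
        if self.S == 0:
            return np.empty(0)
        return np.concatenate(
            [np.full(c, i / self.n) for i, c in sorted(self.xi.items())]
        )


# ----------------------------------------------------------------- mutation calling
def call_somatic_mutations(
    lineage: Lineage,
    alignment=None,
    annotate_codon_effect: bool = True,
) -> dict[str, list[Mutation]]:
    """Call somatic point mutations for every member against the germline.

    Mutations are reported on germline coordinates; CDR3 columns are
    excluded, ``N`` bases are ignored, and members covering less than half of
    the germline axis are excluded (none arise from the internal aligner,
    which rejects poorly matching members itself).

    The per-site codon effect compares the germline codon with the germline
    codon carrying only the focal substitution (single-site annotation);
    branch-contextual annotation lives in :mod:`repevol.fitness_dnds`.

    Returns a map from sequence_id to its mutation list.
    """
    from .phylo import align_to_germline  # deferred to avoid a module cycle

    if lineage.germline is None:
        raise ValidationError(f"{lineage.lineage_id}: germline reference required")
    if alignment is None:
        alignment = align_to_germline(lineage)
    g = lineage.germline
    out: dict[str, list[Mutation]] = {}
    col_to_ref = alignment.column_positions  # -1 for CDR3 / unaligned columns
    germ_row = alignment.germline_row
    for seq_id, row in zip(alignment.member_ids, alignment.member_rows):
        muts: list[Mutation] = []
        covered = 0
        for col, ref_pos in enumerate(col_to_ref):
            if ref_pos < 0:
                continue
            base = row[col]
            if base == "N" or base == "-":
                continue
            covered += 1
            gbase = germ_row[col]
            if base != gbase:
                muts.append(
                    _annotated_mutation(g, int(ref_pos), gbase, base)
                    if annotate_codon_effect
                    else Mutation(int(ref_pos), gbase, base, g.region_of(ref_pos))
                )
        if covered < 0.5 * np.sum(col_to_ref >= 0):
            continue  # flagged: insufficient germline coverage
        out[seq_id] = muts
    return out


def _annotated_mutation(g, pos: int, gbase: str, dbase: str) -> Mutation:
    from .fitness_dnds import codon_effect_single_site

    return Mutation(pos, gbase, dbase, g.region_of(pos), codon_effect_single_site(g, pos, dbase))


# ----------------------------------------------------------------------- SFS
def build_sfs(
    lineage: Lineage,
    mutations: dict[str, list[Mutation]] | None = None,
) -> SFS:
    """Build the SFS of a lineage from per-member mutation calls.

    ``n`` is the number of member records with mutation calls.  Each
    (position, derived base) pair is one site; its derived count is the
    number of members carrying it.
    """
    if mutations is None:
        mutations = call_somatic_mutations(lineage)
    n = len(mutations)
    if n < 2:
        raise ValidationError(
            f"{lineage.lineage_id}: SFS undefined for fewer than 2 sequences"
        )
    site_counts: dict[tuple[int, str], int] = {}
    for muts in mutations.values():
        for m in muts:
            key = (m.position, m.derived_base)
            site_counts[key] = site_counts.get(key, 0) + 1
    xi: dict[int, int] = {}
    fixed = 0
    for count in site_counts.values():
        if count == n:
            fixed += 1
        else:
            xi[count] = xi.get(count, 0) + 1
    return SFS(n=n, xi=xi, fixed=fixed)


def site_table(
    lineage: Lineage, mutations: dict[str, list[Mutation]] | None = None
) -> list[dict]:
    """Per-site table: position, derived base, count, frequency, region."""
    if mutations is None:
        mutations = call_somatic_mutations(lineage)
    n = len(mutations)
    sites: dict[tuple[int, str], dict] = {}
    for muts in mutations.values():
        for m in muts:
            key = (m.position, m.derived_base)
            if key not in sites:
                sites[key] = {
                    "lineage_id": lineage.lineage_id,
                    "position": m.position,
                    "germline_base": m.germline_base,
                    "derived_base": m.derived_base,
                    "region": m.region,
                    "codon_effect": m.codon_effect,
                    "count": 0,
                }
            sites[key]["count"] += 1
    rows = sorted(sites.values(), key=lambda r: (r["position"], r["derived_base"]))
    for r in rows:
        r["frequency"] = r["count"] / n
    return rows


def bin_sfs(sfs: SFS, bin_edges: np.ndarray = DEFAULT_BIN_EDGES) -> np.ndarray:
    """Binned, normalized spectrum.

    ``bin_edges`` are interior breakpoints on (0,1); sites are assigned to
    bins by frequency i/n with right-closed bins, and the result is
    normalized to sum 1.  An empty spectrum yields an all-zero vector.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0) or edges.size == 0:
        raise ValidationError("bin_edges must be strictly increasing")
    if edges[0] <= 0 or edges[-1] >= 1:
        raise ValidationError("bin_edges must lie strictly inside (0, 1)")
    nbins = edges.size + 1
    out = np.zeros(nbins)
    if sfs.S == 0:
        return out
    for i, c in sfs.xi.items():
        b = int(np.searchsorted(edges, i / sfs.n, side="left"))
        out[b] += c
    return out / out.sum()


def average_sfs(
    lineage_sfs_list: list[SFS], bin_edges: np.ndarray = DEFAULT_BIN_EDGES
) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted mean of per-lineage normalized binned spectra, with SEM.

    Lineages with empty spectra carry no information and are skipped.
    """
    if len(lineage_sfs_list) < 2:
        raise ValidationError("averaging requires at least 2 lineages")
    spectra = np.array(
        [bin_sfs(s, bin_edges) for s in lineage_sfs_list if s.S > 0]
    )
    if spectra.shape[0] < 2:
        raise ValidationError("fewer than 2 nonempty spectra")
    mean = spectra.mean(axis=0)
    sem = spectra.std(axis=0, ddof=1) / np.sqrt(spectra.shape[0])
    return mean, sem
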