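"""Lineage abundance trajectories and vaccination-dynamics classification.

The fractional abundance of a lineage at a timepoint is its number of unique
sequences divided by the total number of unique sequences in that subject's
repertoire at that timepoint.  Lineages are classified by their fold change
(FC) of fractional abundance from D0 to D7:

* vaccine-responsive — FC > 50 (lineages undetected at D0 but present at D7
  have infinite FC and qualify);
* persistent — FC < 2 and fractional abundance at D7 above 0.1%;
* other — everything else.

FC is computed on fractional abundances rather than raw counts, which makes
the classification robust to per-timepoint sequencing depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .repertoire_model import (
    GermlineReference,
    Lineage,
    SequenceRecord,
    ValidationError,
)

INFINITE = math.inf
#: marker for quantities undefined on the data (0/0 fold changes etc.)
UNDEFINED = float("nan")


@dataclass
class AbundanceTrajectory:
    lineage_id: str
    subject: str
    counts: dict[str, int]  # timepoint -> unique-sequence count
    fractions: dict[str, float]  # timepoint -> fractional abundance

    def count(self, t: str) -> int:
        return self.counts.get(t, 0)

    def fraction(self, t: str) -> float:
        return self.fractions.get(t, 0.0)


@dataclass
class DynamicsThresholds:
    responsive_fold: float = 50.0
    persistent_fold: float = 2.0
    persistent_min_fraction: float = 0.001
    t0: str = "D0"
    t1: str = "D7"
    #: minimum member count at t1 for a lineage to feed selection analyses
    min_t1_count_for_selection: int = 100


@dataclass
class DynamicsLabel:
    lineage_id: str
    label: str  # vaccine_responsive / persistent / other
    fold_change_d0_d7: float
    d7_fraction: float
    d7_count: int = 0


# ------------------------------------------------------------------ abundance
def repertoire_totals(records: list[SequenceRecord]) -> dict[tuple[str, str], int]:
    """Unique-sequence totals per (subject, timepoint)."""
    totals: dict[tuple[str, str], int] = {}
    for r in records:
        key = (r.subject, r.timepoint)
        totals[key] = totals.get(key, 0) + 1
    return totals


def fractional_abundance(
    lineage: Lineage, timepoint: str, totals: dict[tuple[str, str], int]
) -> float:
    """count(lineage, t) / total_unique(subject, t); NaN when the subject has
    no sequences at the timepoint."""
    subject_tps = {t for (s, t) in totals if s == lineage.subject}
    if timepoint not in subject_tps:
        raise ValidationError(
            f"timepoint {timepoint!r} absent from subject {lineage.subject}'s repertoire"
        )
    total = totals.get((lineage.subject, timepoint), 0)
    if total == 0:
        return UNDEFINED
    count = sum(1 for m in lineage.members if m.timepoint == timepoint)
    return count / total


def abundance_trajectories(
    lineages: list[Lineage], records: list[SequenceRecord]
) -> dict[str, AbundanceTrajectory]:
    """Per-lineage trajectories over all timepoints present in the table."""
    totals = repertoire_totals(records)
    timepoints = sorted({t for (_, t) in totals})
    out: dict[str, AbundanceTrajectory] = {}
    for lin in lineages:
        counts: dict[str, int] = {t: 0 for t in timepoints}
        for m in lin.members:
            counts[m.timepoint] = counts.get(m.timepoint, 0) + 1
        fractions = {
            t: (counts[t] / totals[(lin.subject, t)])
            if totals.get((lin.subject, t), 0) > 0
            else UNDEFINED
            for t in timepoints
        }
        out[lin.lineage_id] = AbundanceTrajectory(
            lin.lineage_id, lin.subject, counts, fractions
        )
    return out


def fold_change(trajectory: AbundanceTrajectory, t0: str, t1: str) -> float:
    """f(t1)/f(t0); INFINITE when f(t0)=0 < f(t1); 0 when f(t1)=0 < f(t0);
    NaN when both are 0."""
    f0 = trajectory.fraction(t0)
    f1 = trajectory.fraction(t1)
    if math.isnan(f0) or math.isnan(f1):
        return UNDEFINED
    if f0 == 0 and f1 == 0:
        return UNDEFINED
    if f0 == 0:
        return INFINITE
    return f1 / f0


def classify_lineages(
    trajectories: dict[str, AbundanceTrajectory],
    thresholds: DynamicsThresholds = DynamicsThresholds(),
) -> dict[str, DynamicsLabel]:
    """Deterministic (FC, D7-fraction) classification; the three labels
    partition the lineages."""
    out: dict[str, DynamicsLabel] = {}
    th = thresholds
    for lid, traj in trajectories.items():
        fc = fold_change(traj, th.t0, th.t1)
        f1 = traj.fraction(th.t1)
        f1 = 0.0 if math.isnan(f1) else f1
        if fc > th.responsive_fold:  # math.inf > k holds
            label = "vaccine_responsive"
        elif (not math.isnan(fc)) and fc < th.persistent_fold and f1 > th.persistent_min_fraction:
            label = "persistent"
        else:
            label = "other"
        out[lid] = DynamicsLabel(
            lineage_id=lid,
            label=label,
            fold_change_d0_d7=fc,
            d7_fraction=f1,
            d7_count=traj.count(th.t1),
        )
    return out


# ------------------------------------------------------------------ gene usage
def gene_usage_enrichment(
    lineages: list[Lineage],
    in_set: set[str],
    gene: str = "v",
    bonferroni: bool = False,
) -> dict[str, tuple[float, float]]:
    """Per-gene enrichment of usage in a lineage set vs the background.

    For each germline gene, a 2x2 table of (lineage in set vs not) x (uses
    gene vs not) at the lineage level is scored with a two-sided Fisher
    exact test.  Fold enrichment is in-set usage fraction over background
    (all other lineages) usage fraction; INFINITE when the background never
    uses the gene.  Genes absent from both sets are excluded.

    Returns gene -> (fold_enrichment, p).  With ``bonferroni`` the p-values
    are multiplied by the number of genes tested (capped at 1).
    """
    attr = "v_gene" if gene == "v" else "j_gene"
    inside = [lin for lin in lineages if lin.lineage_id in in_set]
    outside = [lin for lin in lineages if lin.lineage_id not in in_set]
    if len(inside) < 2 or len(outside) < 2:
        raise ValidationError("need >= 2 lineages in each compared set")
    genes = sorted({getattr(lin, attr) for lin in lineages})
    out: dict[str, tuple[float, float]] = {}
    for gname in genes:
        a = sum(1 for lin in inside if getattr(lin, attr) == gname)
        b = len(inside) - a
        c = sum(1 for lin in outside if getattr(lin, attr) == gname)
        d = len(outside) - c
        if a + c == 0:
            continue
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        in_frac = a / len(inside)
        bg_frac = c / len(outside)
        fold = INFINITE if bg_frac == 0 else (in_frac / bg_frac)
        out[gname] = (fold, float(p))
    if bonferroni:
        k = len(out)
        out = {g: (f, min(1.0, p * k)) for g, (f, p) in out.items()}
    return out


# ------------------------------------------------------------------- mutation load
def mutation_density(record: SequenceRecord, germline: GermlineReference) -> float:
    """Somatic mutation density within the V gene: mismatches over aligned V
    positions, comparing the record's V part with the germline V (positions
    before the CDR3 region).  N bases are ignored; trailing unaligned bases
    do not contribute."""
    vlen = germline.pre_cdr3_len
    v_part = record.nucleotide_seq[:vlen]
    g_part = germline.seq[:vlen]
    L = min(len(v_part), len(g_part))
    if L == 0:
        raise ValidationError(f"{record.sequence_id}: no aligned V positions")
    mismatches = sum(
        1 for a, b in zip(v_part[:L], g_part[:L]) if a != b and a != "N" and b != "N"
    )
    aligned = sum(1 for a, b in zip(v_part[:L], g_part[:L]) if a != "N" and b != "N")
    if aligned == 0:
        raise ValidationError(f"{record.sequence_id}: no alignable V positions")
    return mismatches / aligned
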