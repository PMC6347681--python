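"""End-to-end orchestration: cluster → dynamics → SFS → selection → trees →
sweeps → fitness/dN/dS, with reproducible seeded outputs.

The pipeline consumes an annotated repertoire table plus germline
references, and emits per-stage TSVs along with a manifest recording the
seed and a hash of the configuration.  All randomness flows from one seeded
generator hierarchy, so a rerun with the same seed reproduces every numeric
table byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats

from . import coalescent, dynamics, fitness_dnds, phylo, selection_tests, sfs as sfs_mod
from .dynamics import DynamicsLabel, DynamicsThresholds
from .lineage_clustering import ClusterConfig, cluster_repertoire
from .repertoire_model import (
    GermlineReference,
    Lineage,
    SequenceRecord,
    ValidationError,
    write_results_table,
)
from .selection_tests import SelectionResult
from .sweeps import HNullCache, SweepConfig, count_sweeps, detect_selected_subclones

logger = logging.getLogger("repevol")

STAGES = ("cluster", "dynamics", "sfs", "selection", "trees", "sweeps", "fitness")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    seed: int = 0
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    thresholds: DynamicsThresholds = field(default_factory=DynamicsThresholds)
    #: minimum member count at the peak timepoint to enter selection analyses
    min_members_for_selection: int = 100
    selection_replicates: int = 10_000
    null_models: tuple[str, ...] = ("kingman", "expanding")
    growth_rate: float = coalescent.DEFAULT_GROWTH_RATE
    tree_method: str = "nj"
    sweep: SweepConfig = field(default_factory=SweepConfig)
    #: minimum lineage size to scan for subclone sweeps
    min_leaves_for_sweeps: int = 100
    top_k_branches: int = 3
    dnds_bootstrap: int = 100
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})

    def config_hash(self) -> str:
        def _default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=_default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResults:
    lineages: list[Lineage]
    labels: dict[str, DynamicsLabel]
    spectra: dict[str, sfs_mod.SFS]
    selection: dict[str, SelectionResult]
    sweeps: dict[str, int]
    fitness_rows: list[dict]
    dnds: dict[str, dict]
    manifest: dict


def run_full_analysis(
    records: list[SequenceRecord],
    germline_db: dict[tuple[str, str], GermlineReference],
    config: RunConfig = RunConfig(),
    outdir: str | os.PathLike | None = None,
) -> RunResults:
    """Run every enabled stage on an annotated repertoire.

    Stage order is fixed; disabling a stage disables everything downstream
    that needs its output (a missing-input error is raised instead of
    silently skipping).  Partial outputs written before a failure are left
    in place.
    """
    rng = np.random.default_rng(config.seed)
    on = config.stages
    out: dict = {}
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)

    def _write(name: str, rows: list[dict]):
        if outdir is not None:
            write_results_table(rows, os.path.join(outdir, name))

    # ---- cluster
    if not on.get("cluster", True):
        raise PipelineError("cluster", "pipeline requires the clustering stage")
    try:
        lineages = cluster_repertoire(records, config.cluster)
        for lin in lineages:
            lin.germline = germline_db.get((lin.v_gene, lin.j_gene))
        logger.info("cluster: %d records -> %d lineages", len(records), len(lineages))
        _write(
            "lineages.tsv",
            [
                {"sequence_id": m.sequence_id, "lineage_id": lin.lineage_id}
                for lin in lineages
                for m in lin.members
            ],
        )
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("cluster", str(exc)) from exc

    # ---- dynamics
    labels: dict[str, DynamicsLabel] = {}
    if on.get("dynamics", True):
        trajectories = dynamics.abundance_trajectories(lineages, records)
        labels = dynamics.classify_lineages(trajectories, config.thresholds)
        _write(
            "labels.tsv",
            [
                {
                    "lineage_id": lab.lineage_id,
                    "label": lab.label,
                    "fold_change_d0_d7": lab.fold_change_d0_d7,
                    "d7_fraction": lab.d7_fraction,
                    "d7_count": lab.d7_count,
                }
                for lab in labels.values()
            ],
        )
        logger.info(
            "dynamics: %s",
            {
                k: sum(1 for v in labels.values() if v.label == k)
                for k in ("vaccine_responsive", "persistent", "other")
            },
        )

    # ---- SFS + selection
    spectra: dict[str, sfs_mod.SFS] = {}
    mutation_calls: dict[str, dict] = {}
    alignments: dict[str, phylo.LineageAlignment] = {}
    eligible = [
        lin
        for lin in lineages
        if lin.germline is not None and len(lin) >= config.min_members_for_selection
    ]
    if on.get("sfs", True):
        for lin in eligible:
            aln = phylo.align_to_germline(lin)
            muts = sfs_mod.call_somatic_mutations(lin, alignment=aln)
            if len(muts) < 2:
                continue
            alignments[lin.lineage_id] = aln
            mutation_calls[lin.lineage_id] = muts
            spectra[lin.lineage_id] = sfs_mod.build_sfs(lin, mutations=muts)
        rows = []
        for lid, s in spectra.items():
            binned = sfs_mod.bin_sfs(s)
            rows.append(
                {"lineage_id": lid, "n": s.n, "S": s.S, "fixed": s.fixed}
                | {f"bin{i}": f"{v:.6g}" for i, v in enumerate(binned)}
            )
        _write("spectra.tsv", rows)

    selection: dict[str, SelectionResult] = {}
    if on.get("selection", True):
        if not on.get("sfs", True):
            raise PipelineError("selection", "missing input: the sfs stage is disabled")
        for lid, s in spectra.items():
            selection[lid] = selection_tests.score_lineage(
                lid,
                s,
                replicates=config.selection_replicates,
                seed=np.random.default_rng(rng.integers(2**31)),
                models=config.null_models,
                growth_rate=config.growth_rate,
            )
        _write(
            "selection.tsv",
            [
                {
                    "lineage_id": r.lineage_id,
                    "n": r.n,
                    "S": r.S,
                    "theta_pi": f"{r.theta_pi:.6g}",
                    "theta_H": f"{r.theta_H:.6g}",
                    "H": f"{r.H:.6g}",
                    "nonmono": f"{r.nonmono:.6g}",
                    "p_vs_constant": f"{r.p_vs_constant:.6g}",
                    "p_vs_expanding": ""
                    if r.p_vs_expanding is None
                    else f"{r.p_vs_expanding:.6g}",
                    "significance_score": f"{r.significance_score:.6g}",
                }
                for r in selection.values()
            ],
        )

    # ---- trees
    trees: dict[str, "phylo.Genealogy"] = {}
    branch_muts: dict[str, dict] = {}
    if on.get("trees", True):
        if not on.get("sfs", True):
            raise PipelineError("trees", "missing input: the sfs stage is disabled")
        for lin in eligible:
            lid = lin.lineage_id
            if lid not in alignments:
                continue
            tree = phylo.build_tree(alignments[lid], method=config.tree_method)
            tree = phylo.root_on_germline(tree)
            branch_muts[lid] = phylo.map_mutations_to_branches(
                tree, alignments[lid], lineage=lin
            )
            trees[lid] = tree
            if outdir is not None:
                treedir = os.path.join(outdir, "trees")
                os.makedirs(treedir, exist_ok=True)
                with open(os.path.join(treedir, f"{lid}.nwk"), "w") as fh:
                    fh.write(tree.to_newick() + "\n")

    # ---- sweeps
    sweep_counts: dict[str, int] = {}
    if on.get("sweeps", True):
        if not on.get("trees", True):
            raise PipelineError("sweeps", "missing input: the trees stage is disabled")
        cache = HNullCache(
            replicates=config.sweep.replicates,
            grid_factor=config.sweep.grid_factor,
            seed=config.sweep.seed,
        )
        rows = []
        for lid, tree in trees.items():
            if tree.n_leaves < config.min_leaves_for_sweeps:
                continue
            calls = detect_selected_subclones(tree, config.sweep, null_cache=cache)
            sweep_counts[lid] = count_sweeps(calls)
            for c in calls:
                rows.append(
                    {
                        "lineage_id": lid,
                        "node": c.node,
                        "clade_size": c.clade_size,
                        "clade_S": c.clade_S,
                        "clade_H": f"{c.clade_H:.6g}",
                        "clade_p": f"{c.clade_p:.6g}",
                        "selected": int(c.selected),
                    }
                )
        _write("sweeps.tsv", rows)

    # ---- fitness / dN/dS
    fitness_rows: list[dict] = []
    dnds: dict[str, dict] = {}
    if on.get("fitness", True):
        if not on.get("trees", True):
            raise PipelineError("fitness", "missing input: the trees stage is disabled")
        top_sets, bottom_sets = [], []
        for lid, tree in trees.items():
            ann = fitness_dnds.local_branching_index(tree)
            top, bottom, _ = fitness_dnds.rank_branches_by_fitness_change(
                tree, ann, k=config.top_k_branches
            )
            bm = branch_muts[lid]
            top_sets.append(fitness_dnds.lineage_branch_mutations(tree, bm, top))
            bottom_sets.append(fitness_dnds.lineage_branch_mutations(tree, bm, bottom))
            for leaf in range(tree.n_leaves):
                fitness_rows.append(
                    {
                        "lineage_id": lid,
                        "sequence_id": tree.leaf_labels[leaf],
                        "lbi": f"{ann.lbi[leaf]:.6g}",
                        "tau": f"{ann.tau:.6g}",
                    }
                )
        _write("fitness.tsv", fitness_rows)
        if top_sets:
            boot_rng = np.random.default_rng(rng.integers(2**31))
            for name, sets in (("top", top_sets), ("bottom", bottom_sets)):
                dnds[name] = fitness_dnds.regional_dnds_enrichment(
                    sets, bootstrap_reps=config.dnds_bootstrap, rng=boot_rng
                )
            _write(
                "dnds.tsv",
                [
                    {
                        "branch_set": name,
                        "region": r.region,
                        "nonsynonymous": r.nonsynonymous,
                        "synonymous": r.synonymous,
                        "enrichment": f"{r.enrichment:.6g}",
                        "bootstrap_sd": f"{r.bootstrap_sd:.6g}",
                        "fisher_p": f"{r.fisher_p:.6g}",
                    }
                    for name, res in dnds.items()
                    for r in res.values()
                ],
            )

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_records": len(records),
        "n_lineages": len(lineages),
        "n_selection_scored": len(selection),
        "n_trees": len(trees),
        "stages": {s: bool(on.get(s, True)) for s in STAGES},
    }
    if outdir is not None:
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return RunResults(
        lineages=lineages,
        labels=labels,
        spectra=spectra,
        selection=selection,
        sweeps=sweep_counts,
        fitness_rows=fitness_rows,
        dnds=dnds,
        manifest=manifest,
    )


# -------------------------------------------------- selection vs expansion
@dataclass
class SelectionExpansionSummary:
    spearman_rho: float
    spearman_p: float
    abs_rho: float
    mannwhitney_U: float
    mannwhitney_p: float
    median_fc_selected: float
    median_fc_nonselected: float
    cutoff_table: list[dict]


def selection_vs_expansion(
    selection: dict[str, SelectionResult],
    labels: dict[str, DynamicsLabel],
    alpha: float = 0.05,
    fc_cutoffs: tuple[float, ...] = (2, 5, 10, 20, 50, 100),
) -> SelectionExpansionSummary:
    """Correlate per-lineage selection scores with clonal expansion.

    Uses the signed significance score (-log10 p, signed like H) against the
    D0→D7 fold change.  Infinite fold changes (lineages undetected at D0)
    are mapped to the top shared rank; NaN fold changes are dropped.
    """
    lids = [
        lid
        for lid in selection
        if lid in labels and not math.isnan(labels[lid].fold_change_d0_d7)
    ]
    if len(lids) < 3:
        raise ValidationError("need >= 3 lineages with defined fold change")
    score = np.array([selection[lid].significance_score for lid in lids])
    fc = np.array([labels[lid].fold_change_d0_d7 for lid in lids])
    finite_max = np.nanmax(np.where(np.isinf(fc), np.nan, fc))
    if not np.isfinite(finite_max):
        finite_max = 1.0
    fc_rank = np.where(np.isinf(fc), finite_max * 10, fc)
    rho, rho_p = stats.spearmanr(score, fc_rank)
    sel_mask = np.array([selection[lid].p_vs_constant < alpha for lid in lids])
    cutoff_table = []
    for cut in fc_cutoffs:
        cutoff_table.append(
            {
                "fc_cutoff": cut,
                "frac_selected_expanding": float(np.mean(fc[sel_mask] > cut))
                if sel_mask.any()
                else float("nan"),
                "frac_nonselected_expanding": float(np.mean(fc[~sel_mask] > cut))
                if (~sel_mask).any()
                else float("nan"),
            }
        )
    if sel_mask.any() and (~sel_mask).any():
        u, u_p = stats.mannwhitneyu(
            fc_rank[sel_mask], fc_rank[~sel_mask], alternative="two-sided"
        )
        med_sel = float(np.median(fc[sel_mask]))
        med_non = float(np.median(fc[~sel_mask]))
    else:
        u, u_p, med_sel, med_non = (float("nan"),) * 4
    return SelectionExpansionSummary(
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        abs_rho=float(abs(rho)),
        mannwhitney_U=float(u),
        mannwhitney_p=float(u_p),
        median_fc_selected=med_sel,
        median_fc_nonselected=med_non,
        cutoff_table=cutoff_table,
    )
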