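"""Detection of positively selected subclones on lineage phylogenies.

A selective sweep inside a clonal lineage shows up as a clade whose internal
site frequency spectrum carries an excess of high-frequency derived
mutations (strongly negative Fay & Wu's H).  The detector walks the rooted
genealogy breadth-first from the root's children; every visited clade with
at least ``min_clade_size`` leaves is scored by the H statistic of the SFS
restricted to its members (mutation frequencies relative to the clade
sample size) against a constant-population-size neutral null matched to the
clade's leaf count and segregating sites.  When a clade is significant the
search does not descend into it (greedy pruning), which makes reported
sweeps mutually non-nested by construction.

Null distributions are shared through a cache keyed on a geometric grid of
(sample size, segregating sites); the compared statistic is H/S, whose null
distribution varies slowly in both coordinates, so grid snapping changes
p-values only marginally — and the per-clade significance threshold is
*calibrated* end-to-end on neutral simulations run through this exact
machinery, targeting a 1% rate of lineages with any false sweep call.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import coalescent
from .coalescent import SimConfig
from .genealogy import Genealogy
from .selection_tests import _h_from_counts, simulate_null_site_counts

#: Default per-clade significance threshold, produced by
#: :func:`calibrate_alpha` on 2,000 neutral constant-size lineages in the
#: large-lineage regime (1,000-leaf trees, theta 15; 10,000-replicate null
#: cache, seed 42) with the one-sided 99% binomial bound, so that at most
#: 1% of neutral lineages yield any sweep call on fresh data; see
#: docs/methods.md.
DEFAULT_CLADE_ALPHA = 3.5e-4


@dataclass
class SweepConfig:
    min_clade_size: int = 50
    per_clade_alpha: float = DEFAULT_CLADE_ALPHA
    null_model: str = "kingman"
    replicates: int = 10_000  # null samples per grid cell
    seed: int = 0
    target_fdr: float = 0.01
    grid_factor: float = 1.25

    def __post_init__(self):
        if not (0 < self.per_clade_alpha < 1):
            raise ValueError("per_clade_alpha must be in (0, 1)")
        if self.min_clade_size < 10:
            raise ValueError("min_clade_size must be >= 10")
        if self.null_model != "kingman":
            raise ValueError("only the constant-size neutral null is supported")


@dataclass
class SubcloneCall:
    node: int
    clade_size: int
    clade_S: int
    clade_H: float
    clade_p: float
    selected: bool


class HNullCache:
    """Cached null samples of Fay & Wu's H under the fixed-S Kingman
    coalescent.

    Sample sizes are snapped to a geometric grid; for each grid size one
    batch of ``replicates`` genealogies is simulated and ``s_max`` i.i.d.
    sites are dropped on each.  Because sites are exchangeable given the
    tree, the running sum of the first ``S`` per-site H contributions is an
    exact null sample of H conditioned on ``S`` segregating sites — so a
    single batch serves every queried S without re-simulation.  Each grid
    size is seeded deterministically from the base seed and its key, so
    cached p-values do not depend on query order.
    """

    def __init__(
        self,
        replicates: int = 10_000,
        grid_factor: float = 1.25,
        seed: int = 0,
        s_max: int = 256,
    ):
        self.replicates = int(replicates)
        self.grid_factor = float(grid_factor)
        self.seed = int(seed)
        self.s_max = int(s_max)
        self._cums: dict[int, np.ndarray] = {}  # n_g -> (R, s_max) cumsums
        self._sorted: dict[tuple[int, int], np.ndarray] = {}

    def _snap(self, x: int) -> int:
        if x < 2:
            return 2
        f = self.grid_factor
        g = round(math.log(x) / math.log(f))
        return max(2, int(round(f**g)))

    def _cell(self, n_g: int, S: int) -> np.ndarray:
        key = (n_g, S)
        if key not in self._sorted:
            while S > self.s_max:
                self.s_max *= 2
                self._cums.clear()
                self._sorted = {k: v for k, v in self._sorted.items()}
            if n_g not in self._cums:
                ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(n_g,))
                rng = np.random.default_rng(ss)
                counts = simulate_null_site_counts(
                    n_g, self.s_max, self.replicates, rng=rng
                )
                c2 = n_g * (n_g - 1) / 2.0
                contrib = counts * (n_g - 2.0 * counts) / c2
                self._cums[n_g] = np.cumsum(contrib, axis=1)
            self._sorted[key] = np.sort(self._cums[n_g][:, S - 1])
        return self._sorted[key]

    def p_value(self, H: float, n: int, S: int) -> float:
        """Lower-tail empirical p of H (given n, S) with add-one correction."""
        if S < 1:
            return 1.0
        n_g = self._snap(n)
        null = self._cell(n_g, S)
        # per-site weights scale as x(1-2x) * n/(n-1) with x = i/n; rescale
        # the observed H onto the grid size's normalization
        obs = H * (n_g / (n_g - 1)) * ((n - 1) / n) if n != n_g else H
        hits = int(np.searchsorted(null, obs, side="right"))
        return (1 + hits) / (null.size + 1)


# ------------------------------------------------------------------ detection
def _clade_stats(genealogy: Genealogy, node: int, mut_counts: np.ndarray, below: np.ndarray):
    """(clade leaf count, clade S, clade H) for the subtree at ``node``.

    Mutations on the clade root's own branch are shared by every member and
    are fixed within the clade, so they are excluded.
    """
    n = int(below[node])
    S = 0
    hsum = 0.0
    c2 = n * (n - 1) / 2.0
    stack = list(genealogy.children[node])
    while stack:
        v = stack.pop()
        m = int(mut_counts[v])
        if m:
            i = int(below[v])
            if i < n:
                S += m
                hsum += m * i * (n - 2.0 * i)
        stack.extend(genealogy.children[v])
    return n, S, hsum / c2


def detect_selected_subclones(
    genealogy: Genealogy,
    config: SweepConfig = SweepConfig(),
    null_cache: HNullCache | None = None,
) -> list[SubcloneCall]:
    """Greedy breadth-first scan for positively selected subclones.

    The genealogy must be rooted and carry per-branch mutations (from the
    coalescent simulators or from parsimony mapping).  Returns every visited
    clade with its score; selected clades are flagged and, by greedy
    pruning, mutually non-nested.
    """
    if genealogy.parent[genealogy.root] >= 0:  # pragma: no cover - container invariant
        raise ValueError("genealogy must be rooted")
    if null_cache is None:
        null_cache = HNullCache(
            replicates=config.replicates,
            grid_factor=config.grid_factor,
            seed=config.seed,
        )
    below = genealogy.n_leaves_below()
    mut_counts = genealogy.branch_mutation_counts()
    calls: list[SubcloneCall] = []
    queue = [
        v
        for v in genealogy.children[genealogy.root]
        if not genealogy.is_leaf(v) and below[v] >= config.min_clade_size
    ]
    while queue:
        v = queue.pop(0)
        n, S, H = _clade_stats(genealogy, v, mut_counts, below)
        p = null_cache.p_value(H, n, S)
        selected = p < config.per_clade_alpha
        calls.append(
            SubcloneCall(
                node=int(v), clade_size=n, clade_S=S, clade_H=H, clade_p=p,
                selected=selected,
            )
        )
        if not selected:
            queue.extend(
                c
                for c in genealogy.children[v]
                if not genealogy.is_leaf(c) and below[c] >= config.min_clade_size
            )
    _assert_non_nested(genealogy, [c.node for c in calls if c.selected])
    return calls


def _assert_non_nested(genealogy: Genealogy, nodes: list[int]) -> None:
    chosen = set(nodes)
    for v in nodes:
        p = int(genealogy.parent[v])
        while p >= 0:
            if p in chosen:
                raise AssertionError("selected subclones must not be nested")
            p = int(genealogy.parent[p])


def count_sweeps(calls: list[SubcloneCall]) -> int:
    """Number of distinct (mutually non-nested) selected subclones."""
    return sum(1 for c in calls if c.selected)


def min_clade_pvalue(
    genealogy: Genealogy, config: SweepConfig, null_cache: HNullCache
) -> float:
    """Smallest per-clade p over all scannable clades (no greedy pruning).

    The lineage-level event "detect_selected_subclones reports >= 1 sweep at
    threshold alpha" is equivalent to "min_clade_pvalue < alpha", which makes
    threshold calibration a single pass per simulated lineage.
    """
    below = genealogy.n_leaves_below()
    mut_counts = genealogy.branch_mutation_counts()
    best = 1.0
    for v in range(genealogy.n_leaves, genealogy.n_nodes):
        if v == genealogy.root or below[v] < config.min_clade_size:
            continue
        n, S, H = _clade_stats(genealogy, v, mut_counts, below)
        best = min(best, null_cache.p_value(H, n, S))
    return best


# ---------------------------------------------------------------- calibration
def calibrate_alpha(
    config: SweepConfig,
    size_distribution,
    n_lineages: int = 500,
    theta: float = 15.0,
    seed: int = 0,
    alpha_grid: np.ndarray | None = None,
    null_cache: HNullCache | None = None,
    confidence: float = 0.99,
) -> float:
    """Largest per-clade alpha whose neutral lineage-level detection rate is
    at most ``config.target_fdr``.

    ``size_distribution`` is either an integer (all lineages that size), a
    sequence of sizes to sample from, or a callable ``rng -> size``.
    Neutral lineages are simulated under the constant-size coalescent with
    mutation rate ``theta`` and scanned without pruning; the calibrated
    threshold is read off the empirical distribution of per-lineage minimum
    p-values.

    The target is treated as a guarantee, not a point estimate: the grid
    value chosen is the largest whose one-sided binomial upper confidence
    bound (at ``confidence``) on the neutral detection rate stays at or
    below the target, so a fresh neutral batch respects the target despite
    calibration sampling noise.  Set ``confidence=0.5`` for a plain
    point-estimate calibration.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    z = float(norm.ppf(confidence))
    if null_cache is None:
        null_cache = HNullCache(
            replicates=config.replicates, grid_factor=config.grid_factor,
            seed=config.seed,
        )
    if alpha_grid is None:
        R = null_cache.replicates
        alpha_grid = np.unique(
            np.concatenate(
                [
                    (np.arange(1, 11) + 0.5) / (R + 1),
                    np.logspace(np.log10(20.5 / (R + 1)), np.log10(0.05), 25),
                ]
            )
        )
    min_ps = np.empty(n_lineages)
    for i in range(n_lineages):
        n = _draw_size(size_distribution, rng)
        gen = coalescent.simulate_kingman(SimConfig(n=n, theta=theta), rng)
        coalescent.drop_mutations(gen, theta=theta, mode="rate", rng=rng)
        min_ps[i] = min_clade_pvalue(gen, config, null_cache)
    rates = np.array([(min_ps < a).mean() for a in alpha_grid])
    upper = rates + z * np.sqrt(np.maximum(rates * (1 - rates), 0) / n_lineages)
    ok = np.flatnonzero(upper <= config.target_fdr)
    if ok.size == 0:
        warnings.warn(
            "no grid alpha meets the target false-discovery rate; "
            "returning the smallest grid value"
        )
        return float(alpha_grid[0])
    return float(alpha_grid[ok[-1]])


def _draw_size(size_distribution, rng) -> int:
    if callable(size_distribution):
        return int(size_distribution(rng))
    if np.isscalar(size_distribution):
        return int(size_distribution)
    arr = np.asarray(size_distribution)
    return int(arr[rng.integers(arr.size)])


# ---------------------------------------------------------------- summaries
def sweep_size_correlation(
    lineage_results: list[tuple[int, int]],
) -> tuple[float, float]:
    """Pearson correlation between per-lineage sweep count and leaf count.

    ``lineage_results`` holds (leaf_count, sweep_count) pairs.  Returns
    (nan, nan) when either variable has zero variance.
    """
    if len(lineage_results) < 3:
        raise ValueError("need >= 3 lineages")
    sizes = np.array([x for x, _ in lineage_results], dtype=float)
    counts = np.array([y for _, y in lineage_results], dtype=float)
    if np.ptp(sizes) == 0 or np.ptp(counts) == 0:
        return (float("nan"), float("nan"))
    r, p = stats.pearsonr(sizes, counts)
    return float(r), float(p)
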