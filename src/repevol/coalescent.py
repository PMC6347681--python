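"""Coalescent simulators for the three evolutionary null/alternative models.

Three genealogy models are compared against observed lineages:

* ``kingman`` — neutral evolution at constant population size: with ``k``
  ancestral lineages, pairwise mergers occur at total rate ``k(k-1)/2`` in
  coalescent time units and the merging pair is uniform.
* ``expanding`` — neutral evolution with exponentially growing population
  size: the Kingman process under the deterministic time change implied by
  ``N(t) = N0 * exp(-g t)`` backward in time, simulated by inverse-CDF
  transformation of the waiting times (topology is unchanged).
* ``bsz`` — continuous adaptation, whose genealogies converge to the
  Bolthausen–Sznitman multiple-merger coalescent.  With ``k`` lineages, a
  merger of ``b`` of them (2 <= b <= k) occurs at rate

      lambda_{k,b} = C(k,b) * (b-2)! (k-b)! / (k-1)!  =  k / (b (b-1)),

  the Λ-coalescent rates for Λ = Uniform(0,1); the total merger rate is
  ``k - 1`` and participants are uniform.  Merger sizes are drawn by exact
  inversion of ``P(B >= b | k) = (1/(b-1) - 1/k) / (1 - 1/k)``.

Mutations are dropped on branches under the infinite-sites model, either at
rate ``theta/2`` per unit branch length (Poisson) or conditioned on an exact
number of segregating sites ``S`` (multinomial on branch lengths), the
standard convention for null distributions matched to an observed lineage.

Times are in scaled coalescent units (N = 1); no conversion to generations
is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genealogy import Genealogy
from .sfs import SFS

MODELS = ("kingman", "expanding", "bsz")

#: Default exponential growth rate for the expanding model (coalescent time
#: units).  The value is chosen so that, at sample size ~100, the expected
#: singleton fraction of the spectrum sits roughly midway between the
#: Kingman and Bolthausen–Sznitman extremes; it is configuration, reported in
#: output metadata, not a fitted quantity.
DEFAULT_GROWTH_RATE = 10.0


@dataclass
class SimConfig:
    """Configuration of one genealogy simulation."""

    n: int
    theta: float
    model: str = "kingman"
    growth_rate: float = DEFAULT_GROWTH_RATE
    seed: int | None = None

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("sample size n must be >= 2")
        if self.theta < 0:
            raise ValueError("theta must be positive")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "expanding" and self.growth_rate <= 0:
            raise ValueError("growth_rate must be > 0 for the expanding model")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ------------------------------------------------------------------ simulators
def simulate_kingman(config: SimConfig, rng=None) -> Genealogy:
    """Standard n-coalescent genealogy."""
    rng = _rng(rng if rng is not None else config.seed)
    n = config.n
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    node_time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    for k in range(n, 1, -1):
        t += rng.exponential(2.0 / (k * (k - 1)))
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        # replace slot i with the merged node, drop slot j
        active[i] = nxt
        active[j] = active[-1]
        active.pop()
        nxt += 1
    blen = node_time[parent] - node_time
    blen[parent < 0] = 0.0
    return Genealogy(parent, blen, n)


def simulate_expanding(config: SimConfig, rng=None) -> Genealogy:
    """Kingman topology with exponential-growth time rescaling.

    Backward in time the pair-coalescence rate at time ``t`` is
    ``k(k-1)/2 * exp(g t)``; waiting times are drawn by analytic inversion of
    the integrated rate.
    """
    rng = _rng(rng if rng is not None else config.seed)
    n, g = config.n, config.growth_rate
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    node_time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    for k in range(n, 1, -1):
        rate = k * (k - 1) / 2.0
        e = rng.exponential()
        # solve: rate/g * (exp(g (t+tau)) - exp(g t)) = e
        t = np.log(np.exp(g * t) + g * e / rate) / g
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        active[i] = nxt
        active[j] = active[-1]
        active.pop()
        nxt += 1
    blen = node_time[parent] - node_time
    blen[parent < 0] = 0.0
    return Genealogy(parent, blen, n)


def bsz_merger_rate(k: int, b: int) -> float:
    """Rate at which *some* ``b`` of ``k`` lineages merge under BSZ."""
    if not 2 <= b <= k:
        raise ValueError("need 2 <= b <= k")
    return k / (b * (b - 1))


def _draw_bsz_merger_size(k: int, u: float) -> int:
    """Exact inversion of P(B >= b | k) = (1/(b-1) - 1/k)/(1 - 1/k)."""
    v = u * (1.0 - 1.0 / k) + 1.0 / k
    return min(k, int(np.floor(1.0 + 1.0 / v)))


def simulate_bsz(config: SimConfig, rng=None) -> Genealogy:
    """Bolthausen–Sznitman multiple-merger genealogy."""
    rng = _rng(rng if rng is not None else config.seed)
    n = config.n
    # at most 2n-1 nodes (binary worst case)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    node_time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    k = n
    while k > 1:
        t += rng.exponential(1.0 / (k - 1))  # total merger rate = k - 1
        b = _draw_bsz_merger_size(k, float(rng.random()))
        merged = rng.choice(k, size=b, replace=False)
        node_time[nxt] = t
        for idx in merged:
            parent[active[idx]] = nxt
        # remove merged slots (descending) and append the new node
        for idx in sorted(map(int, merged), reverse=True):
            active[idx] = active[-1]
            active.pop()
        active.append(nxt)
        nxt += 1
        k = len(active)
    parent = parent[:nxt]
    node_time = node_time[:nxt]
    blen = node_time[parent] - node_time
    blen[parent < 0] = 0.0
    return Genealogy(parent, blen, n)


def simulate(config: SimConfig, rng=None) -> Genealogy:
    """Dispatch on ``config.model``."""
    fn = {
        "kingman": simulate_kingman,
        "expanding": simulate_expanding,
        "bsz": simulate_bsz,
    }[config.model]
    return fn(config, rng)


# ------------------------------------------------------------------- mutations
def drop_mutations(
    genealogy: Genealogy,
    theta: float = 0.0,
    mode: str = "rate",
    S: int | None = None,
    rng=None,
) -> Genealogy:
    """Place infinite-sites mutations on branches (in place; also returned).

    ``mode="rate"``: each branch receives Poisson(theta/2 * length) new
    sites.  ``mode="fixed_S"``: exactly ``S`` sites are placed, each on a
    branch chosen with probability proportional to its length.
    """
    rng = _rng(rng)
    root = genealogy.root
    lengths = genealogy.blen.copy()
    lengths[root] = 0.0
    sites: dict[int, list[int]] = {}
    if mode == "rate":
        if theta <= 0:
            raise ValueError("theta must be > 0 in rate mode")
        counts = rng.poisson(0.5 * theta * lengths)
    elif mode == "fixed_S":
        if S is None or S < 0:
            raise ValueError("fixed_S mode requires S >= 0")
        counts = np.zeros(genealogy.n_nodes, dtype=np.int64)
        total = lengths.sum()
        if total > 0 and S > 0:
            branches = rng.choice(
                genealogy.n_nodes, size=S, p=lengths / total
            )
            np.add.at(counts, branches, 1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    site_id = 0
    for v in np.flatnonzero(counts):
        c = int(counts[v])
        sites[int(v)] = list(range(site_id, site_id + c))
        site_id += c
    genealogy.set_branch_sites(sites)
    return genealogy


def genealogy_to_sfs(genealogy: Genealogy) -> SFS:
    """SFS implied by per-branch mutations: xi_i counts mutations on
    branches subtending exactly i leaves."""
    below = genealogy.n_leaves_below()
    n = genealogy.n_leaves
    xi: dict[int, int] = {}
    fixed = 0
    for v, sites in genealogy.branch_sites.items():
        if v == genealogy.root or not sites:
            continue
        i = int(below[v])
        if i >= n:
            fixed += len(sites)
        else:
            xi[i] = xi.get(i, 0) + len(sites)
    return SFS(n=n, xi=xi, fixed=fixed)
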