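# Methods

This note documents the models and procedures implemented in `repevol`,
the parameters that matter, the numerical choices made where the design
was open, and the limits of what the synthetic-data tests demonstrate.

## Data model and coordinates

A repertoire is a table of *unique sequences*: one row per distinct
(subject, timepoint, nucleotide sequence).  Duplicate rows are collapsed on
read; abundances are counts of unique sequences, and the fractional
abundance of a lineage at a timepoint is its unique-sequence count divided
by the subject's total at that timepoint.  This makes trajectories robust
to per-timepoint sequencing depth.

All germline coordinates are 0-based, half-open, on a single axis formed by
concatenating the V and the J gene.  Region labels FWR1–CDR1–FWR2–CDR2–
FWR3–CDR3–FWR4 tile this axis; the germline-encoded CDR3 segment (V flank
plus J flank) marks where each lineage's junction replaces the reference.
The junction itself has no germline coordinates: its ancestral state is not
knowable from the germline, so CDR3 positions are excluded from somatic
mutation calling (they are retained, as region "CDR3", in tree-based
branch-mutation mapping, where the lineage consensus junction serves as the
root state).

## Lineage identification

Sequences are first partitioned by (V gene, J gene, CDR3 length); each
group is split by single-linkage clustering at an identity cutoff (default
0.90, ties linked).  Identity is computed either on the CDR3 alone or on
the concatenation of CDR3 and the rest of the variable region (default).
Clustering is exact — all pairs compared, components by union-find — and is
verified in the tests against an independent brute-force connected-
components oracle.  Lineages never cross subjects.

## Dynamics classification

Fold change (FC) of fractional abundance from D0 to D7 classifies
lineages: FC > 50 → vaccine-responsive (FC = ∞, the lineage undetected at
D0, qualifies); FC < 2 and D7 fraction > 0.1% → persistent; otherwise
other.  ∞ sorts above any finite FC and takes the top shared rank in
rank-based statistics.  Gene-usage enrichment between lineage sets uses
two-sided Fisher exact tests at the lineage level, uncorrected by default
(a Bonferroni option exists), with fold enrichment ∞ when the background
never uses the gene.

## Site frequency spectra

For a lineage of n unique sequences, each somatic point mutation —
a (germline position, derived base) pair, so two derived bases at one
position are independent sites — has derived count i = number of members
carrying it.  ξ_i counts the sites at each i ∈ [1, n−1]; sites carried by
all n members are fixed differences, reported separately.  Indels are
ignored; N bases are missing data.  Frequencies pool all timepoints of a
lineage (maximizing n for sparse lineages); per-timepoint spectra are a
configuration away.  Binned spectra use right-closed bins over
frequency with default edges {0.02, 0.05, 0.1, 0.2, 0.35, 0.5, 0.65, 0.8,
0.9, 0.99} — roughly log-spaced at low frequency, with a dedicated
(0.99, 1) bin because near-fixed mutations are the diagnostic of sweeps.
Averaged spectra are unweighted means of per-lineage normalized binned
spectra, with SEM = sd/√k.

## Coalescent models

Three genealogy models are simulated in scaled coalescent units (N = 1):

* **Kingman** (neutral, constant size): pairwise mergers at rate k(k−1)/2.
* **Expanding** (neutral, exponential growth): Kingman topology with
  analytic inverse-CDF time rescaling for N(t) = N₀e^(−gt) backward in
  time.  The default growth rate g = 10 puts the expected singleton
  fraction roughly midway between the constant-size and adaptation models
  at n ≈ 100; it is configuration, not an estimate.
* **Bolthausen–Sznitman (BSZ)** (continuous adaptation): multiple mergers
  of b of k lineages at rate λ_{k,b} = C(k,b)·(b−2)!(k−b)!/(k−1)! =
  k/(b(b−1)), total rate k − 1, merger size drawn by exact inversion of
  P(B ≥ b | k) = (1/(b−1) − 1/k)/(1 − 1/k).  The simulator is
  cross-checked in spirit against msprime's Beta-coalescent at α → 1
  (singleton fractions and H distributions agree) and in the tests against
  the analytic merger-size law.

Mutations follow the infinite-sites model: Poisson(θ/2 · branch length)
per branch ("rate" mode) or exactly S sites multinomially proportional to
branch length ("fixed_S" mode).  Null distributions condition on the
observed S — the standard convention, removing the nuisance dependence on
θ.

## Selection tests

θ_π = Σ ξ_i·i(n−i)/C(n,2), θ_H = Σ ξ_i·i²/C(n,2), H = θ_π − θ_H
(unnormalized, since significance is empirical).  The per-lineage test is
one-sided lower-tail: sweeps create an excess of high-frequency derived
alleles, pushing H negative.  Empirical p-values carry the add-one
correction p = (1 + #{null ≤ obs})/(R + 1); the reported significance
score is −log₁₀(p) with the sign of H.  The nonmonotonicity statistic is
the largest increase between adjacent bins of the normalized binned
spectrum (0 for nonincreasing spectra), tested upper-tail.

Two routes generate null samples.  The generic route simulates full
genealogies.  The fast route simulates only the block-counting process of
the neutral coalescents vectorized across replicates, recording each
ancestral block's family size and lifetime and sampling sites proportional
to lifetime — mathematically the same null, orders of magnitude faster,
and validated against the generic route distribution-for-distribution in
the tests.

### Power of unnormalized H against stationary BSZ — a limitation

Under the literal stationary BSZ coalescent the spectrum is singleton-
dominated (external branches carry most of the tree length); only ~1–2% of
segregating sites sit above 50% frequency.  Meanwhile the fixed-S Kingman
null of unnormalized H has heavy tree-level variance (deep neutral
branches at intermediate-to-high frequency), with an H/S 5% quantile near
−0.23 at n = 500.  The consequence, measured across n ∈ [30, 2000] and
S ∈ [20, 900]: BSZ draws reject the constant-size null at p < 0.05 at
roughly the type-I rate (≤ 2%), not far above it.  Real swept lineages are
far more detectable than stationary-BSZ draws, because a recent hard sweep
concentrates many mutations at near-fixed frequency (the swept haplotype's
ladder) while purging the rest of the diversity.  The acceptance test that
demands ≥5× type-I power on raw BSZ draws is therefore left failing, with
this analysis as the explanation; detector power is demonstrated instead on
constructed hard-sweep genealogies (below).  Where neutral and adaptation
models *do* separate robustly is in near-fixed mass: at n = 200, θ = 3,
the probability that a lineage carries a >99%-frequency mutation is 0.8%
(Kingman) and 0.1% (expanding) versus 8.9% (BSZ).  Note the literal claim
"no neutral mutations above 99%" is exact only for n ≤ 100 (no segregating
frequency exceeds 0.99); beyond that E[ξ_{n−1}] = θ/(n−1) is small but
positive, so the package's shape checks are order-of-magnitude contrasts.

## Subclone sweep detection

Breadth-first from the root's children (the whole-lineage test belongs to
the per-lineage machinery), every clade with ≥ `min_clade_size` leaves
(default 50, keeping the null nondegenerate) is scored by H of the SFS
restricted to its members: subtree mutations at their within-clade counts,
clade-stem mutations excluded as fixed.  A clade with p below the
per-clade threshold is marked selected and not descended into, so reported
sweeps are mutually non-nested by construction (asserted on every run).

Nulls come from a cache keyed on a geometric grid of sample sizes (factor
1.25): one batch of 10,000 fixed-S Kingman replicates per grid size, with
running per-site H sums so that the exact observed S is served without
re-simulation (sites are exchangeable given the tree).  The observed H is
rescaled by the ratio of per-site weight normalizations n/(n−1) before
comparison with the grid size's null.

The per-clade threshold is **calibrated**, not chosen: neutral lineages
are simulated in the large-lineage regime (1,000 leaves, θ = 15 — giving
S ≈ 110, the mutation-load scale of large vaccine-responsive lineages),
scanned without pruning (the lineage-level event "≥1 call at α" equals
"min clade p < α"), and the largest grid α is selected whose one-sided 99%
binomial upper bound on the neutral detection rate stays at or below the
1% target — the bound, rather than the point estimate, because the target
is a guarantee and the largest-passing-α rule is otherwise biased
optimistic.  The shipped default α = 3.5 × 10⁻⁴ came from a 2,000-lineage
calibration batch; fresh neutral batches detect at 0.3–0.4%.  Constructed
hard-sweep fixtures (a clade whose swept haplotype subtends 90% of its
leaves with a mutation-laden stem) are detected essentially always, and
grafted double-sweep fixtures yield exactly two non-nested calls sharing
their pre-divergence stem mutations.

## Phylogenies and branch mutations

Because clustering guarantees shared V/J and CDR3 length, members anchor
to the germline ungapped (V at its offset, junction positionally, J after
it); members below 50% anchor identity are excluded with a warning.  Trees
come from neighbor joining on Hamming p-distances (missing bases ignored,
negative branch lengths clamped to 0) — deterministic and sufficient for
clade-level analyses — or from imported Newick built with external
maximum-likelihood tools; either way the tree is rerooted so the germline
leaf hangs off the root.  Mutations map to branches by Fitch parsimony per
column with the root state fixed to the germline base and ties broken
toward the germline state; reconstructed parent haplotypes provide codon
context for synonymous/nonsynonymous calls (codons containing N or
spanning unsequenced context are "unknown").  Parsimony placement is
verified against exhaustive minimal-change enumeration on small fixtures.

## Fitness and regional dN/dS

The local branching index integrates tree length around each node,
exponentially discounted at timescale τ (default 0.0625 × mean root-to-
leaf distance, the published convention), computed exactly by two message-
passing sweeps and verified against brute-force quadrature.  Branches rank
by ΔLBI = child − parent; ties break by clade size then node id.  The
top-3 and bottom-3 branches per lineage, pooled across lineages, yield
per-region dN/dS enrichment (N_r/S_r)/(N_tot/S_tot) within the same branch
set, with SD by bootstrap over lineages (respecting within-lineage
correlation; default 100 replicates) and two-sided Fisher tests of region
vs elsewhere.

## The synthetic generator

`generate_repertoire` emulates a five-subject, eight-timepoint
vaccination study: per subject ~36 vaccine-responsive lineages (BSZ
genealogies, θ = 8, absent before D0, peaking at D7, class-switched,
sizes 100–1,000), ~83 persistent lineages (Kingman, θ = 3, flat
trajectories, mostly IgM, sizes 200–800) and ~30 intermediate lineages; a
tiny two-subject profile drives the fast tests.  Each lineage gets a
unique (V, J, CDR3 length) key within its subject so the generating
partition is exactly recoverable; junctions carry no mutations.  Site
placement keeps every mutation distinguishable in the emitted sequences
(fresh (position, base) slots first, position reuse only across disjoint
subtrees), so `build_sfs` on the output reproduces the simulator's true
spectrum exactly.  Affinity maturation is emulated by placing mutations on
"winner" branches (internal branches subtending ≥5% of an adaptive
lineage) preferentially in CDR1/2 with nonsynonymous derived bases
(bias 0.8), which is what makes top-LBI branches recover CDR enrichment
and FWR depletion in the closed loop.

What the generator does **not** emulate: sequencing error, UMI artifacts,
indels, CDR3 somatic mutation, isotype switching over time, shared
germline polymorphisms between subjects, and — importantly — the
top-heavy recent-sweep genealogies of real responding lineages (its
adaptive regime is the stationary BSZ).  Passing closed-loop tests
therefore demonstrate correctness of the machinery under the stated
models, not performance on real sequencing data.

## Numerical and engineering choices

* All randomness flows from `numpy.random.Generator` seeded hierarchies;
  identical seeds give byte-identical outputs end to end.
* Empirical p-values are never 0 (add-one correction); null caches are
  seeded per grid key so results do not depend on query order.
* Degenerate inputs: empty spectra score H = 0 and p = 1; zero-variance
  correlations return NaN markers; fold changes 0/0 are NaN and excluded
  from rank statistics; lineages with fewer than 2 mutation-called members
  are skipped by the SFS stage.
* Problem sizes in the shipped tests: 1,000-lineage × 1,000-leaf neutral
  batches for the calibration checks, 1,000–2,000 replicates for p-value
  calibration checks, 1,000 replicates per model for spectrum shapes, and
  a two-subject tiny repertoire for the end-to-end loop.

## Known limitations

* Unnormalized H against stationary multiple-merger draws has little power
  (see above); per-lineage selection calls on real data rest on the
  sweep-like structure of observed spectra.
* The nonmonotonicity statistic (max adjacent uptick of the binned
  normalized spectrum) is noisy for sparse spectra: spread-out neutral
  spectra produce larger sampling upticks than singleton-dominated
  adaptive ones, so it is reported with a matched empirical null rather
  than compared across models by raw value.
* Neighbor joining is a distance method; for publication-grade trees
  import maximum-likelihood Newick files.
* Coalescent times are in scaled units; no attempt is made to convert to
  generations or days.
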