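# repevol

Population-genetic analysis of clonal B-cell lineages in antibody
repertoires.

After vaccination, some B-cell lineages expand dramatically while
accumulating somatic mutations under strong selection for antigen binding;
others persist at stable abundance and drift neutrally.  `repevol` turns a
time-resolved, annotated repertoire (an AIRR-Rearrangement-style table of
unique sequences with V/J gene calls, CDR3 junctions and isotypes) into
quantitative evolutionary statements about each clonal lineage:

* **Lineage identification** — group sequences by (V gene, J gene, CDR3
  length), then single-linkage clustering at 90% nucleotide identity.
* **Dynamics classification** — fractional-abundance trajectories; lineages
  with a >50-fold increase in fractional abundance from day 0 to day 7 are
  *vaccine-responsive*, lineages with <2-fold change and >0.1% abundance
  are *persistent*.
* **Selection tests** — per-lineage site frequency spectra (SFS) of somatic
  mutations called against the personalized germline (CDR3 excluded), Fay &
  Wu's *H* = θ<sub>π</sub> − θ<sub>H</sub> with
  θ<sub>π</sub> = Σᵢ ξᵢ·i(n−i)/C(n,2) and θ<sub>H</sub> = Σᵢ ξᵢ·i²/C(n,2),
  scored against coalescent null models (neutral constant size, neutral
  exponential expansion) matched to the lineage's sample size *n* and
  segregating sites *S*, with the Bolthausen–Sznitman coalescent as the
  continuous-adaptation alternative.
* **Subclone sweeps** — a greedy breadth-first scan of each lineage
  phylogeny that flags clades whose internal SFS shows the high-frequency
  excess of a selective sweep, with the per-clade threshold calibrated so
  that at most 1% of neutral lineages produce any call.
* **Fitness and mutations** — local branching index (LBI) fitness
  inference on the lineage tree, top/bottom-3 branches by fitness change,
  and regional dN/dS enrichment of their mutations across FWR1–4/CDR1–3
  with bootstrap uncertainty.

A first-class synthetic-repertoire generator (5 subjects, 8 timepoints,
class-specific genealogies, mutation loads, trajectories and isotype
profiles, with complete ground truth) makes every stage testable without
access to sequencing data.

## Worked example

```python
import numpy as np
from repevol import (
    RepertoireDesign, generate_repertoire, cluster_repertoire,
    abundance_trajectories, classify_lineages, build_sfs, score_lineage,
)

bundle = generate_repertoire(RepertoireDesign.tiny(seed=3))
lineages = cluster_repertoire(bundle.records)
labels = classify_lineages(abundance_trajectories(lineages, bundle.records))
print(len(lineages), "lineages:",
      {k: sum(1 for v in labels.values() if v.label == k)
       for k in ("vaccine_responsive", "persistent", "other")})

lin = max(lineages, key=len)
lin.germline = bundle.germline_db.reference(lin.v_gene, lin.j_gene)
res = score_lineage(lin.lineage_id, build_sfs(lin), replicates=2000, seed=1)
print(f"n={res.n} S={res.S} H={res.H:.3f} p_vs_constant={res.p_vs_constant:.3f}")
```

prints

```
20 lineages: {'vaccine_responsive': 8, 'persistent': 11, 'other': 1}
n=86 S=12 H=-0.623 p_vs_constant=0.211
```

Twenty lineages are recovered (exactly the generating partition).  The
largest lineage here carries 12 segregating sites among 86 unique
sequences; its *H* is negative (a mild excess of high-frequency derived
mutations) but not extreme relative to the matched neutral null
(empirical p ≈ 0.21), so this lineage alone would not be called selected.

The same stages run from the shell:

```bash
repevol synth --tiny --seed 4 --out synth/
repevol run --input synth/repertoire.tsv --v-fasta synth/germline_v.fasta \
    --j-fasta synth/germline_j.fasta --regions synth/regions.bed \
    --out results/ --seed 2 --reps 2000
```

which writes `labels.tsv`, `selection.tsv`, `sweeps.tsv`, `fitness.tsv`,
`dnds.tsv`, per-lineage trees and a manifest with the seed and config hash.

## Documentation

`docs/methods.md` describes the models, statistics, calibration procedure,
numerical choices, what the synthetic generator does and does not emulate,
and known limitations (including an honest account of the power of
unnormalized *H* against the stationary multiple-merger alternative).
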