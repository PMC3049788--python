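# cnc4c

Analysis pipeline for circular chromosome conformation capture (4C)
experiments that interrogate conserved non-coding sequences (CNCs): from
filtered alignment tags to called interacting regions, cis/trans
summaries, conservation-proximity enrichment statistics, bait–bait
proximity networks and gene-set overlap tests — plus a synthetic-data
generator so every stage is testable with known ground truth.

## The problem

A 4C library enumerates the genomic contact partners of one fixed
restriction fragment (the *bait* or viewpoint). For baits placed on
conserved non-coding elements, the questions are:

1. **Which fragments does the bait contact?** Tags are assigned to DpnII
   (GATC) restriction fragments; a fragment observed at least *t* = 50
   times is called an interacting region (CIR). The bait fragment and its
   directly flanking fragments are excluded first — they are
   over-represented through partial digestion and the proximity effect.
2. **How much contact is in trans?** The trans share is
   100 · Σ counts(members off the bait chromosome) / Σ counts(members).
   A library built from purified, non-cross-linked DNA samples fragments
   uniformly, so its trans share approaches the off-bait-chromosome
   genome fraction (~99% for a chromosome-21 bait) — the natural negative
   control.
3. **Do contacted fragments sit near conserved elements?** For each
   member fragment, the center-to-center distance to the nearest
   *non-exonic conservation block* (conserved elements minus exonic
   intervals, pieces inheriting the parent's score) is measured. The
   experiment's distance distribution is compared against a uniform
   sample of genomic fragments (the *simulation* null, default 10 000
   fragments) with the two-sided two-sample Wilcoxon/Mann–Whitney
   rank-sum test, alongside quantile–quantile summaries.
4. **Do baits contact each other, and which genes are nearby?** A
   directed proximity edge A→B records a member fragment of library A
   within 5 kb of bait B; genes within 10 kb of member fragments feed a
   hypergeometric over-representation test
   P[X ≥ k], X ~ Hypergeom(N, K, n).

## Worked example

```python
from dataclasses import replace
import numpy as np
from cnc4c import *
from cnc4c.synthetic import LibraryModel

cfg = SyntheticConfig(seed=7)                 # scaled-down genome, bait chrom ~1.5%
genome = generate_genome(cfg)
index = digest_genome(genome)                 # in-silico DpnII digestion
conserved, exons, _ = generate_annotation(cfg, genome)
blocks = build_nonexonic_blocks(conserved, exons)
bait = make_baits(replace(cfg, n_baits=1), index)[0]

lib = generate_library(cfg, index, blocks, bait, seed=7)
cirs = call_cirs(lib, bait, index, threshold=50)
summary = cis_trans_summary(cirs)
print(f"{cirs.n_members} interacting fragments at the 50-tag threshold")
print(f"trans share: {summary.trans_tag_pct:.1f}% of member tags")

exp = distance_sample(cirs, blocks, label="experiment")
null = sample_null_fragments(index, NullConfig(n_samples=2000, seed=8))
sim = distance_sample(null, blocks, label="simulation")
res = wilcoxon_rank_sum(exp, sim)
print(f"median distance to nearest block: "
      f"{np.median(exp.values):.0f} bp (experiment) vs {np.median(sim.values):.0f} bp (null)")
print(f"rank-sum test: p = {res.p_value:.3g} ({res.method})")
```

prints

```
3602 interacting fragments at the 50-tag threshold
trans share: 100.0% of member tags
median distance to nearest block: 2253 bp (experiment) vs 8102 bp (null)
rank-sum test: p = 0 (normal-approximation)
```

The generator placed a 4× sampling weight on fragments within 5 kb of a
conservation block, and the pipeline recovers exactly that signal: member
fragments sit ~4× closer to blocks than uniformly sampled fragments, and
the rank-sum p-value underflows double precision. The trans share is 100%
here because the bait chromosome is tiny and its cis contacts concentrate
on the excluded bait-flanking fragments.

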