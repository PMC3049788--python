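# Methods

## Coordinate model and digestion

All coordinates are 0-based, half-open; BED I/O is native and the
published-style count-table dialect (`BaitID, Chr, DpnIIStart, DpnIIEnd,
NumbReads`) is converted on read/write, treated as 1-based inclusive by
default because the convention is undocumented (configurable via
`dialect=`). DpnII cleaves 5′ of GATC, so a cut coordinate is the start of
every GATC occurrence and each internal fragment begins with GATC. N bases
never participate in a site match (repeat-masked genomes carry N runs). A
site at position 0 would create a zero-length leading fragment; it can
hold no tags and is dropped. Per chromosome the fragments chain exactly
over `[0, length)`; this partition is asserted property-style in the test
suite against a character-by-character scan oracle.

## Tag processing

Alignments arrive as blat PSL. A tag is kept when: match length ≥ 29 nt
(`matches + repMatches`), no single gap > 1 nt, the read begins with GATC,
and the read maps to exactly one locus. Gap sizes are computed per gap
from consecutive block coordinates (query and target sides), falling back
to the total inserted bases when block structure is absent — the criterion
is per-gap, not total. PSL does not carry read sequence, so when sequences
are unavailable the GATC-prefix criterion is inferred from the alignment
covering the query from position 0; the sequencing primer design
guarantees reads begin at the restriction site, making query-start-0
equivalent to an intact GATC prefix. Accepted tags are anchored to
fragment boundaries: + strand tags to the fragment starting at the tag's
5′ end, − strand tags to the fragment ending at its 3′ end. The default
boundary tolerance is 0 bp (boundaries are exact by construction);
unassignable tags are counted and dropped, and assignment conserves tags
(assigned + dropped = input).

## Interaction calling

The bait fragment and `n_flank` = 1 fragment on each side are removed
before thresholding (the flanking count is a parameter because "directly
flanking" fixes no number; one fragment per side is the minimal reading).
Members are fragments with count ≥ 50, sorted by position; the call is
monotone in the threshold. The trans percentage is computed over member
*tags* (the fraction-of-mappable-tags phrasing), with the member-fragment
percentage reported alongside; an unthresholded whole-library trans share
(`library_cis_trans`) is also provided — thresholding plus flank exclusion
systematically inflates the trans share because cis tags concentrate on
the excluded bait-adjacent fragments, so the unthresholded share is the
right estimator of the underlying trans contact fraction.
Replicate reproducibility is deliberately asymmetric — overlap divided by
the experiment-1 member count — with the symmetric Jaccard offered as a
secondary metric.

## Conservation proximity

Non-exonic conservation blocks are conserved elements minus the union of
exon intervals (interval subtraction via an interval tree); surviving
pieces inherit the parent score. Distances are center-to-center using
floor midpoints, same-chromosome only (no cross-chromosome distance is
defined); fragments on block-free chromosomes are excluded and counted.
Nearest-block ties resolve to the smaller start coordinate. The null is a
uniform sample of restriction fragments, without replacement, seed
mandatory; sampling is per-fragment, not length-weighted. Distances may be
pooled across baits or tested per bait; pooled is the default. The
rank-sum test uses exact enumeration for tie-free samples with
n₁ + n₂ ≤ 20 and otherwise the normal approximation with mid-ranks, tie
correction and continuity correction (ties disable the exact path);
p-values are two-sided throughout. Q–Q summaries use type-7 (linear)
quantile interpolation, fixed and documented because published plots
rarely state theirs.

## Networks and gene overlap

Bait–bait proximity edges are directed (A observed near B) and
center-to-center, consistent with the distance convention; an edge-to-edge
gap measure is available by flag. Reciprocity is not required. Gene
proximity uses the interval gap (genes are long; positional proximity of
the tag is what "within 10 kb" means), overlap counting as gap 0, with a
strict ≤ window boundary. The over-representation p-value is the exact
hypergeometric upper tail; the universe defaults to all supplied genes
because externally curated universes are not bundled.

## Synthetic data: what it emulates

The generator produces the features the statistics rest on and nothing
else — no GC content, repeats, PCR duplicates or quality scores:

- **Genome.** Six chromosomes, 2.69 Mb total, human-like length
  proportions with the bait chromosome smallest (~1.5% of the genome, as
  chromosome 21 is of the human genome). GATC sites are planted at
  geometric spacing (mean 256 bp, the expectation for a 4-cutter);
  background bases are drawn from {A, G, T} so sites occur exactly where
  planted. Deterministic per seed.
- **Annotation.** Non-overlapping conservation blocks with scores uniform
  in [525, 710] (the conservation-score range of the baits this pipeline
  targets). Block counts scale with chromosome length (40 on the longest)
  so block density — and hence the distance-to-block field — is stationary
  across chromosomes; equal per-chromosome counts would make short
  chromosomes denser and invalidate the uniform null. A configurable
  fraction (default 0.2) of blocks is duplicated into the exon annotation,
  so exon subtraction removes them entirely.
- **Libraries.** Each tag is trans with probability `trans_fraction`
  (default 0.95, the trans-dominated end of the observed spectrum), else
  cis with weight (1 + |center − bait center|)^(−1); fragments whose
  center lies within 5 kb of a non-exonic block carry a multiplicative
  weight (default 4). Under this decay the bait fragment itself absorbs
  most cis mass — the self-ligation excess that motivates flank exclusion
  in real libraries. `crosslinked=False` forces uniform per-fragment
  sampling genome-wide regardless of the other parameters. Draws are
  multinomial, equivalent to independent per-tag sampling.
- **PSL emission** writes each tag as a boundary-anchored + strand record
  and can inject known failure modes (sub-29-nt matches, 2-nt gaps,
  multi-mappers) that the filter must remove.

Because trans draws are uniform over off-bait-chromosome fragments, the
whole-library trans share is an exact Binomial(T, trans_fraction)/T draw —
the basis of the parameter-recovery analysis.

## Simulation study conditions

Default library depth is 400 000 tags. At that depth the uniform
per-fragment tag rate is λ ≈ 37, so with no conservation preference only
~2–6% of the ~10 500 fragments cross the 50-tag threshold. This mirrors
the regime of a genome-scale experiment (called fragments ≪ fragment
universe) and matters statistically: when members are a large share of the
universe, the experiment sample and the uniform null sample share many
fragments, the rank test's independence assumption breaks, and the test
becomes conservative. At these conditions the experiment-vs-null test is
well calibrated (empirical type-I ≈ 4–5% at α = 0.05 over 1000
replicates), rejects essentially always at enrichment 4 with hundreds of
member fragments, and declares no-cross-link control libraries
indistinguishable from the null in ≈ 99% of replicates at α = 0.01.

The trans-recovery study uses 19 000 tags per library: the estimator's 2σ
interval is discrete, and its exact binomial coverage varies with depth
around the nominal 95.45%; 19 000 is where the exact coverage is maximal
(95.60%) at trans_fraction 0.95, computed analytically before any
simulation. Note that a "≥ 95% of replicates inside 2σ" check sits at the
estimator's nominal coverage, so individual 200-replicate runs fall below
it with substantial probability even though the estimator is exactly
calibrated; the replicated harness converges to 95.5–95.6%.

## Known limitations

- The PSL-only GATC-prefix proxy cannot detect a read whose first four
  bases align from position 0 yet are not GATC; with the primer design
  this pipeline assumes, such reads do not occur.
- Tags are counted per boundary-anchored fragment only; how tags entering
  a fragment from its far side were originally handled is undocumented.
- No per-fragment significance model beyond the plain count threshold,
  and no multiple-testing correction across baits (raw p-values are
  reported, matching standard practice for this design).
- The synthetic genome's background alphabet omits C; digestion behaviour
  is exact but base composition is unrealistic by construction.
- Published end-to-end numbers that depend on the original genome build's
  conservation and exon tracks (and on an undocumented pooling choice)
  are outside what the synthetic studies can validate; the statistical
  machinery is validated by oracle agreement and calibration instead.
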