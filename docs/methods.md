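# Methods

This note records the models, parameter choices and numerical
conventions behind binforge, and what the synthetic test substrate does
and does not demonstrate about real data.

## Bin quality model

Completion and contamination follow the universal single-copy marker
convention: a catalog of markers expected exactly once per genome;
completion = percentage of markers present at least once in a bin,
contamination = percentage of *extra* copies, Σ_m max(0, copies(m)−1)
over the catalog size. Counting total extra copies (rather than the
fraction of markers that are duplicated) lets contamination exceed
100% for badly merged bins, which is the behaviour of the widely used
checkers; the duplicated-marker-fraction reading is available behind
the `duplicate_fraction` flag of `estimate_quality_markers`.

Gold-standard quality attributes a bin to the genome contributing the
most base pairs (ties broken by lexicographic genome id for
determinism): completion = 100·recall of that genome, contamination =
100·(1−precision). This is the simplest recall/precision →
completion/contamination conversion; note the two estimators live on
slightly different scales (gold contamination is bounded by 100, marker
contamination is not). Genome length in the gold standard is the bp of
that genome *present in the assembly*, so assembly gaps do not depress
gold completion.

Bins are ranked by `S = completion − w·contamination` with default
`w = 5`. The linear form and the weight are this package's design
choice: with w = 5 a percentage point of contamination costs five
points of completion, encoding a strong preference for purity without
making completion irrelevant. `w` is exposed everywhere the score is
used.

Thresholds are inclusive (completion ≥ c, contamination ≤ x)
throughout, matching the convention used when counting "acceptable"
bins.

## Hybridization and consolidation

Hybridization groups contigs by membership signature across the
ordered inputs; contigs unbinned in *any* input are excluded (strict
intersection semantics). The signature relation is an equivalence, so
grouping by identical signature equals the pairwise "no two contigs
together that any input separated" rule; the test suite checks this
against a brute-force oracle. Subset combinations are enumerated
size-ascending, lexicographic by input index, giving a fixed candidate
order: originals (input order) first, then hybrids.

Undersized hybrid signature groups can be dropped via `min_bin_size`.
The library default is 0 (no filtering) so that small or synthetic
assemblies are not silently emptied; the CLI's `hybridize --min-size`
defaults to 500 kb, a sensible floor for real bacterial assemblies.
Filtering happens before scoring.

"Versions of a bin" are identified by greedy matching on shared bp as
a fraction of the smaller bin, threshold 0.8, ties broken by bin name —
deterministic and O(n·m) per pair of sets. Consolidation is a left
fold: the accumulator is matched against the next candidate set,
matched pairs keep their better version, unmatched bins carry over.
Variants meeting (c, x) strictly outrank failing ones; within a class
the score decides; exact ties keep the earlier candidate set, so three
identical inputs come back unchanged. Quality is estimated once per
candidate set, not re-estimated between fold steps (the workflow is
linear: hybridize → score → select → de-replicate).

Bins failing (c, x) are dropped *before* de-replication so their
contigs cannot be stolen from passing bins. De-replication keeps each
shared contig in its highest-scoring bin (ties to the
lexicographically smaller name) and is idempotent. Because removing
contigs can push a survivor back below the thresholds, the final set
is re-estimated and filtered once more — the output therefore always
satisfies the advertised (c, x), at the cost of occasionally dropping
a de-replication casualty.

Two or three input sets are supported (3 or 7 candidate sets); higher
arities are rejected rather than silently generalized.

## Read recruitment and reassembly

The built-in aligner is ungapped Hamming matching over full-length
placements, seeded by exact 21-mer hits on either strand; placements
running off a contig end are skipped and indels are unscored. This is
an adequate stand-in for a real mapper on substitution-only synthetic
reads; real-data users plug an external mapper/assembler through the
same contracts. Strict mode means 0 mismatches; permissive means at
most 4 ("fewer than 5"), applied per mate — a pair is recruited when
its better mate qualifies, so pairs are rescued by one aligned mate
and whole pairs are always emitted. Reads are recruited against each
bin independently, not competitively across bins (competitive mapping
would be a straightforward alternative behind the same interface).

The stub assembler merges reads by greedy longest exact suffix/prefix
overlap (minimum 31 bp), feeding both orientations of every mate into
the pool; it is only meant for error-free synthetic reads. Version
selection reuses the refinement ranking; an exact tie keeps the
original bin, so reassembly never churns output without a measurable
gain, and a failing assembler flags the bin and keeps the original
without aborting the run.

## Quantification

Standardized coverage = raw mean coverage × 10⁹ / total sample bp
(per-Gbp units; "standardized" needs a unit and this one makes equal
community proportions comparable across sample depths). Bin abundance
is the length-weighted mean of member-contig standardized coverages,
so it is bounded by the member min and max. When reads are supplied
instead of a coverage table, coverage is computed from best-placement
read recruitment at the permissive budget — a documented stand-in for
quantification by a dedicated read counter. Heatmaps consume
log10(abundance + 1).

## Synthetic communities

The generator plants exact random marker tags (default 100 per genome,
60 bp) into i.i.d. uniform ACGT backbones — not real genes, but exactly
single-copy by construction, which makes expected completion and
contamination analytic. Strains are derived by per-base substitution
at rate 1 − ANI outside marker loci (markers preserved so marker- and
gold-based quality stay comparable across strains); ANI ≥ 0.95 makes a
"common strain" pair, < 0.95 "unique" genomes. Genomes are cut into
lognormal-length contigs (median 10 kb, σ = 0.7, minimum 1 kb — a heavy
right tail resembling real assemblies) with an exact contig → genome
gold standard; `fragment_with_gaps` instead leaves short uncovered gaps
between contigs to emulate assembly breakage whose losses read
recruitment can recover. Imperfect binnings start from the perfect
per-genome partition and apply contig dropout, random misassignment,
bin merges and bin bisections. Reads are drawn with uniform fragment
starts, normal insert sizes (default 300 ± 30), mate 2
reverse-complemented, and i.i.d. substitution errors.

The study conditions of the benchmark experiments
(`binforge.benchmarks`, driven by `scripts/acceptance.py`):

- **Consolidation**: 5 replicate communities of 20 genomes of 100 kb
  (10 unique + 5 strain pairs at ANI 0.96), 3 binnings each with
  dropout ~ U(0.2, 0.4), misassignment ~ U(0.05, 0.15), 2 merges and
  2 splits; refinement at (c=50, x=10) with the marker estimator;
  evaluation against the gold standard at (90, 5). "Best input" for
  the contamination comparison is the input with the most (90, 5)
  passing bins, ties to the lower mean contamination.
- **Responsiveness**: the same inputs re-refined at (c=90, x=10),
  counting report bins with completion ≥ 90.
- **Recruitment/reassembly**: 10 unrelated genomes of 12 kb,
  error-free reads at depth 20 for recruitment specificity (per-genome
  bins of lossless fragments); never-worse and improvement measured on
  two 4-genome gap-fragmented communities (8 kb genomes, 1.2 kb pieces,
  150 bp gaps) reassembled with the stub assembler.
- **Estimator recovery**: ~120 bins from corrupted binnings of three
  20-genome communities, comparing marker vs gold estimates.

These sizes keep the full benchmark under a minute on one CPU while
exercising every code path at realistic contig/bin granularity.

## What the synthetic substrate does not show

Backbones are i.i.d. uniform, so there are no repeats, no conserved
operons, no compositional (GC, k-mer) structure — the very signals real
binners cluster on — and binning errors are injected, not emergent.
Markers are exact tags, so marker detection has no sensitivity/
specificity trade-off and no estimator bias (real checkers slightly
overestimate both metrics). Reads carry substitutions only — no
indels, chimeras or coverage bias — and the stub assembler cannot
handle errors at all. Passing tests therefore demonstrate the
correctness of the consolidation/selection/recruitment logic under
controlled error modes, not end-to-end performance on real
metagenomes.

## Other limitations and conventions

- Taxonomy is pass-through annotation only; no gene prediction or
  lineage-specific marker selection.
- Contig ids are FASTA headers up to the first whitespace; bin names
  are bin-file basenames; a contig present in a bin but absent from
  the assembly is an error, never silently ignored.
- All randomness flows from numpy Generators seeded explicitly; CLI
  runs write their resolved configuration to `run_config.json`.
- Per-bin quality estimation and per-bin reassembly are independent
  across bins and could be parallelized without changing results; the
  implementation is serial for determinism and simplicity.
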