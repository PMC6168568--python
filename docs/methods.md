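# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of karyoevo. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and data conventions

All internal coordinates are 0-based half-open; GFF3 (1-based closed) is
converted at the I/O boundary and nowhere else. Marker classes
(subtelomeric, pericentromeric, 5S rDNA, large rDNA, tRNA) come from a
curated sidecar table keyed by gene id, because such classes are curated
lists in practice, not free-text GFF attributes. Gene strand on a flipped
contig is recomputed on the fly, never stored twice. Signed genomes are
serialized in the plain text format used by classical rearrangement tools
(one chromosome per line, signed integers, `$` terminator); all writers are
deterministic so round trips are bit-stable.

## Orthology

The unit of evidence is a hit table row (query, subject, E-value, bitscore);
the package never runs a search engine, which keeps analyses deterministic
and desk-scale. A pair is a putative orthologue when each gene is the
other's unique best hit under the E-value ceiling (default 1e-3, the
setting the upstream searches are assumed to use). Best-hit ranking is
bitscore (desc), then E-value (asc), then subject id; a tie surviving all
three marks the query ambiguous and disqualifies it — the deterministic
analogue of excluding unresolvable repeats. Repeat-class genes and genes in
more than one candidate pair are dropped; the synteny filter then keeps a
pair only if at least `min_neighbors` (default 1) other pairs lie within
`window_genes` (default 5) gene positions on both genomes with consistent
order and relative strand. Neither window value is dictated by the source
material ("genes in the neighbourhood were considered"); the defaults were
chosen to recover planted truth at the study scale and are exposed in the
config. Removal is iterated to a fixed point, making the filter idempotent;
the price is that genuinely isolated single-gene orthologues are discarded
by design.

## Synteny blocks

Chaining is per contig pair and per orientation: sparse dynamic programming
maximizes anchor count subject to consecutive anchors lying within
`max_anchor_gap_bp` (default 30 kb) on both genomes with monotone positions
(increasing for +, decreasing for −). The best chain is extracted, its
anchors removed, and the DP repeated; chains below `min_block_anchors`
(default 3) are dropped. The classical minimum-weight criterion of
alignment-based block finders is expressed here in anchor counts — the
aligner-internal weight units of external tools are not portable and are
not imitated numerically. Overlapping blocks are resolved by keeping the
heavier block intact and trimming the lighter at the overlap midpoint, so
blocks tile each genome without overlap. Blocks strictly longer than
`gross_min_block_bp` (20 kb) and outside `subtelomere_margin_bp` (default
50 kb, unquantified in the source material) of a subtelomeric contig end
form the "gross" set used for large-scale counting, since subtelomeres
rearrange promiscuously.

One consequence of gap-bounded chaining: an inverted segment shorter than
`max_anchor_gap_bp` that contains fewer than `min_block_anchors` anchors
can be skipped over by the flanking chain, hiding a micro-inversion. Block
counts therefore equal the true number of maximal conserved segments only
when rearranged segments are longer than the gap bound (tested exactly in
that regime).

## Scaffolding

Contig ends are labelled by the marker classes found within `margin_bp`
(default 50 kb) of each end; pericentromeric markers anywhere on a contig
set a contig-level flag. An adjacency candidate joins two contig ends when
one reference chromosome carries two blocks within `max_reference_gap_bp`
(default 50 kb) of each other, from different contigs, whose contig-side
spans abut the nominated ends with consistent orientation; support is the
bridging anchor count summed per reference. Ordering is a maximum-support
path cover solved by descending-support greedy selection with backtracking
(problem sizes are tens of contigs at most), under three constraints: every
contig used once, each path terminated by subtelomeric-labelled ends, each
path containing a pericentromeric-flagged contig. When references disagree
on a partner for the same end, the earlier reference in the priority order
wins and the conflict is reported; priority defaults to ascending
whole-genome rearrangement distance computed from the blocks themselves, so
the closest relative is trusted most. If several covers tie on support the
assembler reports non-uniqueness rather than silently choosing; a cover
using fewer candidate edges has strictly lower support, so when all true
junctions are supported the true cover is the unique maximum. Assemblies
are canonical up to whole-chromosome reflection (lexicographically smaller
end first) and named by descending assembled length. Contig-end sequence
overlaps are not merged: exported chromosomes join contigs with 100-N
spacers.

## Rearrangement distance and scenarios

The distance model is double cut and join (DCJ), not the restricted
inversion+translocation model: DCJ has an exact closed form
`d = N − C − I/2` over the adjacency graph (N markers, C cycles, I odd
paths), agrees with the restricted distance on the overwhelming majority of
instances, and the distances are used comparatively. The brute-force
breadth-first search the test suite compares against explores all DCJ
moves, so it validates DCJ semantics, not the restricted model.

Scenarios are built greedily: each step realizes one target adjacency,
which provably decreases the distance by one, so scenario length always
equals the distance. Steps are chosen deterministically, preferring (1)
steps whose second join also realizes a target adjacency (resolving a whole
cycle) and (2) same-chromosome inversion-oriented joins, then sorted
order. Operations are typed by their cuts: same chromosome → inversion;
two chromosomes → translocation; a join of two whole chromosomes → fusion;
a pure cut → fission. On rare instances no distance-optimal step keeps all
chromosomes linear (e.g. reordering (+3 +2 +1) to (+1 +2 +3) needs three
linear-only steps but only two DCJs); the scenario then excises a transient
circular segment and reintegrates it, typed `excision`/`reintegration`.
Planted histories of *independent* inversions and translocations are
recovered with their exact type multiset. When planted operations interact
— an inversion spanning a junction an earlier translocation created —
optimal scenarios with different type multisets genuinely coexist, and the
greedy may return one whose counts differ from the history; this is
non-uniqueness of the optimum, not an error, and the type-recovery test
therefore plants independent operations. Circular chromosomes are not
supported as inputs (the study organisms' chromosomes are linear).

Distance summaries divide the operation counts by chromosome number and
genome size (Mb); ratios are rounded half-away-from-zero to 2 decimals and
the gross/all ratio to the nearest integer percent, matching how such
tables are conventionally printed (e.g. 102/16 → 6.38). A zero total count
makes the percentage undefined; it is reported as 0 with a warning.

## Breakpoints and the random breakage model

Adjacent gross blocks on one genome whose counterparts are not immediate,
equally oriented neighbours on the other flank a breakpoint region; the
region is the interval between the block ends, chromosome ends excluded.
Both directions of a comparison can be queried; for histories without
breakpoint reuse the two counts agree. Features are associated with a
region when their span intersects the region extended by
`breakpoint_margin_bp` (default 5 kb — the source material says only that
features sat at block edges, so the margin is exposed in config and
reported next to the counts); association counts are monotone in the
margin. Regions longer than 1 kb containing no gene are flagged "large
intergenic".

Under random breakage, inter-breakpoint segment lengths are exponential,
`f(x) = (1/L)·e^(−x/L)`, with `L` estimated as the sample mean — the
lengths fed in are the gross-block lengths per genome. Because `L` is
estimated from the same data, the plain KS null is wrong; the p-value comes
from a parametric bootstrap (Lilliefors-style): replicates are drawn from
the fitted exponential, the scale re-estimated per replicate, and
`p = (1 + #{D* ≥ D})/(reps + 1)` (default 999 replicates; the statistic is
scale-free under the null, so replicates use unit scale). Samples below 5
segments are refused as meaningless. The acceptance suite calibrates the
test at n = 200: the null rejection rate at α = 0.05 must lie in
0.05 ± 0.02 with uniform p-values, and power against the repeat-clustered
alternative (below) must exceed 0.8.

## Statistics layer

Pearson's r carries the two-sided p from `t = r√(n−2)/√(1−r²)` on n−2
degrees of freedom (at n = 3 this is a Cauchy tail, checked against the
closed form). Group comparisons are rank-based throughout: Kruskal–Wallis
with tie correction, pairwise Mann–Whitney U exact when both groups have
n ≤ 20 and normal-approximated otherwise, p-values reported raw and
Bonferroni-adjusted (both, labelled, since post-hoc conventions differ).
Quartiles use linear interpolation (type-7); the desktop package originally
used for such analyses does not state its convention, so the most common
one was chosen.

## The simulator

The generator emulates the study system, and its defaults are the study
conditions: 3 chromosomes, 500 blocks with log-normal lengths (mean 23 kb,
sd 15 kb, ~11.5 Mb total — the scale of a fission-yeast genome), 9 draft
contigs, histories of 4 inversions + 7 translocations (the closely-related
regime; the second simulated reference uses a longer history), subtelomeric
markers in the 3 terminal blocks of each chromosome arm, pericentromeric
markers in the 3 central blocks, 30 dispersed 5S rDNA loci (the
fission-yeast count is of that order) and 20 tRNA genes near centromeres,
and a 10% decoy rate in hit tables. Each block carries one gene (the
anchor) spanning the block minus 500 bp margins; repeats are 120 bp genes
attached to a block end, so they travel with their flanking sequence
through rearrangements. Cut sites fall on inter-block adjacencies,
uniformly or with 10× mass on repeat-flanking adjacencies under the
repeat-biased model. Fragmentation cuts between blocks, keeps at least
`min_contig_blocks` (20) per contig — a draft contig too short to carry
anchors could never be placed and would make recovery ill-posed — then
shuffles and flips contigs with probability 0.5. All randomness flows
through one seeded generator per run.

Two deliberate idealizations. First, sequence evolution is not modelled:
orthology evidence is injected at the hit-table level (true pairs as strong
mutual best hits, decoys strictly weaker, repeat families many-to-many), so
passing tests say nothing about alignment-level artefacts, paralogy beyond
the repeat mechanism, or gene gain/loss. Second, in the scaffold-recovery
benchmark the reference histories avoid a ±3-block window around the
planted contig junctions. Without that, a reference breakpoint falling
within `min_block_anchors` blocks of a junction erases that junction's
synteny support on that reference, and a non-negligible fraction of random
instances becomes unrecoverable by *any* method; excluding the windows
makes every junction supported in principle, so the benchmark measures
assembler correctness rather than instance solvability. Real data offer no
such guarantee — on real drafts the assembler is expected to report
incomplete or ambiguous covers, which is exactly what the non-uniqueness
and conflict reporting are for.

The repeat-clustered alternative for the breakage-test power run is a
two-point mixture: half the segments near 0.2× the mean, half near 1.8×,
with ±5% jitter — the length signature of breakage concentrated at
recurrent loci, preserving the mean while grossly violating the
exponential law.

## Benchmark problem sizes

The shipped suites use: 200 random ≤6-marker instances for the brute-force
distance check; 150 random ≤8-marker instances for scenario replay; 50
seeded simulations at the default spec for scaffold recovery (must be
100%); 100 seeds at 500 blocks / 20 operations for count recovery (≥95%;
breakpoint reuse at that density is rare, and the distance never exceeds
the planted count); 500 null seeds and 200 alternative seeds at n = 200
segments and 499 bootstrap replicates for the breakage test. These sizes
keep the whole suite in the tens of seconds while leaving the binomial
noise on every rate well inside its acceptance band.

## Known limitations

- Headline counts from the original chromosome-level study (orthologue
  totals, tool-specific block counts, the exact 7-translocation +
  4-inversion scenario, the published supercontig order) depend on the real
  genomes and on manual curation inside external aligners; they are outside
  what simulation can validate and are treated as external references only.
- DCJ distance can undershoot the restricted inversion+translocation
  distance on instances needing circular intermediates; for comparative use
  at study scale the discrepancy is negligible (and bounded below by the
  BFS-verified optimum).
- The per-Mb normalizations depend on the genome sizes supplied by the
  caller; published tables do not print their denominators, so those
  columns are produced but not externally validated.
- Pairwise only: no simultaneous multi-genome blocks, no rearrangement
  phylogenies or medians, no weighted operation costs.
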