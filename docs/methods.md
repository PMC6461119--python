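# Methods

This note documents the models, algorithms and numerical choices behind
islandcap, module by module, including the design decisions that were
genuinely open and what the synthetic-data tests do and do not demonstrate.

## Coordinates and the mask channel

All internal coordinates are 0-based half-open. Exactly two conversion
boundaries exist: GFF3 (1-based inclusive) on input, and VCF (1-based) on
input and output. BED, bedGraph, the 4-column pileup TSV (contig, pos0,
depth, alt_count) and the read-interval TSV (contig, start, end, sample,
dup_flag) are already half-open/0-based.

Lowercase residues are the low-complexity mask channel end to end: the DUST
masker writes lowercase, collapse and merging preserve case, and the tiler
reads it. `N` is treated as masked for probe purposes. Masked bases remain
*members* of the design space — masking steers probe selection and the
≥ 40 bp discard rule, never space membership.

## Similarity engine

The redundancy stages need a local aligner with fixed thresholds
(e-value ≤ 10⁻⁵, identity ≥ 95%, length ≥ 100 bp; all configurable). The
built-in engine is deterministic seed-and-extend:

- exact k-mer seeds, k = 16, both strands, grouped by (subject, diagonal);
- ungapped X-drop extension (X = 20) under +1/−2 match/mismatch scoring,
  reporting the best-scoring extents; seeds inside an already-extended span
  on the same diagonal are skipped;
- significance via the ungapped Karlin–Altschul form
  E = K·m·n·exp(−λ·S) with K = 0.46, λ = 1.28 (the standard constants for
  +1/−2), m and n the *total* lengths of the query and subject sets
  (pairwise-database convention, no effective-length correction).

Because the identity and length thresholds dominate the filter — a qualifying
100 bp hit at 95% identity scores ≥ 70, far beyond significance at desk
scale — the significance constants are non-critical; they are exposed as
configuration.

Gapped extension is deliberately omitted. The redundancy the pipeline
collapses (homoeologous and paralogous copies) is modelled as substitution
divergence, under which the ungapped optimum coincides with the
Smith–Waterman optimum for any gap cost at least as severe as a mismatch.
The test suite holds the engine to that standard: on planted instances the
hits must match Biopython's `PairwiseAligner` local alignments within 2 bp at
each endpoint (local alignment ends legitimately wobble by a base or two when
a flanking base happens to match). An `AlignParams` boundary allows an
external aligner to be substituted without changing downstream contracts.
Indel-bearing inputs would need such a backend; that is a known limitation.

## Symmetric DUST masking

For a nucleotide interval of length L with k = L − 2 overlapping triplets of
counts c_t, the raw score is N = Σ c_t(c_t − 1)/2 and the normalised score
N/(k − 1). An interval (capped at the 64 bp window) is high-scoring when
10·N > T·(k − 1) with T = 20 (the conventional 10× scale, i.e. normalised
score > 2.0), and *perfect* when no proper subinterval scores strictly
higher. The mask is the union of all perfect intervals; the perfectness
condition is what confines the mask to a low-complexity tract instead of
letting high-scoring supersets bleed into flanking sequence.

The implementation enumerates all O(n·w) interval scores incrementally and
computes the running subinterval maximum by the recurrence
M(i, k) = max(score(i, k), M(i, k−1), M(i+1, k−1)), entirely in integer
cross-products — never floats — so rational score ties behave identically in
the implementation and in the brute-force oracle the tests compare against
(which re-enumerates every interval with exact `Fraction` arithmetic).
Masking never crosses a non-ACGT character; runs are processed
independently. The shortest maskable pattern is 5 identical triplets (a 7 bp
homopolymer); a dinucleotide repeat must reach 12 bp. Uniform-random ACGT
sequence is essentially never masked (expected window score ≈ 0.5, threshold
2.0), which the tests assert on seeded fixtures.

## Target extraction

- **Gene targets**: the full 5′UTR-start to 3′UTR-end span, introns included;
  minus-strand targets carry the reverse-complemented sequence. Only
  high-confidence genes pass by default; the confidence label is read from a
  configurable GFF attribute key (default `confidence`, values mapped
  case-insensitively, missing → high) because annotation releases encode
  HC/LC labels in different places.
- **Promoters**: the TSS is the 5′-most base of the gene span (the 5′UTR
  start). A promoter is the 2,000 bp immediately upstream, clipped at contig
  edges and dropped only when clipping leaves nothing — clipping rather than
  dropping preserves maximal target space. One promoter per gene.
- **5′UTR selection** (the promoter-2 extension): a 5′UTR qualifies when
  strictly more than 99% of its bases have depth strictly above 10× in the
  supplied validation track.
- **Exonic miRNAs**: a pre-miRNA is placed by its best full-length hit (ties
  broken by contig then coordinate; multi-mapping pre-miRNAs contribute only
  their best placement). It is exonic iff the pre-miRNA lies wholly inside
  one exon or the whole mature miRNA does; boundary equality counts as
  inside. Exonic mature sequences join the promoter design space.

## Design-space construction

Per reference and per kind (gene / promoter):

1. **Self-collapse.** Sequences with no qualifying self-set hit pass through.
   A sequence whose hit coverage is ≥ 80% of its length enters the redundant
   pool whole; otherwise only its hit-covered sub-spans (merged when gaps
   < 10 bp) enter as fragments, and the unhit remainder is retained. The pool
   is single-linkage clustered over the hit graph; each cluster keeps its
   longest member. Ties prefer the member whose *origin* sequence is longer —
   this maximises reintegration — then the lexicographically smaller id. A
   kept fragment is reinserted at its original coordinates, so an origin that
   kept its remainder comes out contiguous (`reassembled`). The 80% and 10 bp
   constants are genuinely open choices (the collapse semantics require a
   whole-versus-fragment rule but do not determine it) and are configurable.
2. **Organelle purge.** Spans with qualifying hits to the organelle genomes
   are excised; surviving pieces become `.1`, `.2`, … contigs; fully-hit
   sequences disappear.
3. **Masking** (above), then a **length filter** dropping contigs < 120 bp.

References are then merged in their given, recorded order (the merge is
order-dependent by construction): for each addition contig, spans hit by the
accumulated base are removed and unique fragments ≥ 75 bp are appended; base
contigs are never modified. A final < 75 bp filter closes the build. The NR
property — no qualifying hit between any two retained sequences — is asserted
by exhaustive all-vs-all search in the tests, as is idempotence of the
collapse. Reverse-complement redundancy between references is detected (both
strands are always searched) and collapses like any other hit.

Every contig carries provenance blocks (source reference, origin target id,
target-local span) that survive slicing, excision and merging, so probes can
be mapped back to genome coordinates exactly.

## Island tiling

Nominal probe starts lie at 0, 120, 240, … per contig, while at least 50 bp
remain. Candidates at each island are all (start, length) pairs with start
within ±10 bp of the nominal position and length in {50, 55, …, 100};
candidates holding a masked run ≥ 40 bp are discarded. The winner is the
lexicographic minimum of (score, |length − 75|, |start − nominal|, start),
with score = w_mask·masked_bases + w_offtarget·off_target_kmers. On clean
sequence every island therefore yields a 75 bp probe exactly on the grid —
mean spacing 120 bp and mean length 75 bp are calibration checks, not tuned
outcomes. Two readings of "within a 20 bp window" were possible (±10 bp
symmetric, or [nominal, nominal+20)); the symmetric reading was chosen for
evenness and is configurable. A probe never starts at or before its
predecessor. A trailing island is emitted only if ≥ 50 bp remain.

Off-target similarity is a deterministic k-mer proxy for an alignment screen:
the index holds canonical 17-mers present in the background genome but absent
from the design space, and a candidate's penalty is its count of indexed
k-mers. Capacity enforcement inflates spacing to ⌈spacing·n/capacity⌉ and
retiles once, then drops worst-score-first to exactly the capacity if needed.

Capture-coverage estimation pads each probe to the library fragment length
(default 200 bp; left pad ⌊(f − len)/2⌋, remainder right — the fragment's
position relative to the probe is not determined by hybridization itself, so
centring is a convention), clips to the contig, and reports the union as a
fraction of the N-excluded design-space size.

## Evaluation

Breadth, per-target statistics and the coefficient of variation (population
σ/μ over the target-base union, overlaps counted once) are plain per-base
computations, each tested against an independent per-base recount.
High-coverage flagging marks a region whose maximum depth exceeds
10× the *median* of per-region maxima; the median was chosen over the mean
because a single extreme region inflates a mean threshold toward
unreachability (a mean option is retained).

Saturation curves subsample reads binomially and *nested*: each read draws
one uniform deviate and is kept at fraction f iff the deviate ≤ f, so curves
are monotone by construction at a fixed seed. The saturation point is the
smallest fraction whose marginal breadth gain to the next grid fraction is
below 0.5 percentage points.

SNP post-filters: keep iff qual ≥ 50, depth ≥ 5 and alternate allele fraction
strictly > 0.80 (homozygosity); then remove every call lying in *any* 10 bp
span containing ≥ 3 stage-one survivors — the most conservative reading of a
per-window cluster rule, with windows sliding per base. The filter is
idempotent and its output a subset of its input; both are asserted. A
position is comparable across samples iff every sample has a filtered SNP or
≥ 5× coverage with no SNP; the count covers all such positions, while the
returned allele matrix is restricted to positions carrying at least one SNP.

The `naive_pileup_caller` (qual = 50 + 10·alt_count capped at 99) exists to
supply calls for synthetic tests; it is a fixture-grade caller, not a
genotyper, and real pipelines should feed VCFs from an external caller.

## Synthetic data: what it emulates, and what it does not

The genome generator emulates an allopolyploid: each of `n_gene_families`
families has one copy per subgenome. `homoeolog_identity` (default 0.97) is
defined as the identity of each non-anchor copy *to the first-subgenome
anchor*, so the configured value is an exact pairwise identity that interacts
analytically with the 95% collapse threshold; identity between two non-anchor
copies is lower (≈ 1 − 2(1 − i)). Promoter context receives the same
treatment as the gene body. Mutations are substitutions only, so planted
identities are exact and threshold-boundary tests are analytic; indel
divergence is out of scope for the generator. Genes carry 5′/3′ UTRs and
introns (default 3 exons), alternate strands by family, sit downstream of a
2 kbp promoter, and may receive planted (AT)ₙ low-complexity tracts and
organellar insertions, all recorded in a truth set.

The capture simulator is Lander–Waterman-style: probe capture windows are
mapped to genome coordinates through provenance and merged per contig so
overlapping windows do not double-count; fragment counts per merged window
are Poisson with the configured mean depth (default 30×, a desk-scale
simulation size), fragment starts uniform; off-target fragments fall
uniformly over non-design sequence at a rate giving the configured on-target
fraction (default 0.75) and duplicates are flagged binomially (default
0.042). The on-target and duplicate defaults are the values measured for the
full-scale gene capture this design procedure was validated on. Planted
variants are homozygous (allele fraction drawn in [0.9, 1.0]), heterozygous
(drawn in [0.4, 0.6] and capped below the 0.8 filter boundary, so the
homozygosity rule must remove them) or clustered homozygous trios within
8 bp (so the window rule must remove them); clean sites are spaced > 20 bp
apart so dispositions are unambiguous.

What passing tests therefore show: the pipeline's arithmetic, filtering and
selection logic are exact under substitution-only divergence, uniform
fragment placement and Poisson depth. What they do not show: behaviour under
indels and structural variation, hybridization chemistry and GC bias,
repeat landscapes of real polyploid genomes, or mapper-specific artifacts —
none of which the generator attempts to model.

## Determinism

Every stochastic component funnels through `numpy.random.default_rng`
seeded from one configured seed (generators derive fixed offsets for their
sub-streams). Tiling, collapse and all evaluation statistics are fully
deterministic; end-to-end reruns under one seed are byte-identical, which the
acceptance suite asserts file by file.
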