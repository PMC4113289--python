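# Methods

This note records the models, rules and numerical choices behind each
stage of the pipeline, what the read simulator does and does not emulate,
and the design decisions taken where more than one reasonable convention
exists.

## Amplicon model and study design

The pipeline assumes dual-labelled ITS2 amplicons sequenced as overlapping
paired-end reads (2 × 250 bp MiSeq-style):

```
tag(8) + primer_F + anchor_5.8S + ITS2 + anchor_LSU + rc(primer_R) + rc(tag)
```

The same tag sits at both ends of a fragment; both tags are sequenced.
This is the design that lets demultiplexing demand a perfect tag+primer
match at *both* ends, which turns tag switching (a chimera of labels
rather than templates) into an unassignable read instead of a
cross-contaminated sample. Read orientation off the flow cell is random,
roughly 50/50, so reads are reoriented before demultiplexing.

## Stage rules and parameters

| Stage | Parameter | Default | Meaning |
|---|---|---|---|
| quality filter | `mean_q` | 26 | minimum mean phred per mate |
| | `len_min` | 150 bp | minimum mate length |
| merge | `min_overlap` | 5 bp | smallest overlap considered |
| | `max_overlap_mismatch_frac` | 0.25 | reject merges above this overlap mismatch rate |
| | `reject_N` | true | drop merged reads containing N |
| orientation | `mismatches` | 1 | substitutions tolerated in the primer search |
| trim | `head`/`tail` | tag+primer length (26) | bases cut from each end after demultiplexing |
| ITS2 extraction | `max_mismatches` | 1 | per anchor motif |
| | `search_window_*` | 80 bp | how far from each read end an anchor may sit |
| | `min_its2_len` | 30 bp | shorter extractions are uninformative at 97% |
| clustering | `min_size` | 2 | singletons are removed before clustering |
| | `identity_threshold` | 0.97 | OTU radius and read-mapping threshold |
| bimera rule | `model_gain` | 0.02 | two-parent model must beat the best parent by this |
| | `min_diffs` | 3 | diagnostic matches required on each side |
| | `abundance_skew` | 2.0 | de-novo parents must be ≥ 2× the query abundance |
| reference filter | `n_chunks` / `candidates_per_chunk` | 4 / 4 | chunked 8-mer candidate search |
| LCA gate | `min_score` | 170 | bitscore floor |
| | `top_percent` | 5 | hits within 5% of the best bitscore vote |
| | `min_support` | 1 | queries per node; 1 makes it a no-op |

The quality/length thresholds, minimum overlap, 26-bp trim, minsize-2
singleton removal, 97% radii, plus-strand-only chimera search and the LCA
triple (170, 5%, 1) are the standard parameterization for this kind of
dual-tagged MiSeq ITS2 experiment; all are exposed in `PipelineConfig`.

### Merging

Candidate overlaps are every length L from min(len1, len2) down to
`min_overlap` between the 3′ end of R1 and the 5′ end of rc(R2), scored as
matches − mismatches; the highest score wins and ties go to the longer
overlap (more evidence, and deterministic). Consensus qualities follow the
usual posterior convention: agreement min(q1+q2, 41) — 41 being the
phred+33 'J' ceiling — disagreement |q1 − q2| taking the higher-quality
base, and an equal-quality disagreement takes the R1 base at quality 2 so
the uncertainty stays visible. This transparent scoring is deliberately
simple enough to check against an exhaustive oracle; it is not a
re-implementation of any particular assembler's probabilistic model. Note
that with a 5-bp minimum overlap, unrelated read pairs are rejected only
~97% of the time: a short spurious near-perfect overlap occasionally
passes the mismatch cap, which is precisely why downstream primer,
tag and structure checks exist.

### Global identity

Identity between sequences is computed from a Needleman–Wunsch/Gotoh
alignment with match +1, mismatch −1, gap open −2, gap extension −1, and
terminal gaps charged **half an extension point per base** (implemented in
doubled integer units). Identity is matches divided by alignment columns
after trimming terminal-gap columns, so a fragment contained in a longer
sequence scores 1.0. Terminal gaps must be cheap — otherwise ragged
extraction lengths crater the identity of genuinely identical regions —
but they cannot be *free*: with fully free ends the optimal alignment of
two unrelated sequences degenerates to a one-column overlap whose trimmed
identity is a meaningless 1.0. The half-point charge keeps containment
alignments intact and forces unrelated pairs end-to-end, where they score
~0.5–0.65. Ties in the DP prefer substitution over gap states and, among
equal-scoring end cells, the last column before the last row; the suite
pins the whole scheme against an independently written textbook DP.

The DP is numba-jitted; alignments and match profiles are memoised,
which matters because amplicon data is massively replicated.

### The bimera rule

Both chimera filters use one explicit rule. The query's per-base match
profiles against each candidate parent are projected from the pairwise
global alignments onto query coordinates; the two-parent model score at
crossover c is (matches to the left parent before c) + (matches to the
right parent after c), maximized over c and both parent orders (leftmost
best crossover, left-parent-A preferred on ties). The query is bimeric
when the best model identity (per query base) is ≥ the clustering
threshold, exceeds the best *single* parent identity by `model_gain`, and
each side contributes ≥ `min_diffs` diagnostic positions where its parent
matches and the other does not. Single-parent identities inside this rule
use the same per-query-base projection as the model so the gain comparison
is apples-to-apples; the column-based global identity remains the
clustering/mapping measure.

De novo, candidate parents are existing centroids at ≥ 2× the query's
abundance (templates outnumber their chimeras). In reference mode the
skew rule is necessarily waived — references carry no abundances — and
candidate parents come from a chunked 8-mer search: the query is cut into
4 contiguous chunks and each chunk nominates the 4 references sharing the
most 8-mers, because a chimera's halves match *different* references and
a whole-query ranking can miss the minority parent. The accept/reject
decision always uses the full alignment-based rule; the k-mer stage only
nominates candidates, and the suite checks the chunked search against the
exhaustive all-pairs oracle (≥ 99% agreement, misses only ever on the
candidate side, never invented chimeras). The search is plus-strand only,
so reverse-complemented chimeras are by design not detected.

### Clustering conventions

Dereplication is exact, full-length and case-insensitive (output
uppercase). Sorting is by descending size with lexicographic tie-break for
determinism, and `min_size` is applied at sort time — i.e. singletons
never reach the chimera checks. Greedy clustering processes uniques in
that order; a unique joins the first centroid (creation order) within the
identity radius, is otherwise tested as a bimera, and only then founds a
new OTU. Member joins update centroid sizes, so the abundance-skew test
always sees current sizes.

### LCA gate

`top_percent` is implemented as percent-of-best-bitscore (a hit votes when
its bitscore ≥ (1 − p/100) × best); the alternative reading (a fixed score
window) is not used. `min_support` pushes queries assigned to nodes
supported by fewer than the required number of queries up one level until
support suffices; at the default of 1 it is a no-op. Complexity filtering
is disabled (none is applied). Non-fungal OTUs are tallied by the lineage
node directly below the root; unassigned OTUs (no surviving hit, or absent
from the hits file) are tallied as "No hits/unassigned". The homology
search itself is external: the gate consumes a 4-column TSV
(qseqid, lineage, bitscore, evalue).

### OTU table

Reads mapped back to the table are the *pre-dereplication* ITS2 reads,
including singletons that never entered clustering, so table totals can
exceed the summed centroid sizes. Mapping is plus-strand, best-identity
with ties to the lower OTU index, and reads below the threshold are
counted as unmapped (distinguishing "below threshold" from "no OTUs").

## The simulator

`simdata` emulates exactly the study conditions the pipeline targets:
2 × 250 bp pairs; per-sample dual tags (8 bp, the built-in tag set has
pairwise Hamming distance ≥ 5 so single corruptions cannot alias another
sample); ITS2 cores of 180–260 bp drawn at ≥ 10% mutual divergence
(verified with the same identity function the clusterer uses); ~50/50
random read orientation; uniform per-base substitution error at 0.1% with
constant quality q = round(−10·log₁₀ e) capped to [2, 40]; 2%
single-crossover within-sample bimeras with the breakpoint uniform in the
middle 60% of the ITS2 (matching the bimera model the detectors
implement); 1% multi-primer artifacts that carry an extra internal
forward-primer copy at unchanged length, since real artifacts present at
plausible fragment lengths; and optional tag corruption / tag switching
for demultiplexing stress tests. Every read is logged in a ground-truth
table, alongside the OTU × sample table an ideal run should recover
(intact, correctly tagged reads only).

What it does **not** emulate: position-dependent Illumina quality decay
and indel errors, PhiX carry-over, chimeras formed across more than one
crossover or across samples, length-heterogeneous tag sets, and real ITS2
secondary-structure constraints (cores are uniform random DNA, which makes
them *more* divergent than many congeneric species pairs). Passing the
simulation suite therefore demonstrates the correctness of the pipeline's
rules under its own amplicon model, not clustering accuracy on taxa whose
true divergence sits near the 3% radius.

The anchor motifs are configuration data (`src/fungits/data/anchors.yaml`)
shared by the simulator and the extractor, so extraction tests are
model-independent; the default motifs are synthetic conserved-flank
stand-ins of realistic length (26 bp), not copies of any database's 5.8S/LSU
consensus.

## Problem sizes

The test suite and the acceptance script run entirely on simulated data at
desk scale, chosen to keep a full run in the tens of seconds while leaving
every rate measurable: ground-truth recovery uses 10 species × 5 samples ×
2,000 pairs; oracle-equivalence batteries use 1,000 merges, 500 identity
pairs and 200 bimera constructs; demultiplexing stress uses 1,600 pairs
with 6% tag corruption and 6% tag switching; chimera sensitivity uses 8%
injected bimeras (~90 distinct chimeric uniques) and the false-positive
rate is measured over ~300 error-derived uniques. Published-scale read
counts are exercised only through the chimera-accounting arithmetic, which
is size-independent.

## Known limitations

- Quality encoding is fixed to phred+33; other offsets are rejected, not
  auto-detected.
- The merger is not a probabilistic assembler; its mismatch-fraction cap
  is a blunt instrument compared to overlap posterior tests.
- Anchor extraction requires both flanks; fragments truncated into an
  anchor are discarded rather than rescued one-sidedly.
- Reference chimera filtering cannot flag chimeras whose parents are
  absent from the reference set, and false positives on genuinely
  recombinant lineages are possible — verdicts carry `id_model` and
  `id_best_single` so borderline calls can be audited.
- The greedy clusterer is order-dependent by construction (as
  abundance-greedy centroid methods are); determinism is guaranteed, but
  a different sort order would give a different (equally valid) OTU set.
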