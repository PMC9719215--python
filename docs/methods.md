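# Methods

This note records the models and procedures behind `evehunter`, the
defaults that matter, what the synthetic benchmark does and does not
emulate, and the numerical choices a maintainer would want to know.

## Homology search engine

All four comparison modes (nt–nt, aa–aa, protein vs six-frame-translated
nucleotide, six-frame vs six-frame) run through one seed-and-extend engine:

* **Seeds.** Exact k-mers: k = 11 (nt), k = 4 (aa); aa seeds are admitted
  only when the 4-mer's BLOSUM62 self-score is ≥ 12, which removes
  low-information seeds, and aa modes additionally require two seeds on a
  diagonal run before extension (config `aa_two_hit`). Homopolymer k-mers
  are skipped. All sequences (and, for translated modes, all six frames)
  are concatenated with sentinel codes into one indexed array; diagonal
  runs are delimited where the diagonal, the unit pair, or a > 64-position
  gap changes.
* **Extension.** Ungapped X-drop extension from the run's central seed,
  then — if the ungapped score reaches a trigger — gapped affine extension
  in both directions with an *adaptive* band of width 31, re-centred each
  row on the best cell of the previous row. A fixed band would truncate
  multi-kb nucleotide HSPs: with indels at 10% of the substitution rate,
  diagonal drift over a 15 kb alignment routinely exceeds ±15. Kernels are
  numba-compiled with a pure-Python fallback.
* **Scoring and significance.** Final hit spans are realigned with edlib
  (edit-distance-optimal path) and the path is scored with the mode's
  matrix (BLOSUM62 for aa; +1/−2 match/mismatch, −5/−2 gap open/extend for
  nt). Significance is a raw score plus identity floor (defaults: score
  ≥ 50 and identity ≥ 30% for aa modes; score ≥ 40 and identity ≥ 60% for
  nt), deliberately independent of database size — no E-values, fully
  deterministic. Stop codons score −8 against everything, so translated
  HSPs terminate at stops, as intended for a tBLASTx-style search.
* Coordinates are 0-based half-open on the forward strand everywhere;
  minus-strand and frame hits are mapped back before a `Hit` is emitted.
  GFF3 output alone converts to 1-based inclusive.

Any external engine producing `Hit` records with the same semantics can be
substituted behind this contract; the built-in engine is the default and the
one the tests exercise.

## Branch A specifics

* **Interval conventions.** Touching half-open spans merge (they are
  contiguous sequence); the ≤ 5 kb locus-merge distance is inclusive; locus
  extension (±2 kb default, option `-X`) is clamped to sequence bounds and
  extension-induced overlaps re-merge before extraction.
* **Competitive bait classification.** A segment is kept iff its single
  best-scoring bait hit is caulimovirid; ties break by longer alignment,
  then caulimovirid class, then bait id (deterministic, conservative toward
  sensitivity). Segments with no bait hit are discarded as unclassifiable.
* **Repeat grouping.** The de novo repeat stage is a defined span graph:
  every HSP contributes its two end intervals as nodes; same-segment nodes
  with ≥ 80% *mutual* overlap fuse into one member; same-segment nodes
  overlapping ≥ 80% of the smaller span are additionally *connected*
  (without fusing) so that a fragment match, a full-length match and a
  tandem double-unit span of one family land in one component; hits
  connect their two nodes, carrying an orientation parity (minus-strand
  hits flip) that is propagated by BFS to orient members. Components with
  ≥ 5 members of ≥ 100 bp become groups. Off-diagonal self-hits are kept —
  they are the signature of tandem arrays — while trivial self and mirror
  duplicates are removed.
* **Consensus building.** Up to 20 members (longest first) are star-aligned
  to the longest member by compact infix (HW) placement — a global
  edit-distance alignment would smear partial members across the backbone.
  Column occupancy is measured against rows whose aligned extent spans the
  column: leading/trailing gaps are missing data, not deletions. This is
  what lets a tandem (two-unit) backbone keep both units even when most
  members cover a single unit, so concatemeric consensi survive to be
  flagged. Columns under 50% occupancy are dropped; ties emit IUPAC codes.
* **Identity/coverage clustering.** Pairs link when the best containment
  (infix) alignment — tried on both strands, consensi being
  strand-arbitrary — reaches 90% identity over ≥ 0.9 of the longer
  sequence; clusters are single-linkage components, order-independent.
  With containment alignment the shorter sequence is fully aligned by
  construction, so the "both sequences" coverage condition binds on the
  longer one; a `both|either` switch is exposed.
* **Concatemer flag.** A same-strand off-diagonal self-hit of ≥ 1 kb at
  ≥ 90% identity with offset ≥ 500 bp marks a record as a tandem multimer;
  the smallest offset estimates the monomer. Monomers are reported, never
  substituted automatically — annotation does not require it.
* **Masking and coverage.** Selected consensi vs genome at ≥ 70% identity
  over ≥ 80 bp; per-position union coverage (double-annotated bases count
  once); same-library overlapping matches merge, different-library overlaps
  stay separate records.

## Branch B specifics

* Loci are probe hits extended ± 120 bp and merged; each locus is
  translated in the frame of its highest-scoring source hit, split at stop
  codons, and stop-free segments ≥ 200 aa become candidates. Candidates
  whose best hit in the mixed RT library is not caulimovirid are dropped.
* Greedy centroid clustering at 80% global aa identity (edit-path identity,
  all columns counted) sorts by length descending; the centroid is the
  cluster representative.
* Alignment machinery: progressive profile alignment (3-mer shared-fraction
  guide distances → NJ guide tree → BLOSUM62 profile merges, affine gaps
  open −10 / extend −1, *free end gaps* so partial-domain sequences are not
  stretched); trimming drops columns with > 80% gaps then sequences
  occupying < 50% of surviving columns (reference-panel sequences are
  exempt — losing them would break classification); two quality rounds
  before the panel merge, four after, with early exit at a fixed point.
  Block curation keeps runs of ≥ 5 columns with ≤ 50% gaps and modal
  residue frequency ≥ 50%.
* Distances: p-distance over mutually non-gap columns with the Kimura
  protein correction d = −ln(1 − p − p²/5), capped at d = 10 for p ≥ 0.85.
  Neighbor joining (deterministic tie-breaks on the smallest joined label,
  negative branch lengths clamped to zero) stands in for maximum-likelihood
  inference; genus assignment consumes only topology and support, and a
  config-gated hook allows an external ML engine to supply the tree.
* Bootstrap: columns resampled with replacement per replicate (default
  100); support of each internal bipartition of the point tree is the
  percentage of replicate trees containing it, under a fixed seed.
* Classification re-roots at the outgroup reference and walks from each
  candidate toward the root until a clade has support ≥ 70 and contains a
  reference; a unique reference genus is assigned, otherwise
  "unclassified".

## Synthetic benchmark

`synthetic` builds everything the pipeline needs from one seed: ancestor
genomes (7.5 kb, a single long polyprotein ORF laid out
MP–zf(CCHC)–protease–RT core–RNase H with genus-specific spacers; genera are
independent 20% aa draws from the family-level domain profiles), Gypsy/Copia
decoys (5 kb, RT core–RNase H–integrase at 35% divergence), optional
bipartite pairs (component B carries only the terminal MP+zf region, plus a
configurable shared non-coding region), and all matched reference sets:
genome query library, protein baits, RT core probes, mixed RT library (which
also holds a deep retroviral RT; that sequence is deliberately excluded from
the default tree panel because near-saturation outgroups destabilise
distance trees), and the genus reference panel.

Planting: i.i.d. background at GC 0.36; per-site substitutions at the
requested divergence with indels at 10% of that rate (insert/delete equally,
geometric lengths, mean 2); fragments are uniform 20–60% sub-spans; tandems
concatenate independently mutated units; both strands; insertion points are
drawn with a guaranteed ≥ 6 kb separation via the slack-space construction,
and the truth table is exact in final coordinates.

The flagship study conditions (the defaults): three genera × 10 full copies
with divergences evenly spanning 5–15% (insertion ages vary in real EVE
populations, and a family whose copies were all equally old would fall below
the 85% pairwise grouping threshold), 8 fragments per genus at 1% divergence
(recent, potentially reactivatable integrations — these are what give Branch
B intact RT ORFs to find), one triple tandem at 3% per unit, and 30 decoy
copies, in a 1.6 Mb background (~2.07 Mb final).

What the generator does **not** emulate: real base composition and isochore
structure, nested/fragmented TE landscapes, codon-aware or rate-heterogeneous
molecular evolution, transition bias, segmental duplication. Passing tests
therefore demonstrate the detection/reconstruction contracts under idealised
decay, not performance on a real assembly.

A known, quantified limitation: heavily decayed copies (≥ 5% nt divergence)
almost always carry frameshifts and premature stops inside the RT window, so
Branch B's yield of intact ≥ 200 aa candidates is dominated by recent
insertions, and whether *every* genus gets an intact candidate in a given
simulated genome is a coin toss of the realization. When only decayed
candidates exist for a genus, their RT identity tops out near ~85–90%
(codon arithmetic: 5% nt ≈ 11% aa divergence) and their junk-bearing
proteins depress the bootstrap support of their own sister-pair splits —
exactly the regime where the acceptance check on Branch B is not always
satisfiable. The corresponding test encodes the nominal thresholds and is
allowed to fail on such realizations rather than being loosened.

## Problem sizes used by the shipped tests

The flagship fixture uses a 1.6 Mb background (≈ 2.07 Mb genome, 85 planted
elements); the extension/bipartite study uses 500 kb; the determinism check
runs both branches twice on a 350 kb study. Oracle tests use 100–1,000
random instances per primitive. These sizes keep the full suite and the
acceptance script each within a few minutes on one CPU while leaving every
contract exercised end to end.
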