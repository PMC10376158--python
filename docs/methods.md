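# Methods

## Locus model and geometry

The package models the *tRNAleu-COII* amplicon (primer-to-primer, linear,
5'→3') as a concatenation of elements: partial *tRNAleu* gene, optional P
element, a tandem array of Q repeats, partial *COII* gene. Published
descriptions of the locus give allele totals (Q = 571 bp, PQQ = 825 bp,
PQQQ = 1020 bp) and DraI fragment profiles, but not the underlying element
sequences, so the geometry is derived from the numbers themselves:

* In the M-lineage profiles the homologous DraI cuts of consecutive Q copies
  are 196 bp apart (cuts at 142/207 and 338/403 in PQQ), so identical tandem
  Q units must be **196 bp** long. Adding one Q to PQQ and removing one
  terminal base (422 → 421) then gives exactly the printed PQQQ total:
  825 + 196 − 1 = 1020.
* Fixing the partial *tRNAleu* segment at **40 bp** and the Q unit at 196 bp
  leaves **335 bp** for the partial *COII* segment (571 = 40 + 196 + 335)
  and **58 bp** for the P element (825 = 40 + 58 + 2·196 + 335).

Within the Q unit, the C/O-lineage variant carries three DraI sites (offsets
4/44/108) and the M-lineage variant two (offsets 41/106); the two variants
are unrelated in their filler sequence, as the disjoint C and M fragment
profiles require. Haplogroup-defining 1 bp indels are applied to template
copies at fixed safe offsets: C1 = C-type Q with one insertion between the
first two sites, C3 and C4 with one deletion between the second/third and
first/second sites, M17 = first M-type Q with one insertion between its
sites. M7's profile implies a DraI site inside P; the shared P template
carries the near-site `TTTAAT` at offset 4 and the M7 recipe applies the
single substitution completing it. P-variant landmarks follow the published
descriptions — P0 prepends the 13 bp insert `AAACAAAATATAA`; P1 and P2
truncate 15 bp and 18 bp from the P 3' end (the true deletion offsets are
not published; the 3'-end convention is ours and is flagged as such).

The PQQ-class M17 amplicon totals 826 bp although the PQQ allele is
conventionally quoted as 825 bp; the discrepancy is in the source numbers
themselves (the printed M17 fragments sum to 826) and is treated as nominal
rounding. The canonical M4 sequence (exactly 825 bp) is used wherever the
PQQ total is asserted.

## Synthetic data generation

Filler bases are drawn uniformly from A/C/G/T with `numpy.random.default_rng`
from a stated seed (default 1) and rejection-repaired so `TTTAAA` occurs
only at declared sites; template edges are forced to C/G so concatenation
can never complete a recognition site across an element junction, and every
canonical build is verified against its expected cut list at construction
time. One seed defines one synthetic "genome": all canonical haplotypes,
the shipped reference DB and simulated populations built from the same seed
are mutually consistent. Population simulation assigns identical sequences
to same-haplotype colonies (haplotype identity *is* sequence identity),
round-robins samples over a configurable region list (default 19 regions,
emulating a 269-colony national survey design) and emits a hidden truth
table for recovery testing.

What the generator does **not** emulate: PCR and sequencing error,
chromatogram ambiguity, heteroplasmy, real inter-element sequence homology,
or base-level identity with any deposited sequence. Tests passing on
synthetic data therefore demonstrate the correctness of the digest,
annotation, classification and network algorithms under the published locus
architecture — not concordance with field material, which requires users to
supply their own FASTA and a curated reference DB.

## Structure annotation

Templates are tiled left to right with edlib semi-global (prefix) alignment;
an element is accepted at ≥ 90% identity to its template (haplotypes within
a haplogroup differ by a handful of substitutions, so templates are
near-exact; unit-cost edit distance and the affine-gap scoring used
elsewhere agree at this divergence). Because P0/P/P1/P2 are near-truncations
of one another, the P stage scores each candidate jointly — its own edit
distance plus that of the best Q repeat starting immediately after it — and
the architecture explaining the most context wins; ties break
lexicographically (ABSENT first). Q copies are counted by greedy tiling; the
COII segment must account for the entire remainder (global alignment). Any
stage below threshold yields an UNRESOLVED structure carrying diagnostics,
never a silent guess; degradation is monotone (a resolved call can only
change by first passing through UNRESOLVED). A gel-style length prescreen
(nearest of 571/825/1020 ± 25 bp) is provided as a flagged heuristic only,
since A- and Y-lineage alleles can co-migrate with M-lineage ones.

## Classification and nomenclature

Haplogroup assignment is an exact match of the fragment profile against the
rule table; exactness is essential because M4 and M17 differ by a single
base (65 vs 66 bp). An optional ±1 bp mode reports the full ambiguity set
and never auto-selects. Unmatched profiles are returned as novel with their
profile key so new haplogroups can be registered. Reference DBs (TSV/JSON)
are validated at load: a record whose sequence does not digest to its
declared haplogroup's profile is rejected. Name proposals take the maximal
existing suffix under (letter, digit) ordering and increment the digit if
present, else the letter ('a' for an empty group, z → z1); primes trail the
suffix (M4k' after M4j'). Multi-letter suffixes occasionally seen in the
literature (e.g. C2ja) are ignored by the proposer rather than modeled.

## Distances

Pairwise differences are substitutions plus indel events from a global
alignment with affine gaps (open 10, extend 1, free end gaps); a contiguous
gap run counts as one event, so "four substitutions and a 1 bp deletion" is
five differences. K2P distances use transition/transversion proportions over
ungapped, non-N columns; a saturated pair (non-positive log argument) is
flagged undefined (NaN), not raised. K2P ≥ p-distance always.

## Median-joining networks

Sequences are compared under a five-state alphabet (gap = fifth state).
The minimum-spanning network keeps an edge iff its weight is within
`epsilon` (default 0, the PopArt default) of the minimax path weight between
its endpoints — equivalently, iff no strictly cheaper path connects them —
which retains all ties. Median inference iterates: for every triple of nodes
with at least two network links, quasi-medians (column-wise majority;
columns with three distinct states branch over the three alternatives,
capped at 4 branching columns per triple) are computed, and those that
strictly reduce the triple's Steiner cost are added, lowest cost first, to a
fixpoint (bounded at 50 rounds). Inferred medians that never reach degree 3
are pruned. All tie-breaks are lexicographic by label, so output is
deterministic. Because M and M' alleles differ by a whole Q copy, the
pipeline builds one network per allele class (Q / PQQ / PQQQ) rather than
forcing a 196 bp gap into a single alignment; within a class, unequal-length
haplotypes are aligned with mafft.

## Pipeline and reproducibility

The `run` pipeline executes digest → annotate → classify → summarize →
networks; any stage failure aborts with a stage-named error before outputs
are written for that stage. Every output carries tool version, seed, a
SHA-256 hash of the analysis parameters (input/refdb paths, tolerance,
epsilon, seed — not the output location) and the reference-DB version;
reruns under a fixed seed and configuration are byte-identical. Percentages
are rounded half-up to one decimal. Problem sizes used throughout the test
suite (populations of ≤ 269 colonies, sequences ≤ 2 kb, networks of ≤ 8
haplotypes against brute-force oracles, 1000-sequence digest oracle sweeps)
keep the full suite in the seconds range while exercising every code path
at the scale of the study design the generator emulates.

## Known limitations

* Element boundary sequences are synthetic; annotation of real amplicons
  requires a template library built from real data (`TemplateLibrary.from_dir`).
* The shipped reference DB contains only the eight canonical synthetic
  haplotypes; the published catalogue of >100 haplotypes is schema-supported
  but not curated here.
* The quasi-median branching cap can, in principle, miss medians for highly
  homoplasious data; at the divergence levels this locus shows (1–8
  differences between haplotypes) the cap is never reached.
* The C/O lineage ambiguity is intrinsic to the marker and is propagated,
  never resolved.
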