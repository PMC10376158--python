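# beehap

In-silico DraI typing of the honey-bee mitochondrial *tRNAleu-COII* locus.

## The problem

The non-coding mtDNA region between the tRNA-leucine and cytochrome-oxidase-II
genes (the *tRNAleu-COII* or *COI-COII* intergenic locus) is the standard
marker for establishing the maternal evolutionary lineage of *Apis mellifera*
colonies — a question that matters wherever native subspecies such as the dark
forest bee *A. m. mellifera* (lineage M) hybridize with introduced C-lineage
stock (*A. m. carnica*, *A. m. ligustica*). The locus consists of a partial
*tRNAleu* gene, an optional **P element** (forms P0 / P / P1 / P2,
distinguished by a 13 bp insert `AAACAAAATATAA` and 15 bp / 18 bp deletions),
one to three tandem copies of a ~196 bp **Q element**, and a partial *COII*
gene. Lineage C/O lacks P entirely (allele `Q`, 571 bp); lineage M carries
`P(Q)1–n` (`PQQ` = 825 bp, `PQQQ` = 1020 bp); lineages A and Y carry the
P0/P1 and P2 forms.

Digesting the amplicon with DraI (recognition site `TTTAAA`, blunt cut
`TTT^AAA`) yields a fragment-length profile that defines the **haplogroup**
(e.g. `47/40/64/420` → C2, `142/66/131/65/422` → M17,
`142/65/131/65/131/65/421` → M4'); unique sequences within a haplogroup are
**haplotypes**, named by letter suffix (C2c, M17j, M4g'...).

`beehap` implements this workflow end to end, for users typing their own
FASTA amplicons and for method work on synthetic data:

* **synthetic locus generator** — deterministic canonical and mutated
  amplicons reproducing the published allele sizes and digest profiles,
  plus whole simulated populations with truth tables;
* **in-silico DraI digestion** and profile reporting;
* **structure annotation** — element tiling (tRNAleu / P form / Q count /
  COII) by semi-global alignment at a 90% identity gate, and lineage calling;
* **classification** — haplogroup rule table, exact-sequence haplotype
  matching against a reference DB, novelty detection with
  nomenclature-compliant name proposals;
* **population statistics** — frequency reports, substitution+indel
  difference counts, Kimura 2-parameter distances
  (d = −½·ln((1−2P−Q)·√(1−2Q)));
* **median-joining haplotype networks** with quasi-median inference,
  exported as GML and a PopArt-style Nexus network block.

## Worked example

Simulate the design of a 269-colony survey (71 C-lineage colonies carrying
the C2 haplotype, 198 M-lineage colonies carrying M17) and run the full
pipeline:

```bash
echo '{"C2": 71, "M17": 198}' > freqs.json
beehap simulate --freqs freqs.json --seed 1 --out-prefix pop
beehap run pop.fasta --outdir out
```

The run prints one log line per sample per stage and finishes with

```
lineage shares: {"C_or_O": 26.4, "M": 73.6}
```

i.e. 26.4% of colonies belong to lineage C (reported as `C_or_O` because
this marker cannot separate the C from the O lineage) and 73.6% to lineage
M. `out/report.json` contains the full frequency report
(`"haplotype_counts": {"C2": 71, "M17": 198}`), `out/calls.tsv` the
per-sample lineage/haplogroup/haplotype calls, `out/profiles.tsv` the digest
profiles (e.g. `S0001  571  3  47/40/64/420`), and `out/networks/` one
median-joining network per allele class. Every output names the tool
version, seed, config hash and reference-DB version.

The same steps are available as library calls (`simulate_population`,
`digest`, `annotate`, `match_haplotype`, `summarize`, `build_mjn`) and as
individual subcommands (`beehap digest|annotate|classify|network|report`).

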