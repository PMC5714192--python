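# asmrecon

Assembly reconciliation and quality-control toolkit for the situation every
reference-genome upgrade faces: a new, more contiguous assembly must be
compared against, merged with, and error-checked against its predecessor.
It is written for genome-assembly practitioners and grew out of the
computations used when a fragmented great-ape reference (180 000+ contigs,
~160 000 gaps, contig N50 around 50 kbp) was replaced by a hybrid assembly
with a contig N50 in the hundreds of kbp.

What it does:

* **Contiguity statistics** — scaffold/contig N50 and N90, assembly length
  with and without Ns, contig and gap counts, under the standard
  definition of a gap as a run of ≥ 10 consecutive `N`s and Nxx as the
  smallest L with pieces ≥ L holding x of the bases.
* **Cross-assembly gap patching and closure accounting** — extract the
  flanks of every gap, map them to a second assembly, keep only unique and
  concordant flank pairs that span no gap on the other side, and either
  merge the spanned donor sequence in or count the gap as closed. Implied
  fill lengths may be negative: wrongly separated overlapping contig ends.
* **Misjoin detection and scaffold breaking** — discordant mapping of
  long-insert end pairs (fosmid-scale, ~40 kbp inserts) against a robust
  insert-size model; clustered discordances with no concordant spanning
  pair become break calls, snapped to gaps.
* **Polishing** — pileup-consensus correction of near-fixed substitutions
  and short indels, strictly < 6 bp, with heterozygous-like sites left
  untouched.
* **Segmental duplications** — WGAC (repeat-masked self-alignment, blocks
  ≥ 1 kbp at ≥ 90% identity, redundant pairs plus non-redundant union) and
  WSSD (read-depth excess vs known unique regions from reads placed at
  > 94% identity, calls ≥ 10 kbp), and their bp-level concordance.
* **Feature permutation test** — empirical enrichment of intervals in
  annotation features under a length-preserving, gap-excluded random
  placement null, P = (1 + #{null ≥ obs})/(reps + 1).
* **A seeded simulator** — genomes with repeats and duplications, derived
  draft assemblies with planted gaps/misjoins/errors/collapses, end pairs
  and reads with true placements: exact ground truth for every stage.

Standard formats throughout: FASTA, AGP v2.0, BED, PAF, SAM. The built-in
k-mer/edlib aligner handles desk-scale inputs (≤ ~10 Mbp); precomputed PAF
from an external aligner is accepted everywhere alignments are consumed.

## Worked example

Simulate a 500 kbp genome, derive a draft with 20 planted gaps (15% of
them negative), and reconcile the draft against the genome:

```bash
$ asmrecon simulate --genome-len 500000 --n-gaps 20 --neg-frac 0.15 \
      --seed 7 --out-dir sim
genome 500000 bp; derived has 20 gaps, 0 errors, 0 junctions

$ asmrecon stats --fasta sim/derived.fasta --out-dir stats_out
Scaffold N50, bp              487588
Contig N50, bp                 28026
Contig N90, bp                 10772
Assembly length, bp           487588
Assembly length w/o Ns, bp    481593
Scaffolds                          1
Contigs                           21
Gaps                              20

$ asmrecon gappatch --asm sim/derived.fasta --donor sim/genome.fasta \
      --out-dir patch_out
gaps: 20  filled: 20 (100.0%)  fill bp: 18723
patches applied: 20  skipped: 0

$ asmrecon stats --fasta patch_out/patched.fasta --out-dir stats2
Scaffold N50, bp              500000
Contig N50, bp                500000
...
Contigs                            1
Gaps                               0
```

Reading the numbers: the draft's 20 gaps split one 500 kbp sequence into
21 contigs (contig N50 28 kbp); its 487 588 bp include 5 995 bp of gap Ns
in place of 18 723 bp of true sequence (some fills are negative, so the
draft is shorter than the genome). All 20 flank pairs map uniquely and
concordantly to the donor, all 20 patches apply, and the patched assembly
is exactly the 500 kbp genome again — one contig, no gaps. Each command
also writes a `run_manifest.json` (command, config, input checksums, seed,
wall-clock) and machine-readable outputs (verdict TSV, fill-length
spectrum, patched FASTA + AGP).

`asmrecon demo --seed 7` runs every stage on synthetic data and writes a
truth-vs-called scorecard; the other subcommands (`breakfix`, `polish`,
`segdup`) follow the same pattern on SAM/TSV/BED inputs.

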