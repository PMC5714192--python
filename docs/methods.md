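# Methods

`asmrecon` implements the quality-control and reconciliation computations
used when a fragmented mammalian reference assembly is superseded by a more
contiguous one built from the same individual: contiguity statistics,
cross-assembly gap patching and closure accounting, long-insert end-pair
misjoin detection, pileup polishing of small residual errors, and
segmental-duplication detection by self-alignment (WGAC) and by read-depth
excess (WSSD). A seeded simulator generates genomes and derived draft
assemblies with exact ground truth, so every stage is testable end to end
without external data.

## Definitions and conventions

All coordinates are 0-based half-open internally and in BED/TSV output; AGP
output is 1-based inclusive per the AGP v2.0 standard. A **gap** is a
maximal run of at least `min_gap_len` (default 10) consecutive `N` bases;
**contigs** are the complementary maximal stretches with no qualifying
N-run. Shorter N-runs are contig-internal bases: they do not split contigs,
but they are still Ns and therefore excluded from "assembly length without
Ns". Nxx is the smallest piece length L such that pieces of length ≥ L
contain at least x of the total bases; when the cumulative sum hits x·total
exactly, that piece's length is returned (≥ convention), so results are
bit-stable. Ambiguity codes are normalized to N on read (count logged);
soft-masking is recorded but ignored by the gap census, whose definition
concerns Ns only.

## Built-in aligner

Flank mapping and WGAC need a local aligner at desk scale. The built-in one
seeds with exact k-mers (k = 15, sorted-array index), clusters seeds by
diagonal (band 100 bp, chain gap 2 kbp), and refines each candidate locus
with an edlib glocal alignment, whose extended CIGAR gives exact match
counts. Score is `matches − 4·edits`. **Uniqueness** uses the standard
score-gap proxy: the best hit must exceed the runner-up by ≥ 20% of its own
score. The aligner is intended for queries up to a few kbp against targets
up to ~10 Mbp; larger jobs should be aligned externally (e.g. minimap2) and
imported as PAF — the module interfaces accept precomputed alignments for
exactly this reason.

## Gap patching and closure accounting

For each gap we extract `flank_len` = 1000 bp of flanking sequence on each
side (truncated at scaffold ends and neighboring gaps; flanks under 200 bp
make the pair unusable). Both flanks are mapped to the donor assembly and
the pair is classified: **PATCHABLE/CLOSED** requires both flanks unique,
on one donor scaffold and strand, correctly ordered, implied fill within
[−flank_len, 100 kbp], and no donor gap inside the spanned interval
(**SPANS_GAP** otherwise); remaining cases are AMBIGUOUS, DISCORDANT or
UNMAPPED. The **implied fill length** is the donor distance between the
inner flank-hit ends and may be negative: the gapped assembly wrongly
separated overlapping contig ends. Patching copies the donor sequence
strictly between the inner hit ends (reverse-complemented for minus-strand
hits); a negative fill of −o removes the gap's Ns plus the o duplicated
bases following the gap, collapsing the overlap once. Flank lengths, the
uniqueness margin, and the fill-span guard are not dictated by the
procedure being reproduced (which states only "unique and concordant
mappings that do not span any gaps"); they are documented defaults, and
closure percentages should be treated as parameter-sensitive.

## Misjoin detection from end pairs

Long-insert end pairs (fosmid-scale, modeled Normal(40 kbp, 4 kbp)) are
classified against a robust insert model (median, MAD·1.4826, SD floor
1 bp, fitted from ≥ 50 same-scaffold innie pairs): CONCORDANT requires one
scaffold, convergent orientation, and an implied insert within
mean ± 3 SD. Discordant pairs are clustered **per orientation class**
before span intersection. This matters for inversions: pairs straddling
the left junction have both ends on + (the inner mate is reflected to the
segment's far side), pairs straddling the right junction are both on −,
and their spans all cover nearly the whole inverted segment. Pooled
clustering would intersect the two families into an interval whose
interior carries normal concordant coverage, vetoing the call; per-class
clustering separates the junctions. Each ++/−− cluster's interval is then
tightened with the mirror cluster's near ends, which bound the same
junction from the other side. A cluster becomes a break call when it has
≥ 3 supporting pairs and some point of its interval has zero concordant
spanning coverage; the breakpoint snaps to the nearest gap inside the
concordant-free window (scaffolding joins are where misjoins live), else
to its midpoint. Cross-scaffold pairs alone are not evidence
(conservative). At 6× physical coverage a junction is spanned by
Poisson(6) discordant pairs, so ~6% of junctions fall below the 3-pair
threshold — recall near 0.9–1.0 per run is the expected physics, and
breakpoint precision is a few kbp (observed mean 0.6–2.3 kbp on the
bundled fixtures). Junctions of rearranged segments much shorter than the
insert are increasingly spanned by fully concordant pairs and are
intrinsically hard for this evidence type. Equal-length segment swaps
(translocation chimeras) produce four junctions whose discordant spans
interleave; the caller typically localizes one or two of them — inversion
junctions are the well-posed case and are what the bundled fixtures plant.

## Polishing

Reads are piled up per site with per-allele counts (substitutions,
insertion strings anchored before a position, deletions anchored at their
first base). Sites within 10 bp of a gap edge are never edited. An edit
requires depth ≥ 5 and a near-fixed allele: support ≥ 0.8 with
substitutions additionally out-voting the reference base. Heterozygous-like
sites (support ≈ 0.5) are deliberately left alone — the assembly is a
haploid mosaic and only near-fixed discrepancies qualify as errors. Two
subtleties drive the design:

* **Representation fragmentation.** Aligners may express one multi-base
  indel as different, equally optimal combinations of smaller ops in
  different reads, so no single allele reaches the support threshold.
  Indel candidacy therefore uses locus support — the fraction of spanning
  reads carrying *any* indel within ±10 bp — with the reported allele
  backed by at least half of those carriers. Partial repairs complete on a
  subsequent pileup round; the bundled closed loop iterates to convergence
  (one or two rounds in practice).
* **The strict <6 bp rule.** A 6 bp indel can be split by alignment into
  smaller adjacent ops that would individually pass a per-op length
  filter. The rule is therefore enforced on the net local discrepancy:
  candidate indels within 10 bp are grouped, and a group is rejected when
  its net length change, any single member, or the *median per-read net
  indel content* at the locus exceeds 5 bp. The last criterion sees the
  true size of a large indel even when no aligned op does.

Edits apply right-to-left per scaffold; `invert_edits` produces the exact
inverse set (coordinates shifted by cumulative length changes), giving
byte-identical round-trips.

## Segmental duplications

**WGAC** hard-masks annotated repeats, collects k-mers shared between two
loci on either strand (occurrence cap 50, ≥ 3 shared seeds per diagonal
band), aligns each locus pair with edlib on the seed extents, chains
collinear hits separated by ≤ 2 kbp (identity of a chain is the
column-weighted mean of members — so a block interrupted by a masked
repeat still chains without the mask diluting identity), and keeps pairs
with both sides ≥ 1 kbp at ≥ 90% identity, excluding the trivial
self-match. Every pair is emitted with its mirror; the non-redundant
duplicated bp is the base-level union, with non-gap bases as the
denominator for fractions.

**WSSD** takes read placements filtered to identity strictly above 94%,
computes depth in 5 kbp windows at 1 kbp steps over gap-free sequence, and
calibrates mean/SD on windows fully inside known unique regions
(operationally: the WGAC-negative, gap-free fraction; ≥ 100 calibration
windows required). Windows above mean + 3 SD are flagged, runs merged
across ≤ 2 unflagged windows, and merged regions are trimmed to the
outermost depth-elevated 1 kbp tiles before the ≥ 10 kbp length filter —
full-window flagging alone overhangs true boundaries by up to ~4 kbp.
WSSD sees collapsed duplications (two copies in the genome, one in the
assembly, doubled depth) that self-alignment cannot, which is exactly the
discrepancy the WGAC/WSSD comparison table quantifies.

## Feature permutation test

The observed statistic is the fraction of query intervals with ≥ 1 bp of
feature overlap (a bp-weighted variant is provided). The null re-places
each query interval uniformly at random within the universe —
length-preserving, same scaffold, gap-excluded, segments weighted by the
number of valid start positions — and the one-sided empirical P uses the
+1 correction: P = (1 + #{null ≥ observed})/(reps + 1), so 10 000 default
replicates make P < 10⁻⁴ representable. With the interval-count statistic
the null distribution is discrete and the ≥ tie rule makes the test
conservative (true rejection at α = 0.05 runs below nominal); the
bp-overlap variant is nearly continuous and calibrates at nominal level,
which is what the bundled calibration check measures.

## Simulator

The generator emulates the data regime of a reference upgrade: a random
genome at 41% GC (great-ape-like) with planted repeat families (per-base
divergence from a consensus) and segmental duplications mutated to a
target identity; a derived draft with planted gaps (true sequence replaced
by N-runs of unrelated length; a configurable fraction are negative gaps
that duplicate a contig-end overlap on both sides of the N-run), collapsed
duplication copies, inversions and equal-length segment swaps, and point
errors (substitutions and indels with configurable counts, including
deliberate 6 bp boundary cases); end pairs at a chosen physical coverage
with truncated-normal inserts and optional chimeras; and reads with true
placements emitted as SAM, so no external mapper is needed. Everything is
deterministic under one integer seed. Rearrangements are applied to a
piece table in descending genome coordinate over margin-separated feature
windows, which keeps every planted feature's coordinates exact in both
genome and derived frames; ground truth records gap fills (position,
sequence, signed length), error corrections, junctions, collapse maps and
the full segment map.

What the simulator does not emulate — and hence what passing tests do not
show about real data: sequencing base-quality structure and error biases,
diploid heterozygosity (reads are drawn from the same haploid genome as
the assembly), GC-coverage bias (WSSD's GC correction is off by default
and untested against real bias), tandem/satellite repeat structure beyond
simple unit repeats, and chromosome-scale alignment complexity. Real-data
closure percentages additionally depend on flank length, aligner and
uniqueness margin, which is why the headline closure fraction is treated
as parameter-sensitive rather than a constant of nature.

## Fixture scales

The bundled evaluations use 0.2–5 Mbp genomes: 5 Mbp/100 gaps for the
patch round-trip, 2 Mbp/100 gaps for closure accounting, 3 Mbp with five
inversions (ten junctions) at 6× physical coverage for misjoin detection,
400 kbp with 1000 planted errors at 30× for polishing, 600 kbp–1 Mbp for
WGAC/WSSD, and 20 independent seeds for the WSSD false-positive control.
These sizes exercise every code path with exact planted truth while
keeping the whole suite runnable on a laptop; genome-scale numbers require
external alignments and are outside the bundled evaluations' scope.

## Known limitations

The built-in aligner is desk-scale by design. Scaffold-end joins are not
patched (no joining across scaffolds). Translocation junctions are
under-localized (see above). WGAC locus pairing assumes mostly collinear
duplication structure; heavily nested duplications would need the
imported-PAF route. The polishing CLI runs a single pileup round per
invocation (iterate by re-mapping externally); the bundled closed loop
demonstrates convergence with two rounds.
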