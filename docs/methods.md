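# Methods

`ctdna-integrate` implements, at desk scale, the comparative-genomics
analysis used to show that circulating tumor DNA (ctDNA) can integrate
into the genome of a recipient tumor cell during coculture: a three-way
single-nucleotide-variant (SNV) comparison between the recipient cell
line, the patient ctDNA and the coculture genome; breakpoint ("transition
point") detection in assembly contigs; confirmation of ctDNA origin by
donor-private SNVs; detection of coculture-unique duplications;
transposable-element (TE) annotation and enrichment around transition
points; and a discordant-read-pair caller for transgene-cassette
integration sites. A synthetic-data generator emulates the whole
experimental design so every stage can be validated against a known
truth table.

## The synthetic coculture model

The generator produces, deterministically under `(config, seed)`:

* **Cell genome** — haploid, A/C/G/T only, default two contigs of 150 kb
  at GC 0.41. Haploidy is a deliberate simplification: diploidy, ploidy
  changes and copy-number background are out of scope, so every allele
  frequency is driven purely by the mixture of genomes in a sample.
* **Donor genome** — the cell genome plus private substitutions at rate
  `donor_snv_rate` (default 5e-4 per bp). These donor-private SNVs play
  the role of the tumor variants that mark ctDNA origin.
* **TE library** — per tissue label (MM, PC) a handful of random consensi
  (120–260 bp) named after the elements reported in the field (AluSp,
  MER11C, AluSx, ...). The sequences are synthetic stand-ins: no
  Repbase/Dfam material is bundled, and the generator rejects candidate
  consensi sharing an exact substring long enough to breach the repeat
  scanner's reporting cutoff, so the library is mutually non-homologous
  by construction.
* **ctDNA fragments** — substrings of the donor with lognormal lengths
  (median 170 bp, sigma 0.6, floor 80 bp — the mono-nucleosomal cfDNA
  size regime with a long tail; fragments chosen to carry a TE are
  extended to fit it). With probability `te_end_probability` a TE copy is
  written into the donor at the fragment's origin so that the copy lies
  within 100 nt of a fragment end; the donor is updated in place so that
  every fragment core remains an exact substring of the donor genome.
  Each fragment is guaranteed at least one donor-private SNV in its core
  (`ensure_private_snv`): a fragment with none would be biologically
  indistinguishable from recipient DNA and undetectable by design, so the
  generator forces one substitution when the sampled origin happens to
  contain none. The 14-nt adaptor `GCGCTCTGTGTGCT` is ligated to both
  ends of every fragment; it marks the molecule's 5'/3' termini in the
  library and is **not** part of the integrated sequence.
* **Coculture genome** — the cell genome plus inserted fragment cores
  (adaptors stripped). A fraction `proximity_bias` (default 0.8) of
  insertions land within `proximity_window` (default 10 kb) of the
  fragment's homologous origin locus; the remainder land uniformly.
  Tandem duplications >= 10 bp are planted at `duplication_rate` per base.
  Planted duplications avoid boundary microhomology (the segment's first
  base differs from the base that follows it, and its last from the base
  that precedes it), so each planted event has one well-defined length —
  without this, a 9-bp duplication with a 1-bp chance microhomology is
  indistinguishable from a 10-bp one, for any caller.
* **Reads** — uniform paired-end sampling (default 2x100, insert
  300 +/- 30, 30x) with per-base substitution errors only; indel errors
  are out of scope. Read names encode the true origin. 30x is the
  package's desk-scale default; the full-scale design it emulates used
  50x, and coverage is a single parameter.
* **Transgene scenario** — a random >= 500 bp cassette (a stand-in for a
  CMV-mCherry construct) planted at `n_sites` positions.

Arms of an experiment that represent different patients use different
donor objects: TE copies planted for one arm must not be samplable by
another (the generator mutates its donor in place, so reusing one donor
across arms would leak matched-tissue TEs into mismatched-tissue
fragments).

### What the generator does not emulate

Chromatin and nucleosome footprints of cfDNA, methylation, the NHEJ
repair mechanism itself, assembler-specific error profiles, alignment
artifacts, indel/SV read errors, and diploid genotypes. Passing tests
therefore demonstrate the correctness of the set logic, breakpoint
arithmetic, statistics and parameter recovery under clean mappings — not
robustness to real-data alignment noise.

## Variant calling and the three-way comparison

Reads are piled up through an exact piecewise liftover onto the cell
reference: coculture coordinates map back to cell coordinates, with
inserted-fragment bases mapping to the fragment's donor origin (donor and
cell share coordinates by construction), and ctDNA-sample reads mapping
through the fragment-to-donor map (adaptor bases are unmapped). This is
a perfect-mapper stand-in for the aligner + caller stack of a full-scale
run; externally produced pileup TSVs or VCFs can be ingested at the same
module surface instead.

The caller emits one record per site/alt allele with
`af = depth_alt / (depth_ref + depth_alt) >= 0.01` (inclusive — the
threshold value is standard for ctDNA work; inclusivity and the
`min_depth = 8` floor are this package's choices) and total depth >= 8.
Multi-allelic sites decompose into one record per alt.

**SNVs of interest** are `(ctDNA ∩ coculture) \ cell` on exact
`(contig, pos, ref, alt)` keys; the full 7-region Venn partition is
reported alongside. Because integrated TE copies genuinely differ from
the cell reference, the SNVs-of-interest set contains clusters of
apparent variants across integrated TE sequence in addition to the
donor-private substitutions — the same "gain of nucleotide variants"
signature the three-way design is built to expose.

**VAF shift** at a site is `af_coculture - af_cell` with a two-sided
exact conditional (Fisher) test on the 2x2 allele-depth table; an absent
cell record is treated as homozygous reference at the coculture's site
depth. The full-scale analysis presented the shift descriptively; the
exact test is this package's choice of significance measure.

**Tumor fraction** of a cfDNA pool is the fraction of informative
fragments (those overlapping >= 1 tumor-SNV site) whose base at an
overlapped site equals the tumor alt allele. Fragment-level counting is
an assumption recorded here; a per-locus definition would weight long
fragments differently.

## Transition points, insertions, duplications

Contigs are compared to two references — the cell genome and the ctDNA
fragment set (with adaptors) — by unique k-mer seeding (k = 31; k-mers
occurring in more than one reference, or more than once in a reference,
are discarded as ambiguous) followed by ungapped extension along the
seeded diagonal on both strands. Extension skips an isolated mismatch
only when a budget of 1 per 100 extended nt allows it **and** the next
8 bases match, so extension cannot creep across a junction into randomly
matching sequence; block ends are trimmed back to a match.

Because a fragment core differs from the cell genome only at its private
SNVs and planted TEs, most of its k-mers are cross-reference ambiguous;
seeds come from SNV- and TE-boundary-spanning k-mers, and extension
recovers the full matching segment from a single seed. Two guards handle
chance 1-bp microhomology at junctions, which can seed a spurious
1-anchor block onto a homologous region of the wrong reference (or onto
the fragment's own origin diagonal in the cell genome): blocks mostly
overlapped on the contig by a block with more source-unique anchors are
suppressed, and when several cell blocks abut a ctDNA block within
`max_gap` (default 20 nt, the scale of untemplated end-joining scars),
the junction uses the one with the most anchors.

The **breakpoint** is the boundary adjacent to the maximally extended
cell segment: the end of the maximal cell prefix for a leading
(cell -> ctDNA) junction, the start of the maximal cell suffix for a
trailing one. With junction microhomology the breakpoint therefore sits
at the far edge of the homologous bases; reverse-complementing a contig
mirrors breakpoints exactly. Breakpoints are 0-based in memory, 1-based
in TSV output, and BED intervals are 0-based half-open.

`adaptor_adjacent` is true when the adaptor motif (<= 1 mismatch, either
orientation) occurs within 30 nt of the ctDNA-side contig end, or when
the matched fragment segment reaches within 30 nt of one of that
fragment's ligated adaptor ends. The second route is needed because the
integrated sequence itself carries no adaptor — adaptor evidence lives on
the ctDNA-side molecule. Adaptor evidence on one junction of an insertion
is sufficient.

An **insertion call** merges the leading and trailing junctions bounding
one fragment on a contig; duplicate views of the same event from
overlapping contigs (locus jitter <= 10 bp, same fragment) are merged.
The call is `confirmed` when at least one ctDNA-private SNV (present in
the ctDNA calls, absent from the cell calls) falls inside the inserted
segment lifted to donor coordinates. `distance_to_origin` is
`|insertion position - origin start|` on the shared coordinate system,
or inter-contig.

**Duplications** are reference intervals covered more than once (distinct
diagonals) by a single contig's alignment blocks, with length >= 10 bp
(inclusive). Extension is exact here (no mismatch skipping) so event
lengths are sharp. In the end-to-end pipeline duplication calling runs on
transition-free contigs only: a proximally inserted fragment is itself a
dispersed duplicate of its origin locus and would otherwise be counted in
both event classes; the standalone function has no such restriction.

## Repeats, the 100-nt window, enrichment, tissue specificity

TE annotation is Smith-Waterman local alignment of each library consensus
against the subject on both strands (match +2, mismatch -3, gap open -5,
gap extend -2; reporting cutoff score 40 and identity >= 80%). This is a
transparent stand-in for a RepeatMasker-style scan, adequate for
synthetic non-homologous consensi; all parameters are configurable.
Overlapping hits to different elements resolve by score, then alignment
length, then name.

The transition-window filter keeps hits whose nearest edge is within
100 nt (inclusive) of the breakpoint on the ctDNA side, and only for
transitions with adaptor evidence (`require_adaptor`, default on). The
fragment-level analogue classifies a fragment TE+ when a hit edge lies
within 100 nt of a core end.

Enrichment of TE+ among integrated versus non-integrated fragments is a
Pearson chi-square with 1 df, no continuity correction by default (the
correction is a flag); with any expected count < 5 a warning is raised
and the exact test reported alongside; odds ratios use the Haldane
correction when a zero cell exists. Counting is per fragment by default
(per-occurrence counting is available), since the enrichment unit was an
open choice.

Tissue-specific elements are those observed (count > 0) at
matched-coculture insertions and never at mismatched ones, ranked by
matched count with ties broken by name.

In the end-to-end pipeline the integrated arm is a fragment pool with
TE-end probability 0.9, planted into the coculture, and the
non-integrated arm a pool at 0.2 that is sequenced but never integrated —
TE-bearing fragments integrate preferentially, which is the effect the
enrichment test is built to detect; a single integration rate applied
uniformly to one pool would make the two arms exchangeable and the test
powerless by construction.

## Transgene caller

Reads are mapped by unique 31-mer anchors (verified by >= 90% identity
over the read) to the host genome and the cassette; the design requires
the cassette to share no 31-mer with the host (checked at load, hard
error otherwise). Pairs with one mate on each reference are clustered by
genomic position with single-linkage gap `insert mean + 3 sd`; clusters
below `min_support = 3` are dropped. **Confidence** is one minus the
Poisson probability that the off-site (background) discordant density
would produce at least the observed support in a cluster-sized window —
an invented but documented definition, since the full-scale analysis
plotted detection confidence without a formula. **Frequency** is support
divided by the expected junction-spanning pair coverage (the median
cluster support when not supplied). Per-cell expression strata of the
original single-cell design are emulated as bulk read mixtures.

## Numerical and design choices

* Randomness: `numpy.random.default_rng` throughout; every public
  generator takes an explicit seed, and the pipeline derives stage seeds
  as `seed * 1000 + salt (mod 2^31 - 1)`.
* Coordinates: 0-based half-open everywhere in memory; VCF is 1-based on
  disk and the shift happens once in the VCF layer.
* Ties: repeat-hit resolution by (score, length, name); tissue ranking by
  (count desc, name); greedy one-to-one truth matching by distance.
* Degenerate inputs: zero-depth coculture sites are flagged, not tested;
  zero-margin 2x2 tables raise; empty call sets report recall 0 and
  precision NA.
* Desk-scale problem sizes (package defaults, chosen to exercise every
  code path at comfortable statistical power): 2 x 150 kb genomes, 20–100
  fragments, 30x reads; the acceptance script's proximity run uses 100
  insertions so the recovered fraction has usable binomial bounds.

## Known limitations

* The perfect-origin liftover sidesteps mappability: recall/precision
  figures bound what alignment-based preprocessing could achieve, from
  above.
* Transition detection needs at least one source-unique 31-mer in the
  inserted core; fragments whose only private SNV sits within 31 bp of a
  core end can escape seeding (the recall >= 0.9 target budgets for
  this).
* The de novo assembly of the original design is replaced by perfect
  junction-spanning contigs plus a greedy unitig extender for small
  error-free inputs; neither models a real assembler's error profile, so
  contigs from a real assembler should be ingested for real data.
* The repeat scanner reports the single best local alignment per
  consensus and strand per subject — adequate for fragments carrying at
  most a few TE copies, not for full-genome repeat annotation.
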