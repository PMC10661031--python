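# Methods

## Sequence model and digestion

DNA molecules are strings over {A,C,G,T,N} with 0-based half-open top-strand
coordinates; circular records take indices modulo length and have no
distinguished origin (equality is tested on the lexicographically minimal
rotation of the top strand or its reverse complement, via Booth's algorithm).
Enzyme geometry ships as YAML rather than code: Type IIS offsets are measured
from the 3' end of the recognition site on the recognition strand (REBASE
"(1/5)" convention), within-site cutters from the recognition start.  Cut
coordinates for a site at position *p* with recognition length *m*:

- Type IIS, + strand: top cut at `p + m + cut_top`, bottom at `p + m + cut_bottom`
- Type IIS, − strand: top cut at `p − cut_bottom`, bottom at `p − cut_top`
- within-site: `p + cut_top` / `p + cut_bottom` (+), mirrored for −

Digestion is modeled as complete (no partials): the engine exists for assembly
planning, where the thermocycler program cycles digestion and ligation to
completion.  `N` in a sequence never satisfies a recognition base —
conservative site calling.  Fragments include the 5' single-stranded extension
at their left end and exclude it at their right end, so ligation is string
concatenation, every junction's 4 nt are counted once, and total base count is
conserved through any digest.  The fusion site stored on an end is the
top-strand sequence the junction will have *after* ligation; two ends join iff
the strings match exactly.  No thermodynamic ligation model, star activity, or
methylation sensitivity is attempted.

## Golden Gate assembly

All records in the pot are digested; fragments still carrying a recognition
site of the assembly enzyme are reaction intermediates and are excluded from
products (they get re-cut during cycling).  Surviving fragments form a
directed graph with an edge A→B when A's right fusion equals B's left fusion;
each distinct simple cycle (networkx `simple_cycles`, deduplicated by
canonical circular sequence) is one circular product.  Only circular DNA
propagates in the host, so linear concatemers appear only in diagnostics.  A
result is flagged *unique* iff exactly one product exists and every fusion
site occurs on at most one left and one right end; anything else is flagged
ambiguous, and planners refuse to proceed on ambiguity rather than pick.
Circular records the enzyme cannot cut pass through unchanged, which makes
assembly idempotent on its own products.

Overhang-set fidelity is checked with a deliberately simple heuristic:
duplicates, palindromic (self-reverse-complement) sites, reverse-complement
pairs, and pairs whose site-versus-reverse-complement-of-the-other Hamming
distance falls below a configurable threshold (default 1, i.e. only exact
mispairings are rejected).  This substitutes a transparent rule for empirical
ligation-frequency models; the threshold is a parameter precisely because the
heuristic is coarse.

## Kit grammar

Level-1 fusion sites are the published YTK part-type standard (types 1-8 with
3a/3b and 4a/4b subtypes partitioning their parents' intervals).  Level-2
connector overhangs, the gRNA-array fusion sites, and the BbsI marker-swap
pair are config data in `data/overhangs.yaml`; the shipped defaults are a
synthetic validated set (they pass the fidelity checks above), and a kit
manifest can replace them verbatim with a real kit's sequences.

Cassette positions follow one rule: an internal cassette at position *i*
carries connectors *i* → *i+1*, a terminal cassette at position *i* carries
*i* → terminal.  Nine internal (1-9) plus nine terminal (2-10) configurations
— 18 prebuilt cassettes, mirrored by 18 spacers — cover every assembly of 2 to
10 TUs; the integration vector closes the circle terminal → 1.  A single-TU
construct cannot use a prebuilt cassette and is instead assembled at Level 1
with position-1 terminal connector parts, which the toy kit provides; the
resulting cassette is structurally identical to a prebuilt one.

Marker swapping is an acceptor-style BbsI reaction: the removable stuffer (or
the currently installed marker) carries both recognition sites, so the product
has none — a swap is one-shot, matching the consumption of the sites in the
real reaction.  Screening colors are pure feature presence: reporter-dropout
features (sfGFP → green, mScarlet → red, with an optional host-stage
qualifier) still present in a product determine its colony color; white means
every dropout was replaced.  No expression modeling.

## Gap repair

NotI digestion releases fragments; those annotated as plasmid backbone or as a
reporter dropout are discarded by annotation, never by size.  Overlaps are
exact suffix-prefix matches of at least `min_overlap` bp (default 20, a
conservative floor for efficient homologous recombination in yeast;
mismatched-overlap recombination is out of scope).  The planner requires a
unique Hamiltonian path from the 5'-arm fragment to the 3'-arm fragment;
multiple paths raise an ambiguity error listing all of them.  In the toy kit
the 30 bp connector homology blocks are built so the NotI site sits *inside*
the shared block (the upstream plasmid carries `GGCCGC`+core before its NotI
site, the downstream plasmid core+`GC` after its own), so the released top
strands literally share 30 characters including the NotI remnants and the
exact-match model applies without flap trimming at internal junctions.  The
final integrated locus is the genomic sequence with the segment between the
arm matches replaced by the overlap-merged chain; non-genomic flaps outside
the arms are trimmed at the splice.  Homology arms are designed around the
Cas9 cut and abut exactly at it, so the transient-CRISPR target check accepts
a cut site anywhere in the closed interval between the arms.  Junction PCR
uses exact full-length primer matching (forward on top, reverse on bottom);
amplicon length is the distance between outer 5' ends, with multi-binding
primers reported as warnings.

## gRNA-tRNA arrays

Each array fragment is PCR-derived from the scaffold+tRNA template region of
the CRISPR backbone: the forward tail contributes a BsaI site, the position's
fusion overhang, a 2-nt TA buffer, and the 20-nt spacer; the reverse tail the
next position's overhang behind its own BsaI site.  Fragment *i* therefore
chains as overhang-spacer-scaffold-tRNA, giving spacer→scaffold gRNAs
separated by tRNAs after assembly.  PCR is simulated with exact, full-length
annealing-block matching; mispriming is out of scope.  The TA buffer — and the
toy template's scaffold starting with TA / tRNA ending with TA — exists
because none of the four enzymes' recognition motifs contains the dinucleotide
TA or ends in T or A, so arbitrary user spacers can never complete a
recognition site across a tail junction.  Spacer validation checks length,
alphabet, internal Type IIS/NotI sites, and (when a genome is supplied) a
single exact protospacer match with NGG immediately 3'; genome-uniqueness of
the 23-mer is the entire off-target model, by design.

## Integration-locus selection

A position is eligible when it lies outside every annotated gene body, more
than 1000 bp from every start codon and more than 500 bp from every stop codon
(strand-aware; distances to the codon's first base, with the stop codon's
first base at `end-3` on + genes and `start+2` on − genes), and outside a
blacklist of fragile features (tRNA/rRNA/ARS/LTR/telomere by default,
config-extensible).  Gene bodies are excluded outright because the loci are
meant to be genuinely intergenic.  Maximal eligible runs are the candidate
windows.  Cas9 targets are all 20-mers with NGG immediately 3' on either
strand whose full 23-mer occurs exactly once in the genome, ranked by distance
of the site midpoint from the window center with deterministic ties (position,
then strand).  Cross-strain conservation is exact sequence identity of the
protospacer and both arms in every supplied genome — similarity search is out
of scope.  The repeat diagnostic reports the longest substring shared by any
pair of sequences in either orientation (binary search on length over shared
k-mer sets), used to keep co-installed parts below the level of repeat that
invites recombination.

## The toy fixtures

The fixtures module is first-class, tested code.  The toy genome has three
linear chromosomes (~50 kb total): genes of 600 bp, all on the + strand, are
spaced by gaps of 1300 bp (too narrow to leave any eligible position) except
at exactly `n_loci` places, where a 1699 bp gap leaves a 201 bp window.  A
protospacer+TGG 23-mer is planted at the exact window center (flanked by TA so
no enzyme motif can overlap it) and verified genome-unique, so the top-ranked
target of every window is the planted one by construction.  The first gene
starts 100 bp into the chromosome and the last ends 300 bp before its end, so
chromosome ends contribute no windows.

The toy kit holds 96 entries mirroring the real collection's scale: 28 Level-0
parts, 10 marker cartridges, 18 cassettes, 18 spacers, 10 markerless
integration vectors with arms flanking the planted cuts, 10 spacer vectors,
and two CRISPR backbones (marked and transient).  All payload DNA is random
sequence *domesticated* to contain none of the four enzymes' sites; reporter
CDSs are labeled placeholder features, not real ORFs.  A builder assembles
each plasmid from fixed design tokens and random filler, then verifies that
every recognition motif in the finished circle was deliberately placed
(computed by masking the filler), redrawing the filler otherwise; fixed
seed-dependent tokens (genomic arms, connector homology cores) are guarded by
TA separators or context-checked resampling instead.  Identical config and
seed give byte-identical output.

What passing tests on these fixtures do **not** show: behavior on real genomes
(which contain restriction sites, repeats, N runs and close gene packing that
the toy genome deliberately lacks), real kit sequences, partial digestion,
ligation kinetics, transformation or recombination efficiencies, or any
expression phenotype.  The wet-lab efficiency figures of multiplexed
integration are outside what a sequence-level simulator can reproduce, and no
attempt is made.

## Problem sizes

The test suite and the acceptance script run entirely on desk-scale inputs:
the ~50 kb toy genome, 96 toy plasmids of 1-3 kb, assembly pools of at most
~12 fragments, and brute-force oracles up to 8 fragments (assembly), 7
fragments (gap repair), and 1,000 random sequences (site scanning).  These
sizes were chosen so every oracle comparison is exhaustive rather than
sampled.
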