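# Methods

`trbkit` implements the analysis chain used to characterize a T-cell
receptor beta (TRB) locus from genomic sequence and to interpret the
expressed beta-chain repertoire from rearranged cDNA: gene-unit
delimitation by recombination-signal (RS) and splice-site evidence,
IMGT-style functionality classification, subgroup partition of the V
genes, IMGT unique numbering of V domains, CDR3/junction decomposition
with the ≥5-nt D rule, repertoire statistics, p-distance/neighbor-joining
phylogeny, and 4 Å interface contact analysis of TR/pMH structures.
Every stage is exercised end-to-end against a synthetic locus and
repertoire generator with recorded ground truth, so no external data
are required.

## The synthetic locus

`simulate.generate_germline_locus` builds a genomic region with the
anatomy the annotator assumes:

* **V gene units** — an L-PART1 leader exon (ATG + 43 nt by default),
  a GT..AG intron, and a V exon of L-PART2 (11 nt) plus a V-REGION laid
  out on the IMGT framework architecture (FR1 26 / CDR1 a / FR2 17 /
  CDR2 b / FR3 39 amino acids) with the conserved anchors fixed:
  1st-CYS 23, CONSERVED-TRP 41 (with the FR2 tyrosine 42 of the W41-Y42
  motif also fixed, which keeps the anchor search unambiguous), a
  hydrophobic residue at 89, and 2nd-CYS 104. The germline V carries a
  6-nt tail 3' of codon 104 and ends at the heptamer of a 23-spacer RS
  (`CACAGTG … ACAAAAACC`, the IMGT consensus; configurable).
* **D gene units** — short G-rich stretches (defaults 13 and 15 bp)
  flanked by a 5' 12-spacer and a 3' 23-spacer RS. They are drawn under
  three constraints that mirror what makes real TRBD segments
  identifiable: readable in all three frames with 1–3 glycines per
  frame, no stop in any frame, and no 5-mer shared between the two D
  genes.
* **J gene units** — a 5' 12-spacer RS, a coding region of 40–53 bp
  consisting of a CDR3-contributing 5' part plus the 33-nt FR4 that
  starts at the FGXG J-motif (J-PHE 118), and a 3' GT donor site.
* **C gene units** — four exons with AA lengths 129/6/35/6 by default
  and a terminal stop codon, GT..AG introns.

The default layout emulates a compact artiodactyl-like TRB locus:
23 V genes in 20 subgroups (one subgroup of three members and one of
two — extras are allocated to the lowest-index subgroup up to three
members), then three D-J-C clusters with 6/7/7 J genes, D genes present
in the first and last cluster only, and one C gene per cluster.

**Identity control.** Subgroup structure is generated on a shared root
template with per-branch substitution rates solved from the uniform
4-state chain (`P(same) = 1/4 + 3/4·λ`, λ per branch), so the expected
pairwise V-REGION identity is 0.90 within subgroups and 0.60 between
them (defaults; the partition criterion downstream is >0.75). Germline
variation is substitution-only — no indels outside the explicit
frameshift defect — which makes planted coordinates exactly recoverable
and is the basis of the round-trip tests.

**Defect injection.** `inject_defects` plants one of
stop_codon / frameshift / heptamer_mutation / nonamer_mutation /
splice_mutation / missing_leader / j_motif_mutation in a named unit and
updates the ground-truth functionality (stop codons, frameshifts and
missing anchors give P; signal/regulatory defects with intact coding
give ORF; otherwise F). A frameshift is a single-nucleotide deletion,
planted deep enough in the coding region that an aligner pays the gap
rather than clipping the exemplar end.

## The synthetic repertoire

`simulate.simulate_repertoire` builds cDNA clones as
L + V(−trim) + N1 + D(−5'/3' trims) + N2 + J(−trim) + C-exon-1
fragment. Defaults: 45 clones from 2 subjects with a duplicate rate of
13/45 (emulating redundant sequencing of expanded clones), uniform
trims on 0..4 (V), 0..6 (D, both sides), 0..4 (J), N-segment lengths
uniform on 0..6, and a 0.5 per-(subject, gene) probability that the
expressed V is a "new allele" at 97–99.9% identity to its germline gene
(anchors preserved, open reading frame preserved). Allele draws are
cached per subject and gene so both subjects can share or differ in
alleles, which is what the public-repertoire report consumes. With
these defaults the simulated CDR3 runs ~5–15 AA with a mean near 10,
and roughly 85–90% of clones retain ≥5 consecutive D nucleotides.

**Identifiability by construction.** Junction flanks are drawn so the
analysis assumptions hold the way they do for real G-rich TRBD
segments: the germline V tail and J 5' regions share no 5-mer with any
D gene, and N-segment nucleotides are rejection-sampled (content only —
trims and lengths are drawn once, unconditionally, so their configured
distributions are exactly realized) so that an N addition never extends
an adjacent germline segment and never fabricates a ≥5-nt D-like
stretch. The recorded junction parts are the *canonical
maximal-attribution decomposition* (longest germline V prefix, longest
germline J suffix, longest exact D substring, leftmost on ties) — the
decomposition any observer of the sequence alone can recover — while
the raw trims and the raw count of surviving D nucleotides are recorded
alongside. A D fully consumed by trimming is recorded as absent with a
single N segment.

## Annotation

`annotate.annotate_locus` combines three evidence sources:

1. **RS scanning** (`scan_recombination_signals`): vectorized
   mismatch-profile scan for heptamer/spacer/nonamer elements on both
   strands, either side, spacer classes 12 and 23 with ±1 tolerance.
   Defaults: heptamer ≤1 mismatch with the first three bases (CAC)
   exact, nonamer ≤3 mismatches. A hit is *canonical* when the heptamer
   is exact and the nonamer has ≤1 mismatch (both configurable); worse
   hits are still reported but count as noncanonical-RS defects.
2. **Reference-seeded similarity** (`locate_gene_units`): exact 11-mer
   seeding against a labeled exemplar directory
   (`name|gene_type|subgroup` FASTA headers), diagonal clustering, then
   local alignment (match +5 / mismatch −4 / gap −10/−1) with identity
   ≥0.80 and coverage ≥0.90; both strands. Because germline divergence
   is substitution-dominated, the full-exemplar placement is inferred
   from the alignment offsets, giving exact coordinates.
3. **Snapping**: V exons end at the 3' RS heptamer and are checked for
   the upstream AG acceptor and an ATG/GT-delimited leader located with
   the subgroup's leader exemplar; J coding starts at the 5' RS end and
   ends where the exemplar alignment places the GT donor; C exons are
   anchored on the EX1 candidate and walked exon-by-exon through AG/GT
   sites with per-exon Hamming identity; D genes are called purely from
   facing 12/23 RS pairs with a 10–20 bp gap.

**Frameshift evidence.** Net indels against the exemplar are measured
with a unit-cost infix alignment (edlib), believed only when the gapped
alignment beats the gapless placement by ≥5 edits. A genuine
single-nucleotide frameshift always clears this margin (every
downstream position shifts), whereas gap shuffling near alignment ends
on an 8%-divergent exemplar does not; with an affine or unthresholded
aligner this check false-positives at a few percent per locus.

**Functionality.** Rules applied in order: leader presence (V), RS
canonicality, splice canonicality, expected coding length (J 40–53 bp,
D 10–20 bp), frameshift/stop scan in the reading frame (J frames are
anchored at the 3' end where FR4 sits), FGXG J-motif conservation, and
V-domain anchor validation through the numbering module. Label: P iff
any of {stop_codon, frameshift, missing_anchor}; else ORF iff any
signal/regulatory defect; else F.

**Subgroups and names.** Pairwise V-REGION identity uses global
alignment with free end gaps; identity is matches over aligned columns
excluding terminal overhangs, internal gaps counting as mismatches
(consequence: a terminal block of mismatches can be excluded as
overhang — scattered divergence, the realistic case, is unaffected).
Subgroups are the connected components of the >0.75 graph (transitive
closure). Names transfer from the highest-identity reference subgroup;
multi-member subgroups are numbered 5'→3' (`TRBV5-1` …); ties go to the
lower-numbered reference and are flagged; unmatched subgroups get
sequential novel names. D-J-C clusters are maximal D?-J+-C? runs in
genomic order; cluster numbers transfer from the best-matching C
reference with positional fallback, and J genes are named
`TRBJ<cluster>-<position>`.

## IMGT numbering

`number_v_region` enumerates CDR1/CDR2 length assignments under the
fixed FR architecture (FR1 1–26, CDR1 27–38, FR2 39–55, CDR2 56–65, FR3
66–104) and scores the four anchors, with a half-point preference for a
tyrosine at 42 (the FR2 W41-Y42 motif) used purely as a tie-break;
among equal scores the assignment closest to the modal (5, 6) CDR
lengths wins. CDR gaps fill from both loop ends toward the middle, the
extra gap toward the C-terminal side for odd deficits, so framework
positions never move and degapping returns the input. Residues past the
2nd-CYS form CDR3 (max 13 under this scheme; the junction module
reports raw CDR3 lengths and is not bound by this cap) and, when an
FGXG is present, FR4 positions 118–128. `describe_c_domain` maps the
four C exon translations to C-domain (EX1), connecting region (EX2 +
5' EX3), transmembrane (3' EX3 + first EX4 codon; 21 AA by default),
and cytoplasmic (rest of EX4) regions. The default simulated C protein
is 129 + 21 + 21 + 5 = 176 AA.

## Junction analysis

V genes are assigned by infix alignment (edlib) of each germline
V-REGION *through codon 104* against the cDNA; identity is matches over
aligned columns. Status: `germline_exact` at 1.0, `new_allele` in
[0.97, 1.0) — the band used for reporting novel alleles — and
`low_identity` below that (clones under 0.90 are additionally flagged).
Ties break to the lexicographically smallest gene id and are flagged.
The CDR3 runs from the end of the 2nd-CYS codon (the V alignment end)
to the start of the J-PHE codon, located by mapping the germline FGXG
offset through the J alignment path; translation is in the V frame, and
a clone is productive when the CDR3 length is a codon multiple and
stop-free.

The D gene is identified by the longest exact substring shared between
the CDR3 and any germline D, forward strand only; below 5 nt the call
is `none`, equal maximal lengths across two D genes give `ambiguous`
(grouped with `none` downstream, as "not possible to distinguish"), and
equal-length matches within one D take the leftmost CDR3 span.
Decomposition attributes the longest germline V prefix and J suffix,
truncated at the D span when they would overlap it; the five parts
always concatenate to the CDR3 exactly. Rearrangements are
`intracluster` when D and J share a D-J-C cluster, `intercluster`
otherwise, `unknown` without a unique D. Redundancy collapse is exact
nucleotide identity of the full coding sequence.

## Repertoire statistics

Usage tables (subgroup / gene / allele level) are computed over unique
clones by default, with counts always reported beside fractions;
percentages are rounded only at presentation. CDR3 statistics are AA
lengths of the codon-105–117 region. The public-repertoire report
lists genes, alleles, or identical junctions observed in *every*
subject with per-subject counts. J-set frequencies count unique clones
per J cluster, excluding failed assignments from the denominator.

## Phylogeny

`p_distance` is the proportion of differing sites per pair with
pairwise deletion (columns with a gap/ambiguity in either member of the
pair are excluded); a pair with zero comparable sites is an error
naming the pair. `nj_tree` is the Saitou–Nei agglomeration with a
deterministic tie-break — among Q-minimizing pairs, the one whose
clusters hold the lexicographically smallest leaf labels — and negative
branch lengths clamped to zero (logged on the tree). Input must be
pre-aligned; multiple-alignment construction is out of scope, and the
simulator emits alignable equal-length families. Monophyly is an exact
edge-bipartition test. scikit-bio's independent NJ implementation is
used in the test suite as a cross-check oracle, never as the
implementation.

## Structure contacts

PDB files are read through Bio.PDB (waters skipped, alternate locations
resolved to the highest-occupancy conformer, malformed ATOM records
rejected with their line number). Two residues are in contact when any
inter-atomic distance is ≤ the cutoff (4 Å default), over all atoms
present in the file — heavy atoms unless hydrogens were deposited,
which is the documented convention here. Neighbor search uses a k-d
tree and is verified against the brute-force all-atom-pairs oracle in
the tests. Contacts are labeled with FR/CDR-IMGT regions through
per-chain numbering maps (G-domain maps are accepted as input, not
computed). The standard IMGT pMH contact-site rule maps peptide length
to absent sites among C1–C11: 11 → none, 10 → {C2}, 9 → {C2, C7},
8 → {C2, C7, C8}; lengths outside 8–11 are an error.

## Problem sizes and determinism

The default verification study uses a 23 V / 20 subgroup / 3 cluster
locus (~35 kb), 1 000 clones for junction-analysis checks and 10⁴
clones for distributional checks, 100 random additive trees of ≤12
leaves for NJ, and 60-residue chains for contact geometry; the entire
suite and the acceptance script each run in well under a minute on one
CPU. All randomness flows through a single seeded NumPy generator per
stage; identical seeds give byte-identical loci, repertoires, and
manifests.

## Known limitations

* The generator does not simulate somatic hypermutation, thymic
  selection, clonal expansion beyond the duplicate rate, indel
  polymorphism between alleles, or assembly gaps (an N-run gap is
  available but off by default); passing round-trip tests therefore
  demonstrate correctness of the method's logic under
  substitution-dominated divergence, not robustness to structural
  variation or sequencing error.
* Subgroup identity control targets expectations; realized pairwise
  identities fluctuate by a few percent around 0.90/0.60, far from the
  0.75 threshold, so the partition is stable by design rather than by
  luck.
* The junction truth is canonical attribution: where trimming plus
  chance makes two decompositions of the same sequence equally valid,
  the recorded truth is the one maximal attribution recovers, and raw
  trims are reported separately.
* V assignment candidates are ranked by edit distance before identity
  is computed exactly for the leaders; a gene could in principle win on
  distance but lose on column identity in pathological cases.
* Interface contacts use whatever atoms the file holds; no hydrogen
  placement, occupancy weighting, or symmetry expansion is attempted.
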