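# Methods

## Scope and model

`anxtools` implements the desk-scale computations of a plant annexin
gene-family survey. It deliberately consumes, rather than produces, the
outputs of the heavyweight upstream steps: domain boundaries arrive as an
annotation table (standing in for SMART-style domain calls), collinear gene
pairs as a table (standing in for synteny databases), and codon alignments
as aligned FASTA pairs. What the package computes itself is everything
downstream of those inputs: motif classification, intron-phase and
splicing-pattern analysis, duplication classification with summary
percentages, and Nei–Gojobori Ka/Ks with molecular-clock dating.

## Coordinate conventions

All external genomic and protein coordinates are 1-based inclusive
(GFF3-style); conversion to anything else happens only inside `io_formats`.
Gene models keep coding exons only, ordered 5′→3′ in transcription order
(descending genomic start on the minus strand); a model is *complete* when
its summed coding length is a whole number of codons. Gene order on a
chromosome is the rank by ascending start coordinate, ties broken by
lexicographic gene id, so the tandem rule below is deterministic.

## Type II calcium-binding sites

The canonical site is the anchor `G-x-G-T` followed by a fixed spacer and
then an acidic residue (D or E). The spacer defaults to exactly 38 residues
(`spacer_min = spacer_max = 38`) and is exposed as a range because the
literature states a fixed spacing while practical domain callers tolerate
drift; widening the window can only add canonical hits, never remove one.
"Degenerate" ("mutated") sites have no formal definition in the
literature, so the package declares one and reports the failing component:

- *missing acidic* — intact anchor, but no D/E anywhere in the spacer
  window;
- *anchor mismatch* — a D/E at canonical distance behind an anchor in which
  exactly one of the four positions fails its pattern.

The unknown residue `X` matches no pattern position, including wildcards —
conservative scanning, so an unknown can never create a hit. Per-domain
status is *present* with ≥1 canonical hit, *degenerate* with only
degenerate hits, *absent* otherwise, and a protein's CBS count is the
number of *present* domains (the classic plant configuration is count 2, in
domains I and IV; the vertebrate-like tetrad is count 4).

K/R/HGD tripeptides are related to the CBS of the same domain:
*overlapping* when the intervals intersect, *adjacent* when at most
`adjacency_window` residues (default 5 — the literature gives no number)
separate them, *none* otherwise. Logo information content is plain Shannon
information against the uniform 20-letter background, I = log₂20 − H, with
gaps excluded and no small-sample correction (the simplest logo
definition); a correction could be layered on, but the bounded-in-[0,
log₂20] invariant and the degenerate-case identities hold exactly for the
uncorrected form.

## Intron phases and splicing patterns

Intron phase is the cumulative coding length upstream of the junction mod
3: 0 between codons, 1 after the first base, 2 after the second (phase 2 is
supported although plant annexins exhibit only 0 and 1). Pattern identity
defaults to (exon count, phase string); exon-length signatures are opt-in
with a 10% relative per-exon tolerance, since published pattern figures
group visually similar but unequal exon sizes — the package makes the
grouping rule explicit instead of reproducing a by-eye numbering. Patterns
are numbered by exon count descending, then phase string lexicographic, and
the catalog is invariant under input permutation (genes are pre-sorted
deterministically before greedy grouping).

For cross-gene comparison, introns are projected onto a protein alignment:
every intron maps to the column of the codon containing the junction, with
a phase-0 junction attributed to the codon immediately upstream
(codon = ⌈upstream/3⌉ uniformly across phases). Pattern B is an
*intron-loss derivative* of A when every intron of B matches a distinct
intron of A with equal phase within `column_tolerance` columns (default 1);
the unmatched introns of A are returned as the lost set. The relation is
reflexive and transitive and can never hold when B has more introns than A.

## Duplication classification

The tandem rule — family genes "separated by a maximum of two to five
genes" in the source convention — is operationalised as: two family members
on one chromosome are linked when at most `max_intervening` (default 5)
**non-family** genes sit between them in gene order; whether intervening
family members should also count is unstated in the literature, and
counting only non-family genes is this package's declared choice. Clusters
are connected components of that relation, so chains of pairwise-close
genes merge, and the threshold is monotone: raising it can only grow or
merge clusters.

Segmental duplicates are simply the collinear-table rows with both members
in the family; one-to-many block relationships are kept (one gene may pair
with several partners).

The summary reports tandem% and segmental% as 100 × distinct genes in the
class / family size, rounded half-up to integers by default, and a
*combined* percentage that is their **sum**. The additive convention is
deliberate — it mirrors how such family surveys headline their totals — but
it can exceed the distinct-gene union when a gene is in both classes, so
the union percentage is always emitted alongside.

## Nei–Gojobori Ka/Ks and dating

Site counts: each codon position contributes the fraction of its three
possible point mutations that are synonymous; mutations to stop codons are
excluded from the numerator but kept in the denominator of 3 (the classical
NG86 convention), so s + n = 3 per codon and S + N = 3 × counted codons
always. Difference counts: for a codon pair differing at d positions, Sd
and Nd are the unweighted mean over all d! substitution orderings,
classifying each step against the current intermediate; orderings passing
through a stop codon are dropped and the remainder re-averaged, and in the
(never yet observed) case that every ordering is blocked the codon pair is
excluded and tallied. The standard genetic code (translation table 1) is
fixed. Codon columns containing a gap or ambiguous base in either sequence
are excluded and tallied; an internal stop is an error, a shared terminal
stop column is stripped.

Proportions pS = Sd/S and pN = Nd/N receive the one-parameter Jukes–Cantor
correction d = −¾·ln(1 − 4p/3); at p ≥ 3/4 the channel is flagged saturated
and no distance is reported. The Ka/Ks ratio is defined only when Ks > 0,
and the selection regime is purifying/neutral/positive around 1 with a
configurable tolerance (default 0: only an exact 1 is neutral).

The package ships an independent brute-force `pathway_oracle` that
enumerates substitution orderings by recursion; the tabulated route used by
`ng86` is cross-checked against it over all 61×61 sense-codon pairs in the
test suite, exactly.

Dating: T = Ks/(2λ), with λ the species synonymous substitution rate per
site per year (reference values: 1.5×10⁻⁸ *Arabidopsis*, 6.5×10⁻⁹ rice,
9.1×10⁻⁹ poplar). Reported ages in MYA are **truncated** to two decimals by
default rather than rounded half-up: truncation is the convention evident
in the reference literature values the package reproduces (0.62125/(2·1.5×10⁻⁸)
= 20.7083 MYA, printed as 20.70), and half-up rounding is available via the
`rounding` parameter. Note the method choice: the reference Ks values were
produced by a different estimator (Comeron's), so Ks recomputed here from
sequences is not expected to match printed Ks values; printed Ks are used
as *inputs* to dating, which is therefore estimator-independent.

## Synthetic data: what it emulates and what it does not

Every generator draws from a named stream seeded by the single user seed
(`numpy` `SeedSequence([seed, stream_id])`), so outputs are byte-stable and
independent across generators.

- **Proteins** are four 70-residue domains behind a 12-residue N-terminal
  stub. Backgrounds are uniform over the 20 amino acids and the finished
  domain is rejection-sampled until a scan reports *exactly* the planted
  truth — no accidental anchors, acidic completions, tripeptides, IRI or
  DXXG — so precision and recall against the truth table are exact by
  construction, not approximately so.
- **Gene models** instantiate 12 exon-length templates (all 600 nt of
  coding sequence; first intron phase 1 and the rest phase 0 in the
  plant-annexin-dominant configurations, with all-phase-0 variants and an
  intronless template) at random offsets and strands with random intron
  lengths of 80–500 nt.
- **Genomes** interleave family genes with background genes at controlled
  spacings, including boundary cases exactly at and just above the tandem
  threshold, and emit planted collinear pairs plus decoy pairs touching
  non-family genes.
- **Codon pairs** are evolved from a uniform sense-codon ancestor by point
  events classified at application time, with exact event-count targets
  rather than rates, so recovery tests compare against exact truth. When no
  nonsynonymous events are requested, a synonymous event must additionally
  leave the codon's pathway-averaged nonsynonymous difference from its
  ancestral state at zero; without this, two individually synonymous events
  in one codon (e.g. CTT→CTA→TTA, all Leu) can leave an endpoint pair whose
  pathway average crosses another amino acid (CTT→TTT→TTA passes through
  Phe) and Ka would not be exactly zero.

None of this emulates real evolutionary processes: there are no trees, no
rate heterogeneity, no amino-acid substitution preferences, no indels, and
background composition is uniform rather than proteome-like. Passing the
planted-truth suites therefore demonstrates the correctness of the
*computations* — scanning, counting, clustering, estimation — not the
biological realism of any particular genome's annotation.

## Problem sizes and numerical choices

The validation suites use 1,000 generated proteins for motif accuracy, 12
templates × 3 genes for pattern recovery, 200 pairs of 300 codons with 30
planted synonymous events for Ks recovery (observed mean relative error
1–2%, bound 10% — the Jukes–Cantor correction compensates the multiple-hit
loss at this divergence), and the full 61×61 sense-codon grid for the
oracle check. Percentages are rounded half-up; ages truncated to 2
decimals; pattern grouping and cluster detection are exact integer
computations with no tolerances beyond those documented above.

## Known limitations

- Degenerate-CBS calling is a declared convention, not a reconstruction of
  any published rule; sites with two or more anchor mismatches are invisible.
- The conserved-His check is positional and needs the caller to supply the
  expected region from an alignment; the scanner itself is region-agnostic.
- Tandem classification depends on the completeness of the genome-order
  table; missing background genes shrink apparent spacings.
- NG86 is an equal-weight pathway estimator: no transition/transversion
  weighting, no ML codon model, no confidence intervals. For strongly
  saturated pairs (p ≥ 3/4) no distance is reported at all.
- Multiple transcripts per gene are all read and kept; selecting one
  representative splice form per gene is left to the caller.
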