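# Methods

This note documents the models and procedures implemented in `kissmine`,
the defaults they use, and what the synthetic-data tests do and do not
establish.

## Precursor mining

**ORF definition.** ORFs are maximal stop-to-stop codon runs in all six
frames, not ATG-initiated — degenerate kisspeptin remnants (the interesting
cases) often lack a conventional start, and published avian loci are
described by their stop-delimited ORFs. Runs bounded by the sequence edge
count as ORFs; a codon containing N translates to X and never terminates a
run (even where the ambiguity would resolve, e.g. CGN). All coordinates are
0-based half-open on the forward strand; reverse-strand hits carry a strand
flag. Default minimum ORF length: 60 nt (well below the shortest published
degenerate locus at 99 nt, large enough to skip inter-stop noise).

**Decapeptide scanning.** Every 10-residue window of an ORF translation is
scored against each query with BLOSUM62; a window is reported when its
score reaches `rel_threshold` × the query's self-score (default 0.4). The
0.4 default is the level that admits genuine cross-lineage matches at
30–40% identity — e.g. an avian Kp(10)-like sequence against a reptilian
Kp1(10) query scores almost exactly 0.40 of self — so it cannot be raised
without losing the most interesting hits. X contributes zero to any pair
(unknown residues never match). Windows are annotated with substitutions at
the conserved Kp(10) positions, default `{2: N, 6: F, 9: R}` (Asn2, Phe6,
Arg9 are near-invariant across vertebrate kisspeptins); the set is
configurable.

**Amidation grammar.** The residues immediately 3′ of the window are
classified as `canonical` (G, K/R, K/R), `stop_type` (G, K/R, then the
ORF-delimiting stop), `degenerate` (G, K/R, non-basic — e.g. the avian GKL
and GKG variants — or G, non-basic), else `absent`.

**Cleavage and mature peptides.** Prohormone-convertase cleavage is
modelled as any dibasic pair in {KR, RR, KK, RK} upstream of the
decapeptide; each pair defines a candidate mature peptide from the residue
after the pair to the last decapeptide residue (the amidation signal is
excluded). All variants are reported, longest first; several dibasic sites
give several size variants, as observed for real precursors. This is a
deliberate simplification of trained cleavage predictors: it reproduces the
dibasic-site logic those tools share without their species-specific models.

**Splice acceptors.** Candidate acceptors are AG dinucleotides preceded by
a polypyrimidine tract. The consensus value of a site is defined here as
100 × the pyrimidine fraction of the 12 nt immediately 5′ of the AG; sites
are kept when CV > 80 (configurable). The formula is this package's own
operationalisation of "T/C-rich tract followed by AG" — published splice
scoring matrices are proprietary/unspecified — calibrated so the
conventional >80 retention threshold separates genuine tracts (CV 100 for a
pure tract) from near-misses (9 of 12 pyrimidines → CV 75, rejected).

**Pseudogene diagnosis.** Five flags, then a verdict. `short_orf`
(< 150 nt: too small for a full precursor CDS), `no_dibasic_cleavage` (no
mature peptide can be predicted), `degenerate_amidation`,
`conserved_substitutions` (> 1 substitution at the invariant positions),
`close_upstream_stop` (delimiting stop < 60 nt from the decapeptide codons,
leaving no room for a signal peptide). Verdict `degenerate` requires ≥ 2
flags — a single anomaly is tolerated because intact genes occasionally
show one (the rule is this package's quantification of reasoning that is
qualitative in the literature). All thresholds are keyword arguments.

## Receptor models

Exon discovery is out of scope (receptor junctions are curated or come
from truth files); `validate_gene_model` checks that every intron begins
GT and ends AG on the transcribed strand, splices and translates the CDS,
requires exactly one terminal stop, and flags models with fewer than the
expected five exons as `partial` rather than rejecting them (incomplete
assemblies routinely truncate exon 1). Transmembrane helices are maximal
runs of positions whose 19-residue windowed mean Kyte–Doolittle hydropathy
exceeds 1.6, with runs closer than 5 residues merged — the standard
sliding-window heuristic; it reliably counts 7 helices on GPCR-like
hydrophobicity patterns but is not a topology predictor.

## Peptide comparison

Decapeptide identity is ungapped positional identity with denominator 10;
this is the only rule consistent with the published cross-species
percentages, and X matches nothing. Unequal-length peptides are first
aligned with the affine-gap global aligner (Gotoh DP; defaults BLOSUM62,
gap open −10, extend −1; traceback ties broken diagonal → up → left so runs
are reproducible). The progressive aligner seeds with the most identical
pair and adds sequences in order of best identity to the profile,
profile-column scores being mean pair scores with frozen gaps ("once a
gap, always a gap"). It is a minimal guide-order aligner, adequate for the
short (33–65 aa) mature peptides this pipeline compares; it does not aim
to reproduce any particular MSA program.

## Phylogeny

Distances: p-distance with pairwise gap deletion, or Poisson-corrected
d = −ln(1 − p) capped at 10 for saturated pairs (a pair with zero
comparable columns is an error naming the pair). Neighbor joining uses the
Q-criterion with ties broken by the lexicographically smallest pair of
cluster representatives; negative branch lengths are clamped to zero with
the deficit absorbed by the sibling branch so the joined pair's distance is
preserved. NJ is exact on additive matrices, which the tests exploit:
generated additive matrices must return the generating topology and match
a brute-force least-squares search over all 15 five-taxon topologies.
Bootstrap supports resample alignment columns with replacement
(numpy `default_rng(seed)`), and each internal edge's support is the
percentage of replicate trees containing its bipartition. Rooting places
the root at the midpoint of the edge separating a monophyletic outgroup.
Consensus is plain majority-rule (> threshold ≥ 0.5) with occurrence
percentages as node values. Distance-based NJ is used for both gene
families; maximum-likelihood inference is a non-goal, so clade recovery —
not branch lengths or published support values — is the comparable output.

## Synteny

"Neighbouring" is defined by gene rank (default 15 genes each side of the
focal locus), not base pairs, because assemblies of very different
contiguity are compared. A locus's score for a paralogon type is the
number of that type's markers within the window; unique positive argmax
assigns the type, a tie is `ambiguous`, all-zero is `unclassified`.
Paralog-family members (TEAD1/2/3/4 etc.) are distinguished by exact
symbol. Region-presence assessment divides the number of a region's
markers found anywhere in an assembly by the region's `total_considered`;
below `min_fraction` (default 0.25) the verdict is `region_missing`, and
downstream a gene-absent call in that region is downgraded to `unknown`
— absence of evidence in a missing region is not evidence of absence.
The bundled `paralogons.yaml` transcribes the reference marker sets for
Kiss1–4 and KissR1–4; the Kiss4 region, which retains no Kiss gene in any
living osteichthyan, is delineated by the paralog-family members not
assigned to the other three regions.

## Gain/loss scenarios

Dollo parsimony: one gain at the origin node, losses silencing whole
clades. The minimal count is computed by a post-order DP
(`cost_present(v) = Σ_children min(cost_present(c), 1 if clade(c) can be
all-absent)`), charging each loss on the highest (maximal) possible edge.
`unknown` tips are assigned present or absent to minimise the count; an
exact tie is resolved toward absent and the assignment is recorded — this
never changes the count, only whether an unknown tip is folded into an
adjacent loss. The DP is verified against exhaustive enumeration of all
unknown assignments on seeded random trees of 3–8 tips. Independent-gain
scenarios are not scored. The bundled sarcopterygian tree branches
(amphibian, (mammal, (squamate, (chelonian, (crocodilian, bird))))); the
four-versus-one comparison it supports is robust to the chelonian
placement.

## Synthetic data

The generator emulates the *structure* the miners exploit, not genomic
realism. Background is i.i.d. nucleotides at a configurable GC fraction
(default 0.45) — no repeats, isochores or realistic intron-length
distributions. Kiss implants are two-exon genes whose second exon carries
the stop-bounded precursor ORF (10-residue spacer, KR cleavage site,
43-residue spacer → a 53-aa mature peptide, decapeptide, GKR motif);
KissR implants are five-exon genes with GT..AG introns encoding an
M + 7×23-residue-helix membrane protein with 15-residue loops. Degradation
modes reproduce documented failure patterns: `premature_stop` (default
36 nt 5′ of the decapeptide codons), `motif_substitution` (default
N2→I, R9→G), `cleavage_loss`, `amidation_degeneration` (GKR → G, K,
non-basic).

Because a 0.4 relative BLOSUM threshold is permissive by construction,
random background occasionally contains decapeptide-like windows (measured
≈ 1 per 3.7 kb of i.i.d. sequence). The generator therefore enforces its
noise-free contract literally: with `scrub_background` (default on), each
segment is rejection-sampled until the only six-frame windows scoring
above the threshold against the scrub panel are the implanted decapeptides
themselves. Ground truth is thus exact, and miner recall/precision on
generated genomes measures the miner, not background luck. Consequently,
passing tests show correct recovery of *implanted signal in clean
sequence*; they do not bound false-positive rates on real genomes, where
the practitioner should treat sub-0.5 relative-score hits without an
amidation motif with suspicion.

All generators are pure functions of (config, seed); truth is serialised
as JSON next to the outputs so tests never re-derive it.

## Problem sizes and numerics

Default test and acceptance workloads are desk-scale by design: synthetic
genomes of 4 × 2–2.5 kb, eight-locus neighbourhood sets, ten additive
5-taxon matrices, 120 random Dollo instances (3–8 tips, exhaustive
oracle), and bootstrap saturation at 1,000 replicates × 20 taxa. These
sizes exercise every code path deterministically; none of the published
genome-scale quantities (database hit counts, real ORF lengths, MEGA/RAxML
bootstrap values) are recomputable at this scale, and the pipeline does
not attempt them. Floating-point comparisons in NJ use a 1e-12 tie
tolerance; Poisson distances cap at 10; all stochastic stages require an
explicit seed.
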