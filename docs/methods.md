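# Methods

## The classification rule

TatA-family proteins are classified from their first eight residues,
1-based with the initiator methionine as position 1 — the convention under
which the Glu³/Lys⁸ indices match the E. coli TatE primary sequence
(`MGEISITK…`).  "Charged" means D/E (acidic) or K/R (basic); histidine is
treated as polar-uncharged, consistent with grouping the Gln/His state of
residue 8 with the uncharged TatA type.  The decision order is:

1. length < 8 → `TOO_SHORT`
2. Glu³ and Lys⁸ → `E3K8` (checked before E2K8, so a hypothetical
   E2+E3+K8 sequence lands in the majority pattern)
3. Glu² and Lys⁸ → `E2K8`
4. Lys⁸ without a qualifying Glu → `K8_ONLY`
5. Asp/Glu at 8 → `TATB_LIKE`
6. no charged residue in 2–8: residue 8 ∈ {Q,H,N,S,T} → `TATA_LIKE`,
   otherwise → `UNCHARGED_OTHER`
7. anything else charged in 2–8 → `OTHER_CHARGED`

Arg⁸ is deliberately *not* folded into the lysine class: whether
K⁸-counting surveys include arginine is not decidable from charge alone,
so such sequences are kept separate as `OTHER_CHARGED`.  The Gly-Glu vs
Glu-Gly order at positions 2–3 is recorded descriptively but never used
for classification.  Positions are raw sequence positions, not
alignment-anchored: all motif definitions here are absolute N-terminal
indices, and the proteins are single-domain with the transmembrane
segment starting within a few residues of the start.  A property test
guarantees the class is a total function of the first eight residues.

## Pairwise alignment and statistics

Global (Needleman–Wunsch/Gotoh) and local (Smith–Waterman) alignment are
exact three-state affine-gap dynamic programmes — no word seeding, no
X-drop, no composition-based score adjustment.  Defaults are the
long-standing protein-search settings: BLOSUM62 with gap existence 11 and
extension 1, where a gap of length L costs 11 + L·1.  Raw scores map to
bit scores and E-values by the Karlin–Altschul formulas with the gapped
BLOSUM62 constants λ = 0.267, κ = 0.041; the search-space length `n` for
a database screen is the total residue count of the filtered database
(no edge-effect length correction — simpler and monotone).  Numerical
choices that make outputs bit-reproducible:

- integer scoring throughout the DP (the traceback re-derives each step
  by exact integer comparison);
- tie-breaking fixed as diagonal > gap-in-subject > gap-in-query, and
  M > Ix > Iy between states of equal score;
- the local best cell is the first maximum in row-major order;
- `X` scores 0 against everything (including itself), so undetermined
  residues can neither help nor hurt an alignment;
- percent identity uses the residue–residue column denominator (gap
  columns excluded), the convention behind reported "identities"
  percentages;
- the empty local alignment (score 0) is returned when no positive pair
  exists, with spans (0, 0).

Correctness is established two independent ways: exhaustive enumeration
of all gapped alignment paths for short sequences (the brute-force oracle
shares no code with the DP), and Biopython's `PairwiseAligner` at
realistic lengths.

## Homology screen

"Incomplete entry" is operationalized as the union of cheap, testable
proxies for partial database records: length < 40, more than 5%
undetermined (X) residues, no initiator methionine, or the token
"partial" in the definition line (case-insensitive).  Filtering happens
*before* alignment, so the search space is defined by complete entries;
hits are records with E ≤ 10⁻³, sorted by E-value with ties broken by
record id.  The tally always reconciles:
`n_input = n_removed_incomplete + n_hits + n_above_cutoff`.

## Progressive MSA and consensus

Clustal-style progressive alignment: pairwise global identity distances
(1 − identical/aligned columns), a UPGMA (average-linkage) guide tree
with ties broken by the lexicographically smallest member id, and
profile–profile Needleman–Wunsch merges scoring columns by
frequency-weighted sum-of-pairs (gap frequencies contribute zero) under
the same affine gap costs.  Because tree ties and traceback ties are
id-resolved, the alignment depends only on the *set* of sequences; rows
are emitted in input order and degap exactly to their inputs.  No
iterative refinement is attempted.

Consensus statistics are residue-space quantities: per column, the
consensus residue is the most frequent non-gap residue (ties
alphabetical), conservation is its frequency among non-gap symbols, and
information content is log₂20 minus the Shannon entropy of the
standard-residue distribution (X and gaps excluded), without a
small-sample correction — at the ~100-sequence family sizes used here the
correction is negligible.  All-gap columns report consensus "-",
conservation 0 and information 0.  Logo heights are residue frequency ×
column information, so a column's letter heights sum to its information
content.  Positional claims ("position 8") are anchored by mapping
alignment columns to the coordinates of a designated reference row.

## Synthetic families

The generator exists to carry exact ground truth, not to model protein
evolution.  Sequences follow the family architecture — Met¹, short
uncharged N-tail, hydrophobic transmembrane segment (default start 4,
length 18, alphabet AILVFG), amphipathic stretch of alternating
hydrophobic/polar residues, hydrophilic tail; lengths 50–180 by default.
Positions 2, 3 and 8 are placed by the target class; per-position
conservation probabilities make a member deviate to a defined
alternative (Glu²-arrangement at position 3, Arg at position 8), and the
generating label tracks the *realized* placement, so
`classify ∘ generate` is exact by construction, not by tuning.
Substitution noise is i.i.d. outside positions 1–8 (an unprotected mode
exists for stress tests).  Subfamilies can share a mutated common
ancestor so that every family member is genuinely homologous to a common
query while i.i.d. decoys are not; decoys keep an initiator Met by
default so they reach the E-value test rather than being discarded by
the completeness filter.

What the generator does *not* emulate: insertions/deletions within
families (length varies only at the C-terminus), realistic substitution
matrices for the noise process (uniform alternatives), strain-level
taxonomy, or biophysically plausible TM-helix evolution.  Green tests
therefore demonstrate algorithmic correctness under controlled truth,
not recovery of any particular real-database census.

## Survey conditions and problem sizes

The default synthetic survey (`build_survey_database`) mirrors the
documented family structure: a 111-member TatE-type ortholog family with
Lys⁸ conservation 0.99 and a 72/28 Gly-Glu/Glu-Gly split at positions
2–3; 50 dual-paralog organisms in Vibrionales (charged TatA_1-like +
uncharged TatA_2-like per genome, lengths 63–78 for the charged
paralogs); TatA-type families across Enterobacterales, Pseudomonadales,
Burkholderiales and Rhizobiales; TatB-type, K8-only and
otherwise-charged subfamilies; 20 decoys and 5 incomplete entries — 403
records in total.  The separate eight-member TatA_1/TatA_2 exemplar
octet is generated with exactly seven E³xxxxK⁸ members, one K⁸-only
member and lengths spanning 63–78 with both extremes realized.  These
sizes keep the exact (non-heuristic) dynamic programme comfortable on a
single CPU: the full screen takes well under a minute and the 111-member
MSA a few seconds.

Reported conservation values are the realized Bernoulli counts for the
given seed (e.g. 100/111 lysines at position 8 for seed 1), which is
what the consensus model must reproduce exactly; across seeds they
scatter binomially around the nominal probabilities.

## Dual-paralog detection

An organism (string equality of the organism field) is dual-paralog iff
it has at least one record in {E3K8, E2K8, K8_ONLY} and at least one in
{TATA_LIKE, UNCHARGED_OTHER}.  Records without an organism never
participate; output is sorted by organism and invariant to record order.
Survey rows order Classes alphabetically and Orders by descending total.

## Known limitations

- The screen reports one best local alignment per pair (no multiple
  HSPs) — adequate for short single-domain proteins, wrong for
  multi-domain queries.
- E-values use a fixed λ/κ pair; schemes with other matrices or gap
  costs need their own constants supplied.
- The progressive MSA has no guide-tree re-estimation or consistency
  stage and will not match any particular external aligner's columns.
- Classification reads raw positions; N-terminally truncated or
  mis-annotated start codons are the completeness filter's problem, not
  the classifier's.
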