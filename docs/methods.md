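# Methods

`protcur` implements two connected procedures from mass-spectrometry-based
proteomics of poorly annotated organisms (the motivating case is hexaploid
bread wheat, *Triticum aestivum*): compiling a manually curated,
non-redundant protein sequence database, and inferring a minimal protein
list from replicate peptide-spectrum-match (PSM) tables. This note records
the models, the parameters that matter, the numerical choices, and what the
synthetic fixtures do and do not establish.

## Database curation

The curation model takes a reviewed seed list (Swiss-Prot-style entries), a
large unreviewed candidate pool (TrEMBL-style entries), and optionally a
second list of reviewed entries from phylogenetically related species.

1. **Keyword screening.** Seed entries whose description contains any of
   `gluten`, `gliadin`, `glutenin`, `avenin`, `prolamin` (case-insensitive
   substring) are set aside; the database targets the metabolic
   (salt-soluble) fraction, and gluten proteins are curated elsewhere. The
   singular stem `prolamin` is used so both singular and plural forms match.
2. **Cluster assembly.** Each remaining seed ("query sequence") collects
   pool entries with local-alignment identity >= 80% (at most 1000 hits)
   into one family cluster. Identity is computed BLAST-style: identical
   columns over all columns of the aligned region, gap columns included.
3. **Redundancy elimination.** Within a cluster, candidates are classified
   against retained members by a first-match cascade: *duplicate*
   (byte-identical), *fragment* (exact contiguous subsequence, the shorter
   sequence), *redundant-precursor-only* (identical mature chains, all
   differences upstream of the reference's mature-start), *variant-keep*
   (global identity >= 80% with point mutations or short indels — retained
   as possible isoforms), else *unrelated*. Members are considered in
   retention-priority order — reviewed over unreviewed, then longer, then
   lexicographically smaller accession — which makes the outcome independent
   of input order.
4. **Cross-species stage.** Each related-species "homologue query" is
   mapped to its highest-identity same-organism pool entry (ties: longer
   alignment, then accession); that counterpart is then treated as a new
   query and clustered identically.
5. **Merge.** Retained members from all clusters are merged; cross-cluster
   de-duplication is by accession first, then by exact sequence (a reviewed
   entry displaces an unreviewed one with the same sequence; the absorbed
   accession is recorded in the keeper's `collected_accessions`). The report
   satisfies `n_kept + n_discarded = n_compared`, where an entry is
   "compared" once no matter how many clusters it joined.

Manual removal of incomplete or misannotated entries is deliberately *not*
automated: entries whose description contains `Fragment`, `Uncharacterized`
or `Predicted` are listed in the report for human review. Silent deletion by
irreproducible judgement would change outputs in ways no one could audit.

### Alignment engine

Pairwise alignment is an affine-gap Gotoh dynamic program (global and local
modes) scored with BLOSUM62 as shipped with Biopython, using BLAST's protein
gap defaults: open 11, extend 1, with a gap of length L costing
`11 + L`. Traceback ties prefer a match/mismatch step over a gap in the
first sequence over a gap in the second, making alignments deterministic.
Letters outside the BLOSUM62 alphabet (U, O, J) score as X but count as
ordinary letters in identity tallies, so selenocysteine and ambiguity codes
in unreviewed entries neither crash the pipeline nor silently shrink pools.
The kernels are numba-compiled; correctness is cross-checked in the test
suite against Biopython's `PairwiseAligner` and, for short sequences,
against exhaustive enumeration of all gapped alignments.

The built-in pool search is an exhaustive all-vs-all scan — appropriate at
the scale of a seed list and its candidates. No E-value is computed: the
Karlin-Altschul statistic depends on database size and would be meaningless
on desk-scale pools. Externally produced BLAST tabular (outfmt 6) files can
be ingested instead; their E-values are honoured as a pass-through filter
(<= 10) and identities are taken from the file, not recomputed.

**Coverage floor.** `compile_database` additionally requires a local hit to
cover at least 30% of the query (`coverage_min = 0.3`, applied uniformly to
built-in and ingested hits). Identity alone admits trivially short segment
matches — a shared tripeptide aligns at 100% identity with a BLOSUM62 score
that would even pass a permissive E-threshold at small database sizes — and
no curator would treat such a hit as a family member. The 0.3 floor mirrors
the shortest fragment a cluster is expected to absorb. `search_pool` itself
leaves coverage unconstrained by default, since the identity-only contract
is the documented behaviour of the lower-level operation.

**Mature-start provenance.** Signal/transit-peptide boundaries come from a
two-column sidecar table (accession, 1-based mature start); UniProt feature
parsing is out of scope. When a reference has no mature start, the
precursor-only rule is skipped and such variants are retained as ordinary
variants — a conservative failure mode.

## Protein inference

The inference model starts from PSM tables (peptide, score, replicate,
decoy flag) — spectrum-to-peptide matching itself is out of scope.

1. **Target-decoy filtering.** At score cutoff t,
   `FDR(t) = #decoys>=t / #targets>=t`; a PSM's q-value is the minimum FDR
   over cutoffs at or below its score. Targets with q <= 0.001 (FDR <=
   0.1%) are accepted; decoys never pass. All replicates are validated in
   one pass, as one database search, then accepted PSMs are split by
   replicate. With zero decoys all targets are accepted with a warning.
2. **Peptide mapping.** An accepted peptide maps to a protein iff it occurs
   as a substring with full-tryptic boundaries on both sides (protein
   terminus or a K/R site not followed by P). PEAKS-style modification
   notation (e.g. `M(+15.99)`) is stripped by a configurable pattern before
   matching. I/L folding is off by default (spectra can distinguish them via
   immonium/satellite ions; sequence-only mapping cannot, so a flag is
   provided).
3. **Grouping.** Proteins with identical mapped peptide sets are merged
   into one indistinguishable group; the representative ("top protein") is
   the reviewed member if any, else the smallest accession. A peptide is
   *unique* when it occurs in exactly one group. Uniqueness is computed
   against all groups of the searched database *before* any parsimony
   discard, so it is database-relative by construction: a peptide decisive
   in a small reviewed-only database can stop being decisive in a larger
   curated one.
4. **Parsimony (Occam's razor).** A group whose peptide set is a strict
   subset of a single other group's set is discarded as a *subset protein*.
   A group with no unique peptide whose set is covered by the union of the
   remaining groups is discarded as an *intersection protein*. Intersection
   discards are applied iteratively, smallest peptide set first (ties by
   top-protein accession), re-checking that every accepted peptide remains
   covered by a surviving group. The iterative guard matters on cyclic
   sharing patterns (three proteins pairwise sharing all their peptides):
   unconstrained static rules would discard all three and orphan peptides,
   whereas the guard discards one and leaves the others to fail the
   unique-peptide requirement instead. Subset/intersection checks are exact
   set operations; post-grouping instance sizes make this tractable.
5. **Acceptance and consensus.** A surviving group is reported when it has
   >= 2 matched peptides including >= 1 unique peptide. A protein makes the
   final list when reported in >= 2 of the replicate runs, matched by
   top-protein accession (matching by group-membership overlap is a noted
   alternative; accession matching is what a reader of two reports does).

`compare_searches` is plain set algebra on two final lists, and
`explain_absence` answers why a protein reported by one search is missing
from another: absent from the database, subset of a top protein,
intersection protein, too few peptides, no unique peptide, or reported in
too few replicates. When replicates disagree, the modal discard status wins,
with ties broken in the order just given. A database entry with no mapped
peptides at all is reported as "insufficient peptides" (zero is fewer than
two).

## Synthetic fixtures

The generator module plants families with known structure: exact
duplicates; contiguous fragments covering >= 30% of the parent; precursor
variants mutating only signal-peptide positions (mature start =
signal length + 1); point-mutation variants at 3% per mature residue (a
variant that draws zero mutations is labelled a duplicate, which it is);
plus unrelated uniform-composition random proteins. PSM simulation samples
fully tryptic peptides (no missed cleavages, length 6-35) of the true
proteins per replicate with detection probability 0.8, scores from
N(30, 3); decoy PSMs draw peptides from the digest of reversed database
sequences with scores from N(8, 2.5). Reversal is the standard target-decoy
construction; the score separation emulates a validated search in which
true matches dominate, and is wide enough that q <= 0.001 retains
essentially all targets. All generators are byte-deterministic under a
seed.

What the fixtures do **not** emulate: homology structure in unrelated
proteins (real pools contain distant paralogues near the 80% boundary),
realistic residue composition, shared peptides caused by conserved domains
across families, score distributions with heavy overlap, chimeric or
misassembled TrEMBL entries, and any spectrum-level effect (mass tolerance,
modifications, chimeric spectra). Passing the recovery tests therefore
demonstrates correctness of the bookkeeping and the decision rules under
clean conditions, not identification performance on real data.

## Problem sizes and defaults

The bundled end-to-end runs use 4 planted families (seed + 2 duplicates +
1 fragment + 1 precursor variant + 2 variants) plus 20 unrelated entries
for curation, and 50 true proteins in a 60-entry database across 3
replicates for inference; the parsimony oracle suite uses 1000 random
instances with <= 6 proteins and <= 12 peptides, where exhaustive
classification is feasible. These sizes exercise every code path while
keeping any run comfortably interactive.

Defaults in one place: identity >= 80%, max 1000 hits, coverage floor 0.3
(compilation only), gap open/extend 11/1, q <= 0.001, >= 2 peptides,
>= 1 unique peptide, >= 2 of 3 replicates, tryptic digestion with <= 3
missed cleavages and peptide length 5-60.

## Known limitations

- The built-in search is O(n x m) DP per pair with no k-mer seeding; for
  pools beyond a few thousand entries, run external BLAST and ingest the
  tabular output.
- Redundancy classification is pairwise and greedy under a fixed priority;
  a pathological cluster could in principle depend on which member absorbs
  which (the permutation tests cover the planted cases, not all cases).
- Gene-symbol transfer from the closest cross-species hit is an annotation
  aid; orthology is not verified.
- The two-out-of-three consensus matches proteins by top-protein accession;
  groups whose representative flips between replicates (possible when
  membership changes) would be counted conservatively.
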