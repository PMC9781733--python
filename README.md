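# protcur

Curated protein sequence databases and parsimony protein inference for
mass-spectrometry-based proteomics.

## The problem

Shotgun proteomics identifies proteins indirectly: MS/MS spectra are matched
to peptide sequences, and peptides are assembled into a protein list. Both
steps depend entirely on the protein sequence database searched. For poorly
annotated organisms — hexaploid bread wheat (*Triticum aestivum*) is the
motivating case — the reviewed section of UniProtKB (Swiss-Prot) holds only
a few hundred entries, while the unreviewed section (TrEMBL) holds hundreds
of thousands of redundant, fragmentary and poorly annotated ones. Searching
the former misses proteins; searching the latter drowns the report in
redundancy.

`protcur` automates the two workflows this situation calls for:

1. **Curation** — compile a non-redundant, annotated FASTA database from a
   reviewed seed list plus a large unreviewed pool: keyword-screen the
   seeds, collect >= 80%-identity homologs per seed into family clusters
   (BLOSUM62, affine gaps 11/1), eliminate duplicates, exact fragments and
   entries differing only in the signal/transit peptide, map reviewed
   entries of related species onto their same-organism counterparts, and
   merge with full bookkeeping (`n_kept + n_discarded = n_compared`).
2. **Inference** — from replicate PSM tables: target-decoy filtering at
   q <= 0.001 (`FDR(t) = #decoys>=t / #targets>=t`, q = min FDR at or below
   the PSM's score), full-tryptic peptide-to-protein mapping, grouping of
   indistinguishable proteins, the minimal (Occam's razor) list — subset
   proteins and intersection proteins discarded — acceptance with >= 2
   peptides including >= 1 unique peptide, and a >= 2-of-3 replicate
   consensus. Two search reports can be Venn-compared, with a per-protein
   explanation of why an entry reported by one search is absent from the
   other.

A seeded synthetic-data module generates curation pools and PSM tables with
recorded ground truth, so every stage is testable without downloads. See
`docs/methods.md` for the full model description and its limitations.

## Worked example

```python
import numpy as np
from protcur import fixtures as fx, curation as cur, inference as inf

gen = np.random.default_rng(7)
families = [
    fx.make_family(
        fx.random_protein(int(gen.integers(120, 240)), gen),
        n_duplicates=2, n_fragments=1, n_precursor_variants=1, n_variants=2,
        rng=gen, acc_offset=100 * i, family_label=f"FAM{i+1}",
    )
    for i in range(4)
]
pool, truth = fx.make_pool(families, n_unrelated=20, rng=gen)
queries = sorted(
    (r for r in pool if truth.planted_labels[r.accession]["relation"] == "seed"),
    key=lambda r: r.accession,
)
records, report, annotation = cur.compile_database(queries, [], pool)
print(f"compared {report.n_compared}, kept {report.n_kept}, discarded {report.n_discarded}")
print(f"discards by category: {report.discards_by_category}")

psms, _ = fx.simulate_psms([r.accession for r in records[:5]], records, rng=1)
result = inf.run_inference(psms, records)
print(f"{len(psms)} PSM rows -> final list: {result.final_accessions}")
```

prints

```
compared 28, kept 12, discarded 16
discards by category: {'duplicate': 8, 'fragment': 4, 'redundant_precursor_only': 4}
671 PSM rows -> final list: ['SYN00006', 'SYN00007', 'SYN00101']
```

Four planted families of 7 entries each enter curation (28 compared); per
family the seed and its two point-mutation variants survive (12 kept) while
the 2 duplicates, the fragment and the signal-peptide-only variant are
discarded (16), matching the planted truth exactly. The 20 unrelated pool
entries never join a cluster. In the inference run, five database entries
were declared truly present, three of them from the same family; after
q-value filtering and parsimony, three survive the
two-peptide/one-unique/two-replicate requirements. Of the two casualties,
one is the family seed whose detected peptides are all shared with its two
co-present variants (no unique peptide), and the other is a variant whose
detected peptides formed a subset of a relative's in two of the three
replicates, so it missed the consensus — exactly the conservative behaviour
the minimal-list strategy is designed to produce when near-identical
isoforms are present together.

The same workflows are available from the shell:

```sh
protcur simulate --seed 13 --out-pool pool.fasta --out-psms psms.tsv --out-truth truth.json
protcur curate --queries seeds.fasta --pool pool.fasta \
    --out-fasta db.fasta --out-annotation db.tsv --out-report report.json
protcur infer --psms psms.tsv --database db.fasta \
    --out-report groups.jsonl --out-list final.txt
protcur compare --report-a a.jsonl --report-b b.jsonl \
    --database-a a.fasta --database-b b.fasta --out venn.json
```

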