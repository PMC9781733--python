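"""Curated-database assembly: seed filtering, homolog clustering, redundancy
elimination, cross-species homologue mapping, merge and reporting.

The workflow mirrors how manually curated organism databases are compiled
from a reviewed seed list plus a large unreviewed pool: gluten-family seeds
are excluded by description keywords, every remaining seed ("query
sequence") collects its >= 80%-identity homologs into a family cluster, each
cluster is purged of duplicates, fragments and precursor-only variants, and
a second stage maps reviewed entries of related species onto their
same-organism counterparts before the retained members are merged and
de-duplicated across clusters.

Redundancy classes
------------------
duplicate
    byte-identical sequences.
fragment
    one sequence is an exact contiguous subsequence of the other (the
    shorter one is the fragment).
redundant_precursor_only
    the mature chains are identical and every difference lies in the
    signal/transit peptide upstream of the reference's ``mature_start``.
variant_keep
    distinct sequences above the identity threshold (point mutations or
    short indels) — retained, since they may be genuine isoforms.
unrelated
    below the identity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .homology import (
    DEFAULT_MAX_HITS,
    DEFAULT_MIN_IDENTITY,
    SearchHit,
    hits_from_blast,
    is_exact_subsequence,
    pairwise_align,
    search_pool,
)
from .io_formats import AnnotationRow, BlastHitRow, ProteinRecord

__all__ = [
    "RedundancyVerdict",
    "FamilyCluster",
    "CurationReport",
    "DEFAULT_EXCLUDE_KEYWORDS",
    "REVIEW_FLAG_TERMS",
    "exclude_by_keywords",
    "classify_redundancy",
    "build_cluster",
    "deduplicate_cluster",
    "map_homologue_to_wheat",
    "compile_database",
    "infer_gene_from_ortholog",
]

# Gluten-protein exclusion terms; singular stem "prolamin" also catches the
# plural. Matching is case-insensitive substring on the description.
DEFAULT_EXCLUDE_KEYWORDS = ("gluten", "gliadin", "glutenin", "avenin", "prolamin")

# Terms that flag a kept entry for human review (never auto-deleted).
REVIEW_FLAG_TERMS = ("fragment", "uncharacterized", "predicted")

# Minimum fraction of the query covered by a local hit before it joins a
# cluster. Identity alone admits trivially short segment matches (a shared
# tripeptide aligns at 100% identity); 0.3 mirrors the shortest fragment a
# cluster is expected to absorb.
DEFAULT_COVERAGE_MIN = 0.3

_REDUNDANT_VERDICTS = frozenset(
    {"duplicate", "fragment", "redundant_precursor_only"}
)


@dataclass(frozen=True)
class RedundancyVerdict:
    """Classification of a candidate entry against a reference entry."""

    candidate_acc: str
    reference_acc: str
    verdict: str
    identity_pct: Optional[float] = None
    mismatch_positions: tuple = ()  # 1-based, reference coordinates
    containment_position: Optional[int] = None  # 1-based, in the longer seq

    @property
    def is_redundant(self) -> bool:
        return self.verdict in _REDUNDANT_VERDICTS


@dataclass
class FamilyCluster:
    """The per-query homolog cluster assembled before and after curation."""

    query_acc: str
    family_label: str
    members: list[ProteinRecord] = field(default_factory=list)
    discards: list[RedundancyVerdict] = field(default_factory=list)

    def member_accessions(self) -> list[str]:
        return [m.accession for m in self.members]

    def check_nonredundant(self) -> None:
        """Raise if two members are identical or one contains another."""
        for i, a in enumerate(self.members):
            for b in self.members[i + 1 :]:
                if a.sequence == b.sequence:
                    raise ValueError(
                        f"cluster {self.query_acc}: identical members "
                        f"{a.accession}/{b.accession}"
                    )
                short, long = sorted((a, b), key=lambda r: len(r.sequence))
                contained, _ = is_exact_subsequence(short.sequence, long.sequence)
                if contained:
                    raise ValueError(
                        f"cluster {self.query_acc}: {short.accession} is a "
                        f"subsequence of {long.accession}"
                    )


@dataclass
class CurationReport:
    """Compared/discarded/kept bookkeeping for one compilation run."""

    n_compared: int = 0
    n_discarded: int = 0
    n_kept: int = 0
    discards_by_category: dict = field(default_factory=dict)
    per_cluster: list = field(default_factory=list)
    keyword_removed: list = field(default_factory=list)
    flagged_for_review: list = field(default_factory=list)

    def validate(self) -> None:
        if self.n_kept + self.n_discarded != self.n_compared:
            raise AssertionError(
                f"report arithmetic broken: {self.n_kept} kept + "
                f"{self.n_discarded} discarded != {self.n_compared} compared"
            )
        if sum(self.discards_by_category.values()) != self.n_discarded:
            raise AssertionError("discard categories do not sum to n_discarded")


def exclude_by_keywords(
    records: Sequence[ProteinRecord],
    keywords: Sequence[str] = DEFAULT_EXCLUDE_KEYWORDS,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Split records into (kept, removed) by description keyword screening.

    A record is removed iff its description contains any keyword as a
    case-insensitive substring. Both lists preserve input order.
    """
    lowered = [k.lower() for k in keywords]
    kept: list[ProteinRecord] = []
    removed: list[ProteinRecord] = []
    for rec in records:
        desc = rec.description.lower()
        (removed if any(k in desc for k in lowered) else kept).append(rec)
    return kept, removed


def classify_redundancy(
    candidate: ProteinRecord,
    reference: ProteinRecord,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> RedundancyVerdict:
    """Classify ``candidate`` against ``reference``; first matching rule wins.

    1. identical sequences -> ``duplicate``;
    2. one an exact subsequence of the other -> ``fragment``;
    3. identical mature chains with every difference upstream of the
       reference's ``mature_start`` -> ``redundant_precursor_only``;
    4. global identity >= ``min_identity`` -> ``variant_keep``;
    5. otherwise ``unrelated``.
    """
    cseq, rseq = candidate.sequence, reference.sequence
    if cseq == rseq:
        return RedundancyVerdict(
            candidate.accession, reference.accession, "duplicate", identity_pct=100.0
        )
    short, long = (cseq, rseq) if len(cseq) < len(rseq) else (rseq, cseq)
    contained, pos = is_exact_subsequence(short, long)
    if contained:
        return RedundancyVerdict(
            candidate.accession,
            reference.accession,
            "fragment",
            identity_pct=100.0 * len(short) / len(long),
            containment_position=pos,
        )

    aln = pairwise_align(cseq, rseq, mode="global")
    mismatch_pos = tuple(aln.mismatch_positions_in_b())

    if reference.mature_start is not None:
        if _differs_only_in_precursor(aln, reference.mature_start):
            return RedundancyVerdict(
                candidate.accession,
                reference.accession,
                "redundant_precursor_only",
                identity_pct=aln.identity_pct,
                mismatch_positions=mismatch_pos,
            )

    if aln.identity_pct >= min_identity:
        return RedundancyVerdict(
            candidate.accession,
            reference.accession,
            "variant_keep",
            identity_pct=aln.identity_pct,
            mismatch_positions=mismatch_pos,
        )
    return RedundancyVerdict(
        candidate.accession,
        reference.accession,
        "unrelated",
        identity_pct=aln.identity_pct,
        mismatch_positions=mismatch_pos,
    )


def _differs_only_in_precursor(aln, mature_start: int) -> bool:
    """True iff all differing columns sit before ``mature_start`` of input b
    (the reference) and the aligned mature chains are identical."""
    ref_pos = 0  # 1-based position of the current reference residue
    n_diff_before = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        # reference position this column is attributed to; an insertion in
        # the candidate (gap in the reference row) counts against the next
        # reference residue
        attributed = ref_pos + 1
        if y != "-":
            ref_pos += 1
        if x == y:
            continue
        if attributed >= mature_start:
            return False
        n_diff_before += 1
    return n_diff_before >= 1


def build_cluster(
    query: ProteinRecord,
    hits: Sequence[SearchHit],
    pool: Sequence[ProteinRecord],
    family_map: Optional[Mapping[str, str]] = None,
) -> FamilyCluster:
    """Materialise hit subjects from the pool into a family cluster.

    The query is always a member. The family label comes from the configured
    query -> Pfam-name map, falling back to ``"FAM_" + query accession``.
    """
    by_acc = {rec.accession: rec for rec in pool}
    label = (family_map or {}).get(query.accession, f"FAM_{query.accession}")
    members = [query]
    seen = {query.accession}
    for hit in hits:
        if hit.subject_acc in seen:
            continue
        if hit.subject_acc not in by_acc:
            raise ValueError(f"hit subject {hit.subject_acc} absent from pool")
        members.append(by_acc[hit.subject_acc])
        seen.add(hit.subject_acc)
    return FamilyCluster(query_acc=query.accession, family_label=label, members=members)


def _retention_key(rec: ProteinRecord):
    # reviewed beats unreviewed, then longer sequence, then accession asc
    return (not rec.is_reviewed, -len(rec.sequence), rec.accession)


def deduplicate_cluster(
    cluster: FamilyCluster, min_identity: float = DEFAULT_MIN_IDENTITY
) -> FamilyCluster:
    """All-vs-all redundancy elimination within a cluster.

    Members are considered in retention-priority order (reviewed first, then
    longer, then lexicographically smaller accession); each one is kept
    unless it is a duplicate, fragment or precursor-only variant of an
    already-retained member. The result is independent of the input order.
    """
    ordered = sorted(cluster.members, key=_retention_key)
    retained: list[ProteinRecord] = []
    discards = list(cluster.discards)
    for member in ordered:
        verdict = None
        for keeper in retained:
            v = classify_redundancy(member, keeper, min_identity)
            if v.is_redundant:
                verdict = v
                break
        if verdict is None:
            retained.append(member)
        else:
            discards.append(verdict)
    out = FamilyCluster(
        query_acc=cluster.query_acc,
        family_label=cluster.family_label,
        members=retained,
        discards=discards,
    )
    out.check_nonredundant()
    return out


def map_homologue_to_wheat(
    homologue_query: ProteinRecord,
    pool: Sequence[ProteinRecord],
    organism_filter: str = "Triticum aestivum",
    min_identity: float = DEFAULT_MIN_IDENTITY,
    coverage_min: Optional[float] = None,
) -> Optional[ProteinRecord]:
    """Best same-organism counterpart of a cross-species homologue query.

    Returns the organism-matching pool entry with the highest local identity
    (ties broken by longer alignment, then accession ascending), or None when
    no hit reaches ``min_identity``.
    """
    hits = search_pool(
        homologue_query,
        pool,
        min_identity=min_identity,
        organism_filter=organism_filter,
        coverage_min=coverage_min,
    )
    if not hits:
        return None
    best = min(hits, key=lambda h: (-h.identity_pct, -h.aln_length, h.subject_acc))
    by_acc = {rec.accession: rec for rec in pool}
    return by_acc[best.subject_acc]


def infer_gene_from_ortholog(
    record: ProteinRecord,
    cross_species_pool: Sequence[ProteinRecord],
    min_identity: float = 0.0,
) -> Optional[tuple[str, str]]:
    """Provisional gene symbol from the highest-identity cross-species hit.

    Only pool entries from a different organism that carry a GN value are
    considered. Returns ``(gene_symbol, source_accession)`` or None. The
    result is an annotation aid, not ground truth.
    """
    candidates = [
        rec
        for rec in cross_species_pool
        if rec.gene and rec.organism != record.organism
    ]
    hits = search_pool(record, candidates, min_identity=max(min_identity, 1e-9))
    if not hits:
        return None
    best = min(hits, key=lambda h: (-h.identity_pct, -h.aln_length, h.subject_acc))
    by_acc = {rec.accession: rec for rec in candidates}
    return by_acc[best.subject_acc].gene, best.subject_acc


def compile_database(
    stage_a_queries: Sequence[ProteinRecord],
    stage_b_homologue_queries: Sequence[ProteinRecord],
    pool: Sequence[ProteinRecord],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_hits: int = DEFAULT_MAX_HITS,
    keywords: Sequence[str] = DEFAULT_EXCLUDE_KEYWORDS,
    mature_starts: Optional[Mapping[str, int]] = None,
    family_map: Optional[Mapping[str, str]] = None,
    blast_rows: Optional[Sequence[BlastHitRow]] = None,
    organism_filter: str = "Triticum aestivum",
    coverage_min: Optional[float] = DEFAULT_COVERAGE_MIN,
) -> tuple[list[ProteinRecord], CurationReport, list[AnnotationRow]]:
    """Run the full compilation workflow and return the curated database.

    Stage a: keyword-screen the reviewed seed queries, then collect and
    de-duplicate one homolog cluster per query. Stage b: map each
    cross-species homologue query onto its best same-organism counterpart
    and treat that counterpart as a new query. Finally merge every retained
    member, de-duplicating across clusters by accession and by exact
    sequence (reviewed entry wins, then first encountered).

    Returns ``(records, report, annotation_rows)``; the report satisfies
    ``n_kept + n_discarded = n_compared``.
    """
    mature_starts = dict(mature_starts or {})

    def annotate(rec: ProteinRecord) -> ProteinRecord:
        ms = mature_starts.get(rec.accession)
        return rec.with_mature_start(ms) if ms is not None else rec

    pool = [annotate(r) for r in pool]
    pool_by_acc = {r.accession: r for r in pool}
    stage_a_queries = [annotate(r) for r in stage_a_queries]
    for q in stage_a_queries:
        other = pool_by_acc.get(q.accession)
        if other is not None and other.sequence != q.sequence:
            raise ValueError(
                f"query {q.accession} collides with a pool entry of a "
                "different sequence"
            )

    report = CurationReport()
    kept_queries, removed = exclude_by_keywords(stage_a_queries, keywords)
    report.keyword_removed = [r.accession for r in removed]

    blast_by_query: dict[str, list[BlastHitRow]] = {}
    if blast_rows is not None:
        for row in blast_rows:
            blast_by_query.setdefault(row.query_acc, []).append(row)

    def hits_for(query: ProteinRecord) -> list[SearchHit]:
        if blast_rows is not None:
            rows = blast_by_query.get(query.accession, [])
            if coverage_min is not None:
                qlen = len(query.sequence)
                rows = [
                    r for r in rows
                    if (r.q_end - r.q_start + 1) / qlen >= coverage_min
                ]
            return hits_from_blast(
                rows, pool, min_identity=min_identity, max_hits=max_hits
            )
        return search_pool(
            query,
            pool,
            min_identity=min_identity,
            max_hits=max_hits,
            coverage_min=coverage_min,
        )

    clusters: list[FamilyCluster] = []
    processed_queries: set[str] = set()

    def process_query(query: ProteinRecord) -> None:
        if query.accession in processed_queries:
            return
        processed_queries.add(query.accession)
        cluster = build_cluster(query, hits_for(query), pool, family_map)
        clusters.append(deduplicate_cluster(cluster, min_identity))

    for query in kept_queries:
        process_query(query)

    # Stage b: cross-species homologue queries mapped to the target organism.
    for hq in stage_b_homologue_queries:
        counterpart = map_homologue_to_wheat(
            hq,
            pool,
            organism_filter=organism_filter,
            min_identity=min_identity,
            coverage_min=coverage_min,
        )
        if counterpart is not None:
            process_query(counterpart)

    # Merge retained members across clusters; accession first, then exact
    # sequence. collected[acc] accumulates absorbed accessions per keeper.
    kept: dict[str, ProteinRecord] = {}
    kept_family: dict[str, str] = {}
    by_sequence: dict[str, str] = {}  # sequence -> keeper accession
    collected: dict[str, list[str]] = {}
    merge_discards: list[RedundancyVerdict] = []

    def absorb(keeper_acc: str, other_acc: str) -> None:
        bucket = collected.setdefault(keeper_acc, [])
        if other_acc not in bucket:
            bucket.append(other_acc)

    for cluster in clusters:
        for member in cluster.members:
            if member.accession in kept:
                continue
            incumbent_acc = by_sequence.get(member.sequence)
            if incumbent_acc is not None:
                incumbent = kept[incumbent_acc]
                if member.is_reviewed and not incumbent.is_reviewed:
                    # reviewed newcomer replaces the unreviewed incumbent
                    del kept[incumbent_acc]
                    kept[member.accession] = member
                    kept_family[member.accession] = kept_family.pop(incumbent_acc)
                    by_sequence[member.sequence] = member.accession
                    collected[member.accession] = collected.pop(incumbent_acc, [])
                    absorb(member.accession, incumbent_acc)
                    merge_discards.append(
                        RedundancyVerdict(
                            incumbent_acc, member.accession, "duplicate", 100.0
                        )
                    )
                else:
                    absorb(incumbent_acc, member.accession)
                    merge_discards.append(
                        RedundancyVerdict(
                            member.accession, incumbent_acc, "duplicate", 100.0
                        )
                    )
                continue
            kept[member.accession] = member
            kept_family[member.accession] = cluster.family_label
            by_sequence[member.sequence] = member.accession

    # Bookkeeping: every unique accession that entered a cluster was compared.
    compared: set[str] = set()
    verdict_by_acc: dict[str, RedundancyVerdict] = {}
    for cluster in clusters:
        compared.update(cluster.member_accessions())
        for v in cluster.discards:
            compared.add(v.candidate_acc)
            verdict_by_acc.setdefault(v.candidate_acc, v)
            if v.reference_acc in kept:
                absorb(v.reference_acc, v.candidate_acc)
    for v in merge_discards:
        verdict_by_acc.setdefault(v.candidate_acc, v)

    discarded = {acc for acc in compared if acc not in kept}
    report.n_compared = len(compared)
    report.n_kept = len(kept)
    report.n_discarded = len(discarded)
    for acc in sorted(discarded):
        v = verdict_by_acc.get(acc)
        category = v.verdict if v is not None else "duplicate"
        report.discards_by_category[category] = (
            report.discards_by_category.get(category, 0) + 1
        )
    for cluster in clusters:
        report.per_cluster.append(
            {
                "query_acc": cluster.query_acc,
                "family_label": cluster.family_label,
                "n_retained": len(cluster.members),
                "n_discarded": len(cluster.discards),
            }
        )
    report.flagged_for_review = sorted(
        acc
        for acc, rec in kept.items()
        if any(term in rec.description.lower() for term in REVIEW_FLAG_TERMS)
    )
    report.validate()

    records = list(kept.values())
    annotation = [
        AnnotationRow(
            accession=rec.accession,
            description=rec.description,
            organism=rec.organism,
            gene=rec.gene or "",
            status="fragment" if rec.is_fragment else "complete",
            protein_family=kept_family[rec.accession],
            collected_accessions=tuple(
                a for a in collected.get(rec.accession, []) if a not in kept
            ),
        )
        for rec in records
    ]
    return records, report, annotation
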