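"""Parsimony protein inference from PSM tables, and two-search comparison.

The pipeline mirrors how shotgun-proteomics post-processors assemble peptide
identifications into a minimal protein report (Occam's razor): PSMs are
filtered by target-decoy q-value, accepted peptides are mapped onto the
searched database with full-tryptic boundary checks, proteins sharing an
identical peptide set are merged into one group, groups whose evidence is a
strict subset of a single other group are dropped ("subset proteins"),
groups with no unique peptide whose evidence is covered by the union of the
remaining groups are dropped ("intersection proteins"), and surviving groups
are reported when they carry at least ``min_peptides`` peptides including at
least one unique peptide. A protein makes the final list when reported in at
least ``min_replicates`` of the replicate runs.

Peptide uniqueness is computed against all groups present in the searched
database *before* parsimony discards, so uniqueness is database-relative: a
peptide unique in a small reviewed-only database may stop being decisive in
a larger curated one.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from pyteomics import parser as _pyt_parser

from .io_formats import ProteinRecord, PsmRecord, VALID_RESIDUES

__all__ = [
    "PeptideAssignment",
    "ProteinGroup",
    "VennComparison",
    "AbsenceExplanation",
    "InferenceSettings",
    "InferenceResult",
    "digest_tryptic",
    "filter_psms_by_fdr",
    "map_peptides",
    "group_proteins",
    "apply_parsimony",
    "accept_proteins",
    "replicate_consensus",
    "run_inference",
    "compare_searches",
    "explain_absence",
]

TRYPSIN_RULE = r"[KR](?!P)"  # cleave after K/R except before P

# PEAKS-style modification notation inside peptide strings, e.g. M(+15.99).
DEFAULT_MOD_PATTERN = r"\([^)]*\)|\[[^\]]*\]"


@dataclass(frozen=True)
class PeptideAssignment:
    """One accepted peptide and the database proteins it maps to."""

    peptide: str
    protein_accs: frozenset
    is_unique: bool  # maps to exactly one protein group


@dataclass
class ProteinGroup:
    """A set of indistinguishable proteins and their peptide support."""

    group_id: str
    member_accs: frozenset
    top_protein: str
    peptides: frozenset
    unique_peptides: frozenset
    status: str = "candidate"

    def __post_init__(self) -> None:
        if not self.unique_peptides <= self.peptides:
            raise ValueError(f"{self.group_id}: unique_peptides not within peptides")


@dataclass(frozen=True)
class VennComparison:
    """Set-algebra diff of two final protein lists."""

    only_a: frozenset
    only_b: frozenset
    common: frozenset

    def __post_init__(self) -> None:
        if self.only_a & self.common or self.only_b & self.common or self.only_a & self.only_b:
            raise ValueError("Venn partitions must be pairwise disjoint")


ABSENCE_REASONS = (
    "absent_from_database",
    "subset_of_top_protein",
    "intersection_protein",
    "insufficient_peptides",
    "no_unique_peptide",
    "failed_replicate_consensus",
)

_STATUS_TO_REASON = {
    "subset_discarded": "subset_of_top_protein",
    "intersection_discarded": "intersection_protein",
    "failed_min_peptides": "insufficient_peptides",
    "failed_no_unique": "no_unique_peptide",
}
# precedence when replicates disagree
_REASON_PRECEDENCE = (
    "subset_of_top_protein",
    "intersection_protein",
    "insufficient_peptides",
    "no_unique_peptide",
)


@dataclass(frozen=True)
class AbsenceExplanation:
    """Why a protein present in one search's report is missing from another."""

    accession: str
    reason: str
    supporting_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.reason not in ABSENCE_REASONS:
            raise ValueError(f"unknown absence reason {self.reason!r}")


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------


def digest_tryptic(
    sequence: str,
    max_missed: int = 3,
    min_len: int = 5,
    max_len: int = 60,
) -> list[tuple[str, int]]:
    """Full tryptic peptides of a sequence with their 1-based start positions.

    Cleavage occurs after K or R except when the next residue is P. Products
    with up to ``max_missed`` internal uncleaved sites and length within
    ``[min_len, max_len]`` are returned, ordered by start position then
    length.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    sequence = sequence.upper()
    peptides = {
        (pep, start + 1)
        for start, pep in _pyt_parser.icleave(
            sequence, TRYPSIN_RULE, missed_cleavages=max_missed
        )
        if min_len <= len(pep) <= max_len
    }
    return sorted(peptides, key=lambda t: (t[1], len(t[0])))


# ---------------------------------------------------------------------------
# Target-decoy FDR filtering
# ---------------------------------------------------------------------------


def filter_psms_by_fdr(
    psms: Sequence[PsmRecord], q_threshold: float = 0.001
) -> list[PsmRecord]:
    """Accept target PSMs whose target-decoy q-value is <= ``q_threshold``.

    At each score cutoff t, FDR(t) = (#decoys >= t) / (#targets >= t); the
    q-value of a PSM is the minimum FDR over all cutoffs at or below its
    score. Decoy PSMs are never returned.
    """
    targets = [p for p in psms if not p.is_decoy]
    decoys = [p for p in psms if p.is_decoy]
    if not targets:
        return []
    if not decoys:
        warnings.warn("no decoy PSMs present; accepting all targets with q = 0")
        return list(targets)

    cutoffs = sorted({p.score for p in psms}, reverse=True)
    t_scores = sorted((p.score for p in targets), reverse=True)
    d_scores = sorted((p.score for p in decoys), reverse=True)

    # counts >= cutoff, walking cutoffs from high to low
    fdr_at: dict[float, float] = {}
    ti = di = 0
    for t in cutoffs:
        while ti < len(t_scores) and t_scores[ti] >= t:
            ti += 1
        while di < len(d_scores) and d_scores[di] >= t:
            di += 1
        fdr_at[t] = di / ti if ti else float("inf")

    # q(cutoff) = min FDR over this and every lower cutoff
    qvals: dict[float, float] = {}
    running = float("inf")
    for t in reversed(cutoffs):  # ascending scores
        running = min(running, fdr_at[t])
        qvals[t] = running

    return [p for p in targets if qvals[p.score] <= q_threshold]


# ---------------------------------------------------------------------------
# Peptide-to-protein mapping
# ---------------------------------------------------------------------------


def strip_modifications(peptide: str, mod_pattern: str = DEFAULT_MOD_PATTERN) -> str:
    """Remove modification notation (e.g. ``M(+15.99)``) from a peptide string."""
    return re.sub(mod_pattern, "", peptide).upper()


def _tryptic_occurrences(peptide: str, sequence: str, require_tryptic: bool) -> bool:
    """True iff ``peptide`` occurs in ``sequence`` with tryptic boundaries."""
    start = sequence.find(peptide)
    while start >= 0:
        end = start + len(peptide)
        if not require_tryptic:
            return True
        up_ok = start == 0 or (sequence[start - 1] in "KR" and peptide[0] != "P")
        down_ok = end == len(sequence) or (peptide[-1] in "KR" and sequence[end] != "P")
        if up_ok and down_ok:
            return True
        start = sequence.find(peptide, start + 1)
    return False


def map_peptides(
    peptides: Iterable[str],
    database: Sequence[ProteinRecord],
    require_tryptic: bool = True,
    il_equivalent: bool = False,
    mod_pattern: str = DEFAULT_MOD_PATTERN,
) -> list[PeptideAssignment]:
    """Map peptides onto database proteins; uniqueness is group-relative.

    A peptide maps to a protein iff it occurs as a substring whose upstream
    boundary is the protein start or follows a K/R-not-before-P site, and
    whose downstream boundary is the protein end or a K/R-not-before-P cut.
    ``il_equivalent`` folds I and L together before matching. A peptide is
    unique when it maps to exactly one protein group (groups computed over
    the whole database by :func:`group_proteins`).
    """
    def fold(s: str) -> str:
        return s.replace("L", "J").replace("I", "J") if il_equivalent else s

    cleaned: list[str] = []
    seen: set[str] = set()
    for pep in peptides:
        p = strip_modifications(pep, mod_pattern)
        bad = set(p) - VALID_RESIDUES
        if bad or not p:
            raise ValueError(f"peptide {pep!r} contains non-amino-acid letters")
        if p not in seen:
            seen.add(p)
            cleaned.append(p)

    folded_seqs = {rec.accession: fold(rec.sequence) for rec in database}
    pep_to_prot: dict[str, set[str]] = {}
    for p in cleaned:
        fp = fold(p)
        hits = {
            acc
            for acc, seq in folded_seqs.items()
            if _tryptic_occurrences(fp, seq, require_tryptic)
        }
        pep_to_prot[p] = hits

    # group proteins by identical peptide sets to decide uniqueness
    prot_to_pep: dict[str, frozenset] = {}
    for p, accs in pep_to_prot.items():
        for acc in accs:
            prot_to_pep.setdefault(acc, frozenset())
    for acc in prot_to_pep:
        prot_to_pep[acc] = frozenset(
            p for p, accs in pep_to_prot.items() if acc in accs
        )
    group_of: dict[frozenset, set[str]] = {}
    for acc, peps in prot_to_pep.items():
        group_of.setdefault(peps, set()).add(acc)

    assignments = []
    for p in cleaned:
        groups_hit = {
            frozenset(members)
            for peps, members in group_of.items()
            if p in peps
        }
        assignments.append(
            PeptideAssignment(
                peptide=p,
                protein_accs=frozenset(pep_to_prot[p]),
                is_unique=len(groups_hit) == 1,
            )
        )
    return assignments


def group_proteins(
    assignments: Sequence[PeptideAssignment],
    database: Optional[Sequence[ProteinRecord]] = None,
) -> list[ProteinGroup]:
    """Merge proteins with identical peptide sets into indistinguishable groups.

    The group representative (``top_protein``) is the reviewed member when
    one exists, otherwise the lexicographically smallest accession. Groups
    with empty peptide sets are dropped. Unique peptides are those carried by
    exactly one group.
    """
    reviewed = {r.accession for r in database or [] if r.is_reviewed}
    prot_to_pep: dict[str, set[str]] = {}
    for a in assignments:
        for acc in a.protein_accs:
            prot_to_pep.setdefault(acc, set()).add(a.peptide)

    by_set: dict[frozenset, set[str]] = {}
    for acc, peps in prot_to_pep.items():
        if peps:
            by_set.setdefault(frozenset(peps), set()).add(acc)

    pep_group_count: dict[str, int] = {}
    for peps in by_set:
        for p in peps:
            pep_group_count[p] = pep_group_count.get(p, 0) + 1

    groups = []
    for peps, members in by_set.items():
        rev = sorted(members & reviewed)
        top = rev[0] if rev else min(members)
        groups.append(
            ProteinGroup(
                group_id="",
                member_accs=frozenset(members),
                top_protein=top,
                peptides=peps,
                unique_peptides=frozenset(
                    p for p in peps if pep_group_count[p] == 1
                ),
            )
        )
    groups.sort(key=lambda g: g.top_protein)
    for i, g in enumerate(groups, start=1):
        g.group_id = f"G{i:04d}"
    return groups


# ---------------------------------------------------------------------------
# Parsimony
# ---------------------------------------------------------------------------


def apply_parsimony(groups: Sequence[ProteinGroup]) -> list[ProteinGroup]:
    """Set group statuses by the maximum-parsimony (Occam's razor) rules.

    A group whose peptide set is a strict subset of a single other group's
    set becomes ``subset_discarded``. A group with no unique peptide whose
    set is covered by the union of the remaining non-discarded groups
    becomes ``intersection_discarded``; such discards are applied smallest
    set first (ties by top-protein accession) and re-checked so that every
    accepted peptide stays covered by at least one non-discarded group.
    Remaining groups keep ``candidate`` status.
    """
    groups = list(groups)
    for g in groups:
        for h in groups:
            if h is not g and g.peptides < h.peptides:
                g.status = "subset_discarded"
                break

    def alive() -> list[ProteinGroup]:
        return [g for g in groups if g.status not in ("subset_discarded", "intersection_discarded")]

    candidates = sorted(
        (g for g in alive() if not g.unique_peptides),
        key=lambda g: (len(g.peptides), g.top_protein),
    )
    changed = True
    while changed:
        changed = False
        for g in candidates:
            if g.status != "candidate":
                continue
            others = [h for h in alive() if h is not g]
            union = set().union(*(h.peptides for h in others)) if others else set()
            if g.peptides <= union:
                g.status = "intersection_discarded"
                changed = True
    return groups


def accept_proteins(
    groups: Sequence[ProteinGroup],
    min_peptides: int = 2,
    require_unique: bool = True,
) -> list[str]:
    """Apply the per-replicate acceptance requirements to candidate groups.

    A candidate group is reported when it carries at least ``min_peptides``
    matched peptides and (when ``require_unique``) at least one unique
    peptide; the group's top protein is listed. Failing groups get status
    ``failed_min_peptides`` or ``failed_no_unique``.
    """
    reported = []
    for g in groups:
        if g.status != "candidate":
            continue
        if len(g.peptides) < min_peptides:
            g.status = "failed_min_peptides"
        elif require_unique and not g.unique_peptides:
            g.status = "failed_no_unique"
        else:
            g.status = "reported"
            reported.append(g.top_protein)
    return sorted(reported)


def replicate_consensus(
    per_replicate_reports: Mapping[str, Sequence[str]], min_replicates: int = 2
) -> list[str]:
    """Accessions reported in at least ``min_replicates`` replicate runs."""
    counts: dict[str, int] = {}
    for accs in per_replicate_reports.values():
        for acc in set(accs):
            counts[acc] = counts.get(acc, 0) + 1
    return sorted(acc for acc, n in counts.items() if n >= min_replicates)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InferenceSettings:
    """Thresholds of the identification workflow."""

    q_threshold: float = 0.001  # FDR <= 0.1%
    min_peptides: int = 2
    require_unique: bool = True
    min_replicates: int = 2  # e.g. two out of three LC-MS/MS runs
    require_tryptic: bool = True
    il_equivalent: bool = False
    mod_pattern: str = DEFAULT_MOD_PATTERN

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_threshold <= 1.0):
            raise ValueError("q_threshold must be in [0, 1]")
        if self.min_peptides < 1 or self.min_replicates < 1:
            raise ValueError("min_peptides and min_replicates must be >= 1")


@dataclass
class InferenceResult:
    """Per-replicate groups, per-replicate reports and the consensus list."""

    per_replicate_groups: dict
    per_replicate_reported: dict
    final_accessions: list
    database_accessions: frozenset
    settings: InferenceSettings

    def replicates_reporting(self, accession: str) -> list[str]:
        return sorted(
            rep
            for rep, accs in self.per_replicate_reported.items()
            if accession in accs
        )

    def groups_containing(self, accession: str) -> list[tuple[str, ProteinGroup]]:
        out = []
        for rep in sorted(self.per_replicate_groups):
            for g in self.per_replicate_groups[rep]:
                if accession in g.member_accs:
                    out.append((rep, g))
        return out

    def to_jsonl(self) -> str:
        lines = [
            json.dumps(
                {
                    "settings": {
                        "q_threshold": self.settings.q_threshold,
                        "min_peptides": self.settings.min_peptides,
                        "require_unique": self.settings.require_unique,
                        "min_replicates": self.settings.min_replicates,
                        "require_tryptic": self.settings.require_tryptic,
                        "il_equivalent": self.settings.il_equivalent,
                        "mod_pattern": self.settings.mod_pattern,
                    },
                    "database_accessions": sorted(self.database_accessions),
                },
                sort_keys=True,
            )
        ]
        for rep in sorted(self.per_replicate_groups):
            for g in self.per_replicate_groups[rep]:
                lines.append(
                    json.dumps(
                        {
                            "replicate": rep,
                            "group_id": g.group_id,
                            "members": sorted(g.member_accs),
                            "top_protein": g.top_protein,
                            "peptides": sorted(g.peptides),
                            "unique_peptides": sorted(g.unique_peptides),
                            "status": g.status,
                        },
                        sort_keys=True,
                    )
                )
        lines.append(
            json.dumps({"final_accessions": self.final_accessions}, sort_keys=True)
        )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_jsonl(cls, text: str) -> "InferenceResult":
        """Rebuild a result from its machine-readable report."""
        header: Optional[dict] = None
        per_groups: dict[str, list[ProteinGroup]] = {}
        final: list[str] = []
        for line in text.splitlines():
            if not line.strip():
                continue
            obj = json.loads(line)
            if "settings" in obj:
                header = obj
            elif "final_accessions" in obj:
                final = list(obj["final_accessions"])
            else:
                per_groups.setdefault(obj["replicate"], []).append(
                    ProteinGroup(
                        group_id=obj["group_id"],
                        member_accs=frozenset(obj["members"]),
                        top_protein=obj["top_protein"],
                        peptides=frozenset(obj["peptides"]),
                        unique_peptides=frozenset(obj["unique_peptides"]),
                        status=obj["status"],
                    )
                )
        if header is None:
            raise ValueError("report lacks the settings header line")
        per_reported = {
            rep: sorted(
                g.top_protein for g in groups if g.status == "reported"
            )
            for rep, groups in per_groups.items()
        }
        return cls(
            per_replicate_groups=per_groups,
            per_replicate_reported=per_reported,
            final_accessions=final,
            database_accessions=frozenset(header["database_accessions"]),
            settings=InferenceSettings(**header["settings"]),
        )


def run_inference(
    psms: Sequence[PsmRecord],
    database: Sequence[ProteinRecord],
    settings: InferenceSettings = InferenceSettings(),
) -> InferenceResult:
    """Run FDR filtering, mapping, grouping, parsimony and consensus.

    PSMs from all replicates are validated in one target-decoy pass (as one
    database search); accepted PSMs are then split by replicate for mapping
    and per-replicate acceptance. Deterministic given inputs and settings.
    """
    accepted = filter_psms_by_fdr(psms, settings.q_threshold)
    by_rep: dict[str, set[str]] = {}
    for p in accepted:
        by_rep.setdefault(p.replicate_id, set()).add(p.peptide)

    per_groups: dict[str, list[ProteinGroup]] = {}
    per_reported: dict[str, list[str]] = {}
    for rep in sorted(by_rep):
        peptides = sorted(by_rep[rep])
        assignments = map_peptides(
            peptides,
            database,
            require_tryptic=settings.require_tryptic,
            il_equivalent=settings.il_equivalent,
            mod_pattern=settings.mod_pattern,
        )
        groups = group_proteins(assignments, database)
        apply_parsimony(groups)
        reported = accept_proteins(
            groups,
            min_peptides=settings.min_peptides,
            require_unique=settings.require_unique,
        )
        per_groups[rep] = groups
        per_reported[rep] = reported

    final = replicate_consensus(per_reported, settings.min_replicates)
    return InferenceResult(
        per_replicate_groups=per_groups,
        per_replicate_reported=per_reported,
        final_accessions=final,
        database_accessions=frozenset(r.accession for r in database),
        settings=settings,
    )


# ---------------------------------------------------------------------------
# Two-search comparison
# ---------------------------------------------------------------------------


def compare_searches(result_a: InferenceResult, result_b: InferenceResult) -> VennComparison:
    """Venn partition of two final protein lists, matched by accession."""
    a = set(result_a.final_accessions)
    b = set(result_b.final_accessions)
    return VennComparison(
        only_a=frozenset(a - b), only_b=frozenset(b - a), common=frozenset(a & b)
    )


def explain_absence(
    accession: str,
    own_result: InferenceResult,
    other_result: InferenceResult,
    other_database: Sequence[ProteinRecord],
) -> AbsenceExplanation:
    """Why a protein on ``own_result``'s final list is absent from the other.

    Inspects the other search's group statuses: no database record means
    ``absent_from_database``; a protein reported in some but fewer than
    ``min_replicates`` replicates means ``failed_replicate_consensus``;
    otherwise the recorded discard status is translated. A database entry
    with no peptide support at all counts as ``insufficient_peptides``.
    """
    if accession in other_result.final_accessions:
        raise ValueError(f"{accession} is present in the other search's final list")
    db_accs = {r.accession for r in other_database}
    if accession not in db_accs:
        return AbsenceExplanation(accession, "absent_from_database")

    reporting = other_result.replicates_reporting(accession)
    min_reps = other_result.settings.min_replicates
    hits = other_result.groups_containing(accession)
    if reporting and len(reporting) < min_reps:
        # reported somewhere, but not in enough replicates
        rep = reporting[0]
        gid = next(
            (g.group_id for r, g in hits if r == rep and g.status == "reported"), None
        )
        return AbsenceExplanation(accession, "failed_replicate_consensus", gid)

    reasons: dict[str, tuple[int, Optional[str]]] = {}
    for _, g in hits:
        reason = _STATUS_TO_REASON.get(g.status)
        if reason is None:
            continue
        count, gid = reasons.get(reason, (0, None))
        reasons[reason] = (count + 1, gid or g.group_id)
    if not reasons:
        return AbsenceExplanation(accession, "insufficient_peptides")
    best = max(
        reasons.items(),
        key=lambda kv: (kv[1][0], -_REASON_PRECEDENCE.index(kv[0])),
    )
    return AbsenceExplanation(accession, best[0], best[1][1])
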