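"""Seeded generators for curation pools and PSM tables with known truth.

Everything here is synthetic: protein families with planted duplicates,
fragments, signal-peptide-only (precursor) variants and point-mutation
variants stand in for an unreviewed sequence pool, and replicate-structured
PSM tables with reversed-sequence decoys stand in for validated search
output. Each generator records its ground truth so downstream stages can be
scored without re-deriving anything, and is byte-deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .inference import digest_tryptic
from .io_formats import ProteinRecord, PsmRecord

__all__ = [
    "FixtureTruth",
    "random_protein",
    "make_family",
    "make_pool",
    "simulate_psms",
    "worked_example_records",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Default well-separated PSM score model: high-scoring targets, low-scoring
# decoys, emulating a validated search where true matches dominate.
DEFAULT_TARGET_SCORE = (30.0, 3.0)  # (mean, sd)
DEFAULT_DECOY_SCORE = (8.0, 2.5)

Rng = Union[int, np.random.Generator]


def _as_rng(rng: Rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass
class FixtureTruth:
    """Planted ground truth sufficient to score any downstream stage."""

    planted_labels: dict = field(default_factory=dict)  # acc -> {relation, parent}
    true_proteins: set = field(default_factory=set)
    peptide_origin: dict = field(default_factory=dict)  # peptide -> set of accs
    seed: int = -1

    def merge(self, other: "FixtureTruth") -> None:
        self.planted_labels.update(other.planted_labels)
        self.true_proteins |= other.true_proteins
        for pep, accs in other.peptide_origin.items():
            self.peptide_origin.setdefault(pep, set()).update(accs)


def random_protein(
    length: int,
    rng: Rng,
    composition: Optional[Sequence[float]] = None,
) -> str:
    """An i.i.d. random protein sequence over the 20 standard residues.

    ``composition`` may give per-residue probabilities (in :data:`AMINO_ACIDS`
    order); the default is uniform.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    gen = _as_rng(rng)
    p = None
    if composition is not None:
        p = np.asarray(composition, dtype=float)
        if p.shape != (20,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError("composition must be 20 non-negative probabilities summing to 1")
    idx = gen.choice(20, size=length, p=p)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _mutate(seq: str, positions: Sequence[int], gen: np.random.Generator) -> str:
    """Substitute the given 0-based positions with a different residue each."""
    out = list(seq)
    for pos in positions:
        choices = [c for c in AMINO_ACIDS if c != out[pos]]
        out[pos] = choices[gen.integers(len(choices))]
    return "".join(out)


def make_family(
    seed_seq: str,
    n_duplicates: int = 0,
    n_fragments: int = 0,
    n_precursor_variants: int = 0,
    n_variants: int = 0,
    mutation_rate: float = 0.03,
    signal_len: int = 25,
    rng: Rng = 0,
    acc_offset: int = 0,
    organism: str = "Triticum aestivum",
    family_label: str = "",
) -> tuple[list[ProteinRecord], FixtureTruth]:
    """A reviewed seed protein plus planted redundant/variant children.

    Duplicates are exact copies; fragments are contiguous subranges covering
    at least 30% of the parent; precursor variants mutate only positions
    within the signal peptide (1..``signal_len``) and share the parent's
    mature chain (``mature_start = signal_len + 1``); variants mutate mature
    positions at ``mutation_rate`` (a variant that draws zero mutations is
    an exact copy and is therefore labelled a duplicate). Accessions are
    synthetic, ``SYN{acc_offset+i:05d}``.
    """
    gen = _as_rng(rng)
    if signal_len >= len(seed_seq):
        raise ValueError("signal_len must be shorter than the seed sequence")
    truth = FixtureTruth(seed=rng if isinstance(rng, int) else -1)
    counter = acc_offset

    def next_acc() -> str:
        nonlocal counter
        counter += 1
        return f"SYN{counter:05d}"

    seed_acc = next_acc()
    mature_start = signal_len + 1 if n_precursor_variants > 0 or signal_len > 0 else None
    records = [
        ProteinRecord(
            accession=seed_acc,
            sequence=seed_seq,
            db_section="reviewed",
            description=f"Synthetic family seed {family_label or seed_acc}",
            organism=organism,
            mature_start=mature_start,
        )
    ]
    truth.planted_labels[seed_acc] = {"relation": "seed", "parent": None}

    def child(seq: str, relation: str, desc: str) -> None:
        acc = next_acc()
        records.append(
            ProteinRecord(
                accession=acc,
                sequence=seq,
                db_section="unreviewed",
                description=desc,
                organism=organism,
            )
        )
        truth.planted_labels[acc] = {"relation": relation, "parent": seed_acc}

    for _ in range(n_duplicates):
        child(seed_seq, "duplicate_of", "Synthetic duplicate entry")

    n = len(seed_seq)
    for _ in range(n_fragments):
        frag_len = int(gen.integers(max(int(np.ceil(0.3 * n)), 1), n))
        start = int(gen.integers(0, n - frag_len + 1))
        child(
            seed_seq[start : start + frag_len],
            "fragment_of",
            "Synthetic fragment entry (Fragment)",
        )

    for _ in range(n_precursor_variants):
        k = int(gen.integers(1, min(3, signal_len) + 1))
        positions = gen.choice(signal_len, size=k, replace=False)
        child(
            _mutate(seed_seq, sorted(int(p) for p in positions), gen),
            "precursor_variant_of",
            "Synthetic precursor variant entry",
        )

    mature_positions = np.arange(signal_len, n)
    for _ in range(n_variants):
        mask = gen.random(mature_positions.size) < mutation_rate
        positions = [int(p) for p in mature_positions[mask]]
        if positions:
            child(
                _mutate(seed_seq, positions, gen),
                "variant_of",
                "Synthetic point-mutation variant entry",
            )
        else:
            child(seed_seq, "duplicate_of", "Synthetic duplicate entry")

    return records, truth


def make_pool(
    families: Sequence[tuple[list[ProteinRecord], FixtureTruth]],
    n_unrelated: int = 0,
    rng: Rng = 0,
    unrelated_length: tuple[int, int] = (80, 300),
    organism: str = "Triticum aestivum",
) -> tuple[list[ProteinRecord], FixtureTruth]:
    """Shuffled union of family members plus unrelated random proteins."""
    gen = _as_rng(rng)
    truth = FixtureTruth(seed=rng if isinstance(rng, int) else -1)
    records: list[ProteinRecord] = []
    max_idx = 0
    for fam_records, fam_truth in families:
        records.extend(fam_records)
        truth.merge(fam_truth)
        for rec in fam_records:
            if rec.accession.startswith("SYN"):
                try:
                    max_idx = max(max_idx, int(rec.accession[3:]))
                except ValueError:
                    pass
    for i in range(n_unrelated):
        acc = f"SYN{max_idx + 1 + i:05d}"
        length = int(gen.integers(unrelated_length[0], unrelated_length[1] + 1))
        records.append(
            ProteinRecord(
                accession=acc,
                sequence=random_protein(length, gen),
                db_section="unreviewed",
                description="Synthetic unrelated entry",
                organism=organism,
            )
        )
        truth.planted_labels[acc] = {"relation": "unrelated", "parent": None}
    order = gen.permutation(len(records))
    return [records[i] for i in order], truth


def simulate_psms(
    true_proteins: Sequence[str],
    database: Sequence[ProteinRecord],
    n_replicates: int = 3,
    detect_prob: float = 0.8,
    n_decoys: int = 200,
    target_score: tuple[float, float] = DEFAULT_TARGET_SCORE,
    decoy_score: tuple[float, float] = DEFAULT_DECOY_SCORE,
    rng: Rng = 0,
    max_missed: int = 0,
    min_len: int = 6,
    max_len: int = 35,
) -> tuple[list[PsmRecord], FixtureTruth]:
    """Replicate-structured PSMs for a set of truly present proteins.

    Each replicate samples every fully tryptic peptide of every true protein
    with probability ``detect_prob`` and scores it from the target normal
    distribution; ``n_decoys`` decoy PSMs per replicate draw peptides from
    the tryptic digest of the reversed database sequences and scores from
    the decoy distribution. Replicates are labelled ``"R1"``..``"Rn"``.
    """
    gen = _as_rng(rng)
    by_acc = {rec.accession: rec for rec in database}
    missing = sorted(set(true_proteins) - set(by_acc))
    if missing:
        raise ValueError(f"true proteins absent from the database: {missing}")
    truth = FixtureTruth(
        true_proteins=set(true_proteins), seed=rng if isinstance(rng, int) else -1
    )

    eligible: list[tuple[str, str]] = []  # (peptide, accession)
    for acc in sorted(set(true_proteins)):
        for pep, _pos in digest_tryptic(
            by_acc[acc].sequence, max_missed=max_missed, min_len=min_len, max_len=max_len
        ):
            eligible.append((pep, acc))
            truth.peptide_origin.setdefault(pep, set()).add(acc)

    target_peptides = set(truth.peptide_origin)
    decoy_pool = sorted(
        {
            pep
            for rec in database
            for pep, _pos in digest_tryptic(
                rec.sequence[::-1], max_missed=max_missed, min_len=min_len, max_len=max_len
            )
        }
        - target_peptides
    )
    if n_decoys > 0 and not decoy_pool:
        raise ValueError("no decoy peptides could be generated")

    psms: list[PsmRecord] = []
    seen_pairs: set[tuple[str, str]] = set()
    for r in range(1, n_replicates + 1):
        rep = f"R{r}"
        for pep, _acc in eligible:
            if (rep, pep) in seen_pairs:
                continue
            if gen.random() < detect_prob:
                seen_pairs.add((rep, pep))
                psms.append(
                    PsmRecord(
                        peptide=pep,
                        score=float(gen.normal(*target_score)),
                        replicate_id=rep,
                        is_decoy=False,
                    )
                )
        for _ in range(n_decoys):
            pep = decoy_pool[int(gen.integers(len(decoy_pool)))]
            psms.append(
                PsmRecord(
                    peptide=pep,
                    score=float(gen.normal(*decoy_score)),
                    replicate_id=rep,
                    is_decoy=True,
                )
            )
    return psms, truth


# ---------------------------------------------------------------------------
# Worked-example stand-ins
# ---------------------------------------------------------------------------

# The two published peptide sequences used in the isoform worked example;
# both are fully tryptic (end in K/R, no internal K/R, no leading P).
PEPTIDE_UNIQUE_REVIEWED_ISOFORM = "YGWTAFCGPAGAHGQAACGK"
PEPTIDE_UNIQUE_UNREVIEWED_ISOFORM = "VTNPATGAQVTAR"


def _tryptic_block(gen: np.random.Generator, length: int) -> str:
    """A random fully tryptic peptide: no internal K/R/P trouble spots."""
    interior_letters = [c for c in AMINO_ACIDS if c not in "KRP"]
    body = "".join(
        interior_letters[int(gen.integers(len(interior_letters)))]
        for _ in range(length - 1)
    )
    return body + ("K" if gen.random() < 0.5 else "R")


def _substitute_interior(block: str, gen: np.random.Generator) -> str:
    """One interior substitution that keeps the block fully tryptic."""
    pos = int(gen.integers(1, len(block) - 1))
    choices = [c for c in AMINO_ACIDS if c not in "KRP" and c != block[pos]]
    return block[:pos] + choices[int(gen.integers(len(choices)))] + block[pos + 1 :]


def worked_example_records() -> dict:
    """Synthetic stand-ins for the published redundancy and isoform examples.

    No sequence here is a real UniProt entry: each scenario is a synthetic
    reconstruction carrying only the *relationships* the worked examples
    describe, built deterministically.

    - ``precursor``: a 150-residue reviewed reference with a 30-residue
      transit peptide (``mature_start`` 31) and an unreviewed variant with
      exactly 3 substitutions, all upstream of the mature chain.
    - ``fragment``: a 236-residue parent and a 206-residue exact contiguous
      fragment.
    - ``duplicate``: two accessions with byte-identical sequences.
    - ``isoform_triplet``: three >95%-identical isoforms built from shared
      tryptic blocks, embedding the two published peptides so that one
      peptide is unique to the reviewed isoform in a two-protein database
      but shared in the three-protein one, and a second peptide is unique
      to the unreviewed isoform; plus the 14 observed peptides.
    """
    gen = np.random.default_rng(424242)

    # --- precursor-only variant pair -------------------------------------
    ref_seq = random_protein(150, gen)
    signal_positions = [4, 11, 20]  # 0-based, all < 30
    var_seq = _mutate(ref_seq, signal_positions, gen)
    precursor_ref = ProteinRecord(
        accession="SYNREF01",
        sequence=ref_seq,
        db_section="reviewed",
        description="Synthetic precursor worked example, reference",
        organism="Triticum aestivum",
        mature_start=31,
    )
    precursor_var = ProteinRecord(
        accession="SYNVAR01",
        sequence=var_seq,
        db_section="unreviewed",
        description="Synthetic precursor worked example, signal-peptide variant",
        organism="Triticum aestivum",
    )

    # --- fragment pair (236 vs 206 residues) ------------------------------
    parent_seq = random_protein(236, gen)
    fragment_seq = parent_seq[15 : 15 + 206]
    fragment_parent = ProteinRecord(
        accession="SYNREF02",
        sequence=parent_seq,
        db_section="reviewed",
        description="Synthetic fragment worked example, parent",
        organism="Triticum aestivum",
    )
    fragment_child = ProteinRecord(
        accession="SYNFRG02",
        sequence=fragment_seq,
        db_section="unreviewed",
        description="Synthetic fragment worked example, fragment (Fragment)",
        organism="Triticum aestivum",
    )

    # --- duplicate pair ----------------------------------------------------
    dup_seq = random_protein(120, gen)
    duplicate_ref = ProteinRecord(
        accession="SYNREF03",
        sequence=dup_seq,
        db_section="reviewed",
        description="Synthetic duplicate worked example, reference",
        organism="Triticum aestivum",
    )
    duplicate_copy = ProteinRecord(
        accession="SYNDUP03",
        sequence=dup_seq,
        db_section="unreviewed",
        description="Synthetic duplicate worked example, copy",
        organism="Triticum aestivum",
    )

    # --- isoform triplet ---------------------------------------------------
    # 14 tryptic block positions; see docstring for the sharing pattern.
    blocks = [_tryptic_block(gen, int(gen.integers(8, 15))) for _ in range(14)]
    blocks[5] = PEPTIDE_UNIQUE_REVIEWED_ISOFORM  # position 6
    blocks[7] = PEPTIDE_UNIQUE_UNREVIEWED_ISOFORM  # position 8
    x2_pair, x2_g = blocks[1], _substitute_interior(blocks[1], gen)
    x4_a, x4_other = blocks[3], _substitute_interior(blocks[3], gen)
    x7_a, x7_other = blocks[6], _substitute_interior(blocks[6], gen)
    p6, p6_var = blocks[5], _substitute_interior(blocks[5], gen)
    p8, p8_var = blocks[7], _substitute_interior(blocks[7], gen)

    def assemble(b2, b4, b6, b7, b8):
        parts = list(blocks)
        parts[1], parts[3], parts[5], parts[6], parts[7] = b2, b4, b6, b7, b8
        return "".join(parts)

    iso_a = ProteinRecord(  # carries the two block variants unique to it
        accession="SYNISO92",
        sequence=assemble(x2_pair, x4_a, p6_var, x7_a, p8_var),
        db_section="reviewed",
        description="Synthetic isoform worked example A",
        organism="Triticum aestivum",
    )
    iso_b = ProteinRecord(  # the intersection isoform in the 3-protein database
        accession="SYNISO93",
        sequence=assemble(x2_pair, x4_other, p6, x7_other, p8_var),
        db_section="reviewed",
        description="Synthetic isoform worked example B",
        organism="Triticum aestivum",
    )
    iso_c = ProteinRecord(  # unreviewed isoform carrying the extra peptide
        accession="SYNISOG2",
        sequence=assemble(x2_g, x4_other, p6, x7_other, p8),
        db_section="unreviewed",
        description="Synthetic isoform worked example C",
        organism="Triticum aestivum",
    )
    shared_blocks = [blocks[i] for i in (0, 2, 4, 8, 9, 10, 11, 12, 13)]
    observed_peptides = shared_blocks + [x2_pair, x4_a, x7_a, p6, p8]

    return {
        "precursor": (precursor_ref, precursor_var),
        "fragment": (fragment_parent, fragment_child),
        "duplicate": (duplicate_ref, duplicate_copy),
        "isoform_triplet": (iso_a, iso_b, iso_c),
        "observed_peptides": observed_peptides,
    }
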