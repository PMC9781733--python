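"""Readers and writers for the external formats the toolkit touches.

Covers FASTA in the UniProt header dialect (``>sp|ACC|NAME desc OS=... OX=...
GN=...``) and a plain dialect, NCBI BLAST tabular (outfmt 6), delimited
peptide-spectrum-match (PSM) tables, and the tab-separated annotation table
that accompanies a curated database. Writers are inverses of the readers on
valid data.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

import pandas as pd

__all__ = [
    "ProteinRecord",
    "PsmRecord",
    "AnnotationRow",
    "BlastHitRow",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_blast_tabular",
    "write_blast_tabular",
    "read_psm_table",
    "write_annotation_table",
    "read_annotation_table",
]

# Residue alphabet: the 20 standard amino acids plus selenocysteine (U) and
# the ambiguity codes B, Z, X. These occur in TrEMBL entries and are kept as
# ordinary letters so unreviewed pools are not silently shrunk.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYUBZX")


class FormatError(ValueError):
    """Raised when an input stream violates its declared format."""


@dataclass(frozen=True)
class ProteinRecord:
    """One sequence entry with UniProt-style metadata.

    ``db_section`` is ``"reviewed"`` for Swiss-Prot (``sp|``) entries and
    ``"unreviewed"`` for TrEMBL (``tr|``) entries. ``mature_start`` is the
    1-based residue index where the mature chain begins (i.e. the first
    residue after the signal/transit peptide), when known from a sidecar
    annotation.
    """

    accession: str
    sequence: str
    db_section: str = "unreviewed"
    entry_name: str = ""
    description: str = ""
    organism: str = ""
    taxon_id: Optional[int] = None
    gene: Optional[str] = None
    mature_start: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.accession}: sequence must be non-empty")
        if self.db_section not in ("reviewed", "unreviewed"):
            raise ValueError(f"{self.accession}: bad db_section {self.db_section!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"{self.accession}: invalid residue letters {sorted(bad)}"
            )
        if self.mature_start is not None and not (
            1 <= self.mature_start <= len(self.sequence)
        ):
            raise ValueError(
                f"{self.accession}: mature_start {self.mature_start} outside "
                f"[1, {len(self.sequence)}]"
            )

    @property
    def is_fragment(self) -> bool:
        """True when the description carries UniProt's "(Fragment)" marker."""
        return "(fragment)" in self.description.lower()

    @property
    def is_reviewed(self) -> bool:
        return self.db_section == "reviewed"

    def with_mature_start(self, mature_start: Optional[int]) -> "ProteinRecord":
        return replace(self, mature_start=mature_start)


@dataclass(frozen=True)
class PsmRecord:
    """A scored peptide-spectrum match: one peptide observation in one run."""

    peptide: str
    score: float
    replicate_id: str
    is_decoy: bool = False
    spectrum_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("peptide must be non-empty")
        score = float(self.score)
        if score != score or score in (float("inf"), float("-inf")):
            raise ValueError(f"{self.peptide}: score must be finite")
        object.__setattr__(self, "peptide", self.peptide.upper())
        object.__setattr__(self, "score", score)
        object.__setattr__(self, "replicate_id", str(self.replicate_id))


@dataclass(frozen=True)
class AnnotationRow:
    """One line of the curated-database annotation table."""

    accession: str
    description: str = ""
    organism: str = ""
    gene: str = ""
    status: str = "complete"
    protein_family: str = ""
    allergen_name: str = ""
    last_update: str = ""
    collected_accessions: tuple = ()

    def __post_init__(self) -> None:
        if self.status not in ("complete", "fragment"):
            raise ValueError(f"{self.accession}: bad status {self.status!r}")
        accs = tuple(self.collected_accessions)
        if len(accs) != len(set(accs)):
            raise ValueError(f"{self.accession}: duplicate collected accessions")
        object.__setattr__(self, "collected_accessions", accs)


@dataclass(frozen=True)
class BlastHitRow:
    """One row of NCBI BLAST tabular output (outfmt 6), coordinates 1-based."""

    query_acc: str
    subject_acc: str
    percent_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_UNIPROT_HEADER = re.compile(
    r"^(?P<db>[a-zA-Z0-9]+)\|(?P<acc>[^|\s]+)\|(?P<name>\S*)\s*(?P<rest>.*)$"
)
# OS / OX / GN / PE / SV key-value fields at the tail of a UniProt header.
_FIELD_SPLIT = re.compile(r"\s+(?=(?:OS|OX|GN|PE|SV)=)")


def _open_text(source: Union[str, TextIO, Iterable[str]]):
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def _parse_uniprot_header(header: str, lineno: int) -> dict:
    m = _UNIPROT_HEADER.match(header)
    if m is None:
        raise FormatError(
            f"line {lineno}: header {header!r} is not in the UniProt "
            "'db|ACCESSION|NAME description' dialect"
        )
    db = m.group("db").lower()
    if db == "sp":
        section = "reviewed"
    elif db == "tr":
        section = "unreviewed"
    else:
        warnings.warn(
            f"line {lineno}: unknown database prefix {db!r}; treating entry "
            f"{m.group('acc')} as unreviewed"
        )
        section = "unreviewed"
    parts = _FIELD_SPLIT.split(m.group("rest"))
    if parts and re.match(r"(?:OS|OX|GN|PE|SV)=", parts[0]):
        parts = [""] + parts  # empty description, header starts at a field
    description = parts[0].strip()
    organism = ""
    taxon_id: Optional[int] = None
    gene: Optional[str] = None
    for part in parts[1:]:
        key, _, value = part.partition("=")
        value = value.strip()
        if key == "OS":
            organism = value
        elif key == "OX":
            try:
                taxon_id = int(value)
            except ValueError:
                raise FormatError(f"line {lineno}: OX={value!r} is not an integer")
        elif key == "GN":
            gene = value or None
    return {
        "accession": m.group("acc"),
        "entry_name": m.group("name"),
        "db_section": section,
        "description": description,
        "organism": organism,
        "taxon_id": taxon_id,
        "gene": gene,
    }


def read_fasta(
    source: Union[str, TextIO, Iterable[str]],
    dialect: str = "uniprot",
    on_error: str = "raise",
) -> list[ProteinRecord]:
    """Parse FASTA into :class:`ProteinRecord` objects, order preserved.

    ``dialect="uniprot"`` expects ``>sp|ACC|NAME desc OS=... [OX=...] [GN=...]``
    headers; ``dialect="plain"`` takes the first whitespace-delimited token as
    the accession and the full header as the description. With
    ``on_error="skip"`` malformed entries are dropped with a warning instead
    of aborting the parse.
    """
    if dialect not in ("uniprot", "plain"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if on_error not in ("raise", "skip"):
        raise ValueError(f"on_error must be 'raise' or 'skip', got {on_error!r}")

    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}  # accession -> record ordinal
    header: Optional[str] = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        try:
            if dialect == "uniprot":
                meta = _parse_uniprot_header(header, header_line)
            else:
                token = header.split(None, 1)[0] if header.split() else ""
                if not token:
                    raise FormatError(f"line {header_line}: empty FASTA header")
                meta = {
                    "accession": token,
                    "entry_name": "",
                    "db_section": "unreviewed",
                    "description": header.strip(),
                    "organism": "",
                    "taxon_id": None,
                    "gene": None,
                }
            seq = "".join(chunks).upper().replace(" ", "")
            if not seq:
                raise FormatError(
                    f"line {header_line}: entry {meta['accession']} has an "
                    "empty sequence"
                )
            rec = ProteinRecord(sequence=seq, **meta)
        except (FormatError, ValueError) as exc:
            if on_error == "raise":
                if isinstance(exc, FormatError):
                    raise
                raise FormatError(f"line {header_line}: {exc}") from exc
            warnings.warn(f"skipping malformed FASTA entry: {exc}")
            return
        if rec.accession in seen:
            raise FormatError(
                f"duplicate accession {rec.accession!r}: entries "
                f"{seen[rec.accession] + 1} and {len(records) + 1}"
            )
        seen[rec.accession] = len(records)
        records.append(rec)

    for lineno, line in enumerate(_open_text(source), start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if line.startswith(">"):
            flush()
            header = line[1:]
            header_line = lineno
            chunks = []
        else:
            if header is None:
                raise FormatError(f"line {lineno}: sequence data before any header")
            chunks.append(line.strip())
    flush()
    return records


def write_fasta(
    records: Sequence[ProteinRecord],
    stream: Optional[TextIO] = None,
    dialect: str = "uniprot",
    width: int = 60,
) -> str:
    """Serialise records to FASTA; output re-parses to equal records.

    Sequences are wrapped at ``width`` columns (default 60).
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    out = io.StringIO()
    for rec in records:
        if dialect == "uniprot":
            db = "sp" if rec.is_reviewed else "tr"
            header = f">{db}|{rec.accession}|{rec.entry_name}"
            if rec.description:
                header += f" {rec.description}"
            if rec.organism:
                header += f" OS={rec.organism}"
            if rec.taxon_id is not None:
                header += f" OX={rec.taxon_id}"
            if rec.gene:
                header += f" GN={rec.gene}"
        else:
            header = f">{rec.accession}"
            if rec.description and rec.description != rec.accession:
                header += f" {rec.description}"
        out.write(header + "\n")
        seq = rec.sequence
        for i in range(0, len(seq), width):
            out.write(seq[i : i + width] + "\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------

_BLAST_COLS = 12


def read_blast_tabular(source: Union[str, TextIO, Iterable[str]]) -> list[BlastHitRow]:
    """Parse 12-column tab-separated BLAST output; '#' comment lines skipped."""
    rows: list[BlastHitRow] = []
    for lineno, line in enumerate(_open_text(source), start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != _BLAST_COLS:
            raise FormatError(
                f"line {lineno}: expected {_BLAST_COLS} tab-separated columns, "
                f"found {len(fields)}"
            )
        try:
            rows.append(
                BlastHitRow(
                    query_acc=fields[0],
                    subject_acc=fields[1],
                    percent_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
    return rows


def write_blast_tabular(rows: Sequence[BlastHitRow], stream: Optional[TextIO] = None) -> str:
    out = io.StringIO()
    for r in rows:
        out.write(
            "\t".join(
                str(v)
                for v in (
                    r.query_acc,
                    r.subject_acc,
                    f"{r.percent_identity:.3f}",
                    r.aln_length,
                    r.mismatches,
                    r.gap_opens,
                    r.q_start,
                    r.q_end,
                    r.s_start,
                    r.s_end,
                    f"{r.evalue:.3g}",
                    f"{r.bitscore:.1f}",
                )
            )
            + "\n"
        )
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------


def read_psm_table(
    source: Union[str, TextIO],
    column_map: Mapping[str, str],
    sep: str = "\t",
    decoy_prefix: str = "DECOY_",
) -> list[PsmRecord]:
    """Read a delimited PSM table with a header row into :class:`PsmRecord` s.

    ``column_map`` binds the required logical fields ``peptide``, ``score``
    and ``replicate_id`` — plus either ``is_decoy`` (boolean column) or
    ``decoy_accession`` (accession column matched against ``decoy_prefix``) —
    to the table's column names. ``spectrum_id`` is optional.
    """
    required = ("peptide", "score", "replicate_id")
    for key in required:
        if key not in column_map:
            raise ValueError(f"column_map must bind {key!r}")
    if "is_decoy" not in column_map and "decoy_accession" not in column_map:
        raise ValueError("column_map must bind 'is_decoy' or 'decoy_accession'")

    df = pd.read_csv(_open_text(source), sep=sep, dtype=str)
    available = list(df.columns)
    for key, col in column_map.items():
        if col not in df.columns:
            raise FormatError(
                f"mapped column {col!r} (for {key!r}) not found; available "
                f"columns: {available}"
            )

    records: list[PsmRecord] = []
    for idx, row in df.iterrows():
        peptide = str(row[column_map["peptide"]])
        raw_score = row[column_map["score"]]
        try:
            score = float(raw_score)
        except (TypeError, ValueError):
            raise FormatError(
                f"row {idx + 1}: score {raw_score!r} is not numeric"
            )
        if "is_decoy" in column_map:
            raw = str(row[column_map["is_decoy"]]).strip().lower()
            if raw in ("true", "1", "yes", "t"):
                is_decoy = True
            elif raw in ("false", "0", "no", "f"):
                is_decoy = False
            else:
                raise FormatError(f"row {idx + 1}: unparseable boolean {raw!r}")
        else:
            acc = str(row[column_map["decoy_accession"]])
            is_decoy = acc.startswith(decoy_prefix)
        spectrum_id = None
        if "spectrum_id" in column_map:
            spectrum_id = str(row[column_map["spectrum_id"]])
        try:
            records.append(
                PsmRecord(
                    peptide=peptide,
                    score=score,
                    replicate_id=str(row[column_map["replicate_id"]]),
                    is_decoy=is_decoy,
                    spectrum_id=spectrum_id,
                )
            )
        except ValueError as exc:
            raise FormatError(f"row {idx + 1}: {exc}") from exc
    return records


def write_psm_table(
    psms: Sequence[PsmRecord], stream: Optional[TextIO] = None, sep: str = "\t"
) -> str:
    """Write PSMs with the canonical column names read_psm_table can rebind."""
    out = io.StringIO()
    out.write(sep.join(("peptide", "score", "replicate_id", "is_decoy", "spectrum_id")) + "\n")
    for p in psms:
        out.write(
            sep.join(
                (
                    p.peptide,
                    repr(p.score),
                    p.replicate_id,
                    "true" if p.is_decoy else "false",
                    p.spectrum_id or "",
                )
            )
            + "\n"
        )
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = (
    "accession",
    "description",
    "organism",
    "gene",
    "status",
    "protein_family",
    "allergen_name",
    "last_update",
    "collected_accessions",
)


def write_annotation_table(
    rows: Sequence[AnnotationRow], stream: Optional[TextIO] = None
) -> str:
    """Serialise annotation rows as tab-separated text with a header row.

    ``collected_accessions`` is semicolon-joined in the final column.
    """
    out = io.StringIO()
    out.write("\t".join(_ANNOTATION_COLUMNS) + "\n")
    for r in rows:
        out.write(
            "\t".join(
                (
                    r.accession,
                    r.description,
                    r.organism,
                    r.gene,
                    r.status,
                    r.protein_family,
                    r.allergen_name,
                    r.last_update,
                    ";".join(r.collected_accessions),
                )
            )
            + "\n"
        )
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def read_annotation_table(source: Union[str, TextIO]) -> list[AnnotationRow]:
    stream = _open_text(source)
    header = next(iter(stream), None)
    if header is None:
        return []
    cols = tuple(header.rstrip("\n").split("\t"))
    if cols != _ANNOTATION_COLUMNS:
        raise FormatError(f"unexpected annotation header {cols!r}")
    rows = []
    for lineno, line in enumerate(stream, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != len(_ANNOTATION_COLUMNS):
            raise FormatError(
                f"line {lineno}: expected {len(_ANNOTATION_COLUMNS)} columns, "
                f"found {len(fields)}"
            )
        collected = tuple(a for a in fields[8].split(";") if a)
        rows.append(
            AnnotationRow(
                accession=fields[0],
                description=fields[1],
                organism=fields[2],
                gene=fields[3],
                status=fields[4],
                protein_family=fields[5],
                allergen_name=fields[6],
                last_update=fields[7],
                collected_accessions=collected,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# Sidecar tables (mature-start and family-label maps)
# ---------------------------------------------------------------------------


def read_two_column_map(source: Union[str, TextIO]) -> dict[str, str]:
    """Read a two-column delimited sidecar (accession<TAB>value), '#' comments."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(_open_text(source), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split(None, 1)
        if len(fields) != 2:
            raise FormatError(f"line {lineno}: expected 2 columns, found {len(fields)}")
        mapping[fields[0]] = fields[1]
    return mapping


def read_mature_starts(source: Union[str, TextIO]) -> dict[str, int]:
    """Sidecar accession -> 1-based mature-chain start index."""
    raw = read_two_column_map(source)
    out: dict[str, int] = {}
    for acc, val in raw.items():
        try:
            out[acc] = int(val)
        except ValueError:
            raise FormatError(f"mature start for {acc} is not an integer: {val!r}")
    return out
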