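"""UniProt-dialect FASTA parsing and predictor-eligibility screening.

Reference-proteome FASTA files from UniProt carry headers of the form
``>sp|ACCESSION|ENTRY_NAME Description OS=... PE=n SV=m`` (``sp`` for
Swiss-Prot, ``tr`` for TrEMBL).  This module parses that dialect (tolerating
plain headers), extracts the protein-existence (PE) qualifier, and screens
sequences for the residue codes that disorder predictors do not support.

Disorder predictors handle undetermined, ambiguous or unique residue codes
(B, J, O, U, X, Z) inconsistently -- some silently truncate them, corrupting
the position register of every downstream annotation.  Proteins containing
any such code are therefore excluded from analysis up front, and the
included/excluded partition is retained for the organism-level bookkeeping.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from Bio import SeqIO

from .errors import FastaParseError

__all__ = [
    "ProteinRecord",
    "EligibilityPartition",
    "INELIGIBLE_RESIDUES",
    "parse_uniprot_fasta",
    "screen_eligibility",
    "write_fasta",
    "write_accession_list",
]

#: Residue codes that make a sequence ineligible for disorder prediction.
INELIGIBLE_RESIDUES = frozenset("BJOUXZ")

_VALID_RESIDUES = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ")

_UNIPROT_HEADER = re.compile(r"^(sp|tr)\|([^|\s]+)\|(\S+)")
_PE_TAG = re.compile(r"\bPE=(\d+)")


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry.

    Attributes
    ----------
    accession : str
        UniProtKB-style accession (second pipe-delimited header token for
        ``sp|``/``tr|`` headers, otherwise the first whitespace-delimited
        token of the header).
    source_db : str
        ``"swissprot"``, ``"trembl"`` or ``"other"``.
    name : str
        Entry name (third pipe token), or ``""`` for plain headers.
    pe_qualifier : int | None
        UniProt protein-existence level 1-5, or ``None`` when the header
        carries no ``PE=`` tag.
    sequence : str
        Upper-case residue string with line breaks removed.
    """

    accession: str
    source_db: str
    name: str
    pe_qualifier: int | None
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaParseError(f"entry {self.accession!r}: empty sequence")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise FastaParseError(
                f"entry {self.accession!r}: illegal sequence characters "
                f"{sorted(bad)} (gap/stop symbols indicate a malformed file)")
        if self.pe_qualifier is not None and self.pe_qualifier not in (1, 2, 3, 4, 5):
            raise FastaParseError(
                f"entry {self.accession!r}: PE qualifier {self.pe_qualifier} outside 1-5")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class EligibilityPartition:
    """Outcome of predictor-eligibility screening.

    Every input record lands in exactly one of the two lists; each excluded
    record carries the non-empty set of offending residue codes found in it.
    """

    eligible: list[ProteinRecord] = field(default_factory=list)
    excluded: list[tuple[ProteinRecord, frozenset[str]]] = field(default_factory=list)

    @property
    def n_eligible(self) -> int:
        return len(self.eligible)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def _record_from_header(header: str, sequence: str) -> ProteinRecord:
    m = _UNIPROT_HEADER.match(header)
    if m:
        source_db = "swissprot" if m.group(1) == "sp" else "trembl"
        accession = m.group(2)
        name = m.group(3)
    else:
        source_db = "other"
        accession = header.split()[0] if header.split() else header
        name = ""
    pe = _PE_TAG.search(header)
    pe_qualifier = int(pe.group(1)) if pe else None
    return ProteinRecord(accession=accession, source_db=source_db, name=name,
                         pe_qualifier=pe_qualifier, sequence=sequence.upper())


def parse_uniprot_fasta(source: str | TextIO) -> list[ProteinRecord]:
    """Parse FASTA text into :class:`ProteinRecord` objects, in file order.

    Parameters
    ----------
    source : str or text stream
        FASTA content.  Headers may follow the UniProt ``sp|ACC|NAME ...
        PE=n SV=m`` dialect or be plain; sequences are uppercased.

    Raises
    ------
    FastaParseError
        On sequence data before the first header, an empty sequence, or
        gap/stop symbols (``-``, ``*``) in a sequence, naming the offending
        entry.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    text = source.read()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise FastaParseError("sequence data before first FASTA header")

    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        header = rec.description
        records.append(_record_from_header(header, str(rec.seq)))
    return records


def screen_eligibility(records: Iterable[ProteinRecord]) -> EligibilityPartition:
    """Partition records into predictor-eligible and excluded sets.

    A record is excluded iff its sequence contains any residue code in
    :data:`INELIGIBLE_RESIDUES`; the offending codes are reported per record.
    """
    part = EligibilityPartition()
    for rec in records:
        offending = frozenset(set(rec.sequence) & INELIGIBLE_RESIDUES)
        if offending:
            part.excluded.append((rec, offending))
        else:
            part.eligible.append(rec)
    return part


def _format_header(rec: ProteinRecord) -> str:
    if rec.source_db in ("swissprot", "trembl"):
        tag = "sp" if rec.source_db == "swissprot" else "tr"
        header = f"{tag}|{rec.accession}|{rec.name}"
        if rec.pe_qualifier is not None:
            header += f" PE={rec.pe_qualifier} SV=1"
        return header
    header = rec.accession
    if rec.pe_qualifier is not None:
        header += f" PE={rec.pe_qualifier}"
    return header


def write_fasta(records: Iterable[ProteinRecord], handle: TextIO | None = None,
                width: int = 60) -> str:
    """Write records as FASTA text; returns the text (and writes to *handle* if given).

    Headers are reconstructed in the UniProt dialect so that re-parsing
    reproduces accession, source database, PE qualifier and sequence exactly.
    """
    chunks: list[str] = []
    for rec in records:
        chunks.append(">" + _format_header(rec) + "\n")
        seq = rec.sequence
        for i in range(0, len(seq), width):
            chunks.append(seq[i:i + width] + "\n")
    text = "".join(chunks)
    if handle is not None:
        handle.write(text)
    return text


def write_accession_list(records: Iterable[ProteinRecord | tuple], path) -> None:
    """Export accessions as plain text, one per line.

    Accepts either plain records or ``(record, offending)`` pairs as produced
    by :func:`screen_eligibility`, so both the eligible and excluded lists can
    be exported directly.
    """
    with open(path, "w") as fh:
        for item in records:
            rec = item[0] if isinstance(item, tuple) else item
            fh.write(rec.accession + "\n")
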