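"""Single-file relational database output (SQLite) and validation.

All results for one or more organisms are materialized into one SQLite
file with exactly twelve tables:

========================  =====================================================
organisms                 one row per organism: proteome metadata, screening
                          counts, annotated-residue total, and the per-method
                          decision thresholds used for the run
proteins_included         eligible proteins (accession, name, source, sequence)
proteins_excluded         screened-out proteins with their offending residues
pe_status                 protein-existence qualifier per accession (0 = no
                          PE tag in the header, an extension for non-UniProt
                          inputs; 1-5 as defined by UniProt)
disorder_data             residue-level scores for the four methods plus DCC
                          and agreement ID; key (accession, position)
percent_disorder          per-protein disorder content per method + consensus
cd_regions_iupred         continuous-disorder regions of the I track
cd_regions_disembl_c      ... of the C track
cd_regions_disembl_h      ... of the H track
cd_regions_disembl_r      ... of the R track
cd_regions_consensus      ... of the all-four consensus track
sequence_parameters       charge/hydropathy parameter block per protein
========================  =====================================================

CD tables contain only CD-exhibiting proteins; a method that finds no
region in such a protein gets a single sentinel row with ``'N/A'`` markers.
An undefined kappa is stored as the explicit string ``'undefined'`` so it
can never be confused with a numeric zero.
"""

from __future__ import annotations

import os
import sqlite3
from dataclasses import dataclass, field

import pandas as pd

from .cd_features import CDSummary
from .consensus import agreement_id
from .errors import DatabaseFormatError, DatabaseIntegrityError
from .predictors import METHOD_IDS, PredictorTrack
from .sequence_io import ProteinRecord
from .charge_patterning import SequenceParameters

__all__ = [
    "TABLE_NAMES", "CD_TABLE_BY_METHOD", "NA_SENTINEL", "UNDEFINED_KAPPA",
    "OrganismSummary", "ProteinResult", "OrganismResult", "ValidationReport",
    "write_database", "verify_database", "summarize_pe", "export_tables_tsv",
]

NA_SENTINEL = "N/A"
UNDEFINED_KAPPA = "undefined"

CD_TABLE_BY_METHOD = {
    "I": "cd_regions_iupred",
    "C": "cd_regions_disembl_c",
    "H": "cd_regions_disembl_h",
    "R": "cd_regions_disembl_r",
    "consensus": "cd_regions_consensus",
}

TABLE_NAMES = (
    "organisms", "proteins_included", "proteins_excluded", "pe_status",
    "disorder_data", "percent_disorder",
    "cd_regions_iupred", "cd_regions_disembl_c", "cd_regions_disembl_h",
    "cd_regions_disembl_r", "cd_regions_consensus",
    "sequence_parameters",
)

_SCHEMA = """
CREATE TABLE organisms (
    organism TEXT PRIMARY KEY,
    proteome_id TEXT, fasta_file TEXT, accession_date TEXT,
    n_included INTEGER NOT NULL, n_excluded INTEGER NOT NULL,
    n_annotated_residues INTEGER NOT NULL,
    predictor_source TEXT,
    threshold_I REAL, threshold_C REAL, threshold_H REAL, threshold_R REAL
);
CREATE TABLE proteins_included (
    accession TEXT PRIMARY KEY, organism TEXT NOT NULL,
    entry_name TEXT, source_db TEXT, length INTEGER NOT NULL, sequence TEXT NOT NULL
);
CREATE TABLE proteins_excluded (
    accession TEXT PRIMARY KEY, organism TEXT NOT NULL,
    entry_name TEXT, source_db TEXT, length INTEGER NOT NULL,
    offending_residues TEXT NOT NULL
);
CREATE TABLE pe_status (
    accession TEXT PRIMARY KEY, organism TEXT NOT NULL,
    pe_qualifier INTEGER NOT NULL, included INTEGER NOT NULL
);
CREATE TABLE disorder_data (
    accession TEXT NOT NULL, position INTEGER NOT NULL, residue TEXT NOT NULL,
    score_I REAL, score_C REAL, score_H REAL, score_R REAL,
    dcc INTEGER NOT NULL, agreement_id TEXT NOT NULL,
    PRIMARY KEY (accession, position)
);
CREATE TABLE percent_disorder (
    accession TEXT PRIMARY KEY,
    pct_I REAL, pct_C REAL, pct_H REAL, pct_R REAL, pct_consensus REAL
);
{cd_tables}
CREATE TABLE sequence_parameters (
    accession TEXT PRIMARY KEY,
    f_disorder_promoting REAL, mean_hydropathy REAL, uversky_hydropathy REAL,
    fcr REAL, ncpr REAL, kappa, delta, delta_max,
    proline_content REAL, kappa_warning INTEGER,
    n_positive INTEGER, n_negative INTEGER, n_neutral INTEGER
);
"""

_CD_TABLE_TEMPLATE = """
CREATE TABLE {name} (
    accession TEXT NOT NULL, region_index INTEGER NOT NULL,
    start, end, length, n_regions INTEGER NOT NULL, cd_l, lcpl,
    PRIMARY KEY (accession, region_index)
);
"""


@dataclass(frozen=True)
class OrganismSummary:
    organism: str
    proteome_id: str = ""
    fasta_file: str = ""
    accession_date: str = ""
    predictor_source: str = "builtin"
    thresholds: dict[str, float] = field(default_factory=dict)


@dataclass
class ProteinResult:
    """Everything derived for one eligible protein."""

    record: ProteinRecord
    tracks: dict[str, PredictorTrack]
    annotations: pd.DataFrame
    percent_disorder: dict[str, float]
    cd: CDSummary
    params: SequenceParameters


@dataclass
class OrganismResult:
    summary: OrganismSummary
    included: list[ProteinResult]
    excluded: list[tuple[ProteinRecord, frozenset[str]]]

    @property
    def n_annotated_residues(self) -> int:
        return sum(p.record.length for p in self.included)


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _check_consistency(organisms: list[OrganismResult]) -> None:
    for org in organisms:
        for prot in org.included:
            if len(prot.annotations) != prot.record.length:
                raise DatabaseIntegrityError(
                    f"accession {prot.record.accession}: {len(prot.annotations)} "
                    f"annotation rows for a protein of length {prot.record.length}")


def write_database(organisms: list[OrganismResult], path: str,
                   overwrite: bool = False) -> None:
    """Materialize results as the twelve-table SQLite file.

    Refuses to touch an existing file unless *overwrite* is set, and
    validates annotation/sequence length consistency before writing
    anything.
    """
    _check_consistency(organisms)
    if os.path.exists(path):
        if not overwrite:
            raise DatabaseIntegrityError(
                f"{path} exists; pass overwrite=True to replace it")
        os.remove(path)

    cd_sql = "".join(_CD_TABLE_TEMPLATE.format(name=n)
                     for n in CD_TABLE_BY_METHOD.values())
    con = sqlite3.connect(path)
    try:
        con.executescript(_SCHEMA.format(cd_tables=cd_sql))
        for org in organisms:
            _insert_organism(con, org)
        con.commit()
    finally:
        con.close()


def _insert_organism(con: sqlite3.Connection, org: OrganismResult) -> None:
    s = org.summary
    thr = s.thresholds
    con.execute(
        "INSERT INTO organisms VALUES (?,?,?,?,?,?,?,?,?,?,?,?)",
        (s.organism, s.proteome_id, s.fasta_file, s.accession_date,
         len(org.included), len(org.excluded), org.n_annotated_residues,
         s.predictor_source,
         thr.get("I"), thr.get("C"), thr.get("H"), thr.get("R")))

    for rec, offending in org.excluded:
        con.execute("INSERT INTO proteins_excluded VALUES (?,?,?,?,?,?)",
                    (rec.accession, s.organism, rec.name, rec.source_db,
                     rec.length, "".join(sorted(offending))))
        con.execute("INSERT INTO pe_status VALUES (?,?,?,0)",
                    (rec.accession, s.organism, rec.pe_qualifier or 0))

    for prot in org.included:
        rec = prot.record
        con.execute("INSERT INTO proteins_included VALUES (?,?,?,?,?,?)",
                    (rec.accession, s.organism, rec.name, rec.source_db,
                     rec.length, rec.sequence))
        con.execute("INSERT INTO pe_status VALUES (?,?,?,1)",
                    (rec.accession, s.organism, rec.pe_qualifier or 0))
        ann = prot.annotations
        con.executemany(
            "INSERT INTO disorder_data VALUES (?,?,?,?,?,?,?,?,?)",
            zip([rec.accession] * len(ann),
                ann["position"].tolist(), ann["residue"].tolist(),
                ann["score_I"].tolist(), ann["score_C"].tolist(),
                ann["score_H"].tolist(), ann["score_R"].tolist(),
                ann["dcc"].tolist(), ann["agreement_id"].tolist()))
        pd_ = prot.percent_disorder
        con.execute("INSERT INTO percent_disorder VALUES (?,?,?,?,?,?)",
                    (rec.accession, pd_.get("I"), pd_.get("C"), pd_.get("H"),
                     pd_.get("R"), pd_.get("consensus")))
        if prot.cd.has_cd:
            _insert_cd(con, rec.accession, prot.cd)
        _insert_params(con, rec.accession, prot.params)


def _insert_cd(con: sqlite3.Connection, accession: str, cd: CDSummary) -> None:
    for method_id, table in CD_TABLE_BY_METHOD.items():
        m = cd.methods.get(method_id)
        if m is None:
            continue
        if m.regions:
            for i, region in enumerate(m.regions, start=1):
                con.execute(
                    f"INSERT INTO {table} VALUES (?,?,?,?,?,?,?,?)",
                    (accession, i, region.start, region.end, region.length,
                     m.n_regions, m.cd_l, m.lcpl))
        else:
            con.execute(f"INSERT INTO {table} VALUES (?,0,?,?,?,0,?,?)",
                        (accession, NA_SENTINEL, NA_SENTINEL, NA_SENTINEL,
                         NA_SENTINEL, NA_SENTINEL))


def _insert_params(con: sqlite3.Connection, accession: str,
                   p: SequenceParameters) -> None:
    k = UNDEFINED_KAPPA if p.kappa is None else p.kappa
    d = UNDEFINED_KAPPA if p.delta is None else p.delta
    dm = UNDEFINED_KAPPA if p.delta_max is None else p.delta_max
    con.execute(
        "INSERT INTO sequence_parameters VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
        (accession, p.f_disorder_promoting, p.mean_hydropathy,
         p.uversky_hydropathy, p.fcr, p.ncpr, k, d, dm,
         p.proline_content, int(p.kappa_warning),
         p.n_positive, p.n_negative, p.n_neutral))


def summarize_pe(records: list[ProteinRecord]) -> pd.DataFrame:
    """Fractions of records per protein-existence qualifier (0 = no tag).

    Fractions sum to 1 for non-empty input; empty input yields an empty
    table.
    """
    if not records:
        return pd.DataFrame(columns=["pe_qualifier", "count", "fraction"])
    quals = pd.Series([r.pe_qualifier or 0 for r in records])
    counts = quals.value_counts().sort_index()
    return pd.DataFrame({"pe_qualifier": counts.index,
                         "count": counts.values,
                         "fraction": counts.values / len(records)})


def _connect_ro(path: str) -> sqlite3.Connection:
    if not os.path.exists(path):
        raise DatabaseFormatError(f"no such file: {path}")
    con = sqlite3.connect(path)
    try:
        con.execute("SELECT name FROM sqlite_master").fetchall()
    except sqlite3.DatabaseError as exc:
        con.close()
        raise DatabaseFormatError(f"{path} is not an SQLite database: {exc}") from exc
    return con


def verify_database(path: str, sample_proteins: int = 50) -> ValidationReport:
    """Structural and semantic validation of a written database file.

    Checks the twelve-table schema, primary-key uniqueness, residue-count
    conservation between ``proteins_included``/``organisms`` and
    ``disorder_data``, the PE qualifier domain, referential integrity of
    accessions, and -- on up to *sample_proteins* proteins -- that DCC and
    agreement IDs re-derived from the stored scores and thresholds
    reproduce the stored values exactly.
    """
    report = ValidationReport()
    con = _connect_ro(path)
    try:
        names = {r[0] for r in con.execute(
            "SELECT name FROM sqlite_master WHERE type='table'")}
        if names != set(TABLE_NAMES):
            report.violations.append(
                f"table set mismatch: expected {len(TABLE_NAMES)} tables, "
                f"found {len(names)}; missing={sorted(set(TABLE_NAMES) - names)}, "
                f"unexpected={sorted(names - set(TABLE_NAMES))}")
            return report

        for check in (_check_keys, _check_conservation, _check_pe_domain,
                      _check_referential):
            try:
                check(con, report)
            except sqlite3.OperationalError as exc:
                report.violations.append(f"malformed table shape: {exc}")
        try:
            _check_rederivation(con, report, sample_proteins)
        except sqlite3.OperationalError as exc:
            report.violations.append(f"malformed table shape: {exc}")
    finally:
        con.close()
    return report


_PRIMARY_KEYS = {
    "organisms": ("organism",),
    "proteins_included": ("accession",),
    "proteins_excluded": ("accession",),
    "pe_status": ("accession",),
    "disorder_data": ("accession", "position"),
    "percent_disorder": ("accession",),
    "sequence_parameters": ("accession",),
    **{t: ("accession", "region_index") for t in CD_TABLE_BY_METHOD.values()},
}


def _check_keys(con: sqlite3.Connection, report: ValidationReport) -> None:
    for table, key in _PRIMARY_KEYS.items():
        cols = ", ".join(key)
        try:
            dup = con.execute(
                f"SELECT {cols}, COUNT(*) c FROM {table} GROUP BY {cols} HAVING c > 1"
            ).fetchall()
        except sqlite3.OperationalError as exc:
            report.violations.append(f"{table}: malformed table shape: {exc}")
            continue
        if dup:
            report.violations.append(
                f"{table}: {len(dup)} duplicated key value(s), e.g. {dup[0][:-1]}")


def _check_conservation(con: sqlite3.Connection, report: ValidationReport) -> None:
    rows = con.execute(
        "SELECT p.accession, p.length, COUNT(d.position) "
        "FROM proteins_included p LEFT JOIN disorder_data d "
        "ON p.accession = d.accession GROUP BY p.accession").fetchall()
    for acc, length, n_rows in rows:
        if length != n_rows:
            report.violations.append(
                f"disorder_data: {acc} has {n_rows} rows for length {length}")
    total = con.execute("SELECT COUNT(*) FROM disorder_data").fetchone()[0]
    declared = con.execute(
        "SELECT SUM(n_annotated_residues) FROM organisms").fetchone()[0] or 0
    if total != declared:
        report.violations.append(
            f"organisms declares {declared} annotated residues, "
            f"disorder_data holds {total}")


def _check_pe_domain(con: sqlite3.Connection, report: ValidationReport) -> None:
    bad = con.execute(
        "SELECT accession, pe_qualifier FROM pe_status "
        "WHERE pe_qualifier NOT IN (0,1,2,3,4,5)").fetchall()
    if bad:
        report.violations.append(f"pe_status: qualifiers outside 0-5: {bad[:5]}")


def _check_referential(con: sqlite3.Connection, report: ValidationReport) -> None:
    known = {r[0] for r in con.execute(
        "SELECT accession FROM proteins_included "
        "UNION SELECT accession FROM proteins_excluded")}
    tables = ["pe_status", "disorder_data", "percent_disorder",
              "sequence_parameters", *CD_TABLE_BY_METHOD.values()]
    for table in tables:
        accs = {r[0] for r in con.execute(f"SELECT DISTINCT accession FROM {table}")}
        orphans = accs - known
        if orphans:
            report.violations.append(
                f"{table}: accessions absent from protein lists: {sorted(orphans)[:5]}")


def _check_rederivation(con: sqlite3.Connection, report: ValidationReport,
                        sample_proteins: int) -> None:
    thr_row = con.execute(
        "SELECT threshold_I, threshold_C, threshold_H, threshold_R "
        "FROM organisms LIMIT 1").fetchone()
    if thr_row is None or any(t is None for t in thr_row):
        return  # no thresholds recorded; nothing to re-derive against
    thresholds = dict(zip(METHOD_IDS, thr_row))
    accs = [r[0] for r in con.execute(
        "SELECT accession FROM proteins_included ORDER BY accession "
        "LIMIT ?", (sample_proteins,))]
    for acc in accs:
        rows = con.execute(
            "SELECT score_I, score_C, score_H, score_R, dcc, agreement_id "
            "FROM disorder_data WHERE accession = ? ORDER BY position",
            (acc,)).fetchall()
        for i, (sI, sC, sH, sR, dcc, agr) in enumerate(rows, start=1):
            calls = tuple(s >= thresholds[m]
                          for m, s in zip(METHOD_IDS, (sI, sC, sH, sR)))
            if sum(calls) != dcc or agreement_id(calls) != agr:
                report.violations.append(
                    f"disorder_data: {acc} position {i}: stored "
                    f"dcc={dcc}/{agr!r} disagrees with scores re-derivation")
                break


def export_tables_tsv(path: str, out_dir: str) -> list[str]:
    """Export every table as a TSV file named after it; returns the paths."""
    con = _connect_ro(path)
    os.makedirs(out_dir, exist_ok=True)
    written = []
    try:
        for table in TABLE_NAMES:
            frame = pd.read_sql_query(
                f"SELECT * FROM {table}", con)
            out = os.path.join(out_dir, f"{table}.tsv")
            frame.to_csv(out, sep="\t", index=False)
            written.append(out)
    finally:
        con.close()
    return written
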