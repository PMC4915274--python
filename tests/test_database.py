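import sqlite3

import pytest

from disorderdb import (ProteinRecord, TABLE_NAMES, export_tables_tsv,
                        summarize_pe, verify_database)
from disorderdb.database import CD_TABLE_BY_METHOD, NA_SENTINEL
from disorderdb.errors import DatabaseFormatError, DatabaseIntegrityError


class TestWriteAndVerify:
    def test_written_database_has_zero_violations(self, pipeline_db):
        path, _ = pipeline_db
        report = verify_database(path)
        assert report.ok, report.violations

    def test_exactly_twelve_tables(self, pipeline_db):
        path, _ = pipeline_db
        con = sqlite3.connect(path)
        names = {r[0] for r in con.execute(
            "SELECT name FROM sqlite_master WHERE type='table'")}
        con.close()
        assert names == set(TABLE_NAMES)
        assert len(TABLE_NAMES) == 12

    def test_residue_row_conservation(self, pipeline_db):
        path, report = pipeline_db
        con = sqlite3.connect(path)
        total = con.execute("SELECT COUNT(*) FROM disorder_data").fetchone()[0]
        lengths = con.execute(
            "SELECT SUM(length) FROM proteins_included").fetchone()[0]
        con.close()
        assert total == lengths == report.total_annotated_residues

    def test_excluded_proteins_only_in_exclusion_and_pe_tables(self, pipeline_db):
        path, _ = pipeline_db
        con = sqlite3.connect(path)
        excluded = {r[0] for r in con.execute(
            "SELECT accession FROM proteins_excluded")}
        assert excluded  # the fixture proteome has ineligible sequences
        for table in ("disorder_data", "percent_disorder", "sequence_parameters",
                      *CD_TABLE_BY_METHOD.values()):
            accs = {r[0] for r in con.execute(
                f"SELECT DISTINCT accession FROM {table}")}
            assert not (accs & excluded), table
        pe_included = {r[0]: r[1] for r in con.execute(
            "SELECT accession, included FROM pe_status")}
        assert all(pe_included[a] == 0 for a in excluded)
        con.close()

    def test_na_sentinel_rows_for_doubting_methods(self, pipeline_db):
        path, _ = pipeline_db
        con = sqlite3.connect(path)
        # every CD-exhibiting protein appears in all five CD tables, either
        # with regions or with an explicit sentinel row
        accs = {}
        for table in CD_TABLE_BY_METHOD.values():
            accs[table] = {r[0] for r in con.execute(
                f"SELECT DISTINCT accession FROM {table}")}
        union = set().union(*accs.values())
        for table, table_accs in accs.items():
            assert table_accs == union, table
        sentinel_rows = con.execute(
            "SELECT start, end, length, cd_l, lcpl FROM cd_regions_consensus "
            "WHERE region_index = 0").fetchall()
        for row in sentinel_rows:
            assert set(row) == {NA_SENTINEL}
        con.close()

    def test_refuses_existing_file_without_overwrite(self, pipeline_db, tmp_path):
        from disorderdb.database import write_database
        path, _ = pipeline_db
        with pytest.raises(DatabaseIntegrityError):
            write_database([], path, overwrite=False)

    def test_foreign_file_is_format_error(self, tmp_path):
        bogus = tmp_path / "not_a_db.sqlite"
        bogus.write_text("this is not a database")
        with pytest.raises(DatabaseFormatError):
            verify_database(str(bogus))

    def test_missing_table_flagged(self, pipeline_db, tmp_path):
        path, _ = pipeline_db
        clone = tmp_path / "eleven.db"
        clone.write_bytes(open(path, "rb").read())
        con = sqlite3.connect(clone)
        con.execute("DROP TABLE sequence_parameters")
        con.commit()
        con.close()
        report = verify_database(str(clone))
        assert any("table set mismatch" in v for v in report.violations)

    def test_duplicated_key_flagged(self, tmp_path):
        # a look-alike file whose disorder_data lacks the key constraint
        path = tmp_path / "dup.db"
        con = sqlite3.connect(path)
        for name in TABLE_NAMES:
            if name == "disorder_data":
                con.execute("CREATE TABLE disorder_data (accession TEXT, "
                            "position INTEGER, residue TEXT, score_I REAL, "
                            "score_C REAL, score_H REAL, score_R REAL, "
                            "dcc INTEGER, agreement_id TEXT)")
            else:
                con.execute(f"CREATE TABLE {name} (accession TEXT)")
        row = ("P1", 1, "M", 0.1, 0.1, 0.1, 0.1, 0, "O")
        con.execute("INSERT INTO disorder_data VALUES (?,?,?,?,?,?,?,?,?)", row)
        con.execute("INSERT INTO disorder_data VALUES (?,?,?,?,?,?,?,?,?)", row)
        con.commit()
        con.close()
        report = verify_database(str(path))
        assert any("duplicated key" in v for v in report.violations)

    def test_tampered_dcc_detected_by_rederivation(self, pipeline_db, tmp_path):
        path, _ = pipeline_db
        clone = tmp_path / "tampered.db"
        clone.write_bytes(open(path, "rb").read())
        con = sqlite3.connect(clone)
        acc = con.execute("SELECT accession FROM proteins_included "
                          "ORDER BY accession LIMIT 1").fetchone()[0]
        con.execute("UPDATE disorder_data SET dcc = (dcc + 1) % 5 "
                    "WHERE accession = ? AND position = 1", (acc,))
        con.commit()
        con.close()
        report = verify_database(str(clone))
        assert any("re-derivation" in v for v in report.violations)


class TestSummarizePe:
    def _rec(self, pe, acc):
        return ProteinRecord(accession=acc, source_db="swissprot", name="x",
                             pe_qualifier=pe, sequence="MKV")

    def test_single_level(self):
        table = summarize_pe([self._rec(1, f"P{i}") for i in range(10)])
        assert table.loc[table.pe_qualifier == 1, "fraction"].item() == 1.0

    def test_mixture_fractions(self):
        recs = [self._rec(1, f"A{i}") for i in range(7)] + \
               [self._rec(5, f"B{i}") for i in range(3)]
        table = summarize_pe(recs)
        assert table.loc[table.pe_qualifier == 5, "fraction"].item() == pytest.approx(0.3)
        assert table["fraction"].sum() == pytest.approx(1.0)

    def test_missing_pe_counted_as_zero(self):
        table = summarize_pe([self._rec(None, "P1")])
        assert table.pe_qualifier.tolist() == [0]

    def test_empty_input(self):
        assert summarize_pe([]).empty


class TestTsvExport:
    def test_deterministic_byte_identical_exports(self, pipeline_db, tmp_path):
        path, _ = pipeline_db
        dir_a, dir_b = tmp_path / "a", tmp_path / "b"
        files_a = export_tables_tsv(path, str(dir_a))
        files_b = export_tables_tsv(path, str(dir_b))
        assert len(files_a) == len(TABLE_NAMES)
        for fa, fb in zip(files_a, files_b):
            assert open(fa, "rb").read() == open(fb, "rb").read()
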