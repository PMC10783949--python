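"""Dump parsing, sequence providers and multi-FASTA compilation."""

import random

import pytest

import ptmconserve as pc
from ptmconserve.preprocess import ConfigurationError

CATALOG = pc.ModificationCatalog.default()

CPLM_HEADER = "source_id\taccession\tposition\tmod_type\tspecies\tsequence\tevidence\tprotein_name"
DBPTM_HEADER = "accession\tposition\tmod_type\tspecies\tevidence\tprotein_name"


def cplm_row(source_id="C1", accession="P1", position=2, mod_type="acetylation",
             species="sp", sequence="MKVLL", evidence="PMID:1", name="prot"):
    return "\t".join((source_id, accession, str(position), mod_type, species,
                      sequence, evidence, name))


class TestParseCplm:
    def test_single_valid_row(self, tmp_path):
        dump = tmp_path / "cplm.tsv"
        dump.write_text(CPLM_HEADER + "\n" + cplm_row() + "\n")
        report = pc.CompilationReport()
        records = list(pc.parse_cplm_dump(dump, CATALOG, report=report))
        assert len(records) == 1
        assert records[0].accession == "P1" and records[0].site_residue == "K"
        assert report.counts["CPLM"].read == 1 and report.counts["CPLM"].skipped == 0

    def test_out_of_range_position_skipped(self, tmp_path):
        dump = tmp_path / "cplm.tsv"
        dump.write_text(CPLM_HEADER + "\n" + cplm_row(position=10, sequence="MKVLL") + "\n")
        report = pc.CompilationReport()
        assert list(pc.parse_cplm_dump(dump, CATALOG, report=report)) == []
        assert report.counts["CPLM"].skipped == 1
        assert report.balances()

    def test_planted_defects_are_counted(self, tmp_path):
        rng = random.Random(5)
        rows, defects = [], 0
        for i in range(100):
            if i % 15 == 3:  # 7 defective rows among 100
                defects += 1
                kind = rng.choice(["range", "residue", "modtype"])
                if kind == "range":
                    rows.append(cplm_row(source_id=f"C{i}", accession=f"P{i}", position=99))
                elif kind == "residue":
                    rows.append(cplm_row(source_id=f"C{i}", accession=f"P{i}", position=1))
                else:
                    rows.append(cplm_row(source_id=f"C{i}", accession=f"P{i}",
                                         mod_type="no-such-mod"))
            else:
                rows.append(cplm_row(source_id=f"C{i}", accession=f"P{i}"))
        dump = tmp_path / "cplm.tsv"
        dump.write_text(CPLM_HEADER + "\n" + "\n".join(rows) + "\n")
        report = pc.CompilationReport()
        written = list(pc.parse_cplm_dump(dump, CATALOG, report=report))
        assert defects == 7
        assert len(written) == 93
        counts = report.counts["CPLM"]
        # written is tallied at compile time; at parse level the yielded
        # records play that role in the balance
        assert (counts.read, len(written) + counts.skipped) == (100, 100)

    def test_missing_column_is_configuration_error(self, tmp_path):
        dump = tmp_path / "cplm.tsv"
        dump.write_text("accession\tposition\nP1\t2\n")
        with pytest.raises(ConfigurationError):
            list(pc.parse_cplm_dump(dump, CATALOG))

    def test_column_map_override(self, tmp_path):
        dump = tmp_path / "cplm.tsv"
        dump.write_text(
            "id\tacc\tpos\ttype\tsp\tseq\tev\tname\n"
            "C1\tP1\t2\tacetylation\tsp\tMKVLL\tPMID:1\tprot\n"
        )
        column_map = {"source_id": "id", "accession": "acc", "position": "pos",
                      "mod_type": "type", "species": "sp", "sequence": "seq",
                      "evidence": "ev", "protein_name": "name"}
        records = list(pc.parse_cplm_dump(dump, CATALOG, column_map=column_map))
        assert len(records) == 1 and records[0].sequence == "MKVLL"


class TestParseDbptm:
    provider = pc.InMemoryProvider({
        "P1": pc.ProviderResult("MKVLL", "prot one", "sp1"),
        "P2": pc.ProviderResult("MAKAA", "prot two", "sp2"),
    })

    def dump(self, tmp_path, rows):
        path = tmp_path / "dbptm.tsv"
        path.write_text(DBPTM_HEADER + "\n" + "\n".join(rows) + "\n")
        return path

    def test_sequence_comes_from_provider(self, tmp_path):
        path = self.dump(tmp_path, ["P1\t2\tacetylation\t\tPMID:9\t"])
        records = list(pc.parse_dbptm_dump(path, self.provider, CATALOG))
        assert records[0].sequence == "MKVLL"
        assert records[0].protein_name == "prot one"
        assert records[0].source == "dbPTM"

    def test_unresolvable_accession_skipped_as_obsolete(self, tmp_path):
        path = self.dump(tmp_path, ["GONE\t2\tacetylation\t\t\t"])
        report = pc.CompilationReport()
        assert list(pc.parse_dbptm_dump(path, self.provider, CATALOG, report=report)) == []
        assert report.counts["dbPTM"].skip_reasons["obsolete"] == 1

    def test_bulk_with_unresolvable_subset(self, tmp_path):
        rows = [f"P{1 + i % 2}\t{2 + i % 2}\tacetylation\t\t\t" for i in range(45)]
        rows += ["GONE\t1\tacetylation\t\t\t"] * 5
        path = self.dump(tmp_path, rows)
        report = pc.CompilationReport()
        written = list(pc.parse_dbptm_dump(path, self.provider, CATALOG, report=report))
        assert len(written) == 45
        assert report.counts["dbPTM"].read == 50
        assert report.counts["dbPTM"].skipped == 5


class TestDirectoryProvider:
    def test_resolves_fasta_with_species_tag(self, tmp_path):
        (tmp_path / "P9.fasta").write_text(">P9 some protein OS=Escherichia coli\nMKVLL\n")
        result = pc.DirectoryProvider(tmp_path).resolve("P9")
        assert result.sequence == "MKVLL"
        assert result.protein_name == "some protein"
        assert result.species == "Escherichia coli"

    def test_missing_accession_raises_not_found(self, tmp_path):
        with pytest.raises(pc.AccessionNotFoundError):
            pc.DirectoryProvider(tmp_path).resolve("NOPE")


class TestCompilation:
    def records(self):
        recs = []
        for i, mod in enumerate(["acetylation"] * 3 + ["succinylation"] * 2):
            seq = "MAKAA"
            recs.append(pc.PTMSiteRecord(
                accession=f"P{i}", position=3, mod_type=mod, source="CPLM",
                source_id=f"C{i}", sequence=seq, length=len(seq),
                evidence=("PMID:1",),
            ))
        return recs

    def test_single_type_selection(self, tmp_path):
        out = tmp_path / "acetylation.fasta"
        report = pc.compile_modification_fasta(self.records(), "acetylation", out, CATALOG)
        entries = pc.read_database(out)
        assert len(entries) == 3
        assert report.balances()
        assert report.counts["CPLM"].skip_reasons["other mod_type"] == 2

    def test_two_sites_same_protein_two_entries(self, tmp_path):
        seq = "MAKAAKA"
        records = [
            pc.PTMSiteRecord(accession="P1", position=p, mod_type="acetylation",
                             source="CPLM", source_id=f"C{p}", sequence=seq,
                             length=len(seq), evidence=())
            for p in (3, 6)
        ]
        out = tmp_path / "db.fasta"
        pc.compile_modification_fasta(records, "acetylation", out, CATALOG)
        entries = pc.read_database(out)
        assert [e.position for e in entries] == [3, 6]
        assert entries[0].sequence == entries[1].sequence == seq

    def test_empty_stream(self, tmp_path):
        out = tmp_path / "empty.fasta"
        report = pc.compile_modification_fasta([], "acetylation", out, CATALOG)
        assert out.read_text() == ""
        assert report.counts == {} or report.balances()

    def test_every_entry_decodes(self, tmp_path):
        out = tmp_path / "db.fasta"
        pc.compile_modification_fasta(self.records(), "acetylation", out, CATALOG)
        for record in pc.read_database(out):
            pc.validate_record(record, CATALOG)

    def test_idempotent_byte_identical(self, tmp_path):
        out1, out2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        pc.compile_modification_fasta(self.records(), "acetylation", out1, CATALOG)
        pc.compile_modification_fasta(self.records(), "acetylation", out2, CATALOG)
        assert out1.read_bytes() == out2.read_bytes()

    def test_wrapped_at_60_columns(self, tmp_path):
        seq = "MAK" + "A" * 150
        record = pc.PTMSiteRecord(
            accession="P1", position=3, mod_type="acetylation", source="CPLM",
            source_id="C1", sequence=seq, length=len(seq), evidence=(),
        )
        out = tmp_path / "db.fasta"
        pc.compile_modification_fasta([record], "acetylation", out, CATALOG)
        body_lines = [l for l in out.read_text().splitlines() if not l.startswith(">")]
        assert max(len(l) for l in body_lines) == 60

    def test_sources_coexist_and_order_deterministic(self, tmp_path):
        seq = "MAKAA"
        records = [
            pc.PTMSiteRecord(accession="B1", position=3, mod_type="acetylation",
                             source="dbPTM", sequence=seq, length=5, evidence=()),
            pc.PTMSiteRecord(accession="A1", position=3, mod_type="acetylation",
                             source="CPLM", source_id="C9", sequence=seq, length=5,
                             evidence=()),
        ]
        out = tmp_path / "db.fasta"
        pc.compile_modification_fasta(records, "acetylation", out, CATALOG)
        entries = pc.read_database(out)
        assert [e.source for e in entries] == ["CPLM", "dbPTM"]
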