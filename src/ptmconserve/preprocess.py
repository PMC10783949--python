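"""Parse CPLM-style and dbPTM-style database dumps into PTM-site records and
compile them into one annotated multi-FASTA per modification type.

Dumps are delimited text with one row per modification site.  CPLM-style rows
carry the protein sequence inline; dbPTM-style rows do not, so the sequence is
resolved through a pluggable :class:`SequenceProvider` (a directory of FASTA
files or an in-memory map — both deterministic and offline).  Rows that fail a
record invariant, reference an unknown modification type, or point at an
accession the provider cannot resolve are skipped and counted, never fatal:
compilation always finishes and its :class:`CompilationReport` balances
(read == written + skipped per source).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Protocol

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ptm_records import (
    ModificationCatalog,
    PTMSiteRecord,
    ValidationError,
    encode_header,
    normalize_mod_type,
    validate_record,
)

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """A column map names a column absent from the dump."""


class AccessionNotFoundError(KeyError):
    """The provider reports the accession unknown or obsolete (permanent)."""


class ProviderTransportError(RuntimeError):
    """The provider failed transiently (retryable), as opposed to obsolete."""


# ---------------------------------------------------------------------------
# Sequence providers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProviderResult:
    sequence: str
    protein_name: str = ""
    species: str = ""


class SequenceProvider(Protocol):
    """Resolve an accession to its sequence and protein metadata.

    Must be deterministic within one run; raises
    :class:`AccessionNotFoundError` for obsolete/unknown accessions and
    :class:`ProviderTransportError` for transient failures.
    """

    def resolve(self, accession: str) -> ProviderResult: ...


class InMemoryProvider:
    """Provider backed by a dict, for tests and programmatic use."""

    def __init__(self, entries: Mapping[str, ProviderResult | str]):
        self._entries = {
            acc: entry if isinstance(entry, ProviderResult) else ProviderResult(entry)
            for acc, entry in entries.items()
        }

    def resolve(self, accession: str) -> ProviderResult:
        try:
            return self._entries[accession]
        except KeyError:
            raise AccessionNotFoundError(accession)


class DirectoryProvider:
    """Provider backed by a directory of single-entry FASTA files.

    ``<directory>/<accession>.fasta`` holds the protein; the description line
    supplies the protein name, with an optional UniProt-style ``OS=`` tag for
    the species.
    """

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)

    def resolve(self, accession: str) -> ProviderResult:
        path = self.directory / f"{accession}.fasta"
        if not path.is_file():
            raise AccessionNotFoundError(accession)
        try:
            record = next(SeqIO.parse(str(path), "fasta"))
        except (OSError, StopIteration) as exc:
            raise ProviderTransportError(f"unreadable provider entry {path}") from exc
        description = record.description
        if description.startswith(record.id):
            description = description[len(record.id):].strip()
        species = ""
        if " OS=" in f" {description} ":
            description, _, os_tail = description.partition("OS=")
            species = os_tail.split(" OX=")[0].split(" GN=")[0].strip()
            description = description.strip()
        return ProviderResult(
            sequence=str(record.seq).upper(),
            protein_name=description,
            species=species,
        )


# ---------------------------------------------------------------------------
# Compilation report
# ---------------------------------------------------------------------------

@dataclass
class SourceCounts:
    read: int = 0
    written: int = 0
    skipped: int = 0
    skip_reasons: Counter = field(default_factory=Counter)

    def balances(self) -> bool:
        return self.read == self.written + self.skipped


@dataclass
class CompilationReport:
    """Per-source tally of records read, written, and skipped (with reason)."""

    counts: dict[str, SourceCounts] = field(default_factory=dict)
    skipped_rows: list[tuple[str, int, str]] = field(default_factory=list)

    def source(self, name: str) -> SourceCounts:
        return self.counts.setdefault(name, SourceCounts())

    def record_read(self, source: str) -> None:
        self.source(source).read += 1

    def record_written(self, source: str) -> None:
        self.source(source).written += 1

    def record_skip(self, source: str, row: int, reason: str) -> None:
        counts = self.source(source)
        counts.skipped += 1
        counts.skip_reasons[reason] += 1
        self.skipped_rows.append((source, row, reason))
        logger.warning("%s row %d skipped: %s", source, row, reason)

    def balances(self) -> bool:
        return all(c.balances() for c in self.counts.values())

    def summary(self) -> str:
        lines = []
        for source in sorted(self.counts):
            c = self.counts[source]
            reasons = ", ".join(f"{r}={n}" for r, n in sorted(c.skip_reasons.items()))
            lines.append(
                f"{source}: read={c.read} written={c.written} skipped={c.skipped}"
                + (f" ({reasons})" if reasons else "")
            )
        return "\n".join(lines) if lines else "no records processed"


# ---------------------------------------------------------------------------
# Dump parsing
# ---------------------------------------------------------------------------

#: Default column names for CPLM-style dumps (sequence included inline).
CPLM_COLUMNS: dict[str, str] = {
    "source_id": "source_id",
    "accession": "accession",
    "position": "position",
    "mod_type": "mod_type",
    "species": "species",
    "sequence": "sequence",
    "evidence": "evidence",
    "protein_name": "protein_name",
}

#: Default column names for dbPTM-style dumps (no sequence column).
DBPTM_COLUMNS: dict[str, str] = {
    "accession": "accession",
    "position": "position",
    "mod_type": "mod_type",
    "species": "species",
    "evidence": "evidence",
    "protein_name": "protein_name",
}

_OPTIONAL_COLUMNS = {"species", "evidence", "protein_name", "source_id"}


def _read_rows(path: str | Path, delimiter: str) -> tuple[list[str], Iterator[tuple[int, dict[str, str]]]]:
    import csv

    handle = open(path, newline="")
    reader = csv.DictReader(handle, delimiter=delimiter)
    if reader.fieldnames is None:
        handle.close()
        raise ConfigurationError(f"{path}: empty dump, no header row")

    def rows() -> Iterator[tuple[int, dict[str, str]]]:
        with handle:
            # row numbers are 1-based over data rows (header excluded)
            for number, row in enumerate(reader, 1):
                yield number, row

    return list(reader.fieldnames), rows()


def _check_columns(
    fieldnames: list[str], column_map: Mapping[str, str], path: str | Path
) -> None:
    missing = [
        column
        for key, column in column_map.items()
        if column not in fieldnames and key not in _OPTIONAL_COLUMNS
    ]
    if missing:
        raise ConfigurationError(
            f"{path}: required column(s) {missing} not in header {fieldnames}"
        )


def _evidence(cell: str) -> tuple[str, ...]:
    return tuple(e.strip() for e in cell.split(";") if e.strip())


def parse_cplm_dump(
    path: str | Path,
    catalog: ModificationCatalog | None = None,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = "\t",
    report: CompilationReport | None = None,
) -> Iterator[PTMSiteRecord]:
    """Stream records from a CPLM-style dump (one site per row, sequence inline).

    Rows violating record invariants are skipped and counted in ``report``;
    a missing required column raises :class:`ConfigurationError` before any
    row is processed.
    """
    catalog = catalog or ModificationCatalog.default()
    columns = dict(CPLM_COLUMNS, **(column_map or {}))
    report = report if report is not None else CompilationReport()
    fieldnames, rows = _read_rows(path, delimiter)
    _check_columns(fieldnames, columns, path)

    def get(row: dict[str, str], key: str) -> str:
        return (row.get(columns[key]) or "").strip()

    for row_number, row in rows:
        report.record_read("CPLM")
        try:
            sequence = get(row, "sequence").upper()
            record = PTMSiteRecord(
                accession=get(row, "accession"),
                position=int(get(row, "position")),
                mod_type=normalize_mod_type(get(row, "mod_type")),
                source="CPLM",
                source_id=get(row, "source_id"),
                protein_name=get(row, "protein_name"),
                species=get(row, "species"),
                sequence=sequence,
                length=len(sequence),
                evidence=_evidence(get(row, "evidence")),
            )
            validate_record(record, catalog)
        except ValidationError as exc:
            report.record_skip("CPLM", row_number, f"invalid {exc.field}")
            continue
        except ValueError:
            report.record_skip("CPLM", row_number, "invalid position")
            continue
        yield record


def parse_dbptm_dump(
    path: str | Path,
    provider: SequenceProvider,
    catalog: ModificationCatalog | None = None,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = "\t",
    report: CompilationReport | None = None,
) -> Iterator[PTMSiteRecord]:
    """Stream records from a dbPTM-style dump, resolving sequences through
    ``provider``.

    Rows whose accession the provider reports unknown/obsolete are skipped
    with reason ``obsolete``; transient provider failures propagate as
    :class:`ProviderTransportError` so callers can retry.
    """
    catalog = catalog or ModificationCatalog.default()
    columns = dict(DBPTM_COLUMNS, **(column_map or {}))
    report = report if report is not None else CompilationReport()
    fieldnames, rows = _read_rows(path, delimiter)
    _check_columns(fieldnames, columns, path)

    def get(row: dict[str, str], key: str) -> str:
        return (row.get(columns[key]) or "").strip()

    for row_number, row in rows:
        report.record_read("dbPTM")
        accession = get(row, "accession")
        try:
            resolved = provider.resolve(accession)
        except AccessionNotFoundError:
            report.record_skip("dbPTM", row_number, "obsolete")
            continue
        try:
            record = PTMSiteRecord(
                accession=accession,
                position=int(get(row, "position")),
                mod_type=normalize_mod_type(get(row, "mod_type")),
                source="dbPTM",
                source_id="",
                protein_name=get(row, "protein_name") or resolved.protein_name,
                species=get(row, "species") or resolved.species,
                sequence=resolved.sequence,
                length=len(resolved.sequence),
                evidence=_evidence(get(row, "evidence")),
            )
            validate_record(record, catalog)
        except ValidationError as exc:
            report.record_skip("dbPTM", row_number, f"invalid {exc.field}")
            continue
        except ValueError:
            report.record_skip("dbPTM", row_number, "invalid position")
            continue
        yield record


# ---------------------------------------------------------------------------
# Multi-FASTA compilation
# ---------------------------------------------------------------------------

def _sort_key(record: PTMSiteRecord) -> tuple:
    return (record.source, record.source_id or record.accession, record.accession,
            record.position)


def _to_seqrecord(record: PTMSiteRecord, catalog: ModificationCatalog) -> SeqRecord:
    header = encode_header(record, catalog)
    id_block, _, description = header.partition(" ")
    return SeqRecord(Seq(record.sequence), id=id_block, description=description)


def compile_modification_fasta(
    records: Iterable[PTMSiteRecord],
    mod_type: str,
    out: str | Path,
    catalog: ModificationCatalog | None = None,
    report: CompilationReport | None = None,
) -> CompilationReport:
    """Write one annotated FASTA entry per record of ``mod_type`` to ``out``.

    One entry per modification *site*: the same protein with two sites yields
    two entries with identical sequence and different headers.  Entries from
    both sources coexist in one file, in deterministic order (source, then
    source id/accession, then position), so compilation is idempotent.
    """
    catalog = catalog or ModificationCatalog.default()
    report = report if report is not None else CompilationReport()
    wanted = catalog.resolve(mod_type)
    selected: list[PTMSiteRecord] = []
    for number, record in enumerate(records, 1):
        report.record_read(record.source)
        if catalog.resolve(record.mod_type) == wanted:
            selected.append(record)
        else:
            report.record_skip(record.source, number, "other mod_type")
    selected.sort(key=_sort_key)
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w") as handle:
        SeqIO.write(
            (_to_seqrecord(r, catalog) for r in selected), handle, "fasta"
        )
    for record in selected:
        report.record_written(record.source)
    return report


def compile_databases(
    records: Iterable[PTMSiteRecord],
    out_dir: str | Path,
    catalog: ModificationCatalog | None = None,
    report: CompilationReport | None = None,
) -> tuple[dict[str, Path], CompilationReport]:
    """Write one annotated multi-FASTA per modification type present in
    ``records`` (``<out_dir>/<mod_type>.fasta``); every record is written
    exactly once."""
    catalog = catalog or ModificationCatalog.default()
    report = report if report is not None else CompilationReport()
    by_type: dict[str, list[PTMSiteRecord]] = {}
    for record in records:
        report.record_read(record.source)
        by_type.setdefault(catalog.resolve(record.mod_type), []).append(record)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for mod_type in sorted(by_type):
        group = sorted(by_type[mod_type], key=_sort_key)
        path = out_dir / f"{mod_type}.fasta"
        with open(path, "w") as handle:
            SeqIO.write((_to_seqrecord(r, catalog) for r in group), handle, "fasta")
        for record in group:
            report.record_written(record.source)
        paths[mod_type] = path
    return paths, report


def build_databases(
    out_dir: str | Path,
    cplm_dump: str | Path | None = None,
    dbptm_dump: str | Path | None = None,
    provider: SequenceProvider | None = None,
    catalog: ModificationCatalog | None = None,
    delimiter: str = "\t",
) -> tuple[dict[str, Path], CompilationReport]:
    """End-to-end compilation: parse the given dumps and write one database
    per modification type, returning paths and a balanced report."""
    catalog = catalog or ModificationCatalog.default()
    report = CompilationReport()

    def stream() -> Iterator[PTMSiteRecord]:
        if cplm_dump is not None:
            yield from parse_cplm_dump(
                cplm_dump, catalog, delimiter=delimiter, report=report
            )
        if dbptm_dump is not None:
            if provider is None:
                raise ConfigurationError("a sequence provider is required for dbPTM dumps")
            yield from parse_dbptm_dump(
                dbptm_dump, provider, catalog, delimiter=delimiter, report=report
            )

    # parse_* already counted reads; compile_databases must not double-count
    by_type: dict[str, list[PTMSiteRecord]] = {}
    for record in stream():
        by_type.setdefault(catalog.resolve(record.mod_type), []).append(record)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for mod_type in sorted(by_type):
        group = sorted(by_type[mod_type], key=_sort_key)
        path = out_dir / f"{mod_type}.fasta"
        with open(path, "w") as handle:
            SeqIO.write((_to_seqrecord(r, catalog) for r in group), handle, "fasta")
        for record in group:
            report.record_written(record.source)
        paths[mod_type] = path
    (out_dir / "compilation_report.txt").write_text(report.summary() + "\n")
    return paths, report
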