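"""Domain types for PTM-site records, the FASTA-header metadata codec, and the
modification/residue compatibility catalog.

Every known modification site is one :class:`PTMSiteRecord`: a protein sequence
plus a single 1-based site position, a modification type, and provenance
(source database, source-local id, evidence strings).  Because a database is
compiled to one FASTA entry *per site*, all per-site metadata must survive a
round trip through a FASTA description line; :func:`encode_header` /
:func:`decode_header` implement that codec.  The header grammar is a
pipe-delimited identity block followed by ``key=value`` pairs::

    accession|position|mod_type|source|source_id protein_name=... species=... length=... evidence=...

Free-text values are percent-escaped so the delimiters (``|``, space, ``=``,
``;``, ``%``) can never occur unescaped inside a value, which makes the header
safe for any FASTA tooling.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes.
STANDARD_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Residue alphabet accepted in database sequences (X = unknown residue).
SEQUENCE_ALPHABET = STANDARD_AMINO_ACIDS | {"X"}

#: Recognised source databases.
SOURCES = ("CPLM", "dbPTM")

# Characters that must never appear raw inside a header field value.
_RESERVED = "%| =;"
_ESCAPE_RE = re.compile("%([0-9A-Fa-f]{2})")


class ValidationError(ValueError):
    """A record or query violates an invariant; ``field`` names the culprit."""

    def __init__(self, field_name: str, message: str):
        super().__init__(f"{field_name}: {message}")
        self.field = field_name


class HeaderParseError(ValueError):
    """A FASTA description line does not conform to the header grammar."""


class UnknownModificationError(KeyError):
    """A modification type absent from the catalog (and synonym table)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PTMSiteRecord:
    """One known modification site on one protein.

    ``sequence`` may be empty on records decoded from a bare header; ``length``
    is then the authoritative residue count.
    """

    accession: str
    position: int
    mod_type: str
    source: str
    source_id: str = ""
    protein_name: str = ""
    species: str = ""
    sequence: str = ""
    length: int = 0
    evidence: tuple[str, ...] = ()

    def with_sequence(self, sequence: str) -> "PTMSiteRecord":
        return replace(self, sequence=sequence, length=len(sequence))

    def without_sequence(self) -> "PTMSiteRecord":
        return replace(self, sequence="")

    @property
    def site_residue(self) -> str:
        if not self.sequence:
            raise ValueError("record carries no sequence")
        return self.sequence[self.position - 1]


@dataclass(frozen=True)
class QuerySpec:
    """One question: is the modification at ``position`` of this protein
    already known in a database, for any of ``mod_types``?"""

    accession: str
    sequence: str
    position: int
    mod_types: frozenset[str]
    evalue_threshold: float = 0.01
    range: int = 0

    def __post_init__(self):
        if not (1 <= self.position <= len(self.sequence)):
            raise ValidationError(
                "position",
                f"{self.position} outside 1..{len(self.sequence)} for {self.accession}",
            )
        if not self.mod_types:
            raise ValidationError("mod_types", "at least one modification type required")
        if self.evalue_threshold <= 0:
            raise ValidationError("evalue_threshold", "must be positive")
        if self.range < 0:
            raise ValidationError("range", "must be non-negative")


# ---------------------------------------------------------------------------
# Modification catalog
# ---------------------------------------------------------------------------

_DEFAULT_ENTRIES: dict[str, frozenset[str]] = {
    "acetylation": frozenset("K"),
    "succinylation": frozenset("K"),
    "malonylation": frozenset("K"),
    "crotonylation": frozenset("K"),
    "glutarylation": frozenset("K"),
    "2-hydroxyisobutyrylation": frozenset("K"),
    "beta-hydroxybutyrylation": frozenset("K"),
    "propionylation": frozenset("K"),
    "butyrylation": frozenset("K"),
    "ubiquitination": frozenset("K"),
    "sumoylation": frozenset("K"),
    "methylation": frozenset("KR"),
    "phosphorylation": frozenset("STYHD"),
    "glycosylation": frozenset("NST"),
}

_DEFAULT_SYNONYMS: dict[str, str] = {
    "n6-acetyllysine": "acetylation",
    "β-hydroxybutyrylation": "beta-hydroxybutyrylation",
}


def normalize_mod_type(name: str) -> str:
    """Canonical form: lowercase, internal whitespace/underscores to hyphens."""
    return re.sub(r"[\s_]+", "-", name.strip().lower())


@dataclass(frozen=True)
class ModificationCatalog:
    """Map from modification type to the residues that can carry it.

    Lookup of a type absent from both ``entries`` and ``synonyms`` raises
    :class:`UnknownModificationError`: an unknown modification type is a hard
    error, never silently allowed.
    """

    entries: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(_DEFAULT_ENTRIES)
    )
    synonyms: Mapping[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_SYNONYMS)
    )

    @classmethod
    def default(cls) -> "ModificationCatalog":
        return cls()

    @classmethod
    def from_config(cls, path: str | Path) -> "ModificationCatalog":
        """Load a catalog from a flat key=value file.

        Lines ``<mod_type>=<residues>`` define entries (residues as a run of
        one-letter codes, e.g. ``methylation=KR``); lines
        ``syn:<alias>=<mod_type>`` define synonyms; ``#`` starts a comment.
        Entries extend/override the built-in defaults.
        """
        entries = dict(_DEFAULT_ENTRIES)
        synonyms = dict(_DEFAULT_SYNONYMS)
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key.startswith("syn:"):
                synonyms[normalize_mod_type(key[4:])] = normalize_mod_type(value)
            else:
                residues = frozenset(value.upper())
                if not residues or not residues <= SEQUENCE_ALPHABET:
                    raise ValueError(
                        f"{path}:{lineno}: residues must be one-letter amino-acid codes"
                    )
                entries[normalize_mod_type(key)] = residues
        return cls(entries=entries, synonyms=synonyms)

    def resolve(self, mod_type: str) -> str:
        """Canonical catalog key for ``mod_type``, following synonyms."""
        name = normalize_mod_type(mod_type)
        name = self.synonyms.get(name, name)
        if name not in self.entries:
            raise UnknownModificationError(mod_type)
        return name

    def allowed_residues(self, mod_type: str) -> frozenset[str]:
        return self.entries[self.resolve(mod_type)]

    def __contains__(self, mod_type: str) -> bool:
        try:
            self.resolve(mod_type)
        except UnknownModificationError:
            return False
        return True


# ---------------------------------------------------------------------------
# Record validation
# ---------------------------------------------------------------------------

def validate_record(record: PTMSiteRecord, catalog: ModificationCatalog) -> None:
    """Raise :class:`ValidationError` naming the offending field, or return None.

    Checks the full record invariant set: sequence alphabet, length
    consistency, position bounds, source membership, and site-residue
    compatibility with the modification type (X accepted with a warning).
    """
    if not record.accession:
        raise ValidationError("accession", "must be non-empty")
    if any(not e for e in record.evidence):
        raise ValidationError("evidence", "evidence strings must be non-empty")
    if record.source not in SOURCES:
        raise ValidationError("source", f"{record.source!r} not one of {SOURCES}")
    if record.sequence:
        bad = set(record.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ValidationError(
                "sequence", f"non-amino-acid characters {sorted(bad)!r}"
            )
        if record.length != len(record.sequence):
            raise ValidationError(
                "length", f"{record.length} != sequence length {len(record.sequence)}"
            )
    if record.length < 1:
        raise ValidationError("length", "must be >= 1")
    if not (1 <= record.position <= record.length):
        raise ValidationError(
            "position", f"{record.position} outside 1..{record.length}"
        )
    try:
        allowed = catalog.allowed_residues(record.mod_type)
    except UnknownModificationError:
        raise ValidationError("mod_type", f"unknown modification type {record.mod_type!r}")
    if record.sequence:
        residue = record.site_residue
        if residue == "X":
            logger.warning(
                "%s position %d: unknown residue X accepted for %s",
                record.accession, record.position, record.mod_type,
            )
        elif residue not in allowed:
            raise ValidationError(
                "position",
                f"residue {residue} at {record.position} cannot carry {record.mod_type}"
                f" (allowed: {''.join(sorted(allowed))})",
            )


@dataclass(frozen=True)
class SiteValidation:
    """Structured result of :func:`validate_site`."""

    ok: bool
    failed_check: str | None = None  # "position" | "residue" | None
    message: str = ""
    incompatible_mod_types: tuple[str, ...] = ()


def validate_site(
    sequence: str,
    position: int,
    mod_types: Iterable[str],
    catalog: ModificationCatalog,
) -> SiteValidation:
    """Check that ``position`` is in range and its residue can carry at least
    one of ``mod_types`` (residue X passes with a warning)."""
    mod_types = list(mod_types)
    if not (1 <= position <= len(sequence)):
        return SiteValidation(
            ok=False,
            failed_check="position",
            message=f"position {position} outside 1..{len(sequence)}",
        )
    residue = sequence[position - 1]
    if residue == "X":
        logger.warning("position %d: unknown residue X accepted", position)
        return SiteValidation(ok=True)
    incompatible = tuple(
        m for m in mod_types if residue not in catalog.allowed_residues(m)
    )
    if len(incompatible) == len(mod_types):
        return SiteValidation(
            ok=False,
            failed_check="residue",
            message=f"residue {residue} at {position} cannot carry any of "
                    f"{sorted(normalize_mod_type(m) for m in mod_types)}",
            incompatible_mod_types=incompatible,
        )
    return SiteValidation(ok=True, incompatible_mod_types=incompatible)


# ---------------------------------------------------------------------------
# FASTA-header codec
# ---------------------------------------------------------------------------

def _escape(value: str) -> str:
    return "".join(
        f"%{ord(c):02X}" if (c in _RESERVED or ord(c) < 0x20) else c for c in value
    )


def _unescape(value: str) -> str:
    return _ESCAPE_RE.sub(lambda m: chr(int(m.group(1), 16)), value)


#: Serialized form of a record minus its sequence: one FASTA description line.
AnnotatedHeader = str

_TAIL_KEYS = ("protein_name", "species", "length", "evidence")


def encode_header(
    record: PTMSiteRecord, catalog: ModificationCatalog | None = None
) -> AnnotatedHeader:
    """Serialize a record (minus sequence) to one FASTA description line.

    Deterministic for equal inputs; every field value survives
    :func:`decode_header` exactly, including delimiter characters.
    """
    validate_record(record, catalog or ModificationCatalog.default())
    id_block = "|".join(
        _escape(part)
        for part in (
            record.accession,
            str(record.position),
            normalize_mod_type(record.mod_type),
            record.source,
            record.source_id,
        )
    )
    # evidence elements are escaped individually so ';' can serve as the
    # list joiner; the joined value must not be escaped a second time
    tail = " ".join(
        (
            f"protein_name={_escape(record.protein_name)}",
            f"species={_escape(record.species)}",
            f"length={record.length}",
            "evidence=" + ";".join(_escape(e) for e in record.evidence),
        )
    )
    return f"{id_block} {tail}"


def decode_header(line: AnnotatedHeader) -> PTMSiteRecord:
    """Parse a header produced by :func:`encode_header`.

    Returns a record with an empty ``sequence`` (``length`` carries the residue
    count).  Unknown ``key=value`` pairs are ignored with a warning; a
    malformed identity block raises :class:`HeaderParseError` quoting the line.
    """
    line = line.strip()
    if line.startswith(">"):
        line = line[1:]
    id_block, _, tail = line.partition(" ")
    parts = id_block.split("|")
    if len(parts) != 5:
        raise HeaderParseError(
            f"identity block must have 5 pipe-delimited fields, got {len(parts)}: {line!r}"
        )
    accession, pos_text, mod_type, source, source_id = (_unescape(p) for p in parts)
    try:
        position = int(pos_text)
    except ValueError:
        raise HeaderParseError(f"non-integer position {pos_text!r} in {line!r}")
    if position < 1:
        raise HeaderParseError(f"position must be >= 1, got {position} in {line!r}")
    if source not in SOURCES:
        raise HeaderParseError(f"unknown source {source!r} in {line!r}")

    fields: dict[str, str] = {}
    for token in tail.split(" "):
        if not token:
            continue
        key, sep, value = token.partition("=")
        if not sep:
            raise HeaderParseError(f"expected key=value token, got {token!r} in {line!r}")
        if key not in _TAIL_KEYS:
            logger.warning("ignoring unknown header key %r", key)
            continue
        fields[key] = value

    try:
        length = int(fields.get("length", "0"))
    except ValueError:
        raise HeaderParseError(f"non-integer length in {line!r}")
    evidence_text = fields.get("evidence", "")
    evidence = tuple(
        _unescape(e) for e in evidence_text.split(";") if e
    ) if evidence_text else ()
    return PTMSiteRecord(
        accession=accession,
        position=position,
        mod_type=mod_type,
        source=source,
        source_id=source_id,
        protein_name=_unescape(fields.get("protein_name", "")),
        species=_unescape(fields.get("species", "")),
        sequence="",
        length=length,
        evidence=evidence,
    )
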