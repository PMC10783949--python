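"""Synthetic-data generator: toy PTM databases with known ground truth.

Each *family* consists of an ancestor (the query protein) with a modifiable
residue planted at a chosen site, plus homologs derived by seeded point
substitutions at a controlled sequence identity.  Homologs carry their
modification annotation either at the residue aligned to the query site
(``conserved``), displaced by ``s`` residues (``shifted:s``), or at a distant
position (``absent``), and the generator records the expected outcome of the
positional filter at every tolerance in a :class:`FixtureTruth` table.

Because homologs differ from the ancestor only by substitutions (no indels),
the optimal local alignment is ungapped and full-length at the identities
generated here, so the truth table is computable without running the
aligner: a site shifted by ``s`` residues is retained exactly when the
tolerance is at least ``s``.

Everything is deterministic given the spec's seed (one pseudo-random stream
per spec, never wall-clock seeded).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .ptm_records import ModificationCatalog, PTMSiteRecord

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Placement distance used for "absent" annotations; far beyond any tested
#: tolerance so such records are never reported at small ranges.
ABSENT_OFFSET = 12


class InfeasibleSpecError(ValueError):
    """The requested identity/placement cannot be realised on this length."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic database.

    ``placements`` cycles over the homologs of every family; entries are
    ``"conserved"``, ``"shifted:<s>"`` (s >= 1) or ``"absent"``.  ``sources``
    cycles likewise over ``"CPLM"``, ``"dbPTM"`` or ``"both"`` (a "both"
    record appears in each dump and should merge into one report row).
    """

    seed: int
    n_families: int = 20
    family_size: int = 3
    length_range: tuple[int, int] = (60, 120)
    identity: float = 0.85
    placements: tuple[str, ...] = ("conserved", "shifted:1", "shifted:2", "absent")
    sources: tuple[str, ...] = ("CPLM", "dbPTM", "both")
    mod_type: str = "acetylation"
    site_residue: str = "K"

    def __post_init__(self):
        if not (0.0 < self.identity <= 1.0):
            raise ValueError("identity must be in (0, 1]")
        for rule in self.placements:
            if rule.startswith("shifted:"):
                if int(rule.split(":", 1)[1]) < 1:
                    raise ValueError("shift must be >= 1")
            elif rule not in ("conserved", "absent"):
                raise ValueError(f"unknown placement rule {rule!r}")


@dataclass(frozen=True)
class TruthEntry:
    """Ground truth for one generated database record."""

    accession: str
    family: int
    relation: str          # "conserved" | "shifted:<s>" | "absent"
    annotated_position: int
    offset: int            # |annotated - aligned-to-query| in residues

    def expected_retained(self, range_: int) -> bool:
        return self.offset <= range_


@dataclass
class FixtureTruth:
    """Truth table covering every generated record exactly once."""

    entries: dict[str, TruthEntry] = field(default_factory=dict)

    def add(self, entry: TruthEntry) -> None:
        if entry.accession in self.entries:
            raise ValueError(f"duplicate truth entry {entry.accession}")
        self.entries[entry.accession] = entry

    def expected_accessions(self, range_: int) -> set[str]:
        return {a for a, e in self.entries.items() if e.expected_retained(range_)}


@dataclass(frozen=True)
class Family:
    index: int
    query_accession: str
    query_sequence: str
    site_position: int
    mod_type: str
    records: tuple[PTMSiteRecord, ...]


def _random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_AMINO_ACIDS) for _ in range(length))


def _mutate(
    rng: random.Random,
    sequence: str,
    n_substitutions: int,
    protected: set[int],
) -> str:
    """Apply ``n_substitutions`` point substitutions outside ``protected``
    (0-based indices); each replaces the residue with a different one."""
    positions = [i for i in range(len(sequence)) if i not in protected]
    if n_substitutions > len(positions):
        raise InfeasibleSpecError(
            f"cannot place {n_substitutions} substitutions on length "
            f"{len(sequence)} with {len(protected)} protected positions"
        )
    chosen = rng.sample(positions, n_substitutions)
    residues = list(sequence)
    for i in chosen:
        alternatives = [a for a in _AMINO_ACIDS if a != residues[i]]
        residues[i] = rng.choice(alternatives)
    return "".join(residues)


def generate_family(
    spec: FixtureSpec,
    family_index: int = 0,
    rng: random.Random | None = None,
    truth: FixtureTruth | None = None,
) -> tuple[Family, FixtureTruth]:
    """Generate one query protein plus its annotated homolog records.

    The ancestor is uniform over the 20 residues with the site residue
    planted at the query position; homologs reach the target identity within
    +-2 percentage points by construction (exact substitution counts on an
    ungapped alignment).
    """
    rng = rng or random.Random(spec.seed)
    truth = truth or FixtureTruth()
    lo, hi = spec.length_range
    length = rng.randint(lo, hi)
    # keep the site away from the termini so windows and shifts stay in range
    margin = ABSENT_OFFSET + 3
    if length <= 2 * margin:
        raise InfeasibleSpecError(f"length {length} too short for site margin {margin}")
    site = rng.randint(margin, length - margin)
    ancestor = list(_random_protein(rng, length))
    ancestor[site - 1] = spec.site_residue
    query_sequence = "".join(ancestor)
    query_accession = f"QRY{family_index:03d}"

    n_substitutions = round((1.0 - spec.identity) * length)
    records: list[PTMSiteRecord] = []
    for member in range(spec.family_size):
        rule = spec.placements[(family_index * spec.family_size + member)
                               % len(spec.placements)]
        source = spec.sources[(family_index * spec.family_size + member)
                              % len(spec.sources)]
        accession = f"HOM{family_index:03d}{chr(ord('A') + member)}"
        if rule == "conserved":
            annotated = site
            offset = 0
        elif rule.startswith("shifted:"):
            offset = int(rule.split(":", 1)[1])
            annotated = site + offset
        else:
            offset = ABSENT_OFFSET
            annotated = site + ABSENT_OFFSET
        homolog = list(query_sequence)
        budget = n_substitutions
        if homolog[annotated - 1] != spec.site_residue:
            homolog[annotated - 1] = spec.site_residue
            budget = max(0, budget - 1)  # the planted residue counts as one difference
        protected = {site - 1, annotated - 1}
        mutated = _mutate(rng, "".join(homolog), budget, protected)
        truth.add(TruthEntry(accession, family_index, rule, annotated, offset))
        base = PTMSiteRecord(
            accession=accession,
            position=annotated,
            mod_type=spec.mod_type,
            source="CPLM",
            protein_name=f"synthetic homolog {accession}",
            species=f"Synthetic species {family_index}",
            sequence=mutated,
            length=len(mutated),
        )
        if source in ("CPLM", "both"):
            records.append(
                _with(base, source="CPLM",
                      source_id=f"CPLM{family_index:03d}{member}",
                      evidence=(f"PMID:{1000 + family_index * 10 + member}",))
            )
        if source in ("dbPTM", "both"):
            records.append(
                _with(base, source="dbPTM", source_id="",
                      evidence=(f"dbPTM:{2000 + family_index * 10 + member}",))
            )
    family = Family(
        index=family_index,
        query_accession=query_accession,
        query_sequence=query_sequence,
        site_position=site,
        mod_type=spec.mod_type,
        records=tuple(records),
    )
    return family, truth


def _with(record: PTMSiteRecord, **changes) -> PTMSiteRecord:
    from dataclasses import replace

    return replace(record, **changes)


def generate_fixture(spec: FixtureSpec) -> tuple[list[Family], FixtureTruth]:
    """Generate ``spec.n_families`` families from one seeded stream."""
    rng = random.Random(spec.seed)
    truth = FixtureTruth()
    families = []
    for index in range(spec.n_families):
        family, truth = generate_family(spec, index, rng, truth)
        families.append(family)
    return families, truth


# ---------------------------------------------------------------------------
# On-disk emission (same formats the real pipeline consumes)
# ---------------------------------------------------------------------------

def write_fixture_dumps(
    families: Sequence[Family],
    out_dir: str | Path,
    withheld_accessions: Sequence[str] = (),
) -> dict[str, Path]:
    """Write CPLM/dbPTM-style dumps, a provider directory and a batch file.

    The provider directory resolves every accession except
    ``withheld_accessions`` (to exercise the obsolete-accession path);
    query proteins are included so accession-based queries resolve too.
    Returns paths keyed by artifact name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provider_dir = out_dir / "provider"
    provider_dir.mkdir(exist_ok=True)
    withheld = set(withheld_accessions)

    cplm_rows = ["source_id\taccession\tposition\tmod_type\tspecies\tsequence\tevidence\tprotein_name"]
    dbptm_rows = ["accession\tposition\tmod_type\tspecies\tevidence\tprotein_name"]
    batch_rows = []
    for family in families:
        batch_rows.append(
            f"{family.query_accession}\t{family.site_position}\t{family.mod_type}"
        )
        _write_provider_fasta(
            provider_dir, family.query_accession, family.query_sequence,
            f"synthetic query {family.query_accession}",
            f"Synthetic species {family.index}", withheld,
        )
        for record in family.records:
            if record.source == "CPLM":
                cplm_rows.append("\t".join((
                    record.source_id, record.accession, str(record.position),
                    record.mod_type, record.species, record.sequence,
                    ";".join(record.evidence), record.protein_name,
                )))
            else:
                dbptm_rows.append("\t".join((
                    record.accession, str(record.position), record.mod_type,
                    record.species, ";".join(record.evidence), record.protein_name,
                )))
                _write_provider_fasta(
                    provider_dir, record.accession, record.sequence,
                    record.protein_name, record.species, withheld,
                )

    paths = {
        "cplm_dump": out_dir / "cplm.tsv",
        "dbptm_dump": out_dir / "dbptm.tsv",
        "provider_dir": provider_dir,
        "batch_file": out_dir / "batch.tsv",
    }
    paths["cplm_dump"].write_text("\n".join(cplm_rows) + "\n")
    paths["dbptm_dump"].write_text("\n".join(dbptm_rows) + "\n")
    paths["batch_file"].write_text("\n".join(batch_rows) + "\n")
    return paths


def _write_provider_fasta(
    provider_dir: Path,
    accession: str,
    sequence: str,
    name: str,
    species: str,
    withheld: set[str],
) -> None:
    if accession in withheld:
        return
    path = provider_dir / f"{accession}.fasta"
    if path.exists():
        return
    lines = [f">{accession} {name} OS={species}"]
    lines += [sequence[i:i + 60] for i in range(0, len(sequence), 60)]
    path.write_text("\n".join(lines) + "\n")


def make_fixture(
    out_dir: str | Path,
    seed: int,
    n_families: int = 20,
    family_size: int = 3,
    identity: float = 0.85,
    withheld_accessions: Sequence[str] = (),
) -> tuple[FixtureSpec, list[Family], FixtureTruth, dict[str, Path]]:
    """One-call fixture build used by the CLI and the test suite."""
    spec = FixtureSpec(
        seed=seed, n_families=n_families, family_size=family_size,
        identity=identity,
    )
    families, truth = generate_fixture(spec)
    paths = write_fixture_dumps(families, out_dir, withheld_accessions)
    return spec, families, truth, paths
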