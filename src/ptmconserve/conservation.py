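"""Decide which alignment hits represent a conserved modification site.

This is the core computation: the queried modification position is mapped
through each gapped local alignment, and HSPs pass a three-stage filter:

1. E-value at most the user's threshold.
2. The modified residue lies inside the aligned region on *both* sides:
   the query position within ``[q_start, q_end]`` and the target's annotated
   position within ``[t_start, t_end]``.
3. The query site's alignment column is within ``range`` columns of the
   column holding the target's annotated residue.

The positional tolerance (``range``) is measured in alignment columns around
the query site's column: column units are gap-robust and coincide with
residue offsets in ungapped regions.  Candidate columns where the target has
a gap are skipped, not counted as failures; conversely, when the query site
itself aligns to a target gap, a nearby column within range can still
satisfy stage 3.

Surviving hits are merged into one report row per (accession, target
position, modification type): a site present in both CPLM and dbPTM collapses
into a single row carrying both evidence lists, with E-value/identity/
coverage taken from the best-E-value contributor.
"""

from __future__ import annotations

from dataclasses import dataclass

from .aligner import HSP
from .ptm_records import PTMSiteRecord, QuerySpec, normalize_mod_type


@dataclass(frozen=True)
class PositionMapping:
    """Where a query residue lands in one gapped alignment.

    ``alignment_column`` is the 1-based column of the query residue in the
    aligned strings (None when the residue lies outside the aligned region);
    ``target_position`` is the 1-based target residue index aligned to it
    (None when the query residue sits opposite a target gap).
    """

    alignment_column: int | None
    target_position: int | None


def map_query_position(hsp: HSP, qpos: int) -> PositionMapping:
    """Map a 1-based query position through the alignment.

    Walks alignment columns counting non-gap query characters from
    ``q_start``; the target position is the count of non-gap target
    characters from ``t_start`` through that column.
    """
    if qpos < 1:
        raise ValueError("query position must be >= 1")
    if not (hsp.q_start <= qpos <= hsp.q_end):
        return PositionMapping(None, None)
    query_index = hsp.q_start - 1
    target_index = hsp.t_start - 1
    for column, (qc, tc) in enumerate(zip(hsp.q_aln, hsp.t_aln), 1):
        if qc != "-":
            query_index += 1
        if tc != "-":
            target_index += 1
        if qc != "-" and query_index == qpos:
            if tc == "-":
                return PositionMapping(column, None)
            return PositionMapping(column, target_index)
    raise ValueError("alignment inconsistent with its coordinates")


def _column_of_target_position(hsp: HSP, tpos: int) -> int | None:
    """Alignment column holding target residue ``tpos``, or None outside."""
    if not (hsp.t_start <= tpos <= hsp.t_end):
        return None
    target_index = hsp.t_start - 1
    for column, tc in enumerate(hsp.t_aln, 1):
        if tc != "-":
            target_index += 1
            if target_index == tpos:
                return column
    return None


def filter_hsps(
    hsps: list[HSP], query: QuerySpec
) -> list[tuple[HSP, PositionMapping]]:
    """Apply the three-stage conservation filter; order is preserved.

    Every HSP must carry a target record with one (position, mod_type)
    annotation.
    """
    retained: list[tuple[HSP, PositionMapping]] = []
    for hsp in hsps:
        if hsp.target is None:
            raise ValueError("HSP lacks a target annotation")
        # stage 1: E-value threshold
        if hsp.evalue > query.evalue_threshold:
            continue
        # stage 2: modified residue inside the aligned region on both sides
        if not (hsp.q_start <= query.position <= hsp.q_end):
            continue
        if not (hsp.t_start <= hsp.target.position <= hsp.t_end):
            continue
        # stage 3: annotated target residue within +-range alignment columns
        mapping = map_query_position(hsp, query.position)
        target_column = _column_of_target_position(hsp, hsp.target.position)
        if target_column is None:
            continue
        assert mapping.alignment_column is not None
        if abs(target_column - mapping.alignment_column) <= query.range:
            retained.append((hsp, mapping))
    return retained


def sequence_window(sequence: str, position: int, k: int = 5) -> str:
    """The ``2k+1``-residue window centred on ``position``; flanks that fall
    off the sequence are padded with ``-``."""
    if not (1 <= position <= len(sequence)):
        raise ValueError(f"position {position} outside 1..{len(sequence)}")
    if k < 0:
        raise ValueError("window half-width must be >= 0")
    start = position - 1 - k
    end = position + k
    left_pad = max(0, -start)
    right_pad = max(0, end - len(sequence))
    return "-" * left_pad + sequence[max(0, start):min(end, len(sequence))] + "-" * right_pad


@dataclass(frozen=True)
class ConservedSiteHit:
    """One merged report row: a known modification site conserved at the
    queried position, with per-source evidence."""

    accession: str
    protein_name: str
    mod_type: str
    position: int
    sequence_window: str
    species: str
    evalue: float
    identity_pct: float
    coverage_pct: float
    cplm_ids: tuple[str, ...] = ()
    cplm_evidence: tuple[str, ...] = ()
    dbptm_evidence: tuple[str, ...] = ()


def merge_hits(
    filtered: list[tuple[HSP, PositionMapping]], window_halfwidth: int = 5
) -> list[ConservedSiteHit]:
    """Collapse filtered HSPs into one row per (accession, position, type).

    A site contributed by both a CPLM and a dbPTM record becomes one row with
    both evidence lists populated; alignment statistics come from the
    contributor with the lowest E-value.  Rows are sorted by ascending
    E-value (ties by accession then position).
    """
    groups: dict[tuple[str, int, str], list[HSP]] = {}
    for hsp, _mapping in filtered:
        target = hsp.target
        assert target is not None
        key = (target.accession, target.position, normalize_mod_type(target.mod_type))
        groups.setdefault(key, []).append(hsp)

    rows: list[ConservedSiteHit] = []
    for (accession, position, mod_type), members in groups.items():
        best = min(members, key=lambda h: h.evalue)
        target = best.target
        assert target is not None
        cplm_ids: list[str] = []
        cplm_evidence: list[str] = []
        dbptm_evidence: list[str] = []
        for hsp in members:
            record = hsp.target
            assert record is not None
            if record.source == "CPLM":
                if record.source_id:
                    cplm_ids.append(record.source_id)
                cplm_evidence.extend(record.evidence)
            else:
                dbptm_evidence.extend(record.evidence)
        window = (
            sequence_window(target.sequence, position, window_halfwidth)
            if target.sequence else ""
        )
        rows.append(
            ConservedSiteHit(
                accession=accession,
                protein_name=best.target.protein_name,
                mod_type=mod_type,
                position=position,
                sequence_window=window,
                species=best.target.species,
                evalue=best.evalue,
                identity_pct=best.identity_pct,
                coverage_pct=best.coverage_pct,
                cplm_ids=tuple(dict.fromkeys(cplm_ids)),
                cplm_evidence=tuple(dict.fromkeys(cplm_evidence)),
                dbptm_evidence=tuple(dict.fromkeys(dbptm_evidence)),
            )
        )
    rows.sort(key=lambda r: (r.evalue, r.accession, r.position))
    return rows


def find_conserved_sites(
    hsps: list[HSP], query: QuerySpec, window_halfwidth: int = 5
) -> list[ConservedSiteHit]:
    """Convenience: filter then merge."""
    return merge_hits(filter_hsps(hsps, query), window_halfwidth)
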