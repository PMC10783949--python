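"""Local pairwise alignment of a query protein against a compiled
modification database.

The search contract mirrors a gapped BLASTp run: for each database entry the
single best-scoring local alignment (high-scoring pair, HSP) under
BLOSUM62/affine-gap scoring is computed and assigned a Karlin–Altschul
E-value ``K * m * n * exp(-lambda * S)``, where ``m`` is the query length and
``n`` the total residue count of the database.  The internal engine is an
exact Smith–Waterman/Gotoh dynamic program (no heuristic seeding, no
low-complexity masking, no composition-based statistics), with the
Karlin–Altschul parameters fixed to the published gapped-BLOSUM62 defaults
(lambda = 0.267, K = 0.041); E-values are therefore approximate relative to a
real BLASTp run, but consistent for thresholding.  An optional external
backend shells out to NCBI BLAST+ when it is installed.

Scoring convention: a gap of length L costs ``gap_open + L * gap_extend``
(BLAST's "existence 11, extension 1").
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from numba import njit

from .ptm_records import HeaderParseError, PTMSiteRecord, QuerySpec, decode_header

logger = logging.getLogger(__name__)

_NEG = np.int32(-(2 ** 30))


class DatabaseFormatError(ValueError):
    """A database entry is unreadable or its header does not decode."""


class BackendUnavailableError(RuntimeError):
    """The external alignment engine is not installed on this host."""


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine-gap penalties and E-value statistics.

    Defaults are the standard gapped-BLASTp parameters: BLOSUM62,
    gap existence 11, gap extension 1, lambda 0.267, K 0.041.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k: float = 0.041

    def __post_init__(self):
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    @property
    def alphabet(self) -> str:
        return _matrix_tables(self.matrix_name)[0]

    @property
    def matrix(self) -> np.ndarray:
        return _matrix_tables(self.matrix_name)[1]


@lru_cache(maxsize=None)
def _matrix_tables(name: str) -> tuple[str, np.ndarray]:
    loaded = substitution_matrices.load(name)
    alphabet = str(loaded.alphabet)
    table = np.asarray(loaded, dtype=np.int32)
    return alphabet, table


@lru_cache(maxsize=None)
def _encoder(alphabet: str) -> np.ndarray:
    """Byte-value -> matrix-row lookup; residues outside the matrix alphabet
    are scored as X, never raised."""
    x_index = alphabet.index("X") if "X" in alphabet else len(alphabet) - 1
    table = np.full(256, x_index, dtype=np.int64)
    for index, char in enumerate(alphabet):
        table[ord(char)] = index
    return table


def _encode(sequence: str, alphabet: str) -> np.ndarray:
    raw = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    return _encoder(alphabet)[raw]


# ---------------------------------------------------------------------------
# HSP
# ---------------------------------------------------------------------------

@dataclass
class HSP:
    """One local alignment between the query and one database entry.

    Coordinates are 1-based inclusive; ``q_aln``/``t_aln`` are equal-length
    aligned strings over residues plus ``-``.
    """

    raw_score: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    q_aln: str
    t_aln: str
    identity_pct: float
    coverage_pct: float
    evalue: float = math.inf
    target: PTMSiteRecord | None = None

    def check_invariants(self) -> None:
        if len(self.q_aln) != len(self.t_aln):
            raise ValueError("aligned strings differ in length")
        for qc, tc in zip(self.q_aln, self.t_aln):
            if qc == "-" and tc == "-":
                raise ValueError("column gapped in both sequences")
        if sum(c != "-" for c in self.q_aln) != self.q_end - self.q_start + 1:
            raise ValueError("query span inconsistent with alignment")
        if sum(c != "-" for c in self.t_aln) != self.t_end - self.t_start + 1:
            raise ValueError("target span inconsistent with alignment")


@njit(cache=True)
def _gotoh_fill(q, t, sub, gap_open, gap_extend):  # pragma: no cover - jit
    m = q.shape[0]
    n = t.shape[0]
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), _NEG, np.int32)
    F = np.full((m + 1, n + 1), _NEG, np.int32)
    # ptr_h: 0 stop, 1 diagonal, 2 from E (gap in query), 3 from F (gap in target)
    ptr_h = np.zeros((m + 1, n + 1), np.uint8)
    ptr_e = np.zeros((m + 1, n + 1), np.uint8)  # 0 opened from H, 1 extended
    ptr_f = np.zeros((m + 1, n + 1), np.uint8)
    first_gap = gap_open + gap_extend
    best = np.int32(0)
    best_i = 0
    best_j = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - first_gap
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptr_e[i, j] = 0
            else:
                E[i, j] = e_ext
                ptr_e[i, j] = 1
            f_open = H[i - 1, j] - first_gap
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptr_f[i, j] = 0
            else:
                F[i, j] = f_ext
                ptr_f[i, j] = 1
            diag = H[i - 1, j - 1] + sub[qi, t[j - 1]]
            h = np.int32(0)
            p = np.uint8(0)
            if diag >= h and diag > 0:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptr_h[i, j] = p
            if h > best:  # strict: earliest end cell in row-major order wins
                best = h
                best_i = i
                best_j = j
    return best, best_i, best_j, ptr_h, ptr_e, ptr_f


def local_align(
    query: str, target: str, scheme: ScoringScheme | None = None
) -> HSP | None:
    """Best local alignment of ``query`` against ``target`` under affine-gap
    Smith–Waterman scoring, or None when the best score is not positive.

    Deterministic: the end cell is the earliest (query, then target position)
    maximum-scoring cell, and traceback prefers substitution columns over
    gaps, so equal-scoring alignments resolve to the one with the fewest gaps.
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    scheme = scheme or ScoringScheme()
    q = _encode(query, scheme.alphabet)
    t = _encode(target, scheme.alphabet)
    best, bi, bj, ptr_h, ptr_e, ptr_f = _gotoh_fill(
        q, t, scheme.matrix, scheme.gap_open, scheme.gap_extend
    )
    if best <= 0:
        return None

    q_chars: list[str] = []
    t_chars: list[str] = []
    i, j = bi, bj
    state = 0  # 0=H, 2=E, 3=F
    while True:
        if state == 0:
            p = ptr_h[i, j]
            if p == 0:
                break
            if p == 1:
                q_chars.append(query[i - 1])
                t_chars.append(target[j - 1])
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 2:  # gap in query, consumes target residue j
            q_chars.append("-")
            t_chars.append(target[j - 1])
            state = 0 if ptr_e[i, j] == 0 else 2
            j -= 1
        else:  # gap in target, consumes query residue i
            q_chars.append(query[i - 1])
            t_chars.append("-")
            state = 0 if ptr_f[i, j] == 0 else 3
            i -= 1
    q_aln = "".join(reversed(q_chars))
    t_aln = "".join(reversed(t_chars))
    columns = len(q_aln)
    matches = sum(a == b for a, b in zip(q_aln, t_aln))
    hsp = HSP(
        raw_score=int(best),
        q_start=i + 1,
        q_end=bi,
        t_start=j + 1,
        t_end=bj,
        q_aln=q_aln,
        t_aln=t_aln,
        identity_pct=100.0 * matches / columns,
        coverage_pct=100.0 * (bi - i) / len(query),
    )
    hsp.check_invariants()
    return hsp


def evalue(
    raw_score: int, query_len: int, db_len: int, scheme: ScoringScheme | None = None
) -> float:
    """Karlin–Altschul expectation ``K * m * n * exp(-lambda * S)``.

    Strictly decreasing in the score, linear in both lengths; underflows to
    0.0 for very high scores rather than raising.
    """
    scheme = scheme or ScoringScheme()
    if query_len < 1 or db_len < 1:
        raise ValueError("lengths must be >= 1")
    return scheme.k * query_len * db_len * math.exp(-scheme.lam * raw_score)


# ---------------------------------------------------------------------------
# Database search
# ---------------------------------------------------------------------------

def read_database(db: str | Path) -> list[PTMSiteRecord]:
    """Load an annotated multi-FASTA database as records with sequences."""
    records: list[PTMSiteRecord] = []
    for entry in SeqIO.parse(str(db), "fasta"):
        try:
            record = decode_header(entry.description)
        except HeaderParseError as exc:
            raise DatabaseFormatError(f"{db}: entry {entry.id!r}: {exc}") from exc
        records.append(record.with_sequence(str(entry.seq).upper()))
    return records


def _hsp_sort_key(hsp: HSP) -> tuple:
    target = hsp.target
    return (hsp.evalue, target.accession if target else "",
            target.position if target else 0)


def search_database(
    query: QuerySpec, db: str | Path, scheme: ScoringScheme | None = None
) -> list[HSP]:
    """Align the query against every entry of a compiled database.

    E-values use the database's total residue count (duplicated sequences from
    per-site records included, matching how a compiled file behaves as a
    BLAST database).  Hits are sorted by ascending E-value, ties by target
    accession then position.
    """
    scheme = scheme or ScoringScheme()
    entries = read_database(db)
    total_residues = sum(len(r.sequence) for r in entries)
    hits: list[HSP] = []
    for record in entries:
        hsp = local_align(query.sequence, record.sequence, scheme)
        if hsp is None:
            continue
        hsp.target = record
        hsp.evalue = evalue(hsp.raw_score, len(query.sequence), total_residues, scheme)
        hits.append(hsp)
    hits.sort(key=_hsp_sort_key)
    return hits


# ---------------------------------------------------------------------------
# Optional external backend (NCBI BLAST+)
# ---------------------------------------------------------------------------

_BLAST_FIELDS = "qstart qend sstart send score evalue nident length qseq sseq stitle"


def external_backend_search(
    query: QuerySpec, db: str | Path, scheme: ScoringScheme | None = None
) -> list[HSP]:
    """Search via NCBI BLAST+ (``makeblastdb`` + ``blastp``), same HSP
    contract as :func:`search_database`.

    Raises :class:`BackendUnavailableError` when the binaries are absent,
    suggesting the internal backend.  E-values and scores come from BLAST
    itself and may differ from the internal engine's; the stage-1 threshold
    behaviour on clear homologs is concordant.
    """
    scheme = scheme or ScoringScheme()
    for binary in ("makeblastdb", "blastp"):
        if shutil.which(binary) is None:
            raise BackendUnavailableError(
                f"{binary} not found on PATH; use the internal backend instead"
            )
    db = Path(db)
    with tempfile.TemporaryDirectory() as tmp:
        tmp_path = Path(tmp)
        db_prefix = tmp_path / "db"
        subprocess.run(
            ["makeblastdb", "-in", str(db), "-dbtype", "prot",
             "-out", str(db_prefix)],
            check=True, capture_output=True, text=True,
        )
        query_path = tmp_path / "query.fasta"
        query_path.write_text(f">{query.accession}\n{query.sequence}\n")
        result = subprocess.run(
            ["blastp", "-query", str(query_path), "-db", str(db_prefix),
             "-outfmt", f"6 {_BLAST_FIELDS}", "-max_hsps", "1",
             "-evalue", "1000", "-num_threads", "1",
             "-gapopen", str(scheme.gap_open), "-gapextend", str(scheme.gap_extend),
             "-matrix", scheme.matrix_name],
            check=True, capture_output=True, text=True,
        )
    hits: list[HSP] = []
    for line_number, line in enumerate(result.stdout.splitlines(), 1):
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(_BLAST_FIELDS.split()):
            raise DatabaseFormatError(
                f"malformed blastp output line {line_number}: {line!r}"
            )
        (qstart, qend, sstart, send, score, evalue_text,
         nident, length, qseq, sseq, stitle) = parts
        try:
            record = decode_header(stitle)
        except HeaderParseError as exc:
            raise DatabaseFormatError(
                f"blastp line {line_number}: undecodable subject title: {exc}"
            ) from exc
        hsp = HSP(
            raw_score=int(score),
            q_start=int(qstart),
            q_end=int(qend),
            t_start=int(sstart),
            t_end=int(send),
            q_aln=qseq,
            t_aln=sseq,
            identity_pct=100.0 * int(nident) / int(length),
            coverage_pct=100.0 * (int(qend) - int(qstart) + 1) / len(query.sequence),
            evalue=float(evalue_text),
            target=record,
        )
        hits.append(hsp)
    # re-attach sequences so downstream filtering can window the target
    by_key = {(r.accession, r.position, r.mod_type, r.source, r.source_id): r
              for r in read_database(db)}
    for hsp in hits:
        t = hsp.target
        key = (t.accession, t.position, t.mod_type, t.source, t.source_id)
        if key in by_key:
            hsp.target = by_key[key]
    hits.sort(key=_hsp_sort_key)
    return hits
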