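"""Independent oracles used by the tests.

These deliberately share no code with the package: the alignment oracle is a
memoized recursion over explicit alignment-end states (not the iterative
matrix fill the package uses), and the position-mapping oracle enumerates
alignment columns directly.
"""

from __future__ import annotations

import random
from functools import lru_cache

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM62.alphabet)

NEG = float("-inf")


def blosum62(a: str, b: str) -> int:
    a = a if a in _ALPHABET else "X"
    b = b if b in _ALPHABET else "X"
    return int(_BLOSUM62[a, b])


def oracle_local_score(
    query: str, target: str, gap_open: int = 11, gap_extend: int = 1
) -> int:
    """Best affine-gap local alignment score by memoized recursion.

    States: D(i, j) ends with query[i] aligned to target[j]; P ends with a
    gap in the target (consumes query[i]); Q ends with a gap in the query
    (consumes target[j]).  A gap of length L costs gap_open + L * gap_extend.
    """
    first = gap_open + gap_extend

    @lru_cache(maxsize=None)
    def D(i: int, j: int) -> float:
        prev = 0.0
        if i > 1 and j > 1:
            prev = max(prev, D(i - 1, j - 1), P(i - 1, j - 1), Q(i - 1, j - 1))
        return blosum62(query[i - 1], target[j - 1]) + prev

    @lru_cache(maxsize=None)
    def P(i: int, j: int) -> float:
        if i < 2:
            return NEG
        best = max(D(i - 1, j), Q(i - 1, j)) - first
        best = max(best, P(i - 1, j) - gap_extend)
        return best

    @lru_cache(maxsize=None)
    def Q(i: int, j: int) -> float:
        if j < 2:
            return NEG
        best = max(D(i, j - 1), P(i, j - 1)) - first
        best = max(best, Q(i, j - 1) - gap_extend)
        return best

    best = 0.0
    for i in range(1, len(query) + 1):
        for j in range(1, len(target) + 1):
            best = max(best, D(i, j), P(i, j), Q(i, j))
    return int(best)


def oracle_map_position(
    q_aln: str, t_aln: str, q_start: int, t_start: int, qpos: int
) -> tuple[int | None, int | None]:
    """(alignment column, target position) of query residue ``qpos`` by a
    direct column enumeration; (None, None) outside the alignment."""
    query_index = q_start - 1
    target_index = t_start - 1
    for column in range(1, len(q_aln) + 1):
        qc, tc = q_aln[column - 1], t_aln[column - 1]
        if qc != "-":
            query_index += 1
        if tc != "-":
            target_index += 1
        if qc != "-" and query_index == qpos:
            return column, (target_index if tc != "-" else None)
    return None, None


_ADVERSARIAL = "|=; %\t\x01%20αβ\\\"'"


def random_text(rng: random.Random, max_len: int = 20) -> str:
    pool = "abcdefgXYZ0123456789" + _ADVERSARIAL
    return "".join(rng.choice(pool) for _ in range(rng.randint(0, max_len)))


def random_site_record(rng: random.Random):
    """A valid record with adversarial characters in every free-text field."""
    from ptmconserve import ModificationCatalog, PTMSiteRecord

    catalog = ModificationCatalog.default()
    mod_type = rng.choice(sorted(catalog.entries))
    residue = rng.choice(sorted(catalog.entries[mod_type]))
    length = rng.randint(1, 40)
    position = rng.randint(1, length)
    sequence = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(length))
    sequence = sequence[: position - 1] + residue + sequence[position:]
    source = rng.choice(("CPLM", "dbPTM"))
    return PTMSiteRecord(
        accession="A" + random_text(rng, 8).replace(" ", "_") or "ACC",
        position=position,
        mod_type=mod_type,
        source=source,
        source_id=random_text(rng, 10) if source == "CPLM" else "",
        protein_name=random_text(rng),
        species=random_text(rng),
        sequence=sequence,
        length=length,
        evidence=tuple(
            "e" + random_text(rng, 12) for _ in range(rng.randint(0, 3))
        ),
    )
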