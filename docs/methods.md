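# Methods

## Problem and model

Given a query protein, a 1-based residue position and one or more
modification types, ptmconserve decides which *known* modification sites —
rows of CPLM-style or dbPTM-style database dumps — are conserved at the
queried residue. "Conserved" is defined operationally: in a significant
local alignment between query and database protein, the queried position's
alignment column lies within a user-chosen tolerance of the column holding
the database's annotated residue. There is no evolutionary model behind the
call; it is a sequence-similarity screen whose output is meant for
novelty assessment and prioritisation, not for phylogenetic inference.

## Database compilation and the header codec

Each dump row (one modification site) becomes one FASTA entry whose
description line carries all per-site metadata:

```
accession|position|mod_type|source|source_id protein_name=... species=... length=... evidence=e1;e2
```

Design choices:

- **One entry per site, not per protein.** A protein with sites at positions
  10 and 20 is stored twice with identical sequence. Redundant storage is
  accepted so that a search hit is self-contained: every HSP already knows
  which site it represents.
- **Percent-escaping.** The reserved characters `% | space = ;` and control
  characters are `%XX`-escaped in every free-text value, so the header
  survives arbitrary FASTA tooling and `decode(encode(r))` is exact for all
  valid records. Evidence strings are escaped individually and
  semicolon-joined; empty evidence strings are invalid (they would be
  indistinguishable from an absent list).
- **Compilation never aborts on bad rows.** Rows violating an invariant
  (position out of range, residue incompatible with the modification type,
  unknown type, unresolvable accession) are skipped, logged with row number
  and reason, and tallied in a report that must balance:
  read = written + skipped, per source.
- **Deterministic order** (source, then source id/accession, then position)
  makes compilation idempotent and outputs byte-reproducible.
- dbPTM-style dumps carry no sequences; a **provider** abstraction resolves
  accessions (directory of FASTA files, in-memory map; both offline and
  deterministic). "Accession unknown/obsolete" is a skip; transport failure
  is a distinct, retryable error. Dump column layouts are configurable maps
  because dump dialects vary between releases.

## Modification–residue catalog

Validation requires knowing which residues can carry a modification. The
shipped table maps the lysine acylations (acetylation, succinylation,
malonylation, crotonylation, glutarylation, 2-hydroxyisobutyrylation,
beta-hydroxybutyrylation, propionylation, butyrylation), ubiquitination and
sumoylation to K; methylation to K/R; phosphorylation to S/T/Y/H/D;
glycosylation to N/S/T. The table and a synonym map (e.g.
"N6-acetyllysine" → acetylation) are extensible through a flat `key=value`
config file. An unknown modification type is a hard error; an `X` residue at
the queried position is accepted with a warning so unknown residues in
dumps do not abort compilation. Type names are normalised to lowercase with
hyphens before lookup.

## Alignment and statistics

The internal engine is an exact Smith–Waterman/Gotoh dynamic program
(affine gaps, BLOSUM62 by default). Conventions:

- A gap of length L costs `gap_open + L·gap_extend` (defaults 11 and 1, the
  common "existence/extension" convention).
- Residues outside the matrix alphabet score as X — never an exception.
- One best HSP per database entry. Determinism: the alignment end cell is
  the earliest maximum in row-major (query, then target) order, and
  traceback prefers substitution columns over gaps, so co-optimal
  alignments resolve to the fewest-gap, earliest-end one. (Resolving ties by
  earliest alignment *start* would require enumerating all co-optimal
  tracebacks; the end-cell rule is equally deterministic and coincides with
  it on the ungapped alignments that dominate this use case.)
- The inner DP is JIT-compiled (numba); full DP with no heuristic seeding is
  entirely adequate at the database sizes compiled here.

E-values use the closed Karlin–Altschul form `E = K·m·n·exp(−λS)` with the
published gapped-BLOSUM62 parameters λ = 0.267, K = 0.041, where `n` is the
total residue count of the compiled file (duplicated per-site sequences
included — that is what the compiled file contains). These E-values are
approximate relative to a full BLASTp implementation (no composition-based
statistics, no length corrections); the filter contract only requires
monotone, consistent thresholding, and an optional BLAST+ backend is
available where exact BLAST statistics matter. `exp` underflow returns 0.0.

## The three-stage filter

1. **Significance:** E ≤ threshold (default 0.01 — a deliberate, fairly
   strict default since the queries of interest are clear homologs).
2. **Containment:** the queried position lies in `[q_start, q_end]` *and*
   the target's annotated position lies in `[t_start, t_end]`. Stages are
   conjunctive and applied in order; containment is required even when the
   tolerance could reach outside the aligned region.
3. **Positional agreement:** the queried position's alignment column is
   within `range` columns (default 0) of the column holding the annotated
   target residue. The tolerance is measured in **alignment columns**:
   gap-robust, and identical to residue offsets in ungapped stretches.
   Candidate columns where the target has a gap are skipped, not counted as
   failures; if the query residue itself sits opposite a target gap, a
   nearby column within the tolerance can still satisfy the stage.

Retained hits are merged by (accession, annotated position, type). A site
present in both sources yields a single row with both evidence lists;
E-value/identity/coverage come from the lowest-E-value contributor
(one-row-per-site semantics; listing every contributing alignment was
rejected as redundant). The report row carries an 11-residue window
(half-width k = 5, the conventional PTM context width; configurable) centred
on the annotated residue, padded with `-` at sequence ends.

Monotonicity holds by construction: hit sets are nested under growing
E-value threshold and growing tolerance.

## Command-line interface

`ptmconserve search` validates arguments in a fixed order — FASTA parses /
accession resolves, position in range, residue compatible with at least one
requested type — and each failure class has its own exit code (2 invalid
FASTA, 3 position, 4 residue, 5 unresolvable accession, 6 missing compiled
database, 7 batch error, 8 configuration). `-m all` expands to every
compiled database in the data directory (not every catalog entry). The TSV
dialect is fixed: UTF-8, LF, no quoting, tabs/newlines in free text replaced
by spaces, list cells semicolon-joined. Batch mode pre-validates the whole
file, then runs entries independently (skip-and-continue on failure), and
each output file is byte-identical to the corresponding single run.

## Synthetic data generator

`make-fixtures` builds what the tests and the acceptance script consume:
families consisting of an ancestor (the query, with a lysine planted at the
site) and homologs derived by seeded point substitutions. Defaults: 20
families of 3 homologs, lengths 60–120, 85% identity, acetylation, site
placements cycling conserved / shifted-by-1 / shifted-by-2 / absent
(annotation planted 12 residues away), sources cycling CPLM / dbPTM / both.
These sizes keep one full pipeline pass under a couple of seconds while
giving every placement/source combination multiple instances.

Because homologs contain substitutions only (no indels), the optimal local
alignment is ungapped, and the expected filter outcome at every tolerance is
known *without running the aligner*: shifted-by-s is retained iff the
tolerance is ≥ s. At 85% identity and length ≥ 60 the self-family alignments
score far past the E ≤ 0.01 stage, so the truth table is exact. Gapped
position mapping is exercised separately by hand-written alignment fixtures.

What the generator does **not** emulate: realistic residue composition
(sequences are uniform over the 20 amino acids), indels, paralogy, shared
domains between families, or real evidence codes. Passing tests therefore
demonstrate the correctness of the machinery — parsing, codec, alignment,
mapping, filtering, merging, reporting — not retrieval performance on real
databases, where homology detection difficulty and annotation noise
dominate.

## Numerical and degenerate-input choices

- All positions are 1-based and inclusive throughout (the convention of the
  source databases and of user-facing coordinates).
- Alignment scores are integers; E-value comparisons are exact floating
  point with no epsilon (the filter is a strict ≤).
- Empty databases search to an empty hit list; an empty result still writes
  the TSV header and exits 0.
- `local_align` returns no HSP when the best score is ≤ 0.
- Identity is computed over alignment columns (gaps count as mismatched
  columns); coverage is the aligned fraction of the query.

## Known limitations

- Fixed Karlin–Altschul parameters (not estimated per matrix/gap setting):
  E-values shift accordingly for non-default schemes.
- Single best HSP per entry can miss a conserved site when a protein's
  better-scoring alignment covers a different region than the site.
- The positional tolerance in alignment columns can differ from a
  target-coordinate tolerance in heavily gapped regions; column units were
  chosen as the gap-robust interpretation.
- The full DP is quadratic per entry; for databases far beyond fixture scale
  the BLAST+ backend is the practical choice.
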