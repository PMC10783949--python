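# ptmconserve

**ptmconserve** answers a question that comes up after every proteomics
experiment that maps post-translational modifications (PTMs): *has the
modification I just found — this residue, in this protein — been reported
before, in this or any other species?* Large PTM resources (CPLM-style lysine
modification compendia, dbPTM-style multi-residue collections) are usually
searchable by protein, not by residue, so assessing the novelty and
cross-species conservation of hundreds of freshly identified sites is tedious.
ptmconserve makes it a one-line query for experimentalists and pipeline
builders alike.

## How it works

1. **Compile.** Database dumps (one row per modification site) are converted
   into one annotated multi-FASTA per modification type. All per-site
   metadata — accession, site position, modification type, source database,
   species, evidence — is stored *in the FASTA header itself*
   (`accession|position|mod_type|source|source_id key=value ...`, values
   percent-escaped), so no lookup beyond the search result is ever needed.
2. **Align.** The query protein is aligned against every database entry with
   an exact Smith–Waterman/Gotoh local aligner (BLOSUM62, gap existence 11,
   extension 1). Each high-scoring pair (HSP) gets a Karlin–Altschul
   expectation value E = *K·m·n·e^(−λS)* with the standard gapped parameters
   λ = 0.267, K = 0.041 (*m* = query length, *n* = total database residues).
   NCBI BLAST+ can be used as a drop-in external backend when installed.
3. **Filter.** HSPs pass three stages: (i) E ≤ threshold; (ii) the queried
   position and the database site both lie inside the aligned region;
   (iii) the queried position's alignment column is within a user-chosen
   tolerance (in alignment columns, default 0) of the column holding the
   annotated residue.
4. **Report.** Surviving hits are merged into one TSV row per
   (protein, site, modification type): a site known to both sources appears
   once, with both evidence lists, an 11-residue sequence window centred on
   the modified residue, and the E-value/identity/coverage of its best
   alignment.

A seeded synthetic-data generator (`ptmconserve make-fixtures`) builds toy
databases of homolog families with planted conserved, shifted and absent
sites at controlled identity, with a machine-readable truth table — so the
whole pipeline is testable offline.

## Worked example

The package ships a small synthetic fixture mimicking a cross-species lookup:
a TatA-like query protein acetylated at K66, and a homolog at ~85% identity
carrying the same acetylation at the aligned residue (both sequences are
random — labelled synthetic — but the shapes match a real use case).

```bash
cd $(python -c "import ptmconserve, pathlib; print(pathlib.Path(ptmconserve.__file__).parent/'data')")
ptmconserve compile --cplm synthetic_tata_cplm.tsv --data-dir /tmp/db
ptmconserve search --id SYNQ_TATA -p 66 -m acetylation -o /tmp/tata.tsv \
    --data-dir /tmp/db --provider-dir .
cat /tmp/tata.tsv
```

Output (one header line, one hit):

```
accession	protein_name	mod_type	position	window	species	evalue	identity_pct	coverage_pct	cplm_id	cplm_evidence	dbptm_evidence
SYNH_TATA	synthetic TatA-like homolog (acetylated K66)	acetylation	66	PVHFGKRRDLY	Synthetic organism B	3.42e-48	86.4	98.9	CPLMSYN001	PMID:0000001
```

Reading the row: the queried K66 aligns exactly (tolerance 0) to an
acetylated K66 of `SYNH_TATA`; the local alignment has E-value 3.4×10⁻⁴⁸,
86.4% identity and covers 98.9% of the query; `PVHFGKRRDLY` is the
11-residue window centred on the modified lysine; the evidence column points
at the source record. An empty result writes the header line only and exits 0.

Batch mode (`--batch sites.tsv`, lines `accession<TAB>position[<TAB>mods]`)
runs every entry with the shared options and writes one
`<accession>_<position>.tsv` per line; failing entries are reported and
skipped.

## Limitations

- E-values follow the closed Karlin–Altschul form with fixed parameters; they
  are consistent for thresholding but not identical to BLASTp's
  composition-adjusted values.
- One best HSP per database entry; no low-complexity masking.
- Conservation is presence/absence at a position — no window similarity or
  phylogenetic weighting.
- No download client for live databases; sequence resolution goes through a
  pluggable offline provider (directory of FASTA files or in-memory map).

See `docs/methods.md` for the full model description and design rationale.
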