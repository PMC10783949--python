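import dataclasses
from types import SimpleNamespace

import pytest

import ptmconserve as pc

#: Seed of the shared synthetic database used across the suite.
FIXTURE_SEED = 1234


@pytest.fixture(scope="session")
def catalog():
    return pc.ModificationCatalog.default()


def query_for(family: pc.Family, **overrides) -> pc.QuerySpec:
    defaults = dict(
        accession=family.query_accession,
        sequence=family.query_sequence,
        position=family.site_position,
        mod_types=frozenset({family.mod_type}),
        evalue_threshold=0.01,
        range=0,
    )
    defaults.update(overrides)
    return pc.QuerySpec(**defaults)


def requery(query: pc.QuerySpec, **overrides) -> pc.QuerySpec:
    return dataclasses.replace(query, **overrides)


@pytest.fixture(scope="session")
def pipeline(tmp_path_factory):
    """Full synthetic pipeline: 20 families generated, dumped, compiled and
    searched once; HSP lists are cached per family for re-filtering."""
    tmp = tmp_path_factory.mktemp("pipeline")
    spec, families, truth, paths = pc.make_fixture(tmp, seed=FIXTURE_SEED, n_families=20)
    provider = pc.DirectoryProvider(paths["provider_dir"])
    dbs, report = pc.build_databases(
        tmp / "data", paths["cplm_dump"], paths["dbptm_dump"], provider
    )
    db = dbs[spec.mod_type]
    hsps = {
        family.index: pc.search_database(query_for(family), db)
        for family in families
    }
    return SimpleNamespace(
        spec=spec,
        families=families,
        truth=truth,
        paths=paths,
        provider=provider,
        dbs=dbs,
        db=db,
        report=report,
        hsps=hsps,
        data_dir=tmp / "data",
    )
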