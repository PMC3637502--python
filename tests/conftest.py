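from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from estmine.io_formats import MatureMirna
from estmine.published import candidate_mirna_table


@pytest.fixture(scope="session")
def published_table():
    return candidate_mirna_table()


@pytest.fixture(scope="session")
def published_matures(published_table):
    return [
        MatureMirna(id=n, seq=s)
        for n, s in zip(published_table["name"], published_table["mature_seq"])
    ]


@pytest.fixture(scope="session")
def published_records(published_table):
    from estmine.hairpin_eval import MirnaRecord

    return [
        MirnaRecord(
            name=r.name_,
            query_mirna=r.query_mirna,
            mature_len=int(r.mature_len),
            mature_seq=r.mature_seq,
            n_mismatches_to_query=int(r.n_mismatches),
            arm=r.arm,
            gc_percent=float(r.gc_percent),
            precursor_len=int(r.precursor_len),
            mfe_abs=float(r.mfe_abs),
            mfei=float(r.mfei),
            source_read=r.source_read,
        )
        for r in published_table.rename(columns={"name": "name_"}).itertuples()
    ]


@pytest.fixture(scope="session")
def study_collection():
    """One seeded reference-condition collection shared by the end-to-end tests."""
    from estmine.synthetic_data import default_study_config, simulate_collection

    config = default_study_config(seed=11)
    reads, truth, fixtures = simulate_collection(config)
    return config, reads, truth, fixtures
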