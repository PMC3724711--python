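import io

import pytest

import motif_localize as ml
from motif_localize.synth import generate


@pytest.fixture(scope="session")
def vocab():
    return ml.CompartmentVocabulary.default("twelve")


@pytest.fixture(scope="session")
def demo_data():
    """A mixed synthetic cohort: planted and null motifs of both kinds."""
    return generate(ml.demo_config(seed=3, n_proteins=1000, n_motifs=24))


@pytest.fixture(scope="session")
def demo_records(demo_data):
    return ml.parse_swissprot(io.StringIO(demo_data.swissprot_text))


@pytest.fixture(scope="session")
def demo_dataset(demo_records, vocab):
    return ml.build_dataset(demo_records, vocab)


@pytest.fixture(scope="session")
def demo_motifs(demo_data, demo_records):
    alias = ml.build_alias_index(demo_records)
    return ml.parse_prosite(io.StringIO(demo_data.prosite_text), alias_index=alias)


def make_dataset(assignments, vocab):
    """Dataset literal helper for unit tests."""
    return ml.LocalizationDataset(
        assignments={a: frozenset(c) for a, c in assignments.items()},
        vocab=vocab,
        mode="multiple",
    )


def make_motif(tp=(), fp=(), kind="pattern", accession="PS00001", name="TEST"):
    return ml.MotifRecord(
        accession=accession,
        name=name,
        kind=kind,
        tp_accessions=frozenset(tp),
        fp_accessions=frozenset(fp),
    )
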