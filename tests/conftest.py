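import pytest

from mousehotel import (
    Lexicon,
    PhantomSpec,
    UidGenerator,
    build_acquisition_context_tree,
    build_patient_module,
    make_phantom_volume,
    sr_tree_to_dataset,
    worked_example_record,
)


@pytest.fixture(scope="session")
def lexicon():
    return Lexicon.default()


@pytest.fixture()
def record():
    return worked_example_record()


@pytest.fixture()
def sr_dataset(record, lexicon):
    """A complete worked-example SR dataset (seeded UIDs)."""
    tree = build_acquisition_context_tree(record, lexicon)
    patient = build_patient_module(record, lexicon)
    return sr_tree_to_dataset(tree, patient, UidGenerator(11))


@pytest.fixture()
def phantom():
    """Default 2x2 axial phantom with its ground truth."""
    return make_phantom_volume(PhantomSpec(seed=42))


def normalized_fields(rec, lexicon):
    """Record fields as a dict with the strain code resolved.

    Building an SR materializes the strain code from the lexicon, so a
    record that left ``strain_code`` unset compares equal to its round-trip
    after resolution.
    """
    out = dict(vars(rec))
    if out["strain_code"] is None and out["strain_description"]:
        out["strain_code"] = lexicon.lookup_optional(out["strain_description"], "strain")
    return out
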