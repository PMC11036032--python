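import pandas as pd
import pytest

from foragekit.alignment import align_streams, build_unified_dataset, concat_datasets
from foragekit.hci_stream import hci_to_source, parse_hci_source
from foragekit.rock_io import parse_source
from foragekit.synthetic_data import SimConfig, generate_corpus

TABLE_MOCK_SCENT = pd.DataFrame(
    [[0, 0, 0, -1], [0, 0, 0, 1], [1, -1, 1, 1], [0, 1, 0, 1], [1, 1, -1, 0]],
    index=[f"patch_{i}" for i in range(1, 6)],
    columns=["A", "B", "C", "D"],
)


def unify_bundle(bundle, strict=True):
    """Parse one synthetic session's three streams and build its table."""
    ta = parse_source(bundle.think_aloud_text, "think_aloud", bundle.case_id)
    stim = parse_source(bundle.stimulus_text, "stimulus", bundle.case_id)
    hci = hci_to_source(parse_hci_source(bundle.hci_text, bundle.case_id), bundle.case_id)
    aligned = align_streams(ta, [hci, stim])
    return build_unified_dataset(
        aligned, bundle.case_attributes, bundle.patch_attributes, strict=strict
    )


def unify_corpus(bundles):
    return concat_datasets([unify_bundle(b) for b in bundles])


@pytest.fixture(scope="session")
def small_corpus():
    """Three cases per subsample, fixed seed."""
    return generate_corpus(SimConfig(seed=42, n_cases_per_group=3))


@pytest.fixture(scope="session")
def small_unified(small_corpus):
    return unify_corpus(small_corpus)
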