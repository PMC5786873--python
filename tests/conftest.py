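import numpy as np
import pytest

from chemoqsar import (
    CompoundRecord,
    DescriptorSynthConfig,
    LabeledTable,
    load_fixture,
    simulate_descriptor_table,
)
from chemoqsar.core_data import DescriptorDictionary, DescriptorEntry


def make_table(values_by_descriptor, labels, **extras):
    """Build a LabeledTable from {descriptor: values} and 0/1 labels."""
    names = tuple(values_by_descriptor)
    n = len(labels)
    schema = DescriptorDictionary(tuple(DescriptorEntry(d, d, "") for d in names))
    records = []
    for i in range(n):
        records.append(CompoundRecord(
            serial_id=i + 1,
            name=f"c{i + 1}",
            label="attractant" if labels[i] == 1 else "non_attractant",
            descriptors={d: float(values_by_descriptor[d][i]) for d in names},
            **{k: v[i] for k, v in extras.items()},
        ))
    return LabeledTable(records, names, schema=schema).validate()


@pytest.fixture(scope="session")
def table4():
    return load_fixture("table4_aspartate")


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1_correlations")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2_summaries")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def default_synthetic_table():
    return simulate_descriptor_table(DescriptorSynthConfig(seed=11))
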