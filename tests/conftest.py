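import numpy as np
import pytest

from ntckit.classify import load_default_table, load_ntc_table
from ntckit.fixtures import (
    FragmentSpec,
    build_oligonucleotide,
    make_test_table,
    write_table_csv,
)


@pytest.fixture(scope="session")
def table96():
    return load_default_table()


@pytest.fixture(scope="session")
def table3(tmp_path_factory):
    path = tmp_path_factory.mktemp("tables") / "small.csv"
    write_table_csv(make_test_table(3, seed=42), path)
    return load_ntc_table(path, allow_small=True)


@pytest.fixture(scope="session")
def oligo_factory(table96):
    """Build an RNA/DNA oligonucleotide from a sequence of NtC class names."""

    def build(class_names, sequence=None, **kwargs):
        table = kwargs.pop("table", table96)
        if sequence is None:
            sequence = ("GACU" * 10)[: len(class_names) + 1]
        spec = FragmentSpec(
            sequence=sequence,
            step_params=[table[n].means for n in class_names],
            **kwargs,
        )
        return build_oligonucleotide(spec)

    return build


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
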