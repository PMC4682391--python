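import numpy as np
import pytest
from hypothesis import settings

from seqaffinity.encoding import ComplexRecord, encode_dataset, fit_scaling
from seqaffinity.properties import AMINO_ACIDS, builtin_tables
from seqaffinity.synthetic import GeneratorSpec, generate_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tables3():
    return builtin_tables()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_record(rng, complex_id="CPX", la=120, lb=150) -> ComplexRecord:
    aa = list(AMINO_ACIDS)
    return ComplexRecord(
        complex_id,
        "".join(rng.choice(aa, la)),
        "".join(rng.choice(aa, lb)),
    )


@pytest.fixture(scope="session")
def planted_small():
    """Small planted dataset shared by selection/importance tests:
    60 candidate properties, 3 informative, n=120 complexes."""
    spec = GeneratorSpec(
        n_complexes=120, n_properties=60, n_informative=3, effect_size=2.0, seed=7
    )
    records, tables, truth = generate_dataset(spec)
    labels = [r.label for r in records]
    matrix = encode_dataset(records, tables)
    return {
        "records": records,
        "tables": tables,
        "truth": truth,
        "labels": labels,
        "matrix": matrix,
        "scaled": fit_scaling(matrix),
    }
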