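import pandas as pd
import pytest

from hptmkit import (
    AbundanceMatrix,
    default_registry,
    digest,
    load_packaged_variants,
)

SAMPLES_2 = ["P0_R1", "P12_R1"]


@pytest.fixture(scope="session")
def h3_variants():
    return {v.name: v for v in load_packaged_variants("h3")}


@pytest.fixture(scope="session")
def h4_variant():
    (v,) = load_packaged_variants("h4")
    return v


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def peptide_27_40(h3_variants):
    (p,) = [q for q in digest(h3_variants["H31"], 0) if q.span == (27, 40)]
    return p


def make_matrix(rows: dict[str, list[float]], samples=None) -> AbundanceMatrix:
    """Build a small AbundanceMatrix from {descriptor: per-sample values}."""
    samples = samples or SAMPLES_2[: len(next(iter(rows.values())))]
    table = pd.DataFrame(rows, index=samples).T
    return AbundanceMatrix.from_wide(table)


@pytest.fixture()
def k27_pool_matrix():
    # one backbone pool (27-40) on H31/H32: unmodified 70, K27me3 30
    return make_matrix(
        {
            "H3 H31/H32 27-40 unmod": [70.0, 70.0],
            "H3 H31/H32 27-40 K27me3": [30.0, 30.0],
        }
    )
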