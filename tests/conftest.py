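import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from clipview.fixtures import FixtureSpec, make_fixture
from clipview.io import GenomicRegion, load_annotation, resolve_region


@pytest.fixture(scope="session")
def fixture_dataset(tmp_path_factory):
    """The standard synthetic dataset: 4 crosslink tracks in 2 groups,
    BED9 auxiliary feature, 3 coverage groups, multi-isoform GTF."""
    out = tmp_path_factory.mktemp("fixture_data")
    return make_fixture(FixtureSpec(seed=1), str(out))


@pytest.fixture(scope="session")
def annotation_db(fixture_dataset):
    return load_annotation(fixture_dataset["gtf"])


@pytest.fixture(scope="session")
def gene_region(annotation_db):
    return resolve_region(annotation_db, "CD55-like")


@pytest.fixture()
def region():
    """A plain stranded window, independent of any annotation."""
    return GenomicRegion("chr1", 100, 600, "+", "test-region")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return str(path)
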