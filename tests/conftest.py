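import numpy as np
import pytest

from mutyhtms import reduce_catalog, synthetic_catalog
from mutyhtms.catalog import SignatureCatalog, write_catalog
from mutyhtms.simulate import write_toy_reference


@pytest.fixture(scope="session")
def catalog():
    """The deterministic synthetic 14-signature catalog."""
    return synthetic_catalog()


@pytest.fixture(scope="session")
def small3(catalog):
    """Three-signature basis small enough for the grid-search oracle."""
    return reduce_catalog(catalog, ["SBS1", "SBS5", "SBS18"])


@pytest.fixture(scope="session")
def ber_pair(catalog):
    """Two-column fixture catalog with the BER-like signatures renamed."""
    import pandas as pd

    df = catalog.profiles[["SBS18", "SBS36"]].copy()
    df.columns = ["SBS18f", "SBS36f"]
    return SignatureCatalog(df)


@pytest.fixture(scope="session")
def fixture_tsv(tmp_path_factory, ber_pair):
    """The two-signature fixture written in the canonical TSV dialect."""
    path = tmp_path_factory.mktemp("catalog") / "ber_fixture.tsv"
    write_catalog(ber_pair, path)
    return path


@pytest.fixture(scope="session")
def toy_reference(tmp_path_factory):
    import pyfaidx

    path = write_toy_reference(tmp_path_factory.mktemp("ref") / "toy.fa", length=60_000, seed=11)
    return pyfaidx.Fasta(str(path))
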