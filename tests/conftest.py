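import pytest

from beehap.classify import default_reference_db
from beehap.synthetic_locus import build_canonical, canonical_names
from beehap.templates import build_default_templates


@pytest.fixture(scope="session")
def library():
    return build_default_templates(seed=1)


@pytest.fixture(scope="session")
def refdb(library):
    return default_reference_db(library)


@pytest.fixture(scope="session")
def canonicals(library):
    """Canonical synthetic amplicon for every supported haplotype."""
    return {
        name: build_canonical(name, library=library)
        for name in canonical_names()
    }
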