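import pytest

from regulink import pipeline
from regulink.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic bundle (written to disk once per session)."""
    out = tmp_path_factory.mktemp("bundle")
    return simulate(SimConfig(seed=1), out)


@pytest.fixture(scope="session")
def scored(bundle):
    """Linkage scoring of the planted elements of the default bundle."""
    return pipeline.score_cnes(bundle.planted_cnes, bundle.families,
                               bundle.species_meta)


@pytest.fixture(scope="session")
def scan_result(bundle):
    """Scanner output on the default bundle's alignment."""
    return pipeline.scan_maf(bundle.paths["maf"], bundle.species_meta,
                             bundle.exons, bundle.repeats)
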