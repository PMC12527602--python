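import warnings

import pytest

from cohortmatch.models import Ontology
from cohortmatch.pipeline import Bundle, load_bundle
from cohortmatch.synthetic import SimConfig, generate, validation_suite_config


@pytest.fixture(scope="session")
def chain_ontology() -> Ontology:
    """root <- A <- B <- C plus a sibling D of B."""
    return Ontology(
        {
            "HP:0000001": frozenset(),
            "HP:0000002": frozenset(["HP:0000001"]),  # A
            "HP:0000003": frozenset(["HP:0000002"]),  # B
            "HP:0000004": frozenset(["HP:0000003"]),  # C
            "HP:0000005": frozenset(["HP:0000002"]),  # D
        }
    )


@pytest.fixture(scope="session")
def standard_bundle_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("standard_bundle")
    generate(SimConfig(seed=7), out)
    return out


@pytest.fixture(scope="session")
def standard_bundle(standard_bundle_dir) -> Bundle:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return load_bundle(standard_bundle_dir)


@pytest.fixture(scope="session")
def validation_bundle_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("validation_bundle")
    generate(validation_suite_config(seed=11), out)
    return out


@pytest.fixture(scope="session")
def validation_bundle(validation_bundle_dir) -> Bundle:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return load_bundle(validation_bundle_dir)
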