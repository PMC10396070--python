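import numpy as np
import pytest

from cutext import load_packaged_dictionary, load_profiles
from cutext.dictionary import CUDictionary, CUEntry


@pytest.fixture(scope="session")
def picnic():
    return load_packaged_dictionary()


@pytest.fixture(scope="session")
def profiles():
    return load_profiles("paper_tables")


@pytest.fixture(scope="session")
def written_profiles():
    return load_profiles("paper_tables_written")


@pytest.fixture()
def toy_dict():
    """Three-entry dictionary: unambiguous dog/girl-daughter, ambiguous run."""
    return CUDictionary(
        scene_name="toy",
        entries=[
            CUEntry(1, "dog", "entity", "unambiguous",
                    frozenset({("dog", "noun")})),
            CUEntry(2, "girl/daughter", "entity", "unambiguous",
                    frozenset({("girl", "noun"), ("daughter", "noun")})),
            CUEntry(3, "run", "action", "ambiguous",
                    frozenset({("run", "verb")})),
        ],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
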