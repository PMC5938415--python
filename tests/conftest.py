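import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _published module

from ratlas import detect_features, load_bundled_registry
from ratlas.synth import StackSpec, make_stack


@pytest.fixture(scope="session")
def registry():
    return load_bundled_registry()


@pytest.fixture(scope="session")
def registry_as_printed():
    return load_bundled_registry(as_printed=True)


#: Pinned stack emulating a 40-plate atlas tissue series; shared between the
#: ranking tests and the end-to-end experiment analogues (feature detection
#: over the stack is the expensive step, so it runs once per session).
PINNED_STACK_SPEC = StackSpec(seed=11)


@pytest.fixture(scope="session")
def pinned_stack():
    return make_stack(PINNED_STACK_SPEC)


@pytest.fixture(scope="session")
def pinned_stack_features(pinned_stack):
    return [
        detect_features(image, str(level))
        for level, image in enumerate(pinned_stack)
    ]
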