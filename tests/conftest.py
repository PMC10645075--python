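"""Shared fixtures: the two hand-checkable reference networks.

Toy-CHAIN: in -> n1 (1.0); n1 -> n2 (0.5), n1 -> out (0.5); n2 -> out (1.0).
Toy-CYCLE: same but n2 splits its outflow: n2 -> n1 (0.5), n2 -> out (0.5).

Node convention everywhere: core 0..N-1, input N, output N+1.
"""

import numpy as np
import pytest

from flownetevo import FCDN


def _toy(kind: str) -> FCDN:
    a = np.zeros((4, 4))
    a[2, 0] = 1.0  # in -> n1
    a[0, 1] = 0.5  # n1 -> n2
    a[0, 3] = 0.5  # n1 -> out
    if kind == "chain":
        a[1, 3] = 1.0
    else:
        a[1, 0] = 0.5
        a[1, 3] = 0.5
    return FCDN(a)


@pytest.fixture
def toy_chain() -> FCDN:
    return _toy("chain")


@pytest.fixture
def toy_cycle() -> FCDN:
    return _toy("cycle")
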