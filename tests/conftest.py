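"""Shared fixtures: everything is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from ribodomain.contacts import detect_all
from ribodomain.synthetic import (AssemblySpec, HelixSpec, MgSite,
                                  build_aform_duplex, build_assembly)


@pytest.fixture(scope="session")
def duplex8():
    """Ideal 8-bp A-form duplex with ground truth."""
    return build_aform_duplex("GGCAUGCC")


@pytest.fixture(scope="session")
def duplex8_contacts(duplex8):
    model, _ = duplex8
    return detect_all(model)


@pytest.fixture(scope="session")
def three_helix_assembly():
    """Three placed helices, two planted domains, one Mg bridge across them."""
    from ribodomain.domains import DomainDefinition

    spec = AssemblySpec(
        helices=[HelixSpec("GGCAUC", start_i=1, start_j=30),
                 HelixSpec("AGGCCU", start_i=60, start_j=90),
                 HelixSpec("UUCGAA", start_i=120, start_j=150)],
        planted_domains=[DomainDefinition("D1", ((1, 59),)),
                         DomainDefinition("D2", ((60, 200),))],
        mg_sites=[MgSite(partners=(("A", 6), ("A", 60)), distance=2.1)],
        seed=3)
    return build_assembly(spec)


def random_assembly(seed: int, n_helices=None, rng=None):
    """A clash-free multi-helix assembly with seeded random sequences/placement."""
    rng = rng or np.random.default_rng(seed)
    n_h = int(n_helices or rng.integers(2, 6))
    helices, start = [], 1
    for _ in range(n_h):
        length = int(rng.integers(3, 10))
        seq = "".join(rng.choice(list("ACGU"), size=length))
        helices.append(HelixSpec(seq, start_i=start, start_j=start + length + 5))
        start += 2 * length + 15
    return build_assembly(AssemblySpec(helices=helices,
                                       seed=int(rng.integers(2 ** 31))))
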