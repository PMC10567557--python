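"""Shared fixtures: a deterministic synthetic target site and contexts.

A single module-level site is reused across tests so that structure
background caches (keyed by length and context) are shared within the
test process.
"""

from __future__ import annotations

import numpy as np
import pytest

from peginsert.core import InsertSequence, ScreenContext, TargetSite, make_design

# Deterministic synthetic locus: 30 nt upstream / 70 nt downstream of the nick.
_RNG = np.random.default_rng(2023)
_BASES = np.array(list("ACGT"))
SITE = TargetSite(
    name="synthetic_site",
    flank_up="".join(_RNG.choice(_BASES, size=30)),
    flank_down="".join(_RNG.choice(_BASES, size=70)),
)

CTX_MMR_DEFICIENT = ScreenContext(
    "screen_def", "HEK293T-like", mmr_proficient=False, replicate="r1"
)
CTX_MMR_PROFICIENT = ScreenContext(
    "screen_prof", "HAP1-like", mmr_proficient=True, replicate="r1"
)


@pytest.fixture(scope="session")
def site() -> TargetSite:
    return SITE


@pytest.fixture(scope="session")
def ctx_deficient() -> ScreenContext:
    return CTX_MMR_DEFICIENT


@pytest.fixture(scope="session")
def ctx_proficient() -> ScreenContext:
    return CTX_MMR_PROFICIENT


@pytest.fixture()
def design_for(site):
    """Factory: a default-geometry design for a written insert sequence."""

    def _make(seq: str, ins_id: str = "ins"):
        return make_design(InsertSequence(ins_id, seq), site)

    return _make


def random_insert(rng: np.random.Generator, length: int, ins_id: str) -> InsertSequence:
    return InsertSequence(ins_id, "".join(rng.choice(_BASES, size=length)))
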