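import math

import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from pte_risk.core_data import (
    ELEMENTS,
    BatchRecord,
    Category,
    Element,
    default_exposure,
    default_toxicity,
)


def make_record(
    batch_id="B001",
    material="Pheretima",
    category=Category.ANIMAL,
    conc=None,
    nd=(),
):
    """Build a BatchRecord from a {element: value} mapping; elements in ``nd``
    are marked non-detected (value unset)."""
    conc = conc or {}
    full = {}
    detected = {}
    for e in ELEMENTS:
        if e in nd or e.value in nd:
            full[e] = math.nan
            detected[e] = False
        else:
            full[e] = float(conc.get(e, conc.get(e.value, 0.0)))
            detected[e] = True
    return BatchRecord(
        batch_id=batch_id, material=material, category=category, conc=full, detected=detected
    )


@pytest.fixture
def exposure():
    return default_exposure()


@pytest.fixture
def toxicity():
    return default_toxicity()
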