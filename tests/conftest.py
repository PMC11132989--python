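import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from socdiff.data_model import EventLog, ILVTable, Individual

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_ilv() -> ILVTable:
    """Two groups; one trained demonstrator each; varied sex/age/rank."""
    inds = [
        Individual("D1", 1, 0, 25.0, 8.0, trained=True),
        Individual("A", 1, 0, 20.0, 5.0),
        Individual("B", 1, 1, 30.0, 9.0),
        Individual("C", 1, 0, 12.0, 2.0),
        Individual("D2", 2, 0, 28.0, 7.0, trained=True),
        Individual("E", 2, 1, 18.0, 4.0),
        Individual("F", 2, 0, 35.0, 6.0),
    ]
    return ILVTable(inds, kin_pairs=[("A", "C")])


@pytest.fixture
def toy_log() -> EventLog:
    """Small diffusion: A learns socially, B after watching A, E asocially."""
    return EventLog(
        solves=[
            (1.0, "D1"), (2.0, "D1"), (3.0, "D1"),
            (4.0, "A"),
            (5.0, "B"),
            (6.0, "E"),
            (7.0, "A"),
        ],
        observations=[
            (1.0, "A", "D1"), (2.0, "A", "D1"), (3.0, "A", "D1"),
            (2.0, "B", "D1"),
            (4.0, "B", "A"),
            (7.0, "C", "A"),
        ],
        first_manipulations=[(0.5, "A"), (2.5, "B"), (5.5, "E"), (6.5, "C")],
    )
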