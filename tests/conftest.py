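"""Shared fixtures: the small worked-example weighted strings."""

import pytest
from hypothesis import HealthCheck, settings

from wtrep import Threshold, WeightedString

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

AB_HALF = {"a": 0.5, "b": 0.5}


@pytest.fixture
def ex2():
    """aab[(a,0.5)(b,0.5)][(a,0.5)(b,0.5)]bab -- 8 positions, two branching."""
    return WeightedString.build(
        [{"a": 1}, {"a": 1}, {"b": 1}, AB_HALF, AB_HALF, {"b": 1}, {"a": 1}, {"b": 1}],
        "ab",
    )


@pytest.fixture
def ex4():
    """[(a,0.6)(c,0.4)]bab[(a,0.6)(d,0.4)]bab -- two grey positions."""
    return WeightedString.build(
        [
            {"a": 0.6, "c": 0.4},
            {"b": 1},
            {"a": 1},
            {"b": 1},
            {"a": 0.6, "d": 0.4},
            {"b": 1},
            {"a": 1},
            {"b": 1},
        ],
        "abcd",
    )


@pytest.fixture
def ex6():
    """aab[(a,0.5)(b,0.5)][(a,0.5)(b,0.5)]ab -- 7 positions, two branching."""
    return WeightedString.build(
        [{"a": 1}, {"a": 1}, {"b": 1}, AB_HALF, AB_HALF, {"a": 1}, {"b": 1}],
        "ab",
    )


@pytest.fixture
def table1():
    """The 11-position DNA example with one black and two grey positions."""
    return WeightedString.build(
        [
            {"A": 1.0},
            {"A": 0.1, "C": 0.8, "G": 0.1, "T": 0.0},
            {"T": 1.0},
            {"T": 1.0},
            {"A": 0.5, "C": 0.5, "G": 0.0, "T": 0.0},
            {"T": 1.0},
            {"C": 1.0},
            {"A": 0.6, "C": 0.2, "G": 0.0, "T": 0.2},
            {"T": 1.0},
            {"T": 1.0},
            {"T": 1.0},
        ],
        "ACGT",
    )


@pytest.fixture
def half():
    return Threshold.from_value(0.5)


@pytest.fixture
def quarter():
    return Threshold.from_value(0.25)
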