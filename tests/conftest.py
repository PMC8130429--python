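"""Shared fixtures: seeded random call sets, a default synthetic scenario
and a small trained classifier for pipeline-level tests."""

from __future__ import annotations

import numpy as np
import pytest

from svenrich.classify import train_classifier
from svenrich.model import Breakend, BreakpointCall, SVClass, Side, canonicalize
from svenrich.simulate import (
    SimScenario,
    simulate_callset,
    simulate_tracks,
    simulate_truthset,
)

CONTIGS = {"chr1": 500_000, "chr2": 500_000, "chr3": 500_000,
           "chrY": 50_000, "chrMT": 16_000}

_CLASS_SIDES = {
    SVClass.DEL: [(Side.LEFT, Side.RIGHT)],
    SVClass.DUP: [(Side.RIGHT, Side.LEFT)],
    SVClass.INV: [(Side.LEFT, Side.LEFT), (Side.RIGHT, Side.RIGHT)],
    SVClass.INS: [(Side.LEFT, Side.RIGHT)],
}

_FILTER_SETS = [("PASS",), ("LowQual",), ("Gap", "SVcluster"), ()]


def make_random_call(rng: np.random.Generator, i: int,
                     contigs=None) -> BreakpointCall:
    """One random, canonical call across all SV classes and filter states."""
    contigs = contigs or CONTIGS
    names = list(contigs)
    cls = SVClass(["DEL", "DUP", "INV", "INS", "TRA"][int(rng.integers(5))])
    if cls is SVClass.TRA:
        ca, cb = rng.choice(len(names), size=2, replace=False)
        ca, cb = names[ca], names[cb]
        pa = int(rng.integers(1_000, contigs[ca] - 1_000))
        pb = int(rng.integers(1_000, contigs[cb] - 1_000))
        sides = (Side.LEFT if rng.random() < 0.5 else Side.RIGHT,
                 Side.LEFT if rng.random() < 0.5 else Side.RIGHT)
    else:
        ca = cb = names[int(rng.integers(len(names)))]
        pa = int(rng.integers(1_000, contigs[ca] - 12_000))
        pb = pa + int(rng.integers(50, 10_000))
        options = _CLASS_SIDES[cls]
        sides = options[int(rng.integers(len(options)))]
    filters = _FILTER_SETS[int(rng.integers(len(_FILTER_SETS)))]
    features = {"support": float(rng.integers(2, 40)),
                "mapq": float(np.round(rng.uniform(0, 60), 3)),
                "read_length": float(rng.integers(200, 50_000)),
                "score": float(np.round(rng.uniform(0, 1), 3))}
    annotations = {"dist_simple_repeat": float(rng.integers(0, 100_000)),
                   "dist_gap": float(rng.integers(0, 100_000)),
                   "dist_segmental_duplication": float(rng.integers(0, 100_000))}
    return canonicalize(BreakpointCall(
        id=f"rnd_{i:05d}",
        end_a=Breakend(ca, pa, sides[0]),
        end_b=Breakend(cb, pb, sides[1]),
        sv_class=cls,
        filter_flags=frozenset(filters),
        caller_features=features,
        annotations=annotations,
    ))


def make_random_calls(seed: int, n: int, contigs=None) -> list:
    rng = np.random.default_rng(seed)
    return [make_random_call(rng, i, contigs) for i in range(n)]


@pytest.fixture(scope="session")
def scenario() -> SimScenario:
    return SimScenario(seed=11)


@pytest.fixture(scope="session")
def tracks(scenario):
    return simulate_tracks(scenario)


@pytest.fixture(scope="session")
def callset(scenario, tracks):
    calls, labels, dbs = simulate_callset(scenario, None, tracks)
    return calls, labels, dbs


@pytest.fixture(scope="session")
def small_model(scenario):
    """Classifier trained at reduced size for fast pipeline tests."""
    labelset = simulate_truthset(SimScenario(seed=11, n_truth=400))
    model, curve, metrics = train_classifier(
        labelset, seed=11, n_bootstrap=10, n_estimators=100)
    return model


@pytest.fixture(scope="session")
def random_reference():
    rng = np.random.default_rng(29)
    bases = np.array(list("ACGT"))
    return {f"chr{i}": "".join(bases[rng.integers(0, 4, 30_000)])
            for i in (1, 2)}
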