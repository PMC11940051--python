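import numpy as np
import pytest

from lrgat.config import RunConfig
from lrgat.model import CellCommunication
from lrgat.prior import PriorBundle
from lrgat.synthetic import fixture_small


@pytest.fixture(scope="session")
def tiny_bundle() -> PriorBundle:
    return PriorBundle(
        lr_pairs=frozenset({("TGFB1", "TGFBR1"), ("TNF", "TNFRSF1A"), ("A", "B")}),
        ppi_pairs=frozenset({("A", "B"), ("B", "C")}),
        complexes={
            "C1": frozenset({"A", "B"}),
            "C2": frozenset({"A", "B", "C"}),
            "C3": frozenset({"A"}),
        },
        pathways={"P1": frozenset({"A", "B"}), "P2": frozenset({"B", "C"})},
    )


@pytest.fixture(scope="session")
def small_fixture():
    return fixture_small(seed=0)


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    return RunConfig.small()


@pytest.fixture(scope="session")
def fitted(small_fixture, small_config):
    """One fitted pipeline on the tiny world, shared across tests."""
    model = CellCommunication(small_fixture.data, small_fixture.bundle, small_config)
    return model.fit(seed=0)


def random_bundle(rng: np.random.Generator, n_symbols=12, n_complexes=8, n_pathways=6):
    symbols = [f"S{i}" for i in range(n_symbols)]
    lig, rec = symbols[: n_symbols // 2], symbols[n_symbols // 2 :]
    lr = {(l, r) for l, r in zip(lig, rec)}
    complexes = {}
    for k in range(n_complexes):
        size = rng.integers(1, 5)
        complexes[f"C{k}"] = frozenset(rng.choice(symbols, size=size, replace=False))
    pathways = {}
    for k in range(n_pathways):
        size = rng.integers(1, 6)
        pathways[f"P{k}"] = frozenset(rng.choice(symbols, size=size, replace=False))
    return PriorBundle(
        lr_pairs=frozenset(lr),
        ppi_pairs=frozenset(),
        complexes=complexes,
        pathways=pathways,
    )
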