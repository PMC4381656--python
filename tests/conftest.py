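import warnings

import pytest

from oncovote.synthetic import (benchmark_study, make_benchmark, null_config,
                                strong_signal_config)

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def strong_study():
    """Full strong-signal benchmark study with a 20% label hold-out.

    Session-scoped: the generator, feature pipeline, cross-validation and
    hold-out predictions run once and are shared by every test that needs
    a realistic separable benchmark.
    """
    return benchmark_study(strong_signal_config(seed=0))


@pytest.fixture(scope="session")
def null_study():
    """Label-independent (enrichment=1, equal wiring) benchmark realization."""
    ds, ctx = make_benchmark(null_config(seed=0))
    return {"dataset": ds, **ctx}


@pytest.fixture()
def toy_network():
    """Six proteins, two of them cancer, with mixed edge classes."""
    from oncovote.io_data import network_from_edges

    edges = [("A", "B"), ("A", "C"), ("B", "C"), ("C", "D"),
             ("D", "E"), ("E", "F"), ("B", "E")]
    return network_from_edges(edges, cancer=["A", "B"])


@pytest.fixture()
def toy_annotations():
    from oncovote.io_data import annotations_from_mapping

    return annotations_from_mapping({
        "A": ["d1", "d2"], "B": ["d1"], "C": ["d3"],
        "D": ["d2", "d3"], "E": ["d4"], "F": ["d1", "d4"],
    })
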