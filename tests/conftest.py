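import collections

import numpy as np
import pytest

from rocirc.simulate import SimConfig, simulate_dataset


class StubRNG:
    """Deterministic stand-in for numpy Generator: feeds preset uniforms."""

    def __init__(self, uniforms):
        self._u = list(uniforms)

    def random(self, size=None):
        if size is None:
            return self._u.pop(0)
        return np.array([self._u.pop(0) for _ in range(size)])

    def integers(self, *args, **kwargs):  # pragma: no cover - not used by stubs
        raise NotImplementedError


@pytest.fixture
def stub_rng():
    return StubRNG


@pytest.fixture(scope="session")
def small_dataset():
    """20 single-isoform circRNAs at average depth 10, error-free."""
    cfg = SimConfig(n_circ=20, depth_D=10.0, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset_paths(small_dataset, tmp_path_factory):
    from rocirc.simulate import write_dataset

    outdir = tmp_path_factory.mktemp("smallsim")
    return write_dataset(small_dataset, str(outdir))


def truth_by_circ(result):
    """Map circ_id -> {chain: template} and circ_id -> total abundance."""
    chains = collections.defaultdict(dict)
    totals = collections.defaultdict(float)
    for t in result.templates:
        chains[t.circ_id][tuple(t.cirexons)] = t
        totals[t.circ_id] += t.true_abundance
    return chains, totals
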