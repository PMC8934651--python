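import numpy as np
import pytest

from cracpipe.synthetic import (
    SimulationConfig,
    simulate_crac_reads,
    simulate_rnaseq,
    simulate_transcriptome,
)


class Bundle:
    """A simulated dataset plus everything derived from it once per session."""

    def __init__(self, cfg, tset, genome, truth, sam_path, rnaseq):
        self.cfg = cfg
        self.tset = tset
        self.genome = genome
        self.truth = truth
        self.sam_path = sam_path
        self.rnaseq = rnaseq


def _make_bundle(tmp_path, cfg):
    rng = np.random.default_rng(cfg.seed)
    tset, genome, truth = simulate_transcriptome(cfg, rng)
    sam = tmp_path / "crac.sam"
    simulate_crac_reads(tset, truth, cfg, sam, rng)
    rnaseq = simulate_rnaseq(tset, truth, cfg, rng)
    return Bundle(cfg, tset, genome, truth, sam, rnaseq)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A 40-gene simulation for fast unit tests."""
    cfg = SimulationConfig(n_genes=40, seed=1234)
    return _make_bundle(tmp_path_factory.mktemp("small_sim"), cfg)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The full default-condition simulation (200 genes) for recovery tests."""
    cfg = SimulationConfig(seed=20260)
    return _make_bundle(tmp_path_factory.mktemp("default_sim"), cfg)
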