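"""Shared fixtures: one default synthetic dataset reused across modules."""

import numpy as np
import pytest

import nmiscape as nm


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition simulation (seed 1): 1 Mb, 40 genes, 10 plastic
    islands, two tissues, plus called peaks and expression/chromatin."""
    cfg = nm.SimulationConfig(seed=1)
    sim = nm.simulate_genome(cfg)
    sp = sim.truth.species["sp1"]
    peaks = {}
    tracks = {}
    for tissue in cfg.tissues:
        sample, control = nm.simulate_biocap(sim.sequences["sp1"], sp,
                                             tissue, cfg)
        tracks[tissue] = (sample, control)
        peaks[tissue] = nm.call_nmis(sample, control,
                                     read_length=cfg.read_length)
    expr = nm.simulate_expression_and_chromatin(sim.truth, cfg, "sp1")
    return {"cfg": cfg, "sim": sim, "sp": sp, "peaks": peaks,
            "tracks": tracks, "expr": expr}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_sequence(rng, n, p_gc=0.5, p_n=0.0):
    bases = np.array(list("ACGTN"))
    probs = [(1 - p_gc - p_n) / 2, p_gc / 2, p_gc / 2,
             (1 - p_gc - p_n) / 2, p_n]
    return "".join(rng.choice(bases, size=n, p=probs))
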