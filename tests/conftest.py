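import numpy as np
import pandas as pd
import pytest

from dualmpra import SimulationConfig
from dualmpra.barcode_index import build_index
from dualmpra.quantify import quantify_libraries
from dualmpra.simulate import (
    simulate_counts,
    simulate_elements,
    simulate_index_reads,
    simulate_quant_reads,
)


def noiseless_config(**overrides) -> SimulationConfig:
    """Small run with every noise source switched off: the pipeline must
    recover the generative truth exactly."""
    base = dict(
        n_proximal=6,
        n_distal=8,
        n_orf_controls=6,
        barcodes_per_element=5,
        seq_error_rate=0.0,
        chimera_rate=0.0,
        collision_rate=0.0,
        pcr_duplication_mean=0.0,
        orientation_asymmetry_sd=0.0,
        mean_molecules_per_barcode=8.0,
        seed=11,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def noiseless_run():
    """Full in-memory noiseless pipeline: truth, index, counts."""
    cfg = noiseless_config()
    catalog, truth = simulate_elements(cfg)
    reads = simulate_index_reads(catalog, truth, cfg)
    index = build_index(reads.r1, reads.r2, catalog, cfg)
    simulate_counts(truth, cfg)
    libs, meta = simulate_quant_reads(truth, cfg)
    cm = quantify_libraries(libs, meta, index, cfg)
    return {
        "config": cfg,
        "catalog": catalog,
        "truth": truth,
        "index_reads": reads,
        "index": index,
        "libraries": libs,
        "meta": meta,
        "counts": cm,
    }


@pytest.fixture()
def toy_catalog():
    """20 random elements for matcher tests."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    seqs = ["".join(rng.choice(bases, size=120)) for _ in range(20)]
    return pd.DataFrame(
        {"element_id": [f"E{i}" for i in range(20)], "sequence": seqs}
    )
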