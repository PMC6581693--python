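import numpy as np
import pandas as pd
import pytest

from chromdyn import single_cell as sc
from chromdyn.synthetic import (
    SimulationConfig,
    simulate_accessibility,
    simulate_cut_profiles,
    simulate_knockdown,
    simulate_single_cells,
)

STUDY_SEED = 17


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def accessibility(config):
    """(intervals, counts, archetype truth, universe) at the study seed."""
    return simulate_accessibility(config)


@pytest.fixture(scope="session")
def cut_profiles(config):
    return simulate_cut_profiles(config)


@pytest.fixture(scope="session")
def single_cells(config):
    return simulate_single_cells(config)


@pytest.fixture(scope="session")
def knockdown(config):
    return simulate_knockdown(config)


@pytest.fixture(scope="session")
def sc_processed(single_cells):
    """QC flags, kept genes, size factors and CPM for the study simulation."""
    qc = sc.qc_cells(single_cells.counts)
    kept = sc.filter_genes(single_cells.counts, qc)
    sf, cpm = sc.normalize_cells(single_cells.counts[kept], qc)
    binary = (single_cells.counts.loc[cpm.index, kept] > 0).astype(np.int8)
    return {"qc": qc, "kept": kept, "size_factor": sf, "cpm": cpm, "binary": binary}


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=1_000_000, width=(50, 500),
                     with_summit=False):
    """Arbitrary interval sets for brute-force oracle comparisons."""
    from chromdyn.genomic_io import GenomicInterval

    out = []
    for i in range(n):
        w = int(rng.integers(*width))
        start = int(rng.integers(0, span - w))
        summit = int(rng.integers(0, w)) if with_summit else None
        out.append(
            GenomicInterval(
                chrom=str(rng.choice(chroms)),
                start=start,
                end=start + w,
                name=f"iv{i}",
                summit_offset=summit,
            )
        )
    return out
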