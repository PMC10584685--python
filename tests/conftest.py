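import numpy as np
import pandas as pd
import pytest

from ptjoint.io import FragmentSet
from ptjoint.pipeline import PipelineConfig, run_pipeline
from ptjoint.simulate import SimulationConfig

CHROM_SIZES = {"chr1": 100_000}


def make_fragments(rows, chrom_sizes=None, deduplicated=False):
    """Build a FragmentSet from (chrom, start, end, barcode[, count]) tuples."""
    recs = []
    for row in rows:
        chrom, start, end, barcode = row[:4]
        count = row[4] if len(row) > 4 else 1
        recs.append(
            dict(chrom=chrom, start=start, end=end, barcode=barcode, count=count)
        )
    df = pd.DataFrame(
        recs, columns=["chrom", "start", "end", "barcode", "count"]
    )
    return FragmentSet(df, dict(chrom_sizes or CHROM_SIZES), deduplicated)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic dataset for fast module-level checks."""
    from ptjoint.simulate import simulate_dataset

    cfg = SimulationConfig(
        seed=7,
        n_cell_types=3,
        cells_per_type=40,
        n_genes=15,
        n_ccres=60,
        planted_links=6,
        markers_per_type=2,
        fragments_per_cell_median=400.0,
        umis_per_cell_median=600.0,
        chrom_sizes={"chr1": 3_000_000},
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_runs():
    """Full pipeline under the default study conditions, three seeds."""
    return [run_pipeline(PipelineConfig(seed=seed)) for seed in (1, 2, 3)]


@pytest.fixture(scope="session")
def null_runs():
    """Pipeline runs with no planted links (null calibration), three seeds."""
    out = []
    for seed in (11, 12, 13):
        cfg = PipelineConfig(seed=seed, sim=SimulationConfig(planted_links=0))
        out.append(run_pipeline(cfg))
    return out
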