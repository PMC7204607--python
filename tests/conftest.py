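import numpy as np
import pandas as pd
import pytest

from gbsmap import simdata, pipeline
from gbsmap.formats import SnpCallSet


@pytest.fixture(scope="session")
def small_config():
    """A small, clean F2 cross: 2 LGs, deep coverage, no outliers."""
    return simdata.SimConfig(
        n_individuals=80, n_linkage_groups=2, lg_lengths_cm=(80.0, 60.0),
        contigs_per_lg=20, snps_per_contig=6, contig_length_bp=3000,
        mean_depth=12.0, depth_shape=None, outlier_individuals=0, seed=11,
    )


@pytest.fixture(scope="session")
def small_run(small_config):
    """Full pipeline on the small cross (relaxed tag sample gate for n=80)."""
    pc = pipeline.PipelineConfig(tag_min_sample=15)
    result, truth = pipeline.run_simulated_pipeline(small_config, pc)
    return result, truth


def make_callset(calls, depth=None, samples=None, parents=("P1", "P2")):
    """Small hand-rolled SnpCallSet; calls is (n_sites, n_samples) list/array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_samples = calls.shape
    if depth is None:
        depth = np.full_like(calls, 30, dtype=np.int32)
    if samples is None:
        samples = list(parents) + [f"F2_{i}" for i in range(n_samples - 2)]
    sites = pd.DataFrame(
        {
            "contig": [f"ctg{i // 1000}" for i in range(n_sites)],
            "pos": [100 * (i + 1) for i in range(n_sites)],
            "ref": ["A"] * n_sites,
            "alt": ["C"] * n_sites,
        }
    )
    return SnpCallSet(
        samples=samples, sites=sites, calls=calls,
        depth=np.asarray(depth, dtype=np.int32),
        parent1=parents[0], parent2=parents[1],
    )
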