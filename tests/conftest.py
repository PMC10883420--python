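import numpy as np
import pandas as pd
import pytest

from stwmd import run_pipeline
from stwmd.data_model import tensor_from_long
from stwmd.synthetic import generate_tensor, reference_config, reference_spec


def long_frame(records):
    """records: iterable of (stage, sample, region, gene, value)."""
    return pd.DataFrame(records, columns=["stage", "sample", "region", "gene", "value"])


@pytest.fixture
def toy_tensor():
    """3 stages x 2 samples x 2 regions x 2 genes, fully observed."""
    rows = []
    rng = np.random.default_rng(0)
    for t, stage in enumerate(["s0", "s1", "s2"]):
        for sample in ["a", "b"]:
            for region in ["r1", "r2"]:
                for gene in ["g1", "g2"]:
                    rows.append((stage, f"{stage}_{sample}", region, gene,
                                 float(rng.uniform(1, 10))))
    return tensor_from_long(long_frame(rows))


def random_tensor(rng, n_stages=3, n_samples=3, n_regions=4, n_genes=12):
    """Small random positive tensor for property tests."""
    rows = []
    for t in range(n_stages):
        for i in range(n_samples):
            for r in range(n_regions):
                for g in range(n_genes):
                    rows.append((f"t{t}", f"t{t}_i{i}", f"r{r}", f"g{g}",
                                 float(rng.lognormal(2.0, 1.0))))
    return tensor_from_long(long_frame(rows))


@pytest.fixture(scope="session")
def reference_run():
    """One full pipeline run on the committed reference synthetic study.

    Session-scoped: several end-to-end assertions (DEG recovery, clustering,
    staging-tree stability) share this single run.
    """
    spec = reference_spec(seed=20240)
    tensor, truth = generate_tensor(spec)
    result = run_pipeline(tensor, reference_config(seed=20240))
    return spec, tensor, truth, result
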