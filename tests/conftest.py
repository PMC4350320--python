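import numpy as np
import pandas as pd
import pytest

from modhet import preprocess, synthetic


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset shared by read-only tests."""
    design = synthetic.small_design(seed=5)
    probes, probe_map, annotation, truth = synthetic.generate_dataset(design)
    return {
        "design": design,
        "probes": probes,
        "probe_map": probe_map,
        "annotation": annotation,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def gene_matrix(small_dataset):
    """Collapsed and quantile-normalized gene matrix of the small dataset."""
    genes = preprocess.collapse_probes(
        small_dataset["probes"], small_dataset["probe_map"]
    )
    return preprocess.quantile_normalize(genes)


def make_matrix(values, genes=None, samples=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)
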