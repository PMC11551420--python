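import pathlib

import pandas as pd
import pytest

import tfdirect as td


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """Small seeded synthetic dataset with 10% replicate noise."""
    out = tmp_path_factory.mktemp("ds")
    cfg = td.SimulationConfig(seed=1, n_genes=100, n_peaks=60,
                              noise_fraction=0.1)
    truth = td.simulate_dataset(cfg, out)
    return {"dir": pathlib.Path(out), "config": cfg, "truth": truth}


@pytest.fixture(scope="session")
def genes(dataset):
    return td.read_gff3(dataset["dir"] / "annotation.gff3")


@pytest.fixture(scope="session")
def genome(dataset):
    return td.read_fasta(dataset["dir"] / "genome.fa")


@pytest.fixture(scope="session")
def peak_replicates(dataset):
    d = dataset["dir"]
    return (td.read_narrowpeak(d / "tfa_rep1.narrowPeak"),
            td.read_narrowpeak(d / "tfa_rep2.narrowPeak"))


@pytest.fixture(scope="session")
def count_matrix(dataset):
    d = dataset["dir"]
    groups = pd.read_csv(d / "sample_groups.tsv", sep="\t",
                         index_col=0)["group"].to_dict()
    return td.CountMatrix.from_tsv(d / "counts.tsv", groups)
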