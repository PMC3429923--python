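import numpy as np
import pytest

import snpforest as sf


@pytest.fixture(scope="session")
def small_dataset():
    """A small admixed dataset with 3 strong causal SNPs, shared across tests."""
    params = sf.SimParams(n=200, p=30, n_causal=3, beta_sd=2.0, h2_target=0.5, seed=42)
    return sf.simulate_dataset(params)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_tiny_tsvs(tmp_path, geno_rows, pheno_rows, q_rows=None):
    """Write small TSV inputs; each *_rows is a list of tab-joined lines."""
    tmp_path.mkdir(parents=True, exist_ok=True)
    g = tmp_path / "geno.tsv"
    g.write_text("\n".join(geno_rows) + "\n")
    p = tmp_path / "pheno.tsv"
    p.write_text("\n".join(pheno_rows) + "\n")
    q = None
    if q_rows is not None:
        q = tmp_path / "q.tsv"
        q.write_text("\n".join(q_rows) + "\n")
    return g, p, q
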