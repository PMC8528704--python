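"""Shared fixtures: small synthetic datasets generated at test time."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

import tissuespec as ts


def make_adata(values: np.ndarray, gene_names=None, tissues=None) -> ad.AnnData:
    """Tiny AnnData from a raw count array, with a lognorm layer."""
    values = np.asarray(values)
    n, g = values.shape
    gene_names = list(gene_names) if gene_names is not None else [f"g{j}" for j in range(g)]
    obs = pd.DataFrame(
        {"tissue": tissues if tissues is not None else ["T"] * n},
        index=[f"c{i}" for i in range(n)],
    )
    adata = ad.AnnData(
        X=values.astype(np.int64),
        obs=obs,
        var=pd.DataFrame(index=gene_names),
    )
    total = values.sum(axis=1).astype(float)
    total[total == 0] = 1.0
    adata.layers["lognorm"] = np.log1p(1e4 * values / total[:, None])
    return adata


@pytest.fixture(scope="session")
def small_params() -> ts.SimParams:
    return ts.SimParams(
        cells_per_tissue=60,
        n_genes=300,
        ts_genes_per_tissue=5,
        shared_intestinal_genes=4,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_sim(small_params):
    """Small end-to-end simulation: annotation, scRNA, ATAC, truth."""
    ann = ts.generate_annotation(small_params)
    adata, truth0 = ts.generate_scrna(small_params, ann)
    pcm, reps, truth = ts.generate_atac(small_params, ann, truth0)
    return {"params": small_params, "ann": ann, "adata": adata,
            "pcm": pcm, "replicates": reps, "truth": truth}


@pytest.fixture(scope="session")
def default_sim():
    """Mid-size simulation at the generator's standard study conditions
    (1000 genes keeps the ATAC side at 5000 peaks)."""
    params = ts.SimParams(seed=21, n_genes=1000)
    ann = ts.generate_annotation(params)
    adata, truth0 = ts.generate_scrna(params, ann)
    pcm, reps, truth = ts.generate_atac(params, ann, truth0)
    return {"params": params, "ann": ann, "adata": adata,
            "pcm": pcm, "replicates": reps, "truth": truth}
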