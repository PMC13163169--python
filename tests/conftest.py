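"""Shared fixtures: small deterministic matrices and cached heavy runs.

The UMAP/HDBSCAN stages dominate runtime, so anything that needs a full
detection or FGM-inference run goes through the session-scoped caches below
and is computed once per session.
"""

from __future__ import annotations

from dataclasses import replace
from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

import nestedwgcna as nw
from nestedwgcna.synthetic_data import SyntheticSpec


def make_expr(values, gene_ids=None, sample_ids=None, space="linear"):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return nw.ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), space=space
    )


@pytest.fixture
def small_expr():
    """3 genes x 4 samples with distinct values."""
    return make_expr([[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 6.0, 7.0], [2.0, 4.0, 8.0, 16.0]])


#: A fast two-module dataset for detection tests: small enough that a full
#: UMAP+HDBSCAN round runs in a couple of seconds.
FAST_TWO_CGM = SyntheticSpec(
    n_samples=60,
    n_cgms=2,
    genes_per_cgm=120,
    core_fraction=0.4,
    n_subfactors_per_cgm=0,
    genes_per_subfactor=0,
    core_loading=1.0,
    periphery_loading=0.7,
    n_housekeeping=0,
    n_noise_genes=60,
    noise_sd=0.4,
    seed=0,
)


@lru_cache(maxsize=None)
def fast_dataset(seed: int = 0):
    return nw.generate(replace(FAST_TWO_CGM, seed=seed))


@lru_cache(maxsize=None)
def fast_detection(seed: int = 0):
    ds = fast_dataset(seed)
    return ds, nw.detect_cgms(ds.expr, min_cluster_size=30, seed=seed)


@lru_cache(maxsize=None)
def nested_dataset(seed: int = 0):
    return nw.generate(nw.scenario("nested", seed=seed))


@lru_cache(maxsize=None)
def nested_fgm(seed: int = 0, normalize: bool = True):
    ds = nested_dataset(seed)
    fgm = nw.infer_fgms(
        ds.expr,
        cgm_genes=ds.truth_cgm.module_genes(0),
        core_genes=ds.truth_core[0],
        fgm_min_cluster_size=15,
        seed=seed,
        normalize=normalize,
    )
    return ds, fgm


def restricted_ari(truth: pd.Series, detected: pd.Series) -> float:
    """ARI restricted to genes carrying a planted (non-noise) truth label."""
    from sklearn.metrics import adjusted_rand_score

    mask = truth.values >= 0
    return float(
        adjusted_rand_score(truth[mask], detected.loc[truth.index[mask]])
    )
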