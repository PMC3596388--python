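import numpy as np
import pytest

from tsnet.datatypes import Bicluster, ExpressionDataset, PatientProfile


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_dataset(values, labels=None, patient_ids=None, gene_ids=None, mask=None):
    """Small dense ExpressionDataset from a (P, G, T) array."""
    values = np.asarray(values, dtype=float)
    P, G, T = values.shape
    if mask is None:
        mask = ~np.isnan(values)
    ds = ExpressionDataset(
        patient_ids or [f"P{i}" for i in range(P)],
        gene_ids or [f"g{j}" for j in range(G)],
        list(range(1, T + 1)),
        values,
        mask,
        None if labels is None else np.asarray(labels),
    )
    ds.validate()
    return ds


def random_profile(rng, patient_id="P", n_genes=12, T=6, Q=3, max_biclusters=5):
    """Random score-normalized patient profile over a shared gene universe."""
    genes = [f"g{j}" for j in range(n_genes)]
    n_bc = int(rng.integers(1, max_biclusters + 1))
    bcs = []
    for _ in range(n_bc):
        k = int(rng.integers(2, min(5, n_genes) + 1))
        members = sorted(rng.choice(genes, size=k, replace=False).tolist())
        a = int(rng.integers(1, T))
        b = int(rng.integers(a, T + 1))
        profile = rng.integers(1, Q + 1, size=b - a + 1)
        bcs.append(Bicluster(tuple(members), a, b, tuple(int(s) for s in profile)))
    w = rng.random(n_bc) + 0.05
    prof = PatientProfile(patient_id, bcs, w / w.sum())
    prof.validate()
    return prof
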