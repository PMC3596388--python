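"""Expression normalization and missing-value imputation.

Normalization comes first, then imputation: each missing entry is
replaced with a weighted mean of the three present values of the same
(patient, gene) series closest in time index, weighted by inverse
time-index distance, so that the closest neighbors dominate.
"""

from __future__ import annotations

import numpy as np

from .datatypes import ExpressionDataset

__all__ = ["normalize", "impute"]

_MODES = ("none", "zscore_gene", "zscore_patient_gene")


def normalize(dataset: ExpressionDataset, mode: str = "zscore_gene") -> ExpressionDataset:
    """Return a normalized copy of the dataset.

    ``zscore_gene`` standardizes each gene over all its present values
    across patients and time points (mean 0, sd 1); this pools all genes
    onto a comparable scale, which the mixture-emission initialization
    relies on.  ``zscore_patient_gene`` standardizes each (patient,
    gene) series over time.  Constant series map to all-zero.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown normalization mode {mode!r}; choose from {_MODES}")
    out = dataset.copy()
    if mode == "none":
        return out
    vals, mask = out.values, out.mask
    if mode == "zscore_gene":
        for j in range(out.n_genes):
            m = mask[:, j, :]
            if not m.any():
                continue
            v = vals[:, j, :][m]
            sd = v.std()
            centered = vals[:, j, :] - v.mean()
            vals[:, j, :] = np.where(m, centered / sd if sd > 0 else 0.0, np.nan)
    else:  # zscore_patient_gene
        for i in range(out.n_patients):
            for j in range(out.n_genes):
                m = mask[i, j]
                if not m.any():
                    continue
                v = vals[i, j][m]
                sd = v.std()
                centered = vals[i, j] - v.mean()
                vals[i, j] = np.where(m, centered / sd if sd > 0 else 0.0, np.nan)
    return out


def impute(dataset: ExpressionDataset) -> ExpressionDataset:
    """Fill every missing entry from its three closest present neighbors.

    For a missing entry at time index ``t`` of a (patient, gene) series,
    the fill value is ``sum(w_k v_k) / sum(w_k)`` over the (up to) three
    present values nearest in time-index distance, with ``w_k = 1 /
    |t - t_k|``.  Distance ties are broken toward the earlier time
    point.  Present values are never altered; the output mask is
    all-present.  A series with no present value at all is an error.
    """
    out = dataset.copy()
    vals, mask = out.values, out.mask
    T = out.n_times
    positions = np.arange(1, T + 1)  # 1-based time indices
    for i in range(out.n_patients):
        for j in range(out.n_genes):
            m = mask[i, j]
            if m.all():
                continue
            present = positions[m]
            if present.size == 0:
                raise ValueError(
                    f"no present values for (patient {out.patient_ids[i]!r}, "
                    f"gene {out.gene_ids[j]!r}); cannot impute"
                )
            pv = vals[i, j][m]
            for k in np.flatnonzero(~m):
                t = positions[k]
                dist = np.abs(present - t)
                # ties in distance resolved toward the earlier time point
                order = np.lexsort((present, dist))[:3]
                w = 1.0 / dist[order]
                vals[i, j, k] = float(np.dot(w, pv[order]) / w.sum())
            mask[i, j] = True
    return out
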