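"""Bicluster and patient similarity, and the class-distance diagnostic.

Two biclusters are compared with the Jaccard index over their cells:
the intersection counts shared genes times shared time-stamped states,
``|B_i ∩ B_j| = |G_i ∩ G_j| x |J_i ∩ J_j|``, where a time point
contributes to ``|J_i ∩ J_j|`` only if it lies in both windows *and*
both profiles carry the same state there.

Patient-level similarity (PPISim) aggregates pairwise bicluster
similarities weighted by the normalized connectivity scores.  The
default aggregation is a symmetrized weighted best-match: each
bicluster contributes its best counterpart in the other patient,
weighted by its own normalized weight, averaged over both directions.
This form satisfies self-similarity 1 and symmetry, which the
classifier's kernel relies on; a plain weighted double sum is available
as an alternative but cannot reach self-similarity 1.
"""

from __future__ import annotations

import numpy as np

from .datatypes import Bicluster, PatientProfile

__all__ = [
    "bicluster_jaccard",
    "patient_similarity",
    "similarity_matrix",
    "class_distance_ratio",
    "profile_arrays",
    "pairwise_bicluster_similarity",
]

_AGGREGATIONS = ("bestmatch", "doublesum")


def bicluster_jaccard(b1: Bicluster, b2: Bicluster) -> float:
    """Jaccard index between two biclusters over their (gene, time, state) cells."""
    g_inter = len(set(b1.genes) & set(b2.genes))
    if g_inter == 0:
        return 0.0
    lo = max(b1.t_start, b2.t_start)
    hi = min(b1.t_end, b2.t_end)
    j_inter = sum(
        1
        for t in range(lo, hi + 1)
        if b1.profile[t - b1.t_start] == b2.profile[t - b2.t_start]
    )
    inter = g_inter * j_inter
    union = b1.size + b2.size - inter
    return inter / union


def _check_weights(profile: PatientProfile) -> np.ndarray:
    if profile.weights is None:
        raise ValueError(f"profile {profile.patient_id!r} has no normalized weights")
    w = np.asarray(profile.weights, dtype=float)
    if profile.biclusters and abs(w.sum() - 1.0) > 1e-8:
        raise ValueError(
            f"profile {profile.patient_id!r} weights sum to {w.sum()}, expected 1"
        )
    return w


def profile_arrays(profile: PatientProfile, gene_index: dict, T: int):
    """Vectorized bicluster representation for fast pairwise similarity.

    Returns ``(membership, state_grid, sizes)``: a (B, G) 0/1 gene
    membership matrix, a (B, T) state-per-time grid (0 outside the
    window) and the per-bicluster cell counts.
    """
    B = len(profile.biclusters)
    G = len(gene_index)
    membership = np.zeros((B, G))
    grid = np.zeros((B, T), dtype=int)
    sizes = np.zeros(B)
    for k, bc in enumerate(profile.biclusters):
        for g in bc.genes:
            membership[k, gene_index[g]] = 1.0
        grid[k, bc.t_start - 1: bc.t_end] = bc.profile
        sizes[k] = bc.size
    return membership, grid, sizes


def pairwise_bicluster_similarity(rep1, rep2) -> np.ndarray:
    """All-pairs Jaccard between two patients' bicluster sets (vectorized)."""
    m1, s1, z1 = rep1
    m2, s2, z2 = rep2
    g_inter = m1 @ m2.T
    j_inter = ((s1[:, None, :] == s2[None, :, :]) & (s1[:, None, :] > 0)).sum(axis=2)
    inter = g_inter * j_inter
    union = z1[:, None] + z2[None, :] - inter
    return np.where(union > 0, inter / np.maximum(union, 1), 0.0)


def _aggregate(sim: np.ndarray, w1: np.ndarray, w2: np.ndarray, aggregation: str) -> float:
    if aggregation == "bestmatch":
        return 0.5 * float(w1 @ sim.max(axis=1) + w2 @ sim.max(axis=0))
    return float(w1 @ sim @ w2)  # doublesum


def patient_similarity(
    p1: PatientProfile, p2: PatientProfile, aggregation: str = "bestmatch"
) -> float:
    """PPISim between two score-normalized patient profiles, in [0, 1].

    A patient with zero biclusters has similarity 0 to everyone and 1
    to itself.
    """
    if aggregation not in _AGGREGATIONS:
        raise ValueError(f"unknown aggregation {aggregation!r}; choose from {_AGGREGATIONS}")
    if not p1.biclusters or not p2.biclusters:
        same = p1 is p2 or (
            not p1.biclusters and not p2.biclusters and p1.patient_id == p2.patient_id
        )
        return 1.0 if same else 0.0
    w1 = _check_weights(p1)
    w2 = _check_weights(p2)
    sim = np.array(
        [[bicluster_jaccard(a, b) for b in p2.biclusters] for a in p1.biclusters]
    )
    return _aggregate(sim, w1, w2, aggregation)


def similarity_matrix(profiles: list, aggregation: str = "bestmatch") -> np.ndarray:
    """Symmetric patient x patient PPISim kernel with unit diagonal."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    gene_index, T = _universe(profiles)
    reps = [profile_arrays(p, gene_index, T) for p in profiles]
    weights = [
        _check_weights(p) if p.biclusters else np.zeros(0) for p in profiles
    ]
    n = len(profiles)
    K = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if not profiles[i].biclusters or not profiles[j].biclusters:
                K[i, j] = K[j, i] = 0.0
                continue
            sim = pairwise_bicluster_similarity(reps[i], reps[j])
            K[i, j] = K[j, i] = _aggregate(sim, weights[i], weights[j], aggregation)
    return K


def cross_similarity(
    profiles_a: list, profiles_b: list, aggregation: str = "bestmatch"
) -> np.ndarray:
    """PPISim between two sets of profiles (rows: a, columns: b)."""
    gene_index, T = _universe(list(profiles_a) + list(profiles_b))
    reps_a = [profile_arrays(p, gene_index, T) for p in profiles_a]
    reps_b = [profile_arrays(p, gene_index, T) for p in profiles_b]
    wa = [_check_weights(p) if p.biclusters else np.zeros(0) for p in profiles_a]
    wb = [_check_weights(p) if p.biclusters else np.zeros(0) for p in profiles_b]
    out = np.zeros((len(profiles_a), len(profiles_b)))
    for i, pa in enumerate(profiles_a):
        for j, pb in enumerate(profiles_b):
            if not pa.biclusters or not pb.biclusters:
                out[i, j] = 1.0 if pa.patient_id == pb.patient_id else 0.0
                continue
            sim = pairwise_bicluster_similarity(reps_a[i], reps_b[j])
            out[i, j] = _aggregate(sim, wa[i], wb[j], aggregation)
    return out


def _universe(profiles: list) -> tuple[dict, int]:
    genes: dict = {}
    t_max = 1
    for p in profiles:
        for bc in p.biclusters:
            for g in bc.genes:
                genes.setdefault(g, len(genes))
            t_max = max(t_max, bc.t_end)
    return genes, t_max


def class_distance_ratio(kernel: np.ndarray, labels: np.ndarray) -> float:
    """Mean within-class over mean between-class similarity (off-diagonal).

    Larger values mean patients of the same response class sit closer
    in bicluster space than patients of opposite classes.  Returns
    ``inf`` when the between-class mean is zero.
    """
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    n = kernel.shape[0]
    same, cross = [], []
    for i in range(n):
        for j in range(i + 1, n):
            (same if labels[i] == labels[j] else cross).append(kernel[i, j])
    within = float(np.mean(same)) if same else float("nan")
    between = float(np.mean(cross))
    if between == 0:
        return float("inf")
    return within / between
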