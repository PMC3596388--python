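"""KNN-gated soft-margin SVM on the PPISim kernel, with CV harness.

For each test patient the K most similar training patients are found
first; if their labels are unanimous that label is returned directly
(coarse, fast KNN stage).  Otherwise a linear soft-margin SVM is
trained on the neighborhood only, using the patient-similarity matrix
as kernel, and the test patient is classified by the SVM decision
function (fine, slow stage).  The SVM dual

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K_ij
    s.t.   0 <= a_i <= C,  sum_i a_i y_i = 0

is solved exactly by pairwise coordinate ascent (SMO); the similarity
kernel is projected to its nearest positive-semidefinite matrix first
(negative eigenvalues clipped to zero) since PPISim is not guaranteed
PSD.

The cross-validation harness refits the discretization model, the
biclusters, the network scores and the kernel inside every training
fold, so no information from test patients leaks into model fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .config import PipelineConfig
from .datatypes import ExpressionDataset, InteractionNetwork, PatientProfile
from .network_score import score_profiles
from .pipeline import (
    discretize_dataset,
    extract_profiles,
    fit_discretizer,
    preprocess_dataset,
    uniform_profiles,
)
from .similarity import _check_weights, patient_similarity, profile_arrays

logger = logging.getLogger(__name__)

__all__ = [
    "SvmSolution",
    "CvReport",
    "solve_svm_dual",
    "svm_predict",
    "knn_select",
    "ppi_svm_knn",
    "compute_metrics",
    "cross_validate",
    "ablate_network",
    "early_stage_eval",
    "kkt_residual",
]


# ---------------------------------------------------------------------------
# SVM dual


@dataclass
class SvmSolution:
    """Soft-margin dual solution: multipliers, bias and support set."""

    alpha: np.ndarray
    b: float
    y: np.ndarray
    C: float
    support: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.support = np.flatnonzero(self.alpha > 1e-10)


def nearest_psd(K: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone (clip negative eigenvalues)."""
    sym = (K + K.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= 0:
        return sym
    clipped = (vecs * np.maximum(vals, 0.0)) @ vecs.T
    return (clipped + clipped.T) / 2.0


def solve_svm_dual(
    kernel: np.ndarray,
    labels: np.ndarray,
    C: float,
    tol: float = 1e-12,
    max_sweeps: int = 20_000,
) -> SvmSolution:
    """Exact SMO solution of the box-constrained dual on a small kernel.

    Sweeps over all index pairs, maximizing the dual analytically in
    each pair while preserving ``sum(a_i y_i) = 0``, until no pair moves
    by more than ``tol``.  The kernel is PSD-projected first.  The bias
    is the mean of ``y_i - f_i`` over margin vectors (``0 < a_i < C``);
    with no margin vector it is the midpoint of the KKT-consistent
    interval.
    """
    y = np.asarray(labels, dtype=float)
    n = y.size
    if set(np.unique(y)) != {-1.0, 1.0}:
        raise ValueError("both labels (+1, -1) must be present for the SVM stage")
    K = nearest_psd(np.asarray(kernel, dtype=float))
    alpha = np.zeros(n)
    f = np.zeros(n)  # f_i = sum_j alpha_j y_j K_ij

    converged = False
    for sweep in range(max_sweeps):
        max_step = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                s = y[i] * y[j]
                if s < 0:
                    L = max(0.0, alpha[j] - alpha[i])
                    H = min(C, C + alpha[j] - alpha[i])
                else:
                    L = max(0.0, alpha[i] + alpha[j] - C)
                    H = min(C, alpha[i] + alpha[j])
                if H - L < 1e-15:
                    continue
                Ei = f[i] - y[i]
                Ej = f[j] - y[j]
                eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
                aj_old = alpha[j]
                if eta > 1e-14:
                    aj = np.clip(aj_old + y[j] * (Ei - Ej) / eta, L, H)
                else:
                    # dual is linear along the pair direction: move to the
                    # endpoint the gradient points at
                    g = y[j] * (Ei - Ej)
                    if g > 0:
                        aj = H
                    elif g < 0:
                        aj = L
                    else:
                        continue
                d = aj - aj_old
                if abs(d) < 1e-16:
                    continue
                alpha[j] = aj
                alpha[i] -= s * d
                f += y[j] * d * (K[:, j] - K[:, i])
                max_step = max(max_step, abs(d))
        if max_step < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"SMO did not converge in {max_sweeps} sweeps (last max step {max_step:.2e})"
        )
    if abs(float(alpha @ y)) > 1e-8:
        raise RuntimeError("equality constraint sum(alpha*y)=0 violated")

    margin = (alpha > 1e-8) & (alpha < C - 1e-8)
    if margin.any():
        b = float(np.mean(y[margin] - f[margin]))
    else:
        # KKT: alpha=0 -> y(f+b) >= 1, alpha=C -> y(f+b) <= 1
        lowers, uppers = [], []
        for i in range(n):
            bound = y[i] - f[i]
            at_zero = alpha[i] <= 1e-8
            if (y[i] > 0) == at_zero:
                lowers.append(bound)
            else:
                uppers.append(bound)
        lo = max(lowers) if lowers else -np.inf
        hi = min(uppers) if uppers else np.inf
        if np.isinf(lo):
            b = hi
        elif np.isinf(hi):
            b = lo
        else:
            b = (lo + hi) / 2.0
    return SvmSolution(alpha=alpha, b=float(b), y=y, C=float(C))


def dual_objective(alpha: np.ndarray, y: np.ndarray, K: np.ndarray) -> float:
    ay = alpha * y
    return float(alpha.sum() - 0.5 * ay @ K @ ay)


def kkt_residual(sol: SvmSolution, kernel: np.ndarray) -> float:
    """Maximum violation of the dual KKT conditions (0 at the optimum)."""
    K = nearest_psd(np.asarray(kernel, dtype=float))
    f = K @ (sol.alpha * sol.y)
    res = abs(float(sol.alpha @ sol.y))
    for i in range(sol.y.size):
        m = sol.y[i] * (f[i] + sol.b)
        if sol.alpha[i] <= 1e-8:
            res = max(res, max(0.0, 1.0 - m))
        elif sol.alpha[i] >= sol.C - 1e-8:
            res = max(res, max(0.0, m - 1.0))
        else:
            res = max(res, abs(m - 1.0))
    return res


def svm_predict(sol: SvmSolution, kernel_row: np.ndarray) -> int:
    """Sign of the decision function over support vectors.

    An exactly zero decision value falls back to the majority label of
    the neighborhood (ties resolved to the positive class).
    """
    kernel_row = np.asarray(kernel_row, dtype=float)
    val = float(
        (sol.alpha[sol.support] * sol.y[sol.support]) @ kernel_row[sol.support] + sol.b
    )
    if val > 0:
        return 1
    if val < 0:
        return -1
    vote = int(np.sum(sol.y))
    return 1 if vote >= 0 else -1


# ---------------------------------------------------------------------------
# KNN gate


def knn_select(
    test_profile: PatientProfile,
    train_profiles: list,
    K: int,
    aggregation: str = "bestmatch",
) -> list:
    """Indices of the K training patients most similar to the test patient.

    Similarity ties are broken by training order (stable sort), so the
    selection is deterministic.
    """
    if not 1 <= K <= len(train_profiles):
        raise ValueError(f"K={K} outside [1, {len(train_profiles)}]")
    sims = np.array(
        [patient_similarity(test_profile, tr, aggregation) for tr in train_profiles]
    )
    return list(np.argsort(-sims, kind="stable")[:K])


def _predict_from_kernel(
    sims_row: np.ndarray, train_kernel: np.ndarray, labels: np.ndarray, K: int, C: float
) -> int:
    """KNN gate + neighborhood SVM, from precomputed similarities."""
    order = np.argsort(-sims_row, kind="stable")[:K]
    neigh = labels[order]
    if np.all(neigh == neigh[0]):
        return int(neigh[0])
    sol = solve_svm_dual(train_kernel[np.ix_(order, order)], neigh, C)
    return svm_predict(sol, sims_row[order])


def ppi_svm_knn(
    test_profile: PatientProfile,
    train_profiles: list,
    train_labels: np.ndarray,
    K: int,
    C: float,
    aggregation: str = "bestmatch",
) -> int:
    """Classify one patient: unanimous K-neighborhood short-circuits the SVM."""
    train_labels = np.asarray(train_labels, dtype=int)
    neighbors = knn_select(test_profile, train_profiles, K, aggregation)
    neigh_labels = train_labels[neighbors]
    if np.all(neigh_labels == neigh_labels[0]):
        return int(neigh_labels[0])
    from .similarity import similarity_matrix

    sub = [train_profiles[i] for i in neighbors]
    kernel = similarity_matrix(sub, aggregation)
    sims = np.array(
        [patient_similarity(test_profile, p, aggregation) for p in sub]
    )
    sol = solve_svm_dual(kernel, neigh_labels, C)
    return svm_predict(sol, sims)


# ---------------------------------------------------------------------------
# metrics and CV


def compute_metrics(truth, predicted) -> dict:
    """Accuracy, precision, recall and F-measure (positive = good responder).

    Precision and recall are defined as 0 when their denominator is 0.
    """
    t = np.asarray(truth, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise ValueError("truth and prediction lengths differ")
    tp = int(np.sum((t == 1) & (p == 1)))
    fp = int(np.sum((t == -1) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == -1)))
    accuracy = float(np.mean(t == p))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f_measure": f}


@dataclass
class CvReport:
    """Per-repetition fold predictions and summary metrics."""

    predictions: list  # per rep: list of (fold, patient_id, y_true, y_pred)
    per_rep: dict      # metric -> list of per-repetition values
    mean: dict
    sd: dict

    @classmethod
    def from_predictions(cls, predictions: list) -> "CvReport":
        per_rep: dict = {}
        for rep_preds in predictions:
            t = [yt for _, _, yt, _ in rep_preds]
            p = [yp for _, _, _, yp in rep_preds]
            for k, v in compute_metrics(t, p).items():
                per_rep.setdefault(k, []).append(v)
        mean = {k: float(np.mean(v)) for k, v in per_rep.items()}
        sd = {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for k, v in per_rep.items()}
        return cls(predictions, per_rep, mean, sd)


def _stratified_folds(labels: np.ndarray, n_folds: int, random_state: int) -> list:
    """Stratified folds; re-drawn if any fold misses a class."""
    for attempt in range(20):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=(random_state + attempt) % 2**31
        )
        folds = list(skf.split(np.zeros(labels.size), labels))
        if all(len(set(labels[tr].tolist())) == 2 for tr, _ in folds):
            return folds
    raise RuntimeError("could not draw stratified folds with both classes present")


def _fold_kernels(profiles: list, weight_sets: dict, aggregation: str):
    """Full patient x patient kernels, one per weighting arm.

    The pairwise bicluster similarity matrices depend only on the
    biclusters, so they are computed once and aggregated under each
    arm's weights.
    """
    genes: dict = {}
    T = 1
    for p in profiles:
        for bc in p.biclusters:
            for g in bc.genes:
                genes.setdefault(g, len(genes))
            T = max(T, bc.t_end)
    reps = [profile_arrays(p, genes, T) for p in profiles]
    n = len(profiles)
    kernels = {arm: np.eye(n) for arm in weight_sets}

    # stack every patient's biclusters once; per patient i, compare its
    # block against the concatenated blocks of all later patients
    counts = [len(p.biclusters) for p in profiles]
    offsets = np.concatenate([[0], np.cumsum(counts)])
    if offsets[-1] == 0:
        return kernels
    G_all = np.concatenate([r[0] for r in reps if r[0].shape[0]], axis=0)
    S_all = np.concatenate([r[1] for r in reps if r[1].shape[0]], axis=0)
    Z_all = np.concatenate([r[2] for r in reps if r[2].shape[0]], axis=0)
    # one-hot the (time, state) grid so the time-state overlap count
    # becomes a matrix product
    Q_max = int(S_all.max()) if S_all.size else 1
    B_tot, T_all = S_all.shape
    onehot = np.zeros((B_tot, T_all * Q_max))
    nz = S_all > 0
    rows, cols = np.nonzero(nz)
    onehot[rows, cols * Q_max + (S_all[nz] - 1)] = 1.0
    for i in range(n - 1):
        lo_i, hi_i = offsets[i], offsets[i + 1]
        if hi_i == lo_i:
            continue
        rest = slice(hi_i, offsets[-1])
        if rest.start == rest.stop:
            break
        g_inter = G_all[lo_i:hi_i] @ G_all[rest].T
        j_inter = onehot[lo_i:hi_i] @ onehot[rest].T
        inter = g_inter * j_inter
        union = Z_all[lo_i:hi_i, None] + Z_all[None, rest] - inter
        sim_block = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
        for j in range(i + 1, n):
            if counts[j] == 0:
                continue
            sim = sim_block[:, offsets[j] - hi_i: offsets[j + 1] - hi_i]
            best_i = sim.max(axis=1)
            best_j = sim.max(axis=0)
            for arm, weights in weight_sets.items():
                wi, wj = weights[i], weights[j]
                if aggregation == "bestmatch":
                    v = 0.5 * float(wi @ best_i + wj @ best_j)
                else:
                    v = float(wi @ sim @ wj)
                kernels[arm][i, j] = kernels[arm][j, i] = v
    return kernels


def _select_kc(
    kernel: np.ndarray, labels: np.ndarray, grid: dict, random_state: int
) -> tuple[int, float]:
    """Pick (K, C) by inner stratified CV on the training kernel.

    Ties go to the smaller K, then the smaller C.
    """
    K_grid = grid.get("K", [3, 5, 7, 9])
    C_grid = grid.get("C", [0.1, 1.0, 10.0])
    inner = _stratified_folds(labels, min(3, np.bincount((labels + 1) // 2).min()), random_state)
    best = None
    for K in sorted(K_grid):
        for C in sorted(C_grid):
            correct = total = 0
            for tr, te in inner:
                if K > len(tr):
                    continue
                for t in te:
                    pred = _predict_from_kernel(
                        kernel[t, tr], kernel[np.ix_(tr, tr)], labels[tr], K, C
                    )
                    correct += pred == labels[t]
                    total += 1
            if total == 0:
                continue
            acc = correct / total
            if best is None or acc > best[0] + 1e-12:
                best = (acc, K, C)
    if best is None:
        raise ValueError("selection grid produced no feasible (K, C)")
    return best[1], best[2]


def _run_cv(
    dataset: ExpressionDataset,
    network: InteractionNetwork | None,
    config: PipelineConfig,
    arms: tuple,
    label_override: np.ndarray | None = None,
) -> dict:
    """Shared CV engine; arms reuse folds, models and biclusters."""
    if dataset.labels is None and label_override is None:
        raise ValueError("dataset has no labels")
    labels = np.asarray(label_override if label_override is not None else dataset.labels)
    if "ppi" in arms and network is None:
        raise ValueError("network required for the PPI arm")
    ds = preprocess_dataset(dataset, config)
    n = ds.n_patients
    predictions = {arm: [] for arm in arms}
    for rep in range(config.reps):
        folds = _stratified_folds(labels, config.folds, config.seed * 1000 + rep)
        rep_preds = {arm: [] for arm in arms}
        for fold_id, (train_idx, test_idx) in enumerate(folds):
            train_ds = ds.subset_patients(train_idx)
            model = fit_discretizer(train_ds, config)
            states = discretize_dataset(ds, config, model=model)
            raw_profiles = extract_profiles(ds, states, config)

            weight_sets = {}
            for arm in arms:
                if arm == "ppi":
                    arm_profiles = score_profiles(
                        raw_profiles, network, aggregator=config.aggregator
                    )
                else:
                    arm_profiles = uniform_profiles(raw_profiles)
                weight_sets[arm] = [
                    _check_weights(p) if p.biclusters else np.zeros(0)
                    for p in arm_profiles
                ]
            kernels = _fold_kernels(raw_profiles, weight_sets, config.sim_aggregation)

            for arm in arms:
                Kmat = kernels[arm]
                K_train = Kmat[np.ix_(train_idx, train_idx)]
                if config.select_grid is not None:
                    K_use, C_use = _select_kc(
                        K_train, labels[train_idx], config.select_grid,
                        config.seed * 1000 + rep,
                    )
                else:
                    K_use, C_use = config.K, config.C
                K_use = min(K_use, len(train_idx))
                for t in test_idx:
                    pred = _predict_from_kernel(
                        Kmat[t, train_idx], K_train, labels[train_idx], K_use, C_use
                    )
                    rep_preds[arm].append(
                        (fold_id, ds.patient_ids[t], int(labels[t]), int(pred))
                    )
        for arm in arms:
            predictions[arm].append(rep_preds[arm])
    return {arm: CvReport.from_predictions(predictions[arm]) for arm in arms}


def cross_validate(
    dataset: ExpressionDataset,
    network: InteractionNetwork | None,
    config: PipelineConfig,
    label_override: np.ndarray | None = None,
) -> CvReport:
    """Repeated stratified k-fold CV of the full pipeline.

    The discretization model, biclusters, scores and kernel are fitted
    inside each training fold; test patients are decoded with the
    training-fold model.  ``label_override`` substitutes the label
    vector (e.g. a permutation for a null run) without touching the
    dataset.
    """
    arm = "ppi" if network is not None else "uniform"
    return _run_cv(dataset, network, config, (arm,), label_override)[arm]


def ablate_network(
    dataset: ExpressionDataset, network: InteractionNetwork, config: PipelineConfig
) -> tuple[CvReport, CvReport]:
    """Identical pipeline with and without network weighting, shared folds.

    Returns ``(ppi_report, uniform_report)``; only the bicluster
    weights differ between the two arms.
    """
    out = _run_cv(dataset, network, config, ("ppi", "uniform"))
    return out["ppi"], out["uniform"]


def early_stage_eval(
    dataset: ExpressionDataset,
    network: InteractionNetwork | None,
    config: PipelineConfig,
    n_list,
) -> dict:
    """Rerun CV on the first n measurements for each n in ``n_list`` (n >= 3)."""
    reports = {}
    for n_keep in n_list:
        if n_keep < 3:
            raise ValueError("early-stage evaluation requires n >= 3")
        if n_keep > dataset.n_times:
            logger.warning("skipping n=%d > available time points %d", n_keep, dataset.n_times)
            continue
        reports[n_keep] = cross_validate(dataset.truncate(n_keep), network, config)
    return reports
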