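"""Qualitative gene-state inference.

The main discretizer is a hidden Markov model with Gaussian-mixture
emissions: every hidden state ``j`` (a qualitative expression level,
``1..Q``) emits through a mixture of ``n`` Gaussian components, one
component per gene, so gene-specific scale differences are absorbed by
the emission model while the Markov chain captures the tendency of a
gene to stay at a level across contiguous time points.  One model is
fitted per dataset on all (patient, gene) series pooled, giving every
patient a shared state vocabulary; after fitting, states are relabeled
in increasing order of emission mean so that state 1 is always the
lowest expression level.

Simple threshold discretizers (average, mid-range, max-X%max, top-X%,
equal-frequency partition) are provided as baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log, pi as _PI

import numpy as np

from .datatypes import ExpressionDataset, GeneStateMatrix

__all__ = [
    "HmmGmmModel",
    "init_model",
    "em_train",
    "viterbi_decode",
    "baseline_discretize",
    "emission_logprob",
]

_LOG2PI = log(2.0 * _PI)


@dataclass
class HmmGmmModel:
    """Gaussian-mixture-emission HMM parameters.

    ``pi`` is the initial state distribution (Q,), ``A`` the transition
    matrix (Q, Q); ``w``, ``mu``, ``sigma`` are (Q, n) mixture weights,
    component means and component standard deviations, with component
    ``i`` tied to gene ``i``.
    """

    Q: int
    n: int
    pi: np.ndarray
    A: np.ndarray
    w: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    sigma_floor: float
    loglik_history: list = field(default_factory=list, repr=False)

    def validate(self) -> None:
        if abs(self.pi.sum() - 1) > 1e-8:
            raise ValueError("pi must sum to 1")
        if np.abs(self.A.sum(axis=1) - 1).max() > 1e-8:
            raise ValueError("rows of A must sum to 1")
        if np.abs(self.w.sum(axis=1) - 1).max() > 1e-8:
            raise ValueError("rows of w must sum to 1")
        if (self.sigma < self.sigma_floor - 1e-15).any():
            raise ValueError("sigma below floor")

    def copy(self) -> "HmmGmmModel":
        return HmmGmmModel(
            self.Q, self.n, self.pi.copy(), self.A.copy(), self.w.copy(),
            self.mu.copy(), self.sigma.copy(), self.sigma_floor,
            list(self.loglik_history),
        )

    @property
    def state_means(self) -> np.ndarray:
        """Emission mean per state, sum_i w_ji * mu_ji."""
        return (self.w * self.mu).sum(axis=1)


# ---------------------------------------------------------------------------
# initialization


def init_model(
    dataset: ExpressionDataset, Q: int, sigma_floor: float | None = None,
    sigma_floor_frac: float = 1e-3,
) -> HmmGmmModel:
    """Initialize from equal-count bins of the pooled expression values.

    ``pi``, rows of ``A`` and rows of ``w`` start uniform.  All present
    values are pooled, sorted and split into ``Q`` bins of equal count
    (any remainder spread over the lowest bins); ``mu[j, i]`` /
    ``sigma[j, i]`` are the mean / sd of bin-``j`` values belonging to
    gene ``i``.  A gene with fewer than two values in a bin falls back
    to the bin's all-gene mean and sd.
    """
    if Q < 2:
        raise ValueError("Q must be >= 2")
    n = dataset.n_genes
    vals = dataset.values
    mask = dataset.mask
    gene_of = np.broadcast_to(
        np.arange(n)[None, :, None], vals.shape
    )[mask]
    pooled = vals[mask]
    if np.unique(pooled).size < Q:
        raise ValueError(
            f"Q={Q} exceeds the number of distinct pooled values ({np.unique(pooled).size})"
        )
    pooled_sd = float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0
    if sigma_floor is None:
        sigma_floor = max(sigma_floor_frac * pooled_sd, 1e-12)

    order = np.argsort(pooled, kind="stable")
    pooled, gene_of = pooled[order], gene_of[order]
    base, extra = divmod(pooled.size, Q)
    sizes = [base + (1 if j < extra else 0) for j in range(Q)]
    bounds = np.cumsum([0] + sizes)

    mu = np.empty((Q, n))
    sigma = np.empty((Q, n))
    for j in range(Q):
        bv = pooled[bounds[j]: bounds[j + 1]]
        bg = gene_of[bounds[j]: bounds[j + 1]]
        bin_mean = float(bv.mean())
        bin_sd = float(bv.std(ddof=1)) if bv.size > 1 else 0.0
        bin_sd = max(bin_sd, sigma_floor)
        for i in range(n):
            gi = bv[bg == i]
            if gi.size >= 2:
                mu[j, i] = gi.mean()
                sigma[j, i] = max(float(gi.std(ddof=1)), sigma_floor)
            else:
                mu[j, i] = bin_mean
                sigma[j, i] = bin_sd

    return HmmGmmModel(
        Q=Q,
        n=n,
        pi=np.full(Q, 1.0 / Q),
        A=np.full((Q, Q), 1.0 / Q),
        w=np.full((Q, n), 1.0 / n),
        mu=mu,
        sigma=sigma,
        sigma_floor=float(sigma_floor),
    )


# ---------------------------------------------------------------------------
# EM (Baum-Welch over multiple equal-length sequences, vectorized)


def _sequences(dataset: ExpressionDataset) -> np.ndarray:
    """Stack one observation sequence per (patient, gene), shape (P*G, T)."""
    if not dataset.mask.all():
        raise ValueError("dataset must be imputed (no missing values) before HMM fitting")
    P, G, T = dataset.values.shape
    return dataset.values.reshape(P * G, T)


def emission_logprob(model: HmmGmmModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log emission densities for flat observations ``x``.

    Returns ``(logB, comp_log)`` with shapes (M, Q) and (M, Q, n):
    ``logB[m, j]`` is the log mixture density of observation ``m`` under
    state ``j``; ``comp_log`` holds the per-component joint terms
    ``log w_ji + log N(x_m; mu_ji, sigma_ji)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    z = (x[:, None, None] - model.mu[None]) / model.sigma[None]
    comp_log = (
        np.log(np.maximum(model.w[None], 1e-300))
        - np.log(model.sigma[None])
        - 0.5 * (z * z + _LOG2PI)
    )
    m = comp_log.max(axis=2)
    logB = m + np.log(np.exp(comp_log - m[:, :, None]).sum(axis=2))
    return logB, comp_log


def _e_step(model: HmmGmmModel, X: np.ndarray):
    """Scaled forward-backward over all sequences at once.

    Returns total log-likelihood and the sufficient statistics needed by
    the M-step.
    """
    S, T = X.shape
    Q, n = model.Q, model.n
    logB, comp_log = emission_logprob(model, X)
    logB = logB.reshape(S, T, Q)
    off = logB.max(axis=2)  # per-observation offset for numerical safety
    B = np.exp(logB - off[:, :, None])  # (S, T, Q)

    alpha = np.empty((S, T, Q))
    c = np.empty((S, T))
    a = model.pi[None, :] * B[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ model.A) * B[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]

    beta = np.empty((S, T, Q))
    beta[:, T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[:, t] = ((B[:, t + 1] * beta[:, t + 1]) @ model.A.T) / c[:, t + 1, None]

    loglik = float(np.log(c).sum() + off.sum())

    gamma = alpha * beta  # (S, T, Q); rows sum to 1
    # transition counts: xi_t(i,j) = alpha_t(i) a_ij B_{t+1}(j) beta_{t+1}(j) / c_{t+1}
    xi_sum = np.zeros((Q, Q))
    for t in range(T - 1):
        right = B[:, t + 1] * beta[:, t + 1] / c[:, t + 1, None]  # (S, Q)
        xi_sum += model.A * (alpha[:, t].T @ right)

    # per-component responsibilities
    r = comp_log.reshape(S, T, Q, n)
    r = np.exp(r - r.max(axis=3, keepdims=True))
    r /= r.sum(axis=3, keepdims=True)
    gc = gamma[:, :, :, None] * r  # (S, T, Q, n)

    flat_x = X.reshape(S * T)
    gc_flat = gc.reshape(S * T, Q, n)
    stats = {
        "gamma0": gamma[:, 0, :].sum(axis=0),
        "gamma_trans": gamma[:, :-1, :].sum(axis=(0, 1)),
        "gamma_obs": gamma.reshape(S * T, Q).sum(axis=0),
        "xi_sum": xi_sum,
        "gc_sum": gc_flat.sum(axis=0),                       # (Q, n)
        "gc_x": np.einsum("mqn,m->qn", gc_flat, flat_x),     # (Q, n)
        "gc_x2": np.einsum("mqn,m->qn", gc_flat, flat_x**2),
    }
    return loglik, stats


def _m_step(model: HmmGmmModel, stats: dict) -> None:
    eps = 1e-300
    model.pi = stats["gamma0"] / stats["gamma0"].sum()
    A = stats["xi_sum"] / np.maximum(stats["gamma_trans"][:, None], eps)
    model.A = A / A.sum(axis=1, keepdims=True)

    denom = stats["gc_sum"]  # (Q, n)
    ok = denom > 1e-12
    w = np.where(ok, denom, 0.0)
    wsum = w.sum(axis=1, keepdims=True)
    model.w = np.where(wsum > 0, w / np.maximum(wsum, eps), model.w)
    mu_new = np.where(ok, stats["gc_x"] / np.maximum(denom, eps), model.mu)
    var = stats["gc_x2"] / np.maximum(denom, eps) - mu_new**2
    sigma_new = np.sqrt(np.maximum(var, 0.0))
    model.mu = mu_new
    model.sigma = np.maximum(np.where(ok, sigma_new, model.sigma), model.sigma_floor)


def _relabel(model: HmmGmmModel) -> HmmGmmModel:
    """Permute states so emission means are increasing (stable vocabulary)."""
    order = np.argsort(model.state_means, kind="stable")
    out = model.copy()
    out.pi = model.pi[order]
    out.A = model.A[np.ix_(order, order)]
    out.w = model.w[order]
    out.mu = model.mu[order]
    out.sigma = model.sigma[order]
    return out


def em_train(
    model: HmmGmmModel,
    dataset: ExpressionDataset,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> HmmGmmModel:
    """Baum-Welch over all (patient, gene) sequences sharing one parameter set.

    Stops when the relative total log-likelihood improvement drops below
    ``tol`` or after ``max_iter`` iterations.  ``max_iter=0`` (or an
    infinite ``tol``) performs no parameter update.  The returned model
    has its states relabeled in increasing order of emission mean and
    carries the accepted per-iteration log-likelihoods in
    ``loglik_history``.
    """
    model = model.copy()
    if max_iter <= 0 or np.isinf(tol):
        return _relabel(model)
    X = _sequences(dataset)
    ll_prev = None
    for it in range(max_iter):
        ll, stats = _e_step(model, X)
        if not np.isfinite(ll):
            raise FloatingPointError(f"non-finite log-likelihood at EM iteration {it}")
        model.loglik_history.append(ll)
        if ll_prev is not None and (ll - ll_prev) < tol * abs(ll_prev):
            break
        _m_step(model, stats)
        ll_prev = ll
    return _relabel(model)


# ---------------------------------------------------------------------------
# decoding


def viterbi_decode(model: HmmGmmModel, dataset: ExpressionDataset) -> dict:
    """Most probable state path per (patient, gene), in log space.

    Ties are resolved toward the lower state index.  Returns a mapping
    ``patient_id -> GeneStateMatrix`` with states in ``1..Q``.
    """
    X = _sequences(dataset)
    S, T = X.shape
    Q = model.Q
    logB, _ = emission_logprob(model, X)
    logB = logB.reshape(S, T, Q)
    logA = np.log(np.maximum(model.A, 1e-300))
    logpi = np.log(np.maximum(model.pi, 1e-300))

    delta = logpi[None, :] + logB[:, 0]
    psi = np.zeros((S, T, Q), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, :, None] + logA[None]  # (S, Q_prev, Q_cur)
        psi[:, t] = cand.argmax(axis=1)  # argmax takes the first (lowest) on ties
        delta = cand.max(axis=1) + logB[:, t]

    paths = np.empty((S, T), dtype=int)
    paths[:, T - 1] = delta.argmax(axis=1)
    for t in range(T - 2, -1, -1):
        paths[:, t] = psi[np.arange(S), t + 1, paths[:, t + 1]]

    states = paths.reshape(dataset.n_patients, dataset.n_genes, T) + 1
    return {
        p: GeneStateMatrix(list(dataset.gene_ids), list(dataset.time_points), states[i], Q)
        for i, p in enumerate(dataset.patient_ids)
    }


# ---------------------------------------------------------------------------
# baseline threshold discretizers

_BASELINES = ("average", "midrange", "max_x_max", "top_x", "efp")
_SCOPES = ("all", "row", "col")


def _scope_groups(V: np.ndarray, scope: str):
    """Yield (index, flat values) per scope group of one patient matrix."""
    G, T = V.shape
    if scope == "all":
        yield (slice(None), slice(None)), V.ravel()
    elif scope == "row":
        for g in range(G):
            yield (g, slice(None)), V[g]
    else:  # col
        for t in range(T):
            yield (slice(None), t), V[:, t]


def _efp_states(v: np.ndarray, Q: int) -> np.ndarray:
    """Equal-frequency partition of a flat value vector into states 1..Q."""
    order = np.argsort(v, kind="stable")
    base, extra = divmod(v.size, Q)
    sizes = [base + (1 if j < extra else 0) for j in range(Q)]
    states = np.empty(v.size, dtype=int)
    pos = 0
    for j, s in enumerate(sizes):
        states[order[pos: pos + s]] = j + 1
        pos += s
    return states


def baseline_discretize(
    dataset: ExpressionDataset,
    method: str,
    scope: str = "all",
    x: float = 10.0,
    Q: int = 3,
) -> dict:
    """Threshold discretizers computed per patient within a scope.

    ``scope`` selects the value pool each threshold is computed from:
    the whole patient matrix (``all``), each gene (``row``) or each time
    point (``col``).  ``average`` and ``midrange`` produce two states
    (above / not above the threshold); ``max_x_max`` marks values within
    ``x``% of the maximum; ``top_x`` marks the top ``x``% of values
    (ties broken by value order then index); ``efp`` splits each scope
    into ``Q`` equal-frequency states.
    """
    if method not in _BASELINES:
        raise ValueError(f"unknown method {method!r}; choose from {_BASELINES}")
    if scope not in _SCOPES:
        raise ValueError(f"unknown scope {scope!r}; choose from {_SCOPES}")
    if method in ("max_x_max", "top_x") and not 0 < x < 100:
        raise ValueError(f"x must be in (0, 100), got {x}")
    if not dataset.mask.all():
        raise ValueError("dataset must be imputed before discretization")

    out_Q = Q if method == "efp" else 2
    result = {}
    for i, patient in enumerate(dataset.patient_ids):
        V = dataset.values[i]
        states = np.ones(V.shape, dtype=int)
        for idx, v in _scope_groups(V, scope):
            if method == "average":
                states[idx] = np.where(v > v.mean(), 2, 1).reshape(np.shape(states[idx]))
            elif method == "midrange":
                thr = (v.min() + v.max()) / 2.0
                states[idx] = np.where(v > thr, 2, 1).reshape(np.shape(states[idx]))
            elif method == "max_x_max":
                thr = v.max() - (x / 100.0) * v.max()
                states[idx] = np.where(v >= thr, 2, 1).reshape(np.shape(states[idx]))
            elif method == "top_x":
                k = int(np.ceil(x / 100.0 * v.size))
                s = np.ones(v.size, dtype=int)
                s[np.argsort(-v, kind="stable")[:k]] = 2
                states[idx] = s.reshape(np.shape(states[idx]))
            else:  # efp
                states[idx] = _efp_states(v, Q).reshape(np.shape(states[idx]))
        sm = GeneStateMatrix(list(dataset.gene_ids), list(dataset.time_points), states, out_Q)
        sm.validate()
        result[patient] = sm
    return result
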