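"""Synthetic cohorts with known ground truth.

The generator emulates a small clinical time-course study: two response
classes of patients, tens of genes measured over a handful of time
points, and a sparse interaction network over the gene set.  Genes are
organized into modules:

* *discriminative* modules -- genes share a state program that differs
  between the two classes inside a chosen time window, and the module
  is densely wired in the network (these are the planted signal);
* *decoy* modules -- genes are expression-coherent within each patient
  (they form biclusters) but their program is drawn independently per
  patient, so they carry no class information, and they receive no
  planted network edges (network weighting should suppress them);
* *background* genes -- each follows its own fixed random program
  shared by all patients.

Expression at a time point is the state's mean (states spaced one unit
apart) plus noise, matching the mixture-emission generative assumption,
so state recovery is a fair test of the inference rather than a
model-mismatch test; a uniform-noise variant is available to probe
mismatch.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import Bicluster, ExpressionDataset, InteractionNetwork

__all__ = [
    "SyntheticTruth",
    "generate_network",
    "generate_dataset",
    "generate_benchmark",
    "baranzini_like",
]


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    module_genes: dict            # module id -> list of gene ids
    module_kind: dict             # module id -> discriminative | decoy
    programs: dict                # (module id, class label) -> state path, None for decoys
    true_states: dict             # patient id -> (G, T) state array
    planted_biclusters: dict      # class label -> list of Bicluster
    labels: np.ndarray
    seed: int
    params: dict = field(default_factory=dict)


def generate_network(
    gene_ids,
    module_sizes,
    p_in: float,
    p_out: float,
    seed: int,
) -> tuple[InteractionNetwork, dict]:
    """Stochastic-block interaction network over the gene set.

    The first ``sum(module_sizes)`` genes form consecutive modules with
    within-module edge probability ``p_in``; all other pairs (between
    modules and among leftover background genes) connect with
    probability ``p_out``.  Returns the network and the module
    assignment ``module id -> gene list``.
    """
    if not 0 <= p_out < p_in <= 1:
        raise ValueError(f"need 0 <= p_out < p_in <= 1, got p_in={p_in}, p_out={p_out}")
    gene_ids = list(gene_ids)
    if sum(module_sizes) > len(gene_ids):
        raise ValueError("module sizes exceed the number of genes")
    rng = np.random.default_rng(seed)
    module_of = {}
    pos = 0
    modules = {}
    for m, size in enumerate(module_sizes):
        modules[m] = gene_ids[pos: pos + size]
        for g in modules[m]:
            module_of[g] = m
        pos += size
    edges = []
    for i in range(len(gene_ids)):
        for j in range(i + 1, len(gene_ids)):
            gi, gj = gene_ids[i], gene_ids[j]
            same = module_of.get(gi) is not None and module_of.get(gi) == module_of.get(gj)
            p = p_in if same else p_out
            if rng.random() < p:
                edges.append((gi, gj))
    return InteractionNetwork.from_edges(edges, nodes=gene_ids), modules


def _random_walk_program(rng: np.random.Generator, T: int, Q: int) -> np.ndarray:
    """Persistent random walk over states 1..Q (stay 50%, step +-1 else)."""
    path = np.empty(T, dtype=int)
    path[0] = rng.integers(1, Q + 1)
    for t in range(1, T):
        step = rng.choice([-1, 0, 0, 1])
        path[t] = min(Q, max(1, path[t - 1] + step))
    return path


def generate_dataset(
    n_pos: int = 33,
    n_neg: int = 19,
    n_genes: int = 70,
    T: int = 7,
    Q: int = 3,
    noise_sd: float = 0.25,
    missing_rate: float = 0.05,
    decoy_modules: int = 2,
    seed: int = 0,
    n_disc_modules: int = 2,
    module_size: int = 5,
    disc_window: tuple = (2, 5),
    share_window: tuple | None = None,
    noise_model: str = "gaussian",
    identical_classes: bool = False,
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Generate a labeled two-class expression cohort with planted modules.

    Discriminative modules differ between classes at every time point of
    ``disc_window`` (inclusive, 1-based) and agree outside it.  With
    ``share_window`` set, module genes share their program only inside
    that window and run independent paths outside (the planted bicluster
    then spans exactly that window); by default they share over the full
    course.  ``identical_classes=True`` removes all class signal (both
    classes get the positive program) for null experiments.

    Expression is ``state + noise``; states sit one unit apart.
    ``noise_model`` is ``gaussian`` or ``uniform`` (same sd).  Missing
    entries are masked at ``missing_rate`` per cell, always leaving at
    least one present value per (patient, gene) series.
    """
    if T < 3 or Q < 2 or noise_sd < 0:
        raise ValueError("need T >= 3, Q >= 2, noise_sd >= 0")
    rng = np.random.default_rng(seed)
    n_patients = n_pos + n_neg
    patient_ids = [f"P{i + 1:03d}" for i in range(n_patients)]
    gene_ids = [f"G{j + 1:03d}" for j in range(n_genes)]
    labels = np.array([1] * n_pos + [-1] * n_neg)

    n_module_genes = (n_disc_modules + decoy_modules) * module_size
    if n_module_genes > n_genes:
        raise ValueError("modules do not fit into the gene set")

    module_genes: dict = {}
    module_kind: dict = {}
    pos = 0
    for m in range(n_disc_modules):
        module_genes[m] = gene_ids[pos: pos + module_size]
        module_kind[m] = "discriminative"
        pos += module_size
    for d in range(decoy_modules):
        m = n_disc_modules + d
        module_genes[m] = gene_ids[pos: pos + module_size]
        module_kind[m] = "decoy"
        pos += module_size
    background = gene_ids[pos:]

    w0, w1 = disc_window
    if not 1 <= w0 <= w1 <= T:
        raise ValueError(f"disc_window {disc_window} outside [1, {T}]")
    s0, s1 = share_window if share_window is not None else (1, T)

    # class programs for discriminative modules: equal outside the
    # window, forced different inside it
    programs: dict = {}
    for m in range(n_disc_modules):
        base = _random_walk_program(rng, T, Q)
        pos_prog = base.copy()
        neg_prog = base.copy()
        for t in range(w0 - 1, w1):
            a = rng.integers(1, Q + 1)
            b = rng.integers(1, Q)
            b = b if b < a else b + 1  # uniform over states != a
            pos_prog[t], neg_prog[t] = a, b
        programs[(m, 1)] = pos_prog
        programs[(m, -1)] = pos_prog.copy() if identical_classes else neg_prog
    for d in range(decoy_modules):
        m = n_disc_modules + d
        programs[(m, 1)] = programs[(m, -1)] = None  # drawn per patient

    background_prog = {g: _random_walk_program(rng, T, Q) for g in background}

    gidx = {g: j for j, g in enumerate(gene_ids)}
    states = np.empty((n_patients, n_genes, T), dtype=int)
    for i, lab in enumerate(labels):
        for m, genes in module_genes.items():
            if module_kind[m] == "discriminative":
                prog = programs[(m, int(lab))]
                for g in genes:
                    path = prog.copy()
                    # outside the shared window each gene walks on its own
                    for t in range(T):
                        if not s0 - 1 <= t <= s1 - 1:
                            path[t] = rng.integers(1, Q + 1)
                    states[i, gidx[g]] = path
            else:
                prog = _random_walk_program(rng, T, Q)
                for g in genes:
                    states[i, gidx[g]] = prog
        for g in background:
            states[i, gidx[g]] = background_prog[g]

    if noise_model == "gaussian":
        noise = rng.normal(0.0, noise_sd, size=states.shape)
    elif noise_model == "uniform":
        half = noise_sd * np.sqrt(3.0)
        noise = rng.uniform(-half, half, size=states.shape)
    else:
        raise ValueError(f"unknown noise_model {noise_model!r}")
    values = states.astype(float) + noise

    mask = rng.random(states.shape) >= missing_rate
    # every (patient, gene) series keeps at least one present value
    empty = ~mask.any(axis=2)
    for i, j in zip(*np.nonzero(empty)):
        mask[i, j, rng.integers(0, T)] = True
    values = np.where(mask, values, np.nan)

    planted = {1: [], -1: []}
    for m in range(n_disc_modules):
        for lab in (1, -1):
            prog = programs[(m, lab)]
            planted[lab].append(
                Bicluster(
                    genes=tuple(sorted(module_genes[m])),
                    t_start=s0,
                    t_end=s1,
                    profile=tuple(int(s) for s in prog[s0 - 1: s1]),
                )
            )

    dataset = ExpressionDataset(
        patient_ids, gene_ids, list(range(1, T + 1)), values, mask, labels
    )
    dataset.validate()
    truth = SyntheticTruth(
        module_genes=module_genes,
        module_kind=module_kind,
        programs=programs,
        true_states={p: states[i].copy() for i, p in enumerate(patient_ids)},
        planted_biclusters=planted,
        labels=labels.copy(),
        seed=seed,
        params=dict(
            n_pos=n_pos, n_neg=n_neg, n_genes=n_genes, T=T, Q=Q,
            noise_sd=noise_sd, missing_rate=missing_rate,
            decoy_modules=decoy_modules, n_disc_modules=n_disc_modules,
            module_size=module_size, disc_window=disc_window,
            share_window=(s0, s1), noise_model=noise_model,
            identical_classes=identical_classes,
        ),
    )
    return dataset, truth


def generate_benchmark(
    seed: int = 0,
    p_in: float = 0.8,
    p_out: float = 0.04,
    **dataset_kwargs,
) -> tuple[ExpressionDataset, InteractionNetwork, SyntheticTruth]:
    """Dataset plus matching network: discriminative modules are wired at
    ``p_in``; decoy module genes get no planted edges (background rate only)."""
    dataset, truth = generate_dataset(seed=seed, **dataset_kwargs)
    disc_sizes = [
        len(truth.module_genes[m])
        for m in sorted(truth.module_genes)
        if truth.module_kind[m] == "discriminative"
    ]
    network, _ = generate_network(
        dataset.gene_ids, disc_sizes, p_in=p_in, p_out=p_out, seed=seed + 1
    )
    return dataset, network, truth


def baranzini_like(seed: int = 0, **overrides):
    """Preset mirroring the shape of a 52-patient, 70-gene, 7-time-point
    IFN-beta response study: 33 good / 19 bad responders, two planted
    discriminative modules, two decoys, moderate noise."""
    params = dict(
        n_pos=33, n_neg=19, n_genes=70, T=7, Q=3,
        noise_sd=0.25, missing_rate=0.05,
        n_disc_modules=2, decoy_modules=2, module_size=5,
        disc_window=(2, 5),
    )
    params.update(overrides)
    return generate_benchmark(seed=seed, **params)
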