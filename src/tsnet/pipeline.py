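"""Stage glue: preprocess -> discretize -> bicluster -> weight.

These helpers compose the per-stage modules into the patient-profile
representation the classifier consumes.  The discretization model is
always fitted on a *training* set of patients and then applied to any
patient, so cross-validation can keep test patients out of model
fitting.
"""

from __future__ import annotations

import numpy as np

from .bicluster import ql_biclustering
from .config import PipelineConfig
from .datatypes import ExpressionDataset, InteractionNetwork, PatientProfile
from .discretize import baseline_discretize, em_train, init_model, viterbi_decode
from .network_score import score_profiles
from .preprocess import impute, normalize

__all__ = [
    "preprocess_dataset",
    "fit_discretizer",
    "discretize_dataset",
    "extract_profiles",
    "uniform_profiles",
]


def preprocess_dataset(dataset: ExpressionDataset, config: PipelineConfig) -> ExpressionDataset:
    """Normalize then impute (imputation operates on the normalized scale)."""
    return impute(normalize(dataset, config.normalization))


def fit_discretizer(train: ExpressionDataset, config: PipelineConfig):
    """Fit the state-inference model on a training cohort.

    Returns the trained mixture-emission HMM, or None for the baseline
    threshold discretizers (whose thresholds are per-patient and need
    no fitting).
    """
    if config.discretizer != "hmmgmm":
        return None
    model = init_model(train, config.Q, sigma_floor_frac=config.sigma_floor_frac)
    return em_train(model, train, max_iter=config.em_max_iter, tol=config.em_tol)


def discretize_dataset(dataset: ExpressionDataset, config: PipelineConfig, model=None) -> dict:
    """State matrices for every patient, using a fitted model or a baseline."""
    if config.discretizer == "hmmgmm":
        if config.per_patient_model:
            out = {}
            for i, pid in enumerate(dataset.patient_ids):
                sub = dataset.subset_patients([i])
                m = fit_discretizer(sub, config)
                out.update(viterbi_decode(m, sub))
            return out
        if model is None:
            model = fit_discretizer(dataset, config)
        return viterbi_decode(model, dataset)
    return baseline_discretize(
        dataset, config.discretizer, scope=config.scope, x=config.x_percent, Q=config.Q
    )


def extract_profiles(dataset: ExpressionDataset, state_matrices: dict, config: PipelineConfig) -> list:
    """Maximal biclusters per patient, in dataset patient order (unweighted)."""
    return [
        PatientProfile(pid, ql_biclustering(state_matrices[pid], ml=config.ml, mo=config.mo))
        for pid in dataset.patient_ids
    ]


def uniform_profiles(profiles: list) -> list:
    """Equal bicluster weights: the network-free ablation arm."""
    out = []
    for prof in profiles:
        n = prof.n_biclusters
        w = np.full(n, 1.0 / n) if n else np.zeros(0)
        out.append(PatientProfile(prof.patient_id, list(prof.biclusters), w))
    return out


def build_profiles(
    dataset: ExpressionDataset,
    network: InteractionNetwork | None,
    config: PipelineConfig,
    model=None,
) -> list:
    """Full chain from (preprocessed) expression to weighted profiles."""
    states = discretize_dataset(dataset, config, model=model)
    profiles = extract_profiles(dataset, states, config)
    if network is None:
        return uniform_profiles(profiles)
    return score_profiles(profiles, network, aggregator=config.aggregator)
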