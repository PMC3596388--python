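"""Hypergeometric connectivity scoring of biclusters in an interaction network.

A bicluster whose member genes are densely interconnected in the
protein-interaction network is more likely to capture a functional
module than one whose genes co-express by chance.  For each member gene
``i`` the association with the rest of the bicluster is the upper tail
of a hypergeometric draw: gene ``i``'s ``d_i`` interaction partners are
drawn from the other ``N - 1`` network genes, of which the ``m`` other
bicluster members are the successes; the tail probability of observing
at least the actual number of links into the bicluster measures how
surprising the connectivity is.  The bicluster's weight aggregates
``1 - p`` over members (mean by default), and weights are normalized
per patient to sum to one.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.stats import hypergeom

from .datatypes import Bicluster, InteractionNetwork, PatientProfile

__all__ = [
    "ScoreContext",
    "gene_association_p",
    "ppi_score_raw",
    "normalize_scores",
    "score_profiles",
]

_AGGREGATORS = ("mean1mp", "geomean", "minp")


class ScoreContext:
    """Precomputed network quantities: size, degrees, adjacency sets."""

    def __init__(self, network: InteractionNetwork):
        self.network = network
        self.N = network.n_nodes
        self.nodes = set(network.nodes)
        self.adjacency = {g: network.neighbors(g) for g in network.nodes}

    def degree(self, gene) -> int:
        return len(self.adjacency.get(gene, ()))


@lru_cache(maxsize=100_000)
def _hyper_tail(k_obs: int, pop: int, m: int, d: int) -> float:
    """P(X >= k_obs) for X ~ Hypergeometric(pop, m, d)."""
    return float(hypergeom.sf(k_obs - 1, pop, m, d))


def gene_association_p(gene_i, gene_set, context: ScoreContext) -> float:
    """Upper-tail probability of gene ``i``'s links into a gene set.

    With ``M`` the set's network members excluding ``i`` (``m = |M|``),
    ``d_i`` the degree of ``i`` and ``k`` the observed number of edges
    from ``i`` into ``M``, returns ``P(X >= k)`` for ``X ~
    Hypergeometric(N - 1, m, d_i)``.  Returns exactly 1 when ``k = 0``,
    which also covers genes absent from the network or isolated in it.
    """
    M = set(gene_set) - {gene_i}
    if not M:
        raise ValueError("gene_set must contain at least one gene besides gene_i")
    neighbors = context.adjacency.get(gene_i)
    if neighbors is None:
        return 1.0  # gene not in the network
    k_obs = len(neighbors & M)
    if k_obs == 0:
        return 1.0
    m = len(M & context.nodes)
    return _hyper_tail(k_obs, context.N - 1, m, len(neighbors))


def ppi_score_raw(
    bicluster: Bicluster, context: ScoreContext, aggregator: str = "mean1mp"
) -> float:
    """Connectivity preference of a bicluster, in [0, 1).

    ``mean1mp`` (default) averages ``1 - p`` over member genes;
    ``geomean`` returns one minus the geometric mean of the tail
    probabilities; ``minp`` returns ``1 - min(p)``.  All three are 0
    when no member gene has any edge into the bicluster and grow as the
    members interconnect beyond chance.
    """
    if aggregator not in _AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}; choose from {_AGGREGATORS}")
    if len(bicluster.genes) < 2:
        raise ValueError("bicluster must contain at least 2 genes")
    genes = set(bicluster.genes)
    ps = np.array([gene_association_p(g, genes, context) for g in bicluster.genes])
    if aggregator == "mean1mp":
        return float(np.mean(1.0 - ps))
    if aggregator == "geomean":
        return float(1.0 - np.exp(np.mean(np.log(ps))))
    return float(1.0 - ps.min())


def normalize_scores(profile: PatientProfile) -> PatientProfile:
    """Normalize raw bicluster scores to per-patient weights summing to 1.

    If every raw score is 0 (no network support anywhere), the weights
    fall back to uniform.
    """
    if not profile.biclusters:
        raise ValueError("profile has no biclusters to normalize")
    raw = np.array([bc.score for bc in profile.biclusters], dtype=float)
    total = raw.sum()
    weights = raw / total if total > 0 else np.full(raw.size, 1.0 / raw.size)
    out = PatientProfile(profile.patient_id, list(profile.biclusters), weights)
    out.validate()
    return out


def score_profiles(
    profiles: list,
    network: InteractionNetwork,
    aggregator: str = "mean1mp",
) -> list:
    """Score every bicluster of every profile and normalize per patient.

    Profiles with zero biclusters pass through unchanged (they compare
    as dissimilar to everyone downstream).
    """
    context = ScoreContext(network)
    out = []
    for prof in profiles:
        if not prof.biclusters:
            out.append(PatientProfile(prof.patient_id, [], np.zeros(0)))
            continue
        scored = [
            bc.with_score(ppi_score_raw(bc, context, aggregator))
            for bc in prof.biclusters
        ]
        out.append(normalize_scores(PatientProfile(prof.patient_id, scored)))
    return out
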