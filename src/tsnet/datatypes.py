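"""Core domain containers shared by every pipeline stage.

The pipeline moves a patient cohort through four representations:

``ExpressionDataset``
    the raw (or preprocessed) patients x genes x time-points tensor of
    real-valued expression, with a missingness mask and binary response
    labels;
``GeneStateMatrix``
    one per patient -- each gene's qualitative state path (integers
    ``1..Q``) over the time course, produced by a discretizer;
``Bicluster`` / ``PatientProfile``
    a subset of genes sharing an identical state profile over a
    contiguous time window, and a patient's full collection of such
    biclusters with network-derived weights;
``InteractionNetwork``
    the undirected protein-interaction graph over the gene universe,
    used to weight biclusters by connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "ExpressionDataset",
    "InteractionNetwork",
    "GeneStateMatrix",
    "Bicluster",
    "PatientProfile",
]


@dataclass
class ExpressionDataset:
    """Patients x genes x time-points expression tensor with labels.

    Parameters
    ----------
    patient_ids, gene_ids : list of str
        Unique identifiers; axis order of ``values``.
    time_points : list of int
        1-based, strictly increasing time indices (third axis).
    values : ndarray, shape (P, G, T)
        Real expression values; entries where ``mask`` is False are
        undefined (conventionally NaN).
    mask : ndarray of bool, shape (P, G, T)
        True where a measurement is present.
    labels : ndarray of int, shape (P,), optional
        +1 = good responder (positive class), -1 = bad responder.
    """

    patient_ids: list
    gene_ids: list
    time_points: list
    values: np.ndarray
    mask: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)

    # -- shape helpers -------------------------------------------------
    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return len(self.time_points)

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("patient_ids are not unique")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        tp = list(self.time_points)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time_points must be strictly increasing")
        shape = (self.n_patients, self.n_genes, self.n_times)
        if self.values.shape != shape or self.mask.shape != shape:
            raise ValueError(
                f"tensor shape mismatch: values {self.values.shape}, "
                f"mask {self.mask.shape}, expected {shape}"
            )
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite value at a position marked present")
        if self.labels is not None:
            if self.labels.shape != (self.n_patients,):
                raise ValueError("labels length does not match patients")
            if not set(np.unique(self.labels)) <= {-1, 1}:
                raise ValueError("labels must be +1 or -1")

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            list(self.patient_ids),
            list(self.gene_ids),
            list(self.time_points),
            self.values.copy(),
            self.mask.copy(),
            None if self.labels is None else self.labels.copy(),
        )

    def truncate(self, n: int) -> "ExpressionDataset":
        """Restrict to the first ``n`` time points (early-stage evaluation)."""
        if not 1 <= n <= self.n_times:
            raise ValueError(f"n={n} outside [1, {self.n_times}]")
        return ExpressionDataset(
            list(self.patient_ids),
            list(self.gene_ids),
            list(self.time_points[:n]),
            self.values[:, :, :n].copy(),
            self.mask[:, :, :n].copy(),
            None if self.labels is None else self.labels.copy(),
        )

    def subset_patients(self, idx: Sequence[int]) -> "ExpressionDataset":
        idx = list(idx)
        return ExpressionDataset(
            [self.patient_ids[i] for i in idx],
            list(self.gene_ids),
            list(self.time_points),
            self.values[idx].copy(),
            self.mask[idx].copy(),
            None if self.labels is None else self.labels[idx].copy(),
        )


@dataclass
class InteractionNetwork:
    """Undirected simple graph over gene identifiers (no self-loops)."""

    graph: nx.Graph

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple], nodes: Iterable | None = None
    ) -> "InteractionNetwork":
        """Build a simple graph; self-loops and duplicate edges are dropped."""
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for u, v in edges:
            if u == v:
                continue
            g.add_edge(u, v)
        return cls(g)

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list:
        return [tuple(sorted(e)) for e in self.graph.edges]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, gene) -> int:
        return self.graph.degree(gene) if gene in self.graph else 0

    def neighbors(self, gene) -> set:
        return set(self.graph[gene]) if gene in self.graph else set()

    def restrict_to(self, universe: Iterable) -> tuple["InteractionNetwork", int]:
        """Keep only edges with both endpoints in ``universe``.

        Returns the restricted network and the number of dropped edges.
        Idempotent: restricting twice to the same universe is a no-op.
        """
        universe = set(universe)
        kept, dropped = [], 0
        for u, v in self.graph.edges:
            if u in universe and v in universe:
                kept.append((u, v))
            else:
                dropped += 1
        g = nx.Graph()
        g.add_nodes_from(n for n in self.graph.nodes if n in universe)
        g.add_edges_from(kept)
        return InteractionNetwork(g), dropped


@dataclass
class GeneStateMatrix:
    """Discrete state path (1..Q) per gene over the time course; one per patient."""

    gene_ids: list
    time_points: list
    states: np.ndarray  # (G, T) int
    Q: int

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)

    def validate(self) -> None:
        if self.states.shape != (len(self.gene_ids), len(self.time_points)):
            raise ValueError("state matrix shape mismatch")
        if self.states.size and (self.states.min() < 1 or self.states.max() > self.Q):
            raise ValueError(f"states outside [1, {self.Q}]")


@dataclass(frozen=True)
class Bicluster:
    """Genes sharing one state profile over a contiguous time window.

    ``t_start``/``t_end`` are inclusive 1-based time indices; ``profile``
    holds the common state at each window position.  ``score`` carries the
    network-connectivity weight and does not participate in equality, so
    biclusters can be compared as combinatorial objects.
    """

    genes: tuple
    t_start: int
    t_end: int
    profile: tuple
    score: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "profile", tuple(int(s) for s in self.profile))
        if self.t_end - self.t_start + 1 != len(self.profile):
            raise ValueError("profile length does not match window length")

    @property
    def width(self) -> int:
        return self.t_end - self.t_start + 1

    @property
    def size(self) -> int:
        """Number of cells |G| x |J| covered by the bicluster."""
        return len(self.genes) * self.width

    @property
    def key(self) -> tuple:
        return (self.genes, self.t_start, self.t_end, self.profile)

    def with_score(self, score: float) -> "Bicluster":
        return replace(self, score=float(score))


@dataclass
class PatientProfile:
    """A patient's biclusters plus their normalized connectivity weights."""

    patient_id: str
    biclusters: list
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)

    @property
    def n_biclusters(self) -> int:
        return len(self.biclusters)

    def validate(self) -> None:
        if self.weights is None:
            return
        if len(self.weights) != len(self.biclusters):
            raise ValueError("one weight per bicluster required")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if self.biclusters and abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")
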