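"""Gambit-of-the-group social networks and per-individual metrics.

Individuals recorded in the same flocking event are assumed to associate.
Events within a sampling period (a weekend, in the study design: 13
weekends per winter over three winters, 39 networks) are collected into a
binary group-by-individual (GBI) incidence matrix from which pairwise
association weights are computed, by default the simple ratio index
SRI = n_AB / (n_A + n_B - n_AB).

Per-node metrics: degree (number of associates), strength (summed edge
weights), eigenvector centrality on the binarised and on the weighted
graph (leading eigenvector per connected component, globally scaled so
the maximum is 1), and betweenness (number of shortest unit-length paths
through the node, endpoints excluded, equal-path splitting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .events import FlockingEvent

__all__ = [
    "GroupByIndividual",
    "AssociationMatrix",
    "build_gbi",
    "association_matrix",
    "network_metrics",
    "METRIC_NAMES",
]

METRIC_NAMES = (
    "degree",
    "strength",
    "eigen_centrality",
    "weighted_eigen_centrality",
    "betweenness",
)


@dataclass
class GroupByIndividual:
    events: list[str]
    individuals: list[str]
    incidence: np.ndarray  # binary, events x individuals

    def __post_init__(self) -> None:
        assert self.incidence.shape == (len(self.events), len(self.individuals))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.incidence, index=self.events, columns=self.individuals
        )


@dataclass
class AssociationMatrix:
    individuals: list[str]
    weights: np.ndarray  # symmetric, zero diagonal
    index: str  # "sri" | "count"
    _pos: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._pos = {v: i for i, v in enumerate(self.individuals)}

    def loc(self, a: str, b: str) -> float:
        return float(self.weights[self._pos[a], self._pos[b]])

    def to_edgelist(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(len(self.individuals), k=1)
        w = self.weights[iu, ju]
        keep = w > 0
        return pd.DataFrame(
            {
                "id1": [self.individuals[i] for i in iu[keep]],
                "id2": [self.individuals[j] for j in ju[keep]],
                "weight": w[keep],
            }
        )


def build_gbi(events: list[FlockingEvent]) -> GroupByIndividual:
    """Binary event-by-individual incidence matrix for one sampling period."""
    individuals = sorted({m for e in events for m in e.members})
    pos = {v: i for i, v in enumerate(individuals)}
    inc = np.zeros((len(events), len(individuals)), dtype=np.int8)
    for r, e in enumerate(events):
        for m in e.members:
            inc[r, pos[m]] = 1
    return GroupByIndividual([e.event_id for e in events], individuals, inc)


def association_matrix(gbi: GroupByIndividual, index: str = "sri") -> AssociationMatrix:
    """Pairwise association weights from a GBI matrix.

    ``count`` gives raw co-membership counts n_AB; ``sri`` the simple
    ratio index n_AB / (n_A + n_B - n_AB), the fraction of events
    involving either individual in which both appear (in [0, 1]).
    """
    inc = gbi.incidence.astype(float)
    n_ab = inc.T @ inc  # co-occurrence counts; diagonal = sightings n_A
    n_a = np.diag(n_ab).copy()
    if index == "count":
        w = n_ab.copy()
    elif index == "sri":
        denom = n_a[:, None] + n_a[None, :] - n_ab
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(denom > 0, n_ab / denom, 0.0)
    else:
        raise ValueError(f"unknown association index {index!r}")
    np.fill_diagonal(w, 0.0)
    return AssociationMatrix(list(gbi.individuals), w, index)


def _component_eigencentrality(adj: np.ndarray) -> np.ndarray:
    """Non-negative leading eigenvector per connected component.

    Scores are computed on each component's adjacency separately (the
    leading eigenvector of a disconnected graph is not globally defined),
    then scaled together so the overall maximum is 1. Isolated nodes
    score 0.
    """
    n = adj.shape[0]
    scores = np.zeros(n)
    g = nx.from_numpy_array(adj)
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        if len(comp) == 1:
            continue
        sub = adj[np.ix_(comp, comp)]
        w, v = np.linalg.eigh(sub)
        lead = np.abs(v[:, -1])
        scores[comp] = lead * np.sqrt(w[-1]) if w[-1] > 0 else 0.0
    m = scores.max()
    return scores / m if m > 0 else scores


def network_metrics(assoc: AssociationMatrix) -> pd.DataFrame:
    """Per-individual node metrics for one period network.

    Returns a frame indexed by individual with columns ``degree``,
    ``strength``, ``eigen_centrality``, ``weighted_eigen_centrality`` and
    ``betweenness``. Betweenness counts shortest paths on the binarised
    graph with unit edge lengths (Brandes accumulation, endpoints
    excluded); an isolated node gets 0 everywhere.
    """
    w = assoc.weights
    if not np.allclose(w, w.T):
        raise ValueError("association matrix must be symmetric")
    if np.any(w < 0):
        raise ValueError("association weights must be non-negative")
    binary = (w > 0).astype(float)
    degree = binary.sum(axis=1)
    strength = w.sum(axis=1)
    ec = _component_eigencentrality(binary)
    wec = _component_eigencentrality(w)
    g = nx.from_numpy_array(binary)
    bt = nx.betweenness_centrality(g, normalized=False)
    betweenness = np.array([bt[i] for i in range(len(assoc.individuals))])
    return pd.DataFrame(
        {
            "degree": degree,
            "strength": strength,
            "eigen_centrality": ec,
            "weighted_eigen_centrality": wec,
            "betweenness": betweenness,
        },
        index=pd.Index(assoc.individuals, name="individual"),
    )


def metrics_long(metrics_by_period: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-period metric frames into tidy (individual, period, metric, value)."""
    frames = []
    for period, df in metrics_by_period.items():
        m = df.reset_index().melt(
            id_vars="individual", var_name="metric", value_name="value"
        )
        m.insert(1, "period", period)
        frames.append(m)
    return pd.concat(frames, ignore_index=True)
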