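"""Natal similarity matrices for use as random-effect covariances.

Two constructions are provided, both yielding symmetric matrices with
unit diagonal and off-diagonal entries in [0, 1]:

* spatial proximity — 1 minus the scaled Euclidean distance between the
  natal nestboxes of each pair of individuals (1 = same box, 0 = the
  maximally distant pair);
* environmental similarity — five natal-environment variables (altitude,
  edge distance index, northness, oak density within 75 m, square-root
  territory size) are z-scored and the pairwise Euclidean distance in the
  standardised 5-D space is rescaled the same way.

Neither transform guarantees positive semi-definiteness, so
:func:`ensure_psd` repairs a matrix by eigenvalue clipping (or ridging)
before it enters a mixed model as a covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "NestboxLocation",
    "SimilarityMatrix",
    "spatial_proximity_matrix",
    "environmental_similarity_matrix",
    "ensure_psd",
    "ENV_VARIABLES",
]

ENV_VARIABLES = (
    "altitude",
    "edge_distance_index",
    "northness",
    "oak_density_75m",
    "sqrt_territory_size",
)


@dataclass
class NestboxLocation:
    box_id: str
    x: float
    y: float
    section: str


@dataclass
class SimilarityMatrix:
    """Unit-diagonal similarity structure over ordered individuals."""

    ids: list[str]
    values: np.ndarray
    kind: str  # "spatial" | "envsim" | other label
    frobenius_distortion: float = 0.0
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.ids)}

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def submatrix(self, ids: list[str]) -> "SimilarityMatrix":
        ix = [self._index[i] for i in ids]
        return SimilarityMatrix(list(ids), self.values[np.ix_(ix, ix)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _scaled_similarity(ids: list[str], dist: np.ndarray, kind: str) -> SimilarityMatrix:
    d_max = dist.max()
    if d_max <= 0:
        raise ValueError(
            "degenerate geometry: all individuals coincide (d_max = 0), "
            "the scaled similarity is undefined"
        )
    s = 1.0 - dist / d_max
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(list(ids), s, kind)


def spatial_proximity_matrix(
    natal_box: dict[str, NestboxLocation] | pd.DataFrame,
) -> SimilarityMatrix:
    """Pairwise natal spatial proximity, scaled to [0, 1].

    ``s_ij = 1 - d_ij / d_max`` with ``d`` the Euclidean distance between
    natal nestboxes and ``d_max`` the largest observed pairwise distance;
    the diagonal is 1 (maximum proximity with oneself). Individuals born
    in the same box get off-diagonal similarity 1.
    """
    if isinstance(natal_box, pd.DataFrame):
        ids = list(natal_box["individual"])
        xy = natal_box[["x", "y"]].to_numpy(float)
    else:
        ids = list(natal_box)
        xy = np.array([[natal_box[i].x, natal_box[i].y] for i in ids], float)
    if len(ids) < 2:
        raise ValueError("need at least 2 individuals with coordinates")
    if not np.all(np.isfinite(xy)):
        raise ValueError("non-finite nestbox coordinates")
    dist = squareform(pdist(xy))
    return _scaled_similarity(ids, dist, "spatial")


def environmental_similarity_matrix(profiles: pd.DataFrame) -> SimilarityMatrix:
    """Natal environmental similarity from the five environment variables.

    Each variable is standardised to mean 0 and variance 1 across the
    included individuals; the Euclidean distance between standardised
    profiles is converted to a similarity by the same ``1 - d/d_max``
    scaling as the spatial matrix. Individuals with any missing variable
    are dropped with a warning.
    """
    df = profiles.set_index("individual") if "individual" in profiles else profiles
    cols = [c for c in ENV_VARIABLES if c in df.columns]
    if len(cols) != len(ENV_VARIABLES):
        missing = set(ENV_VARIABLES) - set(cols)
        raise ValueError(f"missing environment variables: {sorted(missing)}")
    vals = df[list(ENV_VARIABLES)].astype(float)
    complete = vals.notna().all(axis=1)
    if not complete.all():
        warnings.warn(
            f"dropping {(~complete).sum()} individuals with missing "
            "environment values",
            stacklevel=2,
        )
        vals = vals[complete]
    if len(vals) < 2:
        raise ValueError("need at least 2 individuals with complete profiles")
    z = vals.to_numpy()
    sd = z.std(axis=0)
    for name, s in zip(ENV_VARIABLES, sd):
        if s == 0:
            raise ValueError(f"zero-variance environment variable: {name}")
    z = (z - z.mean(axis=0)) / sd
    dist = squareform(pdist(z))
    return _scaled_similarity(list(vals.index), dist, "envsim")


def ensure_psd(
    m: SimilarityMatrix, method: str = "clip", tol: float = 1e-8
) -> SimilarityMatrix:
    """Repair a similarity matrix to be a valid covariance.

    ``clip`` floors the eigenvalues at ``tol`` and reconstructs; ``ridge``
    adds the smallest multiple of the identity bringing the minimum
    eigenvalue to ``tol``. Either way the diagonal is rescaled back to 1
    and the Frobenius distance to the input is recorded on the result as
    ``frobenius_distortion``. An already-PSD matrix is returned unchanged.
    """
    w, V = np.linalg.eigh(m.values)
    if w[0] >= tol:
        return SimilarityMatrix(list(m.ids), m.values, m.kind, 0.0)
    if method == "clip":
        fixed = (V * np.maximum(w, tol)) @ V.T
    elif method == "ridge":
        fixed = m.values + (tol - w[0]) * np.eye(len(m.ids))
    else:
        raise ValueError(f"unknown method {method!r}")
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    fixed = 0.5 * (fixed + fixed.T)
    dist = float(np.linalg.norm(fixed - m.values, "fro"))
    return SimilarityMatrix(list(m.ids), fixed, m.kind, dist)
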