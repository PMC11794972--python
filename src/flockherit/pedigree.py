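"""Pedigrees and additive genetic relatedness.

A pedigree is an ordered set of (id, sire, dam) records, parents before
offspring. From it the expected additive relationship matrix A (twice the
kinship) is built with the tabular method; a Monte-Carlo gene-dropping
routine provides an independent estimate of the same quantity for
cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "AMatrix",
    "read_pedigree",
    "prune_informative",
    "additive_relationship",
    "gene_drop_relatedness",
]

#: strings accepted as "parent unknown" in input files
UNKNOWN_TOKENS = ("", "NA", "NaN", "nan", "0", "*", ".", "na")


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Attributes
    ----------
    ids : list of str
        Individual identifiers, parents before offspring.
    sire, dam : numpy int arrays
        Index of each individual's sire/dam in ``ids``; -1 when unknown.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {v: i for i, v in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, individual: str) -> int:
        return self._index[individual]

    @property
    def founders(self) -> list[str]:
        return [
            v for i, v in enumerate(self.ids) if self.sire[i] < 0 and self.dam[i] < 0
        ]

    def to_frame(self) -> pd.DataFrame:
        sire = [self.ids[s] if s >= 0 else "" for s in self.sire]
        dam = [self.ids[d] if d >= 0 else "" for d in self.dam]
        return pd.DataFrame({"id": self.ids, "sire": sire, "dam": dam})

    @classmethod
    def from_records(
        cls, records: list[tuple[str, str | None, str | None]]
    ) -> "Pedigree":
        """Build from (id, sire, dam) triples; ``None`` means unknown.

        Parents appearing without a record of their own are inserted as
        founders. Records are topologically sorted; cycles and
        self-parenting are rejected.
        """
        ids = [r[0] for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate ids in pedigree: {dupes}")
        parents: dict[str, tuple[str | None, str | None]] = {}
        for iid, sire, dam in records:
            if iid == sire or iid == dam:
                raise PedigreeError(f"self-parenting: {iid!r} is its own parent")
            parents[iid] = (sire, dam)
        # closure: parents named but not recorded become founders
        for iid in list(parents):
            for p in parents[iid]:
                if p is not None and p not in parents:
                    parents[p] = (None, None)
        order = _toposort(parents)
        index = {v: i for i, v in enumerate(order)}
        sire_ix = np.array(
            [index[parents[v][0]] if parents[v][0] is not None else -1 for v in order],
            dtype=np.int64,
        )
        dam_ix = np.array(
            [index[parents[v][1]] if parents[v][1] is not None else -1 for v in order],
            dtype=np.int64,
        )
        return cls(ids=order, sire=sire_ix, dam=dam_ix)


def _toposort(parents: dict[str, tuple[str | None, str | None]]) -> list[str]:
    """Kahn-style topological sort, parents first; cycles reported with a chain."""
    order: list[str] = []
    state: dict[str, int] = {}  # 0 unvisited, 1 in progress, 2 done

    def visit(node: str, chain: list[str]) -> None:
        if state.get(node) == 2:
            return
        if state.get(node) == 1:
            cyc = chain[chain.index(node):] + [node]
            raise PedigreeError(
                "individual is its own ancestor: " + " -> ".join(cyc)
            )
        state[node] = 1
        for p in parents[node]:
            if p is not None:
                visit(p, chain + [node])
        state[node] = 2
        order.append(node)

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(parents) + 100))
    try:
        for node in parents:
            visit(node, [])
    finally:
        sys.setrecursionlimit(old)
    return order


def read_pedigree(path, unknown: tuple[str, ...] = UNKNOWN_TOKENS) -> Pedigree:
    """Read a CSV with columns ``id,sire,dam`` into a validated :class:`Pedigree`.

    Parameters
    ----------
    path : path or file-like
        Delimited text; extra columns are ignored.
    unknown : tuple of str
        Tokens encoding an unknown parent (default: empty, NA, 0, ``*``, ``.``).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    missing = {"id", "sire", "dam"} - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree file lacks columns: {sorted(missing)}")
    unk = {u.lower() for u in unknown} | {""}

    def clean(v: str) -> str | None:
        v = v.strip()
        return None if v.lower() in unk else v

    records = [
        (row.id.strip(), clean(row.sire), clean(row.dam))
        for row in df.itertuples(index=False)
    ]
    return Pedigree.from_records(records)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def prune_informative(ped: Pedigree, focal: set[str]) -> Pedigree:
    """Prune to focal individuals and their ancestry.

    Keeps every focal individual plus all its pedigree ancestors; because
    relatedness between two individuals is a function of their common
    ancestry only, this preserves every A-matrix entry among retained
    individuals. Focal ids absent from the pedigree are dropped with a
    warning.
    """
    if not focal:
        raise PedigreeError("empty focal set")
    known = set(ped.ids)
    missing = focal - known
    if missing:
        import warnings

        warnings.warn(
            f"{len(missing)} focal ids not in pedigree were ignored", stacklevel=2
        )
    focal_ix = {ped.index_of(f) for f in focal & known}
    if not focal_ix:
        raise PedigreeError("no focal individual is present in the pedigree")
    keep = set()
    stack = list(focal_ix)
    while stack:
        i = stack.pop()
        if i in keep:
            continue
        keep.add(i)
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0:
                stack.append(int(p))
    records = [
        (
            ped.ids[i],
            ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else None,
            ped.ids[ped.dam[i]] if ped.dam[i] >= 0 else None,
        )
        for i in sorted(keep)
    ]
    return Pedigree.from_records(records)


@dataclass
class AMatrix:
    """Additive relationship matrix over ordered individuals.

    ``values[i, j]`` is the expected fraction of alleles shared identical
    by descent between individuals i and j, i.e. twice the kinship; the
    diagonal is ``1 + F_i`` with F the inbreeding coefficient.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.ids)}

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, ids: list[str]) -> "AMatrix":
        ix = [self._index[i] for i in ids]
        return AMatrix(list(ids), self.values[np.ix_(ix, ix)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_long(self) -> pd.DataFrame:
        """3-column long format (upper triangle incl. diagonal)."""
        iu, ju = np.triu_indices(len(self.ids))
        return pd.DataFrame(
            {
                "id1": [self.ids[i] for i in iu],
                "id2": [self.ids[j] for j in ju],
                "value": self.values[iu, ju],
            }
        )


def additive_relationship(ped: Pedigree) -> AMatrix:
    """Expected additive relatedness by the tabular method.

    Processing individuals in pedigree order (parents first):
    ``A[i, i] = 1 + 0.5 * A[sire_i, dam_i]`` (inbreeding from related
    parents; 0 when either parent is unknown) and for earlier j,
    ``A[i, j] = 0.5 * (A[j, sire_i] + A[j, dam_i])``.
    """
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return AMatrix(list(ped.ids), A)


def gene_drop_relatedness(
    ped: Pedigree, n_reps: int = 100_000, seed: int = 0, return_se: bool = False
):
    """Monte-Carlo relatedness by gene dropping.

    Each founder receives two unique alleles; every descendant inherits one
    allele from each parent uniformly at random (an unknown parent
    contributes a fresh unique allele). The returned matrix is the
    empirical mean over replicates of twice the kinship: for each pair,
    the fraction of the four allele comparisons that are identical by
    descent, times two. Agrees with :func:`additive_relationship` in
    expectation. With ``return_se=True`` also returns the elementwise
    Monte-Carlo standard error (empirical SD across replicates divided
    by sqrt(n_reps)).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(ped)
    # allele labels per (individual, chromosome copy, replicate)
    alleles = np.empty((n, 2, n_reps), dtype=np.int64)
    next_label = 0
    for i in range(n):
        for c, p in enumerate((ped.sire[i], ped.dam[i])):
            if p < 0:
                alleles[i, c, :] = next_label
                next_label += 1
            else:
                pick = rng.integers(0, 2, size=n_reps)
                alleles[i, c, :] = alleles[p, pick, np.arange(n_reps)]
    A = np.empty((n, n))
    SE = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            # per-replicate IBD sharing over the 4 allele pairings; x2 => A scale
            per_rep = 2.0 * np.mean(
                alleles[i, :, None, :] == alleles[j, None, :, :], axis=(0, 1)
            )
            A[i, j] = A[j, i] = per_rep.mean()
            SE[i, j] = SE[j, i] = per_rep.std() / np.sqrt(n_reps)
    return (A, SE) if return_se else A
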