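"""Strain-to-strain distance matrices and the Mantel permutation test.

Three distances drive the analysis, all stored in the same
:class:`DistanceMatrix` container and told apart by a role tag:

``d_G``
    genetic distance — the patristic (branch-length path) distance between
    two strains on the phylogeny;
``d_P``
    metabolic phenotypic distance — Euclidean distance between two strains'
    vectors of growth yields (quantitative mode) or of binary growth calls
    (qualitative mode, where ``d_P**2`` is the number of substrates used
    differently);
``d_M``
    metabolic pathway distance — Euclidean distance between two strains'
    vectors of pathway completion fractions.

Association between two distance matrices is tested with the classic Mantel
test: Pearson correlation over the off-diagonal pairs, with a null built by
jointly permuting rows and columns of the second matrix.
"""

from __future__ import annotations

import io as _io
import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .exceptions import (
    DegenerateMatrixError,
    InvalidParameterError,
    NewickParseError,
    TableParseError,
)

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "parse_newick",
    "tree_to_newick",
    "patristic_matrix",
    "euclidean_matrix",
    "mantel",
]


@dataclass
class DistanceMatrix:
    """Symmetric strain x strain distance matrix with labelled axes.

    Parameters
    ----------
    labels : list of str
        Strain identifiers, one per row/column.
    values : ndarray of shape (n, n)
        Nonnegative, symmetric, zero-diagonal distances.
    role : str
        One of ``"genetic"`` (d_G), ``"phenotypic"`` (d_P),
        ``"metabolic"`` (d_M), or any other descriptive tag.
    """

    labels: list[str]
    values: np.ndarray
    role: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InvalidParameterError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise TableParseError("duplicate strain labels in distance matrix")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("distances must be finite")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise InvalidParameterError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise InvalidParameterError("distance matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) entries in scipy's condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        """Return a copy with rows/columns in the given label order."""
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.role)


@dataclass
class MantelResult:
    """Outcome of a Mantel test between two distance matrices."""

    r: float
    n_perm: int
    p_value: float
    seed: int | None = None
    method: str = "permutation"
    r2: float = field(init=False)

    def __post_init__(self) -> None:
        self.r2 = self.r**2

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MantelResult(r={self.r:.4f}, R2={self.r2:.4f}, "
            f"p={self.p_value:.4g}, n_perm={self.n_perm}, method={self.method!r})"
        )


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a dendropy tree.

    Raises
    ------
    NewickParseError
        If the string is not well-formed Newick.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several unrelated types
        raise NewickParseError(f"could not parse Newick input: {exc}") from exc
    if not tree.leaf_nodes():
        raise NewickParseError("tree has no leaves")
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Serialise a tree to a Newick string with branch lengths."""
    out = _io.StringIO()
    tree.write(file=out, schema="newick", suppress_rooting=True)
    return out.getvalue().strip()


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Patristic distance matrix (role ``genetic``, i.e. d_G).

    Each entry is the sum of branch lengths along the path between the two
    leaves.  Computed by a single postorder accumulation of leaf-to-node
    depths, independent of dendropy's own distance-matrix facility.
    """
    leaves = tree.leaf_nodes()
    labels = [lf.taxon.label for lf in leaves]
    if len(set(labels)) != len(labels):
        raise TableParseError("duplicate leaf labels in tree")
    n = len(labels)
    index = {id(lf): i for i, lf in enumerate(leaves)}
    dist = np.zeros((n, n))
    # depth-below-node bookkeeping: for each node, distances from each
    # descendant leaf; pairs meeting at the node get the summed depths.
    below: dict[int, list[tuple[int, float]]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = [(index[id(node)], 0.0)]
            continue
        merged: list[tuple[int, float]] = []
        child_lists = []
        for child in node.child_nodes():
            bl = child.edge.length if child.edge.length is not None else 0.0
            lst = [(i, d + bl) for i, d in below.pop(id(child))]
            child_lists.append(lst)
        for a in range(len(child_lists)):
            for b in range(a + 1, len(child_lists)):
                for i, di in child_lists[a]:
                    for j, dj in child_lists[b]:
                        dist[i, j] = dist[j, i] = di + dj
        for lst in child_lists:
            merged.extend(lst)
        below[id(node)] = merged
    return DistanceMatrix(labels, dist, role="genetic")


def euclidean_matrix(
    features: pd.DataFrame, role: str = "phenotypic"
) -> DistanceMatrix:
    """Pairwise Euclidean distances between the rows of a feature table.

    Works on quantitative growth yields (d_P in the large-panel mode), on
    binary growth calls (d_P in the sequenced-strain mode, where the squared
    distance equals the number of discordant substrates) and on pathway
    completion fractions (d_M).

    Raises
    ------
    DegenerateMatrixError
        If any entry is missing; no silent imputation is performed.
    """
    values = features.to_numpy(dtype=float)
    if values.shape[0] < 1:
        raise InvalidParameterError("need at least one strain")
    if np.isnan(values).any():
        bad = features.index[np.isnan(values).any(axis=1)].tolist()
        raise DegenerateMatrixError(f"missing feature values for strains {bad}")
    dm = squareform(pdist(values, metric="euclidean")) if len(values) > 1 else np.zeros((1, 1))
    return DistanceMatrix(list(features.index.astype(str)), dm, role=role)


def _pearson_offdiag(d1: np.ndarray, d2: np.ndarray, iu) -> float:
    x = d1[iu]
    y = d2[iu]
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        raise DegenerateMatrixError("zero variance in off-diagonal distances")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
    method: str = "permutation",
) -> MantelResult:
    """Mantel test of association between two distance matrices.

    The statistic is the Pearson correlation ``r`` over the n(n-1)/2
    off-diagonal pairs; ``R²`` is reported as ``r²``.  The null distribution
    is generated by simultaneously permuting rows and columns of ``d2``.
    The one-sided (positive association) p-value uses the add-one rule
    ``(#{r_perm >= r_obs} + 1) / (n_perm + 1)``.

    Parameters
    ----------
    method : {"permutation", "exact"}
        ``"exact"`` enumerates all n! relabellings (feasible for n <= 8) and
        returns ``p = #{r_perm >= r_obs} / n!`` with the identity included.
    """
    if d1.labels != d2.labels:
        raise InvalidParameterError(
            "distance matrices must share the same strain registry and order"
        )
    n = d1.n
    if n < 3:
        raise InvalidParameterError("Mantel test needs at least 3 strains")
    iu = np.triu_indices(n, k=1)
    r_obs = _pearson_offdiag(d1.values, d2.values, iu)

    if method == "exact":
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            p = np.array(perm)
            r_p = _pearson_offdiag(d1.values, d2.values[np.ix_(p, p)], iu)
            count += r_p >= r_obs - 1e-12
            total += 1
        return MantelResult(
            r=r_obs, n_perm=total, p_value=count / total, seed=seed, method="exact"
        )
    if method != "permutation":
        raise InvalidParameterError(f"unknown Mantel method {method!r}")

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r_p = _pearson_offdiag(d1.values, d2.values[np.ix_(p, p)], iu)
        count += r_p >= r_obs - 1e-12
    p_value = (count + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, n_perm=n_perm, p_value=p_value, seed=seed)
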