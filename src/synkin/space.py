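"""Object action-similarity space: ratings, similarity matrices, trees.

Builds the rating-derived feature space, correlates objects, clusters
them with Ward's criterion, and compares trees with a normalized
entanglement statistic plus a label-shuffling permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


class InvalidInputError(ValueError):
    """Input violates an operation's precondition."""


class FlaggedObjectError(InvalidInputError):
    """One or more object columns cannot be correlated (zero variance)."""

    def __init__(self, object_ids: list[str]):
        self.object_ids = list(object_ids)
        super().__init__(f"zero-variance object columns: {self.object_ids}")


# ---------------------------------------------------------------------------
# Rating matrix


@dataclass
class RatingMatrix:
    """Group loading per (synergy, object), each entry in [0, 1].

    ``loadings[i, j]`` is the fraction of raters who marked synergy
    ``synergy_ids[i]`` as involved in using object ``object_ids[j]``.
    """

    loadings: np.ndarray
    synergy_ids: list[str]
    object_ids: list[str]

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.ndim != 2:
            raise InvalidInputError("loadings must be 2-D (synergies x objects)")
        if self.loadings.shape != (len(self.synergy_ids), len(self.object_ids)):
            raise InvalidInputError(
                f"loadings shape {self.loadings.shape} does not match "
                f"{len(self.synergy_ids)} synergies x {len(self.object_ids)} objects"
            )
        if np.isnan(self.loadings).any():
            raise InvalidInputError("loadings contain missing values")
        if (self.loadings < 0).any() or (self.loadings > 1).any():
            raise InvalidInputError("loadings must lie in [0, 1]")
        if len(set(self.synergy_ids)) != len(self.synergy_ids):
            raise InvalidInputError("synergy_ids must be unique")
        if len(set(self.object_ids)) != len(self.object_ids):
            raise InvalidInputError("object_ids must be unique")

    @property
    def n_synergies(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_objects(self) -> int:
        return self.loadings.shape[1]

    def column(self, object_id: str) -> np.ndarray:
        return self.loadings[:, self.object_ids.index(object_id)]

    def subset(self, object_ids: list[str]) -> "RatingMatrix":
        idx = [self.object_ids.index(o) for o in object_ids]
        return RatingMatrix(self.loadings[:, idx], list(self.synergy_ids), list(object_ids))


def aggregate_ratings(
    votes: np.ndarray,
    synergy_ids: list[str],
    object_ids: list[str],
    drop_objects: list[str] | None = None,
) -> RatingMatrix:
    """Average per-rater binary votes into a group RatingMatrix.

    Parameters
    ----------
    votes : ndarray, shape (n_synergies, n_objects, n_raters)
        Binary involvement judgments.
    drop_objects : list of str, optional
        Catch-trial / control columns to remove after aggregation.
    """
    votes = np.asarray(votes)
    if votes.ndim != 3 or votes.shape[2] < 1:
        raise InvalidInputError("votes must be (synergies, objects, raters) with >= 1 rater")
    if not np.isin(votes, (0, 1)).all():
        raise InvalidInputError("votes must be binary")
    loadings = votes.mean(axis=2)
    rm = RatingMatrix(loadings, list(synergy_ids), list(object_ids))
    if drop_objects:
        keep = [o for o in rm.object_ids if o not in set(drop_objects)]
        rm = rm.subset(keep)
    return rm


# ---------------------------------------------------------------------------
# Object set / centrality split


@dataclass
class ObjectSet:
    """Objects with behavioral centrality and familiarity scores (1-5 scale)."""

    object_ids: list[str]
    centrality: np.ndarray
    familiarity: np.ndarray
    is_high_centrality: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.centrality = np.asarray(self.centrality, dtype=float)
        self.familiarity = np.asarray(self.familiarity, dtype=float)
        n = len(self.object_ids)
        if self.centrality.shape != (n,) or self.familiarity.shape != (n,):
            raise InvalidInputError("scores must be one value per object")


def select_high_centrality(objs: ObjectSet) -> ObjectSet:
    """Objects strictly above the median centrality; ties at the median drop.

    With an even number of distinct values this returns exactly the top
    half. If all values are equal the subset is empty and a warning is
    emitted.
    """
    med = float(np.median(objs.centrality))
    high = objs.centrality > med
    if not high.any():
        warnings.warn("median split produced an empty high-centrality subset", stacklevel=2)
    flags = np.asarray(high, dtype=bool)
    objs.is_high_centrality = flags
    ids = [o for o, h in zip(objs.object_ids, flags) if h]
    return ObjectSet(
        object_ids=ids,
        centrality=objs.centrality[flags],
        familiarity=objs.familiarity[flags],
        is_high_centrality=np.ones(int(flags.sum()), dtype=bool),
    )


# ---------------------------------------------------------------------------
# Similarity matrices


@dataclass
class SimilarityMatrix:
    """Symmetric objects x objects matrix, similarity (RSM) or 1-r (RDM)."""

    values: np.ndarray
    mode: str  # "similarity" | "dissimilarity"
    object_ids: list[str]
    _tol: float = field(default=1e-8, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.object_ids)
        if self.values.shape != (n, n):
            raise InvalidInputError("similarity matrix must be square over object_ids")
        if self.mode not in ("similarity", "dissimilarity"):
            raise InvalidInputError(f"unknown mode {self.mode!r}")
        if not np.allclose(self.values, self.values.T, atol=self._tol, equal_nan=True):
            raise InvalidInputError("matrix asymmetric beyond tolerance")
        diag_target = 1.0 if self.mode == "similarity" else 0.0
        if not np.allclose(np.diag(self.values), diag_target, atol=self._tol):
            raise InvalidInputError(f"diagonal must be {diag_target} for mode {self.mode}")
        # enforce exact symmetry / diagonal downstream
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, diag_target)

    @property
    def n_objects(self) -> int:
        return len(self.object_ids)

    def to_rdm(self) -> "SimilarityMatrix":
        if self.mode == "dissimilarity":
            return self
        return SimilarityMatrix(_flip(self.values, 0.0), "dissimilarity", list(self.object_ids))

    def to_rsm(self) -> "SimilarityMatrix":
        if self.mode == "similarity":
            return self
        return SimilarityMatrix(_flip(self.values, 1.0), "similarity", list(self.object_ids))

    def offdiag_vector(self) -> np.ndarray:
        """Strictly-lower-triangle entries, row-major."""
        i, j = np.tril_indices(self.n_objects, k=-1)
        return self.values[i, j]


def _flip(values: np.ndarray, new_diag: float) -> np.ndarray:
    out = 1.0 - values
    np.fill_diagonal(out, new_diag)
    return out


def compute_rdm(
    matrix: RatingMatrix | np.ndarray,
    object_ids: list[str] | None = None,
) -> SimilarityMatrix:
    """Correlation-distance RDM (1 - Pearson r) between object columns.

    Accepts a RatingMatrix or any (features x objects) array. Objects with
    zero-variance columns cannot be correlated and raise
    :class:`FlaggedObjectError`.
    """
    if isinstance(matrix, RatingMatrix):
        data, ids = matrix.loadings, list(matrix.object_ids)
    else:
        data = np.asarray(matrix, dtype=float)
        ids = list(object_ids) if object_ids is not None else [f"obj{i:03d}" for i in range(data.shape[1])]
    if data.shape[1] < 2:
        raise InvalidInputError("need at least 2 objects")
    sd = data.std(axis=0)
    if (sd == 0).any():
        raise FlaggedObjectError([ids[k] for k in np.flatnonzero(sd == 0)])
    r = np.corrcoef(data, rowvar=False)
    rdm = 1.0 - r
    np.fill_diagonal(rdm, 0.0)
    return SimilarityMatrix(rdm, "dissimilarity", ids)


# ---------------------------------------------------------------------------
# Dendrograms


@dataclass
class Dendrogram:
    """Agglomerative tree: a linkage table plus an explicit leaf order.

    ``merges`` follows the SciPy linkage convention: row k merges clusters
    ``merges[k, 0]`` and ``merges[k, 1]`` (indices < n are leaves) at
    height ``merges[k, 2]``.
    """

    merges: np.ndarray
    object_ids: list[str]
    leaf_order: np.ndarray  # leaf indices, left-to-right

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        self.leaf_order = np.asarray(self.leaf_order, dtype=int)
        n = len(self.object_ids)
        if self.merges.shape != (n - 1, self.merges.shape[1]):
            raise InvalidInputError("merge table must have n_objects - 1 rows")
        if sorted(self.leaf_order.tolist()) != list(range(n)):
            raise InvalidInputError("leaf_order must be a permutation of the leaves")
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise InvalidInputError("merge heights must be nondecreasing")

    @property
    def n_leaves(self) -> int:
        return len(self.object_ids)

    def leaf_labels(self) -> list[str]:
        return [self.object_ids[i] for i in self.leaf_order]

    def rank_of(self, object_ids: list[str]) -> np.ndarray:
        """1-based left-to-right position of each requested object."""
        pos = {self.object_ids[leaf]: k + 1 for k, leaf in enumerate(self.leaf_order)}
        return np.array([pos[o] for o in object_ids], dtype=float)

    def with_leaf_order(self, leaf_order: np.ndarray) -> "Dendrogram":
        return Dendrogram(self.merges.copy(), list(self.object_ids), np.asarray(leaf_order))

    def relabel(self, new_object_ids: list[str]) -> "Dendrogram":
        return Dendrogram(self.merges.copy(), list(new_object_ids), self.leaf_order.copy())

    def to_newick(self) -> str:
        """Newick string with merge-height differences as branch lengths."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}

        def node_str(k: int) -> str:
            if k < n:
                return self.object_ids[k].replace(" ", "_")
            row = self.merges[k - n]
            a, b = int(row[0]), int(row[1])
            h = row[2]
            la = max(h - _node_height(a), 0.0)
            lb = max(h - _node_height(b), 0.0)
            return f"({node_str(a)}:{la:.6g},{node_str(b)}:{lb:.6g})"

        def _node_height(k: int) -> float:
            return 0.0 if k < n else float(self.merges[k - n, 2])

        return node_str(2 * n - 2) + ";"


def build_dendrogram(rdm: SimilarityMatrix) -> Dendrogram:
    """Cluster the correlation-distance matrix under Ward's criterion.

    The RDM is handed to Ward linkage as the input metric directly. Ward
    formally assumes squared Euclidean distances; applying it to a
    correlation distance is a procedural choice, kept deliberately.
    """
    if rdm.mode != "dissimilarity":
        raise InvalidInputError("build_dendrogram expects a dissimilarity matrix")
    if rdm.n_objects < 2:
        raise InvalidInputError("need at least 2 objects to cluster")
    condensed = squareform(rdm.values, checks=False)
    Z = hierarchy.linkage(condensed, method="ward")
    order = hierarchy.leaves_list(Z)
    return Dendrogram(Z, list(rdm.object_ids), order)


# ---------------------------------------------------------------------------
# Entanglement


def _check_same_leaves(d1: Dendrogram, d2: Dendrogram) -> None:
    if set(d1.object_ids) != set(d2.object_ids):
        raise InvalidInputError("dendrograms must share the same leaf label set")


def _entanglement_from_ranks(r1: np.ndarray, r2: np.ndarray, norm_power: float) -> float:
    n = len(r1)
    num = float(np.sum(np.abs(r1 - r2) ** norm_power))
    worst = float(np.sum(np.abs(np.arange(1, n + 1) - np.arange(n, 0, -1)) ** norm_power))
    if worst == 0:
        return 0.0
    return num / worst


def entanglement(
    d1: Dendrogram,
    d2: Dendrogram,
    norm_power: float = 1.5,
    untangle: bool = False,
) -> float:
    """Disagreement between two trees' leaf orderings, in [0, 1].

    Computes ``||r1 - r2||_L / worst`` where ``r_k`` is the 1-based rank
    of each shared label in tree k's leaf order and ``worst`` is the value
    for exactly reversed orders. 0 means perfectly aligned, 1 completely
    different. With ``untangle=True`` both trees' node rotations are
    first optimized by a stepwise heuristic (see :func:`untangle_trees`);
    the metric itself is reported for the leaf orders as given otherwise.
    """
    _check_same_leaves(d1, d2)
    if untangle:
        d1, d2 = untangle_trees(d1, d2, norm_power=norm_power)
    labels = list(d1.object_ids)
    return _entanglement_from_ranks(d1.rank_of(labels), d2.rank_of(labels), norm_power)


def _leaf_order_with_flips(merges: np.ndarray, n: int, flips: np.ndarray) -> np.ndarray:
    """Left-to-right leaves after optionally swapping children at each merge."""
    order: list[int] = []
    stack = [2 * n - 2]
    while stack:
        k = stack.pop()
        if k < n:
            order.append(k)
            continue
        a, b = int(merges[k - n, 0]), int(merges[k - n, 1])
        if flips[k - n]:
            a, b = b, a
        # push right child first so left is emitted first
        stack.append(b)
        stack.append(a)
    return np.asarray(order, dtype=int)


def untangle_trees(
    d1: Dendrogram,
    d2: Dendrogram,
    norm_power: float = 1.5,
    max_sweeps: int = 10,
) -> tuple[Dendrogram, Dendrogram]:
    """Greedy stepwise node-rotation search minimizing entanglement.

    Sweeps over the internal nodes of each tree in turn, flipping a
    node's children whenever the flip lowers the entanglement, until a
    full sweep makes no improvement. Deterministic.
    """
    _check_same_leaves(d1, d2)
    labels = list(d1.object_ids)
    n = d1.n_leaves
    flips = [np.zeros(n - 1, dtype=bool), np.zeros(n - 1, dtype=bool)]
    trees = [d1, d2]

    def ranks(ti: int) -> np.ndarray:
        order = _leaf_order_with_flips(trees[ti].merges, n, flips[ti])
        pos = {trees[ti].object_ids[leaf]: k + 1 for k, leaf in enumerate(order)}
        return np.array([pos[o] for o in labels])

    best = _entanglement_from_ranks(ranks(0), ranks(1), norm_power)
    for _ in range(max_sweeps):
        improved = False
        for ti in (0, 1):
            other = ranks(1 - ti)
            for node in range(n - 2, -1, -1):
                flips[ti][node] = ~flips[ti][node]
                cand = _entanglement_from_ranks(ranks(ti), other, norm_power)
                if cand < best - 1e-15:
                    best = cand
                    improved = True
                else:
                    flips[ti][node] = ~flips[ti][node]
        if not improved:
            break
    out = []
    for ti in (0, 1):
        order = _leaf_order_with_flips(trees[ti].merges, n, flips[ti])
        out.append(trees[ti].with_leaf_order(order))
    return out[0], out[1]


@dataclass
class PermutationTestResult:
    p_value: float
    observed: float
    null: np.ndarray
    n_perm: int


def entanglement_permutation_test(
    d1: Dendrogram,
    d2: Dendrogram,
    n_perm: int = 10000,
    seed: int = 0,
    norm_power: float = 1.5,
    untangle: bool = False,
) -> PermutationTestResult:
    """Left-tailed permutation test: is the observed entanglement small?

    The null is built by shuffling the leaf labels of the second tree;
    ``p = (1 + #{null <= observed}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    _check_same_leaves(d1, d2)
    observed = entanglement(d1, d2, norm_power=norm_power, untangle=untangle)
    labels = list(d1.object_ids)
    r1 = d1.rank_of(labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    if untangle:
        for p in range(n_perm):
            perm = rng.permutation(len(labels))
            shuffled = d2.relabel([d2.object_ids[k] for k in perm])
            null[p] = entanglement(d1, shuffled, norm_power=norm_power, untangle=True)
    else:
        r2 = d2.rank_of(labels)
        for p in range(n_perm):
            null[p] = _entanglement_from_ranks(r1, rng.permutation(r2), norm_power)
    p_value = (1.0 + float(np.sum(null <= observed))) / (n_perm + 1.0)
    return PermutationTestResult(p_value, observed, null, n_perm)
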