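"""Embedding-space retrieval of augmented twins: ranks, Acc@k, MRR, Recall@K.

For each original embedding e(x_i), all augmented embeddings e(x_j')
are ordered by distance; the retrieval rank of the true partner
e(x_i') drives every metric.  Two exact code paths — a dense distance
matrix and a flat nearest-neighbour index — must agree rank-for-rank;
an approximate graph-index backend is additionally available and is
treated as approximate, never as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial.distance import cdist

TIE_RULE = "competition rank; ties broken by ascending candidate index"


class DistanceKind(str, Enum):
    """Distance definitions for the retrieval pool.

    Similarities (cosine, inner product) are negated/converted so that
    smaller always means closer and one ranking code path serves all
    kinds.  Inner product is deliberately *not* normalized.
    ``APPROX_ANN`` delegates to an approximate nearest-neighbour graph
    index and is excluded from exactness guarantees.
    """

    EUCLIDEAN_L2 = "l2"
    COSINE = "cosine"
    INNER_PRODUCT = "ip"
    APPROX_ANN = "approx"


_EXACT_KINDS = (
    DistanceKind.EUCLIDEAN_L2,
    DistanceKind.COSINE,
    DistanceKind.INNER_PRODUCT,
)


@dataclass
class RankVector:
    """1-based retrieval rank of each original's true augmented partner.

    ``pool_size`` is the number of candidates ranked against (defaults
    to the query count when built by :func:`rank_true_pairs`); ranks
    must lie in 1..pool_size.
    """

    ranks: np.ndarray
    tie_rule: str = TIE_RULE
    pool_size: int | None = None

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=int)
        upper = self.pool_size if self.pool_size is not None else None
        if (self.ranks < 1).any():
            raise ValueError("ranks are 1-based: all must be >= 1")
        if upper is not None and (self.ranks > upper).any():
            raise ValueError(f"ranks must lie in 1..{upper}")

    @property
    def n(self) -> int:
        return self.ranks.shape[0]


def pairwise_distances(A: np.ndarray, B: np.ndarray, kind: DistanceKind) -> np.ndarray:
    """n x m matrix with entry (i, j) = distance from A[i] to B[j].

    Cosine is returned as 1 - cosine similarity; inner product as the
    negated (unnormalized) dot product — in both cases smaller = closer.
    """
    kind = DistanceKind(kind)
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape} vs {B.shape}")
    if kind is DistanceKind.EUCLIDEAN_L2:
        return cdist(A, B, metric="euclidean")
    if kind is DistanceKind.COSINE:
        return cdist(A, B, metric="cosine")
    if kind is DistanceKind.INNER_PRODUCT:
        return -(A @ B.T)
    raise ValueError(f"{kind.value} is not an exact distance kind")


def _ranks_from_distance_rows(
    dist_rows: np.ndarray, cand_idx: np.ndarray, true_idx: np.ndarray
) -> np.ndarray:
    """Competition rank of the true candidate per row, index tie-break.

    rank = 1 + #(strictly closer) + #(equal distance with smaller index).
    """
    n = dist_rows.shape[0]
    ranks = np.empty(n, dtype=int)
    for i in range(n):
        where = np.nonzero(cand_idx[i] == true_idx[i])[0]
        if where.size != 1:
            raise ValueError(f"true candidate {true_idx[i]} absent for query {i}")
        d_true = dist_rows[i, where[0]]
        closer = int((dist_rows[i] < d_true).sum())
        tied_before = int(
            ((dist_rows[i] == d_true) & (cand_idx[i] < true_idx[i])).sum()
        )
        ranks[i] = 1 + closer + tied_before
    return ranks


def rank_true_pairs(
    orig: np.ndarray,
    aug: np.ndarray,
    kind: DistanceKind = DistanceKind.EUCLIDEAN_L2,
    backend: str = "dense",
    seed: int = 0,
) -> RankVector:
    """Rank each e(x_i') among all augmented embeddings by distance to e(x_i).

    ``backend='dense'`` computes the full distance matrix;
    ``backend='index'`` queries an exact flat nearest-neighbour index
    (the two agree exactly for the exact distance kinds);
    ``backend='approx'`` queries an NN-descent graph index and may miss
    neighbours.
    """
    kind = DistanceKind(kind)
    orig = np.asarray(orig, dtype=np.float64)
    aug = np.asarray(aug, dtype=np.float64)
    if orig.shape != aug.shape:
        raise ValueError(f"shape mismatch: originals {orig.shape} vs augmented {aug.shape}")
    n = orig.shape[0]
    true_idx = np.arange(n)

    if kind is DistanceKind.APPROX_ANN or backend == "approx":
        return _rank_approx(orig, aug, seed=seed)

    if backend == "dense":
        D = pairwise_distances(orig, aug, kind)
        cand = np.broadcast_to(np.arange(n), (n, n))
        return RankVector(_ranks_from_distance_rows(D, cand, true_idx), pool_size=n)
    if backend == "index":
        dist, ind = _flat_index_query(orig, aug, kind)
        return RankVector(_ranks_from_distance_rows(dist, ind, true_idx), pool_size=n)
    raise ValueError(f"unknown backend {backend!r}")


def _flat_index_query(orig, aug, kind: DistanceKind):
    """Exact flat-index path via a brute-force nearest-neighbour index."""
    from sklearn.neighbors import NearestNeighbors

    n = aug.shape[0]
    if kind is DistanceKind.EUCLIDEAN_L2:
        nn = NearestNeighbors(n_neighbors=n, algorithm="brute", metric="euclidean")
    elif kind is DistanceKind.COSINE:
        nn = NearestNeighbors(n_neighbors=n, algorithm="brute", metric="cosine")
    elif kind is DistanceKind.INNER_PRODUCT:
        nn = NearestNeighbors(
            n_neighbors=n,
            algorithm="brute",
            metric=lambda a, b: -float(np.dot(a, b)),
        )
    else:  # pragma: no cover
        raise ValueError(f"{kind.value} has no exact index backend")
    nn.fit(aug)
    dist, ind = nn.kneighbors(orig)
    return dist, ind


def _rank_approx(orig, aug, seed: int = 0, k: int | None = None) -> RankVector:
    """Approximate ranks from an NN-descent graph index.

    Queries ``k`` neighbours (default: all, capped at 100); a true
    partner not returned within ``k`` is assigned rank ``k + 1`` — a
    lower bound, adequate for Acc@k at small k.
    """
    try:
        from pynndescent import NNDescent
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "approximate backend requires the pynndescent package"
        ) from exc

    n = aug.shape[0]
    k = min(n, 100) if k is None else min(k, n)
    index = NNDescent(aug, metric="euclidean", random_state=seed, n_neighbors=min(n, 30))
    index.prepare()
    ind, dist = index.query(orig, k=k)
    ranks = np.empty(n, dtype=int)
    for i in range(n):
        pos = np.nonzero(ind[i] == i)[0]
        ranks[i] = int(pos[0]) + 1 if pos.size else k + 1
    return RankVector(ranks, tie_rule=f"{TIE_RULE} (approximate index)", pool_size=n)


# --- metrics ---------------------------------------------------------------

def accuracy_at_k(ranks: RankVector, k: int) -> float:
    """Fraction of queries whose true partner ranks within the top k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return float((ranks.ranks <= k).mean())


def mean_reciprocal_rank(ranks: RankVector) -> float:
    """Mean of 1/rank over all queries."""
    if ranks.n == 0:
        raise ValueError("empty rank vector")
    return float((1.0 / ranks.ranks).mean())


def recall_curve(ranks: RankVector, Ks: list[int]) -> dict[int, float]:
    """Recall@K for each K; with one relevant item per query this equals
    Acc@K, so the curve is non-decreasing and reaches 1 at K = n."""
    if list(Ks) != sorted(Ks):
        raise ValueError("Ks must be sorted ascending")
    return {int(K): accuracy_at_k(ranks, K) for K in Ks}


@dataclass
class RetrievalReport:
    """Retrieval metrics for one (encoder, augmentation, distance) setting.

    Carries both all-pairs metrics and metrics restricted to pairs whose
    augmented string actually differs (``changed``), since inapplicable
    augmentations are retained to keep n fixed.
    """

    n: int
    distance: str
    encoder: str
    acc_at_1: float
    acc_at_5: float
    mrr: float
    recall_curve: dict[int, float]
    n_changed: int
    changed_only: dict[str, float]
    tie_rule: str = TIE_RULE
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.acc_at_1 <= self.acc_at_5 <= 1.0 + 1e-12):
            raise ValueError("Acc@1 must not exceed Acc@5")
        if not (self.acc_at_1 - 1e-12 <= self.mrr <= 1.0 + 1e-12):
            raise ValueError("MRR must lie between Acc@1 and 1")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "distance": self.distance,
            "encoder": self.encoder,
            "acc_at_1": self.acc_at_1,
            "acc_at_5": self.acc_at_5,
            "mrr": self.mrr,
            "recall_curve": {str(k): v for k, v in self.recall_curve.items()},
            "n_changed": self.n_changed,
            "changed_only": self.changed_only,
            "tie_rule": self.tie_rule,
            **({"extra": self.extra} if self.extra else {}),
        }


def _default_ks(n: int) -> list[int]:
    ks = [k for k in (1, 2, 5, 10, 20, 50, 100) if k <= n]
    if not ks or ks[-1] != n:
        ks.append(n)
    return ks


def evaluate_retrieval(
    orig: np.ndarray,
    aug: np.ndarray,
    kind: DistanceKind = DistanceKind.EUCLIDEAN_L2,
    changed_mask: np.ndarray | None = None,
    encoder: str = "unknown",
    backend: str = "dense",
    Ks: list[int] | None = None,
    seed: int = 0,
) -> RetrievalReport:
    """Full report: ranks -> Acc@1/Acc@5, MRR, Recall@K, changed-only block."""
    kind = DistanceKind(kind)
    rv = rank_true_pairs(orig, aug, kind, backend=backend, seed=seed)
    n = rv.n
    Ks = _default_ks(n) if Ks is None else list(Ks)
    if changed_mask is None:
        changed_mask = np.ones(n, dtype=bool)
    changed_mask = np.asarray(changed_mask, dtype=bool)
    if changed_mask.shape[0] != n:
        raise ValueError("changed_mask length must equal n")

    changed_only: dict[str, float] = {}
    if changed_mask.any():
        # ranks stay relative to the full pool; only the query set shrinks
        sub_ranks = rv.ranks[changed_mask]
        changed_only = {
            "acc_at_1": float((sub_ranks <= 1).mean()),
            "acc_at_5": float((sub_ranks <= 5).mean()),
            "mrr": float((1.0 / sub_ranks).mean()),
        }
    return RetrievalReport(
        n=n,
        distance=kind.value,
        encoder=encoder,
        acc_at_1=accuracy_at_k(rv, 1),
        acc_at_5=accuracy_at_k(rv, min(5, n)),
        mrr=mean_reciprocal_rank(rv),
        recall_curve=recall_curve(rv, Ks),
        n_changed=int(changed_mask.sum()),
        changed_only=changed_only,
    )


def layer_sweep(
    orig: "LayerEmbeddings",
    aug: "LayerEmbeddings",
    kind: DistanceKind = DistanceKind.EUCLIDEAN_L2,
) -> dict[int, float]:
    """Acc@1 per layer — probes where in the network synonym recognition
    lives.  Layer index sets on the two sides must match (layer 0 is the
    token-embedding layer)."""
    if orig.layer_indices != aug.layer_indices:
        raise ValueError(
            f"layer sets differ: {orig.layer_indices} vs {aug.layer_indices}"
        )
    return {
        idx: accuracy_at_k(rank_true_pairs(orig.layers[idx], aug.layers[idx], kind), 1)
        for idx in orig.layer_indices
    }
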