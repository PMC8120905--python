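"""Anchor detection: shared CCA embedding and type-constrained mutual neighbors.

An anchor is a cross-batch pair of cells (j1, j2) that are mutual nearest
neighbors — each among the other's k closest cells in the other batch. Here
anchors must (i) lie within a cell type confidently predicted in both
batches and (ii) be mutual nearest neighbors in *both* the scaled
gene-expression space and a shared low-dimensional canonical space, which
together suppress the spurious cross-type pairs that arise when batch
effects are not orthogonal to the biology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import svd
from sklearn.neighbors import NearestNeighbors

from .annotate import UNKNOWN, CellAnnotation, SharedTypeMap
from .io_preprocess import ExpressionMatrix


@dataclass(frozen=True)
class KnnParams:
    """Mutual-neighbor count and metric for anchor search.

    ``k`` follows the classical mutual-nearest-neighbors correction default
    of 20: the per-type correction is a weighted mean of anchor difference
    vectors, and its variance scales inversely with the anchor count, so a
    small k starves types with few cells of anchors and leaves corrections
    noise-dominated.
    """

    k: int = 20
    metric: str = "euclidean"

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.metric not in ("euclidean", "cosine"):
            raise ValueError(f"unsupported metric {self.metric!r}")


@dataclass
class CcaEmbedding:
    """Per-cell coordinates in the shared canonical space of a batch pair."""

    coords: np.ndarray                 # (n1 + n2, d), rows L2-normalized
    d: int
    singular_values: np.ndarray        # length d, non-increasing
    batch_ids: np.ndarray              # per row

    def batch_coords(self, batch: str) -> np.ndarray:
        return self.coords[self.batch_ids == batch]


@dataclass
class AnchorPair:
    """One cross-batch anchor with its expression-difference vector.

    ``diff`` is oriented reference-minus-other (expr(j1) − expr(j2) on the
    lognorm HVG panel) so that adding it to a batch-2 cell moves it toward
    the reference batch.
    """

    j1: int
    j2: int
    b1: str
    b2: str
    type_label: str
    diff: np.ndarray = field(repr=False, default=None)
    weight: float = 1.0


def cca_embed(m1: ExpressionMatrix, m2: ExpressionMatrix, d: int = 20) -> CcaEmbedding:
    """Diagonal CCA of two scaled batches on a shared gene panel.

    Takes the top-``d`` SVD of the cells₁ × cells₂ cross-product
    K = X₁ X₂ᵀ; batch-1 cells receive the left singular vectors, batch-2
    cells the right ones, and every row is then L2-normalized. Column signs
    are fixed so the largest-magnitude entry of each left vector is positive,
    making repeated runs bitwise identical.
    """
    for m in (m1, m2):
        if m.layer != "scaled":
            raise ValueError("cca_embed expects scaled-layer matrices")
    if tuple(m1.gene_ids) != tuple(m2.gene_ids):
        raise ValueError("batches must share an identical gene panel")
    X1, X2 = m1.dense(), m2.dense()
    K = X1 @ X2.T
    U, s, Vt = svd(K, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if d > rank:
        warnings.warn(f"requested d={d} exceeds rank {rank}; reducing")
        d = max(rank, 1)
    U, s, V = U[:, :d], s[:d], Vt[:d].T
    # deterministic sign: largest-|entry| of each left vector positive
    for j in range(d):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] *= -1
            V[:, j] *= -1
    coords = np.vstack([U, V])
    norms = np.linalg.norm(coords, axis=1, keepdims=True)
    coords = coords / np.where(norms > 0, norms, 1.0)
    batch_ids = np.concatenate([m1.batch_ids, m2.batch_ids])
    return CcaEmbedding(coords, d, s, batch_ids)


def mutual_nearest_pairs(a: np.ndarray, b: np.ndarray,
                         params: KnnParams = KnnParams()) -> set:
    """Exact mutual k-nearest-neighbor pairs between point sets a and b.

    Returns the set of (i, j) such that b[j] is among the k nearest
    neighbors of a[i] in b AND a[i] is among the k nearest of b[j] in a.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        return set()
    k_ab = min(params.k, b.shape[0])
    k_ba = min(params.k, a.shape[0])
    metric = params.metric
    nn_b = NearestNeighbors(n_neighbors=k_ab, metric=metric, algorithm="brute").fit(b)
    nbrs_of_a = nn_b.kneighbors(a, return_distance=False)
    nn_a = NearestNeighbors(n_neighbors=k_ba, metric=metric, algorithm="brute").fit(a)
    nbrs_of_b = nn_a.kneighbors(b, return_distance=False)
    fwd = {(i, j) for i, row in enumerate(nbrs_of_a) for j in row}
    rev = {(i, j) for j, row in enumerate(nbrs_of_b) for i in row}
    return fwd & rev


def find_anchors(b1: ExpressionMatrix, b2: ExpressionMatrix,
                 ann1: Sequence[CellAnnotation], ann2: Sequence[CellAnnotation],
                 shared: SharedTypeMap | set | None,
                 params: KnnParams = KnnParams(), d: int = 20,
                 expr1: ExpressionMatrix | None = None,
                 expr2: ExpressionMatrix | None = None,
                 constrain_types: bool = True) -> list:
    """Type-constrained two-space anchors between a batch pair.

    ``b1``/``b2`` are scaled matrices on the shared HVG panel (b1 is the
    reference side); ``expr1``/``expr2`` optionally supply the lognorm
    matrices from which anchor ``diff`` vectors are taken (default: the
    scaled values). With ``constrain_types=False`` the search runs over all
    cells regardless of annotation — the unconstrained-MNN baseline.

    For each candidate type, mutual nearest neighbors are computed in the
    scaled HVG space and in the shared CCA space; only pairs mutual in both
    are kept.
    """
    emb = cca_embed(b1, b2, d)
    n1 = b1.n_cells
    C1, C2 = emb.coords[:n1], emb.coords[n1:]
    X1, X2 = b1.dense(), b2.dense()
    E1 = expr1.dense() if expr1 is not None else X1
    E2 = expr2.dense() if expr2 is not None else X2
    bid1, bid2 = str(b1.batch_ids[0]), str(b2.batch_ids[0])

    if constrain_types:
        if isinstance(shared, SharedTypeMap):
            types = sorted(shared.pair(bid1, bid2))
        else:
            types = sorted(shared or ())
        if not types:
            warnings.warn(f"no shared types between {bid1} and {bid2}; no anchors")
            return []
        t1 = np.asarray([a.predicted_type for a in ann1], dtype=object)
        t2 = np.asarray([a.predicted_type for a in ann2], dtype=object)
        groups = [(t, np.flatnonzero(t1 == t), np.flatnonzero(t2 == t)) for t in types]
    else:
        groups = [("unconstrained", np.arange(n1), np.arange(b2.n_cells))]

    anchors: list = []
    for label, idx1, idx2 in groups:
        if idx1.size == 0 or idx2.size == 0:
            continue
        pairs_orig = mutual_nearest_pairs(X1[idx1], X2[idx2], params)
        pairs_cca = mutual_nearest_pairs(C1[idx1], C2[idx2], params)
        for i, j in sorted(pairs_orig & pairs_cca):
            j1, j2 = int(idx1[i]), int(idx2[j])
            anchors.append(AnchorPair(j1, j2, bid1, bid2, label,
                                      diff=E1[j1] - E2[j2]))
    return anchors


def anchor_mismatch_rate(anchors: Sequence[AnchorPair],
                         truth1: Mapping[str, str] | Sequence[str],
                         truth2: Mapping[str, str] | Sequence[str],
                         cells1: ExpressionMatrix | None = None,
                         cells2: ExpressionMatrix | None = None) -> float:
    """Fraction of anchors whose two cells differ in true type.

    Truth may be index-aligned sequences or cell_id→type mappings (the
    latter require ``cells1``/``cells2`` for the id lookup).
    """
    if not anchors:
        warnings.warn("empty anchor list; mismatch rate defined as 0")
        return 0.0

    def lookup(truth, cells, j):
        if isinstance(truth, Mapping):
            return truth[str(cells.cell_ids[j])]
        return truth[j]

    wrong = sum(lookup(truth1, cells1, a.j1) != lookup(truth2, cells2, a.j2)
                for a in anchors)
    return wrong / len(anchors)


def save_anchors(anchors: Sequence[AnchorPair], path,
                 cells1: ExpressionMatrix, cells2: ExpressionMatrix) -> None:
    """Serialize anchors as TSV: b1, cell1, b2, cell2, type, weight."""
    import pandas as pd

    pd.DataFrame([{
        "b1": a.b1, "cell1": cells1.cell_ids[a.j1],
        "b2": a.b2, "cell2": cells2.cell_ids[a.j2],
        "type": a.type_label, "weight": a.weight,
    } for a in anchors]).to_csv(path, sep="\t", index=False)
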