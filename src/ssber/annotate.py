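"""Supervised cell-type annotation and shared-type identification.

A SciBet-style multinomial classifier: informative genes are chosen by an
entropy-reduction statistic on per-type mean expression, each type is
summarized by a centroid on the probability simplex over those genes, and a
query cell is scored by its multinomial log-likelihood under each centroid.
Softmax posteriors below a confidence threshold (default 0.8) yield the
label ``"unknown"``; anchors are later restricted to types confidently
predicted in both batches of a pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd

from .io_preprocess import ExpressionMatrix, GeneSet

UNKNOWN = "unknown"


@dataclass
class TypeModel:
    """Trained per-type expression centroids over informative genes.

    ``temperature`` rescales log-likelihoods before the softmax; it is set
    during training so that all but the weakest ~1% of held-out reference
    cells clear the default 0.8 confidence gate, which keeps the posterior
    a meaningful rejection score for cells of types absent from the
    reference (their likelihood margins are far smaller than in-reference
    margins).
    """

    types: list
    centroids: np.ndarray          # (n_types, n_genes), rows on the simplex
    informative_genes: GeneSet
    gene_order: list               # informative genes in centroid column order
    pseudocount: float = 1e-6
    temperature: float = 1.0


@dataclass(frozen=True)
class CellAnnotation:
    """Predicted type (or ``"unknown"``) with its softmax posterior."""

    cell_id: str
    predicted_type: str
    posterior: float


@dataclass
class SharedTypeMap:
    """Per-batch predicted type sets and their pairwise intersections."""

    batch_types: dict               # batch id -> set of type labels
    shared: dict                    # frozenset({b1, b2}) -> set of labels

    def pair(self, b1: str, b2: str) -> set:
        return self.shared.get(frozenset((b1, b2)), set())


def _per_type_means(ref: ExpressionMatrix, labels: Sequence[str]):
    labels = np.asarray(labels, dtype=object)
    if len(labels) != ref.n_cells:
        raise ValueError("labels length does not match cell count")
    types = sorted(set(labels))
    if len(types) < 2:
        raise ValueError("need at least 2 cell types in the reference")
    X = ref.dense()
    means = np.empty((len(types), ref.n_genes))
    for i, t in enumerate(types):
        idx = np.flatnonzero(labels == t)
        if len(idx) < 2:
            raise ValueError(f"type {t!r} has fewer than 2 reference cells")
        # sum in cell-id order so the model is bitwise invariant to the
        # order cells arrive in
        idx = idx[np.argsort(ref.cell_ids[idx].astype(str))]
        means[i] = X[idx].mean(axis=0)
    return types, means


def informative_gene_scores(means: np.ndarray, pseudocount: float = 1e-6) -> np.ndarray:
    """Entropy-reduction score per gene from per-type mean expression.

    score(g) = Σ_t m_t log m_t − (Σ_t m_t) · log(mean_t m_t), computed on
    pseudocounted means; non-negative by convexity, zero iff all per-type
    means are equal, and large for genes concentrated in few types.
    """
    m = means + pseudocount
    total = m.sum(axis=0)
    T = m.shape[0]
    return (m * np.log(m)).sum(axis=0) - total * np.log(total / T)


def select_informative_genes(ref: ExpressionMatrix, labels: Sequence[str],
                             n_genes: int = 500) -> GeneSet:
    """Top ``n_genes`` by the entropy-reduction statistic (ties by gene id)."""
    types, means = _per_type_means(ref, labels)
    scores = informative_gene_scores(means)
    genes = list(ref.gene_ids)
    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    return GeneSet(genes[i] for i in order[:min(n_genes, len(genes))])


def _log_likelihoods(centroids: np.ndarray, X: np.ndarray) -> np.ndarray:
    return X @ np.log(centroids).T


def _calibrate_temperature(ref: ExpressionMatrix, labels: np.ndarray,
                           n_genes: int, pseudocount: float,
                           margin_quantile: float, gate: float = 0.8) -> float:
    """Softmax temperature from a held-out fifth of the reference.

    A centroid model is refit without the calibration cells; the temperature
    is chosen so that the `margin_quantile` quantile of their
    best-vs-second log-likelihood margins maps exactly onto the posterior
    ``gate`` in the worst case (all other types tied at the runner-up):
    T = q / ln((K−1)·gate/(1−gate)). Falls back to 1.0 when the reference
    is too small to split (or the quantile margin is non-positive).
    """
    types = sorted(set(labels))
    rng = np.random.default_rng(0)
    cal_idx, fit_idx = [], []
    for t in types:
        ix = np.flatnonzero(labels == t)
        ix = ix[np.argsort(ref.cell_ids[ix])]   # order by id: permutation-safe
        ix = ix[rng.permutation(len(ix))]
        n_cal = max(1, len(ix) // 5)
        if len(ix) - n_cal < 2:
            return 1.0
        cal_idx += list(ix[:n_cal])
        fit_idx += list(ix[n_cal:])
    cal_idx, fit_idx = np.sort(cal_idx), np.sort(fit_idx)
    sub_model = train_classifier(ref.subset_cells(fit_idx), labels[fit_idx],
                                 n_genes, pseudocount, calibrate=False)
    X = ref.subset_cells(cal_idx).subset_genes(sub_model.gene_order).dense()
    L = np.sort(_log_likelihoods(sub_model.centroids, X), axis=1)
    margins = L[:, -1] - L[:, -2]
    q = float(np.quantile(margins, margin_quantile))
    denom = np.log((len(types) - 1) * gate / (1 - gate))
    return q / denom if q > 0 else 1.0


def train_classifier(ref: ExpressionMatrix, labels: Sequence[str],
                     n_genes: int = 500, pseudocount: float = 1e-6,
                     calibrate: bool = True,
                     margin_quantile: float = 0.01) -> TypeModel:
    """Fit per-type centroids on the informative-gene panel.

    Centroids are per-type mean expression plus a pseudocount, renormalized
    to sum to one, so each row is a multinomial parameter vector. With
    ``calibrate=True`` a softmax temperature is additionally fit on a
    held-out fifth of the reference (see :func:`_calibrate_temperature`).
    """
    labels = np.asarray(labels, dtype=object)
    informative = select_informative_genes(ref, labels, n_genes)
    gene_order = informative.sorted()
    sub = ref.subset_genes(gene_order)
    types, means = _per_type_means(sub, labels)
    cent = means + pseudocount
    cent /= cent.sum(axis=1, keepdims=True)
    temperature = (_calibrate_temperature(ref, labels, n_genes, pseudocount,
                                          margin_quantile)
                   if calibrate else 1.0)
    return TypeModel(types, cent, informative, gene_order, pseudocount,
                     temperature)


def predict_types(model: TypeModel, query: ExpressionMatrix,
                  threshold: float = 0.8) -> list:
    """Annotate each query cell; posteriors below `threshold` → ``"unknown"``.

    Log-likelihood of cell x under type t is Σ_g x_g · log c_t(g); posteriors
    are the softmax over types of the max-shifted log-likelihoods divided by
    the model's calibrated temperature.
    """
    present = [g for g in model.gene_order if g in set(query.gene_ids)]
    if not present:
        raise ValueError("query shares no genes with the classifier's panel")
    if len(present) < len(model.gene_order):
        warnings.warn(f"{len(model.gene_order) - len(present)} informative genes "
                      "missing from query; treated as zero expression")
    cols = [model.gene_order.index(g) for g in present]
    logc = np.log(model.centroids[:, cols])          # (T, G')
    X = query.subset_genes(present).dense()          # (N, G')
    ll = X @ logc.T / model.temperature              # (N, T)
    ll -= ll.max(axis=1, keepdims=True)
    post = np.exp(ll)
    post /= post.sum(axis=1, keepdims=True)
    best = post.argmax(axis=1)
    out = []
    for i, cell in enumerate(query.cell_ids):
        p = float(post[i, best[i]])
        label = model.types[best[i]] if p >= threshold else UNKNOWN
        out.append(CellAnnotation(str(cell), label, p))
    return out


def oracle_annotations(cells: ExpressionMatrix, truth: Mapping[str, str] | Sequence[str]) -> list:
    """Wrap ground-truth labels as posterior-1.0 annotations (simulation use)."""
    if isinstance(truth, Mapping):
        labels = [truth[str(c)] for c in cells.cell_ids]
    else:
        labels = list(truth)
    return [CellAnnotation(str(c), str(t), 1.0) for c, t in zip(cells.cell_ids, labels)]


def shared_types(annotations: Mapping[str, Sequence[CellAnnotation]],
                 min_cells: int = 10) -> SharedTypeMap:
    """Type sets per batch (>= `min_cells` confident cells) and pairwise intersections.

    ``"unknown"`` never counts toward a batch's type set.
    """
    if len(annotations) < 2:
        raise ValueError("need annotations for at least 2 batches")
    batch_types = {}
    for batch, anns in annotations.items():
        counts = pd.Series([a.predicted_type for a in anns]).value_counts()
        batch_types[batch] = {t for t, c in counts.items()
                              if c >= min_cells and t != UNKNOWN}
    shared = {}
    for b1, b2 in combinations(sorted(batch_types), 2):
        shared[frozenset((b1, b2))] = batch_types[b1] & batch_types[b2]
    return SharedTypeMap(batch_types, shared)
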