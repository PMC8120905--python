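"""Gaussian-kernel correction vectors and order-independent batch merging.

Each non-reference cell receives a correction vector: a Gaussian-kernel
weighted mean of anchor difference vectors, restricted to anchors of the
cell's own (shared) type. Cells labeled ``"unknown"`` fall back to the
nearest anchors regardless of type; types with no applicable anchors pass
through uncorrected. Batches are merged in a star topology — every batch is
corrected independently against a deterministically chosen reference — so
the result cannot depend on the order in which batches are supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotate import UNKNOWN, CellAnnotation, SharedTypeMap, shared_types
from .anchors import AnchorPair, KnnParams, find_anchors
from .io_preprocess import (ExpressionMatrix, GeneSet, concat, normalize_log,
                            scale_zscore, select_hvg)


@dataclass(frozen=True)
class IntegrationParams:
    """Kernel bandwidth, reference choice and per-cell anchor cap.

    ``sigma`` is in per-gene RMS units of the scaled space (Euclidean
    distance divided by √n_genes), so the default is meaningful regardless
    of HVG panel size.
    """

    sigma: float = 1.0
    reference_batch: str = "auto"
    k_weight: int = 100

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.k_weight < 1:
            raise ValueError("k_weight must be >= 1")


@dataclass
class CorrectionField:
    """Per-cell correction vectors over the HVG panel.

    ``source`` records how each cell was corrected (``typed``,
    ``unknown-fallback`` or ``zero``); ``weight_sq_sum`` is Σ w² of the
    kernel weights used for each cell (its inverse is the effective number
    of anchors, useful for null-calibration checks).
    """

    vectors: np.ndarray
    source: np.ndarray
    weight_sq_sum: np.ndarray = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("correction vectors contain NaN/Inf")
        if self.weight_sq_sum is None:
            self.weight_sq_sum = np.zeros(len(self.vectors))


def gaussian_weights(cell: np.ndarray, anchor_points: np.ndarray,
                     sigma: float, k_fallback: int | None = None) -> np.ndarray:
    """Normalized Gaussian kernel weights of a cell over anchor points.

    w_a ∝ exp(−d_a² / 2σ²) with d_a the per-gene RMS distance from the cell
    to anchor point a. If every raw weight underflows, weights fall back to
    uniform over the ``k_fallback`` nearest anchors (all, when None).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    anchor_points = np.atleast_2d(anchor_points)
    if anchor_points.shape[0] == 0:
        raise ValueError("need at least one anchor point")
    diffs = anchor_points - cell
    d2 = (diffs ** 2).mean(axis=1)          # squared per-gene RMS distance
    raw = np.exp(-(d2 - d2.min()) / (2 * sigma ** 2))
    # subtracting the min distance before exponentiating avoids underflow of
    # the whole vector; it cancels in the normalization
    total = raw.sum()
    if not np.isfinite(total) or total <= 0:
        warnings.warn("Gaussian weights underflowed; falling back to uniform "
                      "over nearest anchors")
        k = len(d2) if k_fallback is None else min(k_fallback, len(d2))
        nearest = np.argsort(d2, kind="stable")[:k]
        w = np.zeros(len(d2))
        w[nearest] = 1.0 / k
        return w
    return raw / total


def correction_vectors(cells: ExpressionMatrix,
                       annotations: Sequence[CellAnnotation],
                       anchors: Sequence[AnchorPair],
                       params: IntegrationParams = IntegrationParams(),
                       anchor_endpoints: np.ndarray | None = None) -> CorrectionField:
    """Per-cell corrections from same-type anchors (nearest anchors for unknowns).

    ``cells`` is the scaled matrix of the batch being corrected;
    ``anchor_endpoints`` are the scaled coordinates of each anchor's cell in
    this batch (default: rows ``a.j2`` of ``cells``). A typed cell is
    corrected by the kernel-weighted mean of the diffs of its own type's
    anchors (capped at the ``k_weight`` nearest); an unknown cell by the
    ``k_weight`` nearest anchors of any type; a typed cell whose type has no
    anchors gets a zero vector.
    """
    X = cells.dense()
    anchors = list(anchors)
    n_feat = len(anchors[0].diff) if anchors else X.shape[1]
    vectors = np.zeros((cells.n_cells, n_feat))
    source = np.full(cells.n_cells, "zero", dtype=object)
    wss = np.zeros(cells.n_cells)
    if not anchors:
        warnings.warn("empty anchor list; returning all-zero correction field")
        return CorrectionField(vectors, source, wss)

    if anchor_endpoints is None:
        anchor_endpoints = np.stack([X[a.j2] for a in anchors])
    diffs = np.stack([a.diff for a in anchors])
    labels = np.asarray([a.type_label for a in anchors], dtype=object)
    by_type = {t: np.flatnonzero(labels == t) for t in set(labels)}

    unconstrained = "unconstrained" in by_type
    types_warned = set()
    for i, ann in enumerate(annotations):
        t = ann.predicted_type
        if t != UNKNOWN and t in by_type:
            idx = by_type[t]
            src = "typed"
        elif t == UNKNOWN or unconstrained:
            # unknowns (and every cell in unconstrained-baseline mode) use
            # the nearest anchors regardless of type
            idx = np.arange(len(anchors))
            src = "unknown-fallback"
        else:
            if t not in types_warned:
                warnings.warn(f"no anchors for type {t!r}; zero correction")
                types_warned.add(t)
            continue
        pts = anchor_endpoints[idx]
        if len(idx) > params.k_weight:
            d2 = ((pts - X[i]) ** 2).sum(axis=1)
            keep = np.argsort(d2, kind="stable")[:params.k_weight]
            idx, pts = idx[keep], pts[keep]
        w = gaussian_weights(X[i], pts, params.sigma, k_fallback=params.k_weight)
        vectors[i] = w @ diffs[idx]
        source[i] = src
        wss[i] = float((w ** 2).sum())
    return CorrectionField(vectors, source, wss)


def apply_correction(cells: ExpressionMatrix, field: CorrectionField,
                     direction: str = "toward_reference") -> ExpressionMatrix:
    """Add the correction field to the (lognorm) expression values.

    Diffs are stored reference-minus-other, so addition moves the batch
    toward the reference.
    """
    if field.vectors.shape != cells.values.shape:
        raise ValueError("correction field is misaligned with the matrix")
    if direction != "toward_reference":
        raise ValueError(f"unknown direction {direction!r}")
    out = cells.dense() + field.vectors
    return ExpressionMatrix(out, cells.cell_ids, cells.gene_ids,
                            cells.batch_ids, "corrected")


def _choose_reference(batch_ids: Sequence[str],
                      annotations: Mapping[str, Sequence[CellAnnotation]],
                      sizes: Mapping[str, int]) -> str:
    """Most cells among batches with the most predicted types; ties by id."""
    n_types = {}
    for b in batch_ids:
        n_types[b] = len({a.predicted_type for a in annotations[b]
                          if a.predicted_type != UNKNOWN})
    top = max(n_types.values())
    candidates = [b for b in batch_ids if n_types[b] == top]
    return sorted(candidates, key=lambda b: (-sizes[b], b))[0]


@dataclass
class IntegrationResult:
    """Merged corrected matrix plus the anchors and run metadata."""

    merged: ExpressionMatrix
    anchors: list
    reference: str
    hvg: GeneSet
    annotations: dict
    warnings_log: list = field(default_factory=list)


def integrate_batches(batches: Sequence[ExpressionMatrix],
                      annotations: Mapping[str, Sequence[CellAnnotation]],
                      params: IntegrationParams = IntegrationParams(),
                      knn: KnnParams = KnnParams(),
                      d: int = 20,
                      n_hvg: int = 3000,
                      min_cells: int = 10,
                      constrain_types: bool = True) -> IntegrationResult:
    """Full correction pipeline: HVG panel → anchors vs reference → merge.

    Input batches may be counts (normalized here) or lognorm. Every
    non-reference batch is corrected independently against the reference;
    cells of types absent from the reference are corrected against the
    lowest-id other batch containing the type (whose own correction has
    already aligned it to the reference), or through the unknown-anchor
    fallback when no such batch exists. Batches are processed in sorted-id
    order throughout, so the output is invariant to input order.
    """
    if len(batches) < 2:
        raise ValueError("need at least 2 batches")
    by_id: dict = {}
    for b in batches:
        bid = str(b.batch_ids[0])
        if len(set(b.batch_ids)) != 1:
            raise ValueError("each input matrix must contain a single batch")
        if bid in by_id:
            raise ValueError(f"duplicate batch id {bid!r}")
        by_id[bid] = b
    order = sorted(by_id)
    warn_log: list = []

    lognorm = {b: (normalize_log(by_id[b]) if by_id[b].layer == "counts"
                   else by_id[b]) for b in order}
    hvg = select_hvg([lognorm[b] for b in order], n_genes=n_hvg)
    panel = hvg.sorted()
    ln = {b: lognorm[b].subset_genes(panel) for b in order}
    sc = {b: scale_zscore(ln[b]) for b in order}

    sizes = {b: by_id[b].n_cells for b in order}
    ref = (params.reference_batch if params.reference_batch != "auto"
           else _choose_reference(order, annotations, sizes))
    if ref not in by_id:
        raise ValueError(f"reference batch {ref!r} not among inputs")
    stm = shared_types(annotations, min_cells=min_cells) if constrain_types else None

    # per-batch predicted presence (for fallback donor lookup)
    presence = ({b: stm.batch_types[b] for b in order} if constrain_types
                else {b: set() for b in order})

    corrected = {ref: ExpressionMatrix(ln[ref].dense(), ln[ref].cell_ids,
                                       ln[ref].gene_ids, ln[ref].batch_ids,
                                       "corrected")}
    all_anchors: list = []
    pass2: list = []   # (batch, type) needing a donor other than the reference

    for b in order:
        if b == ref:
            continue
        anns = list(annotations[b])
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            anchors = find_anchors(sc[ref], sc[b], annotations[ref], anns,
                                   stm, knn, d, expr1=ln[ref], expr2=ln[b],
                                   constrain_types=constrain_types)
        warn_log += [str(w.message) for w in wrec]
        all_anchors += anchors
        anchor_types = {a.type_label for a in anchors}
        # types predicted in b but not anchorable against the reference
        pass2_types = set()
        for t in sorted(presence[b] - anchor_types - {UNKNOWN}):
            donors = [o for o in order if o != b and t in presence[o]]
            if donors:
                pass2.append((b, t, donors[0]))
                pass2_types.add(t)
        if not anchors:
            if not pass2_types:
                warnings.warn(f"batch {b!r} shares no types with the reference "
                              "and has no fallback donor; passing through "
                              "uncorrected")
                warn_log.append(f"batch {b} uncorrected")
                corrected[b] = ExpressionMatrix(ln[b].dense(), ln[b].cell_ids,
                                                ln[b].gene_ids, ln[b].batch_ids,
                                                "corrected")
                continue
        # cells whose type has neither same-type anchors nor a donor batch
        # are corrected like unannotated cells: nearest anchors, no type
        # constraint (their pass-2 peers are overwritten later anyway)
        eff_anns = [a if (a.predicted_type in anchor_types
                          or a.predicted_type in pass2_types
                          or a.predicted_type == UNKNOWN)
                    else CellAnnotation(a.cell_id, UNKNOWN, a.posterior)
                    for a in anns]
        field_ = correction_vectors(sc[b], eff_anns, anchors, params)
        corrected[b] = apply_correction(ln[b], field_)

    # second pass: types unreachable via the reference, corrected against the
    # lowest-id batch that has the type (already aligned to the reference)
    for b, t, donor in sorted(pass2):
        if b not in corrected:
            corrected[b] = ExpressionMatrix(ln[b].dense(), ln[b].cell_ids,
                                            ln[b].gene_ids, ln[b].batch_ids,
                                            "corrected")
        anns_b = list(annotations[b])
        donor_corr = corrected.get(donor)
        if donor_corr is None:   # donor later in order but already corrected above
            continue
        anchors_t = find_anchors(sc[donor], sc[b], annotations[donor], anns_b,
                                 {t}, knn, d,
                                 expr1=donor_corr, expr2=ln[b],
                                 constrain_types=True)
        if not anchors_t:
            warn_log.append(f"no donor anchors for type {t} in batch {b}")
            continue
        all_anchors += anchors_t
        rows = np.flatnonzero(np.asarray(
            [a.predicted_type for a in anns_b], dtype=object) == t)
        sub_sc = sc[b].subset_cells(rows)
        sub_ann = [anns_b[i] for i in rows]
        endpoints = np.stack([sc[b].dense()[a.j2] for a in anchors_t])
        field_t = correction_vectors(sub_sc, sub_ann, anchors_t, params,
                                     anchor_endpoints=endpoints)
        vals = corrected[b].dense()
        vals[rows] = ln[b].dense()[rows] + field_t.vectors
        corrected[b] = ExpressionMatrix(vals, corrected[b].cell_ids,
                                        corrected[b].gene_ids,
                                        corrected[b].batch_ids, "corrected")

    merged = concat([corrected[b] for b in order])
    return IntegrationResult(merged, all_anchors, ref, hvg,
                             dict(annotations), warn_log)
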