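"""Integration-quality metrics: KBET, LISI, ASW, ARI, isolated labels,
HVG conservation and cell-cycle conservation.

Batch-mixing metrics (KBET, iLISI, ASW_batch) ask whether local batch
composition matches the global one; biology-conservation metrics (ARI,
cLISI, ASW_celltype, isolated-label, HVG overlap, cell-cycle) ask whether
the correction preserved cell-type structure. Metrics that need a
low-dimensional embedding default to a PCA of the corrected matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, silhouette_samples
from sklearn.neighbors import NearestNeighbors

from .io_preprocess import ExpressionMatrix, GeneSet, dispersion_scores


@dataclass
class MetricReport:
    """Named results of all integration metrics for one corrected dataset."""

    kbet_median_rejection: float | None = None
    kbet_by_fraction: dict = field(default_factory=dict)
    ilisi: float | None = None
    clisi: float | None = None
    asw_batch: float | None = None
    asw_celltype: float | None = None
    ari: float | None = None
    isolated_label: float | None = None
    cell_cycle: float | None = None
    hvg: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def pca_embedding(m: ExpressionMatrix, n_comps: int = 20) -> np.ndarray:
    """Deterministic PCA of an expression matrix (metrics' default space)."""
    X = m.dense()
    n_comps = min(n_comps, min(X.shape) - 1)
    return PCA(n_components=n_comps, svd_solver="full").fit_transform(X)


# ---------------------------------------------------------------------------
# clustering agreement / silhouettes
# ---------------------------------------------------------------------------

def ari(labels_true: Sequence, labels_pred: Sequence) -> float:
    """Adjusted Rand index between two labelings (pair-counting, chance-corrected)."""
    labels_true, labels_pred = list(labels_true), list(labels_pred)
    if len(labels_true) != len(labels_pred):
        raise ValueError("label sequences differ in length")
    if len(labels_true) < 2:
        raise ValueError("need at least 2 points")
    return float(adjusted_rand_score(labels_true, labels_pred))


def silhouette_asw(embedding: np.ndarray, labels: Sequence,
                   mode: str = "celltype") -> float:
    """Mean silhouette width over all cells.

    ``celltype`` mode: higher = purer cell types. ``batch`` mode: lower =
    better batch mixing. Cells in singleton label groups contribute 0.
    """
    if mode not in ("celltype", "batch"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = np.asarray(labels, dtype=object)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct labels")
    if (counts == 1).any():
        warnings.warn("labels with a single member; their silhouette is 0")
    return float(silhouette_samples(np.asarray(embedding, float), labels).mean())


# ---------------------------------------------------------------------------
# LISI
# ---------------------------------------------------------------------------

def _perplexity_probs(dists: np.ndarray, perplexity: float,
                      tol: float = 1e-5, max_iter: int = 100) -> np.ndarray:
    """Gaussian neighbor probabilities with bandwidth tuned by bisection so
    the distribution's perplexity (2^entropy) matches the target."""
    d2 = dists ** 2
    d2 = d2 - d2.min()
    target = np.log2(perplexity)
    lo, hi = 0.0, np.inf
    beta = 1.0
    p = None
    for _ in range(max_iter):
        w = np.exp(-beta * d2)
        s = w.sum()
        if s <= 0:
            p = np.zeros_like(d2)
            p[np.argmin(d2)] = 1.0
            break
        p = w / s
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -(p[p > 0] * np.log2(p[p > 0])).sum()
        err = h - target
        if abs(err) < tol:
            break
        if err > 0:     # too flat → increase beta
            lo = beta
            beta = beta * 2 if hi == np.inf else (lo + hi) / 2
        else:
            hi = beta
            beta = beta / 2 if lo == 0.0 else (lo + hi) / 2
    return p


def lisi(embedding: np.ndarray, labels: Sequence,
         perplexity: float = 30.0) -> np.ndarray:
    """Per-cell local inverse Simpson's index of a categorical labeling.

    For each cell, neighbor probabilities with perplexity-tuned Gaussian
    bandwidth are aggregated per category; the score is 1/Σ_c p_c² — the
    effective number of categories in the cell's neighborhood. Computed on
    batch labels this is iLISI (→ number of batches when mixing is perfect);
    on type labels it is cLISI (→ 1 when neighborhoods are pure).
    """
    X = np.asarray(embedding, float)
    labels = np.asarray(labels, dtype=object)
    n = len(X)
    cats = pd.unique(labels)
    if len(cats) == 1:
        return np.ones(n)
    if n < 3 * perplexity:
        warnings.warn(f"n={n} is below 3×perplexity; LISI may be unstable")
    k = int(min(n - 1, max(15, 3 * perplexity)))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dists, idx = nn.kneighbors(X)
    dists, idx = dists[:, 1:], idx[:, 1:]   # drop self
    cat_codes = pd.Categorical(labels, categories=cats).codes
    scores = np.empty(n)
    for i in range(n):
        p = _perplexity_probs(dists[i], perplexity)
        pc = np.bincount(cat_codes[idx[i]], weights=p, minlength=len(cats))
        scores[i] = 1.0 / max((pc ** 2).sum(), 1e-300)
    return scores


def median_lisi(embedding: np.ndarray, labels: Sequence,
                perplexity: float = 30.0) -> float:
    """Median per-cell LISI (the reported summary)."""
    return float(np.median(lisi(embedding, labels, perplexity)))


# ---------------------------------------------------------------------------
# KBET
# ---------------------------------------------------------------------------

def kbet(embedding: np.ndarray, batch_labels: Sequence,
         test_fractions: Sequence[float] = (0.05, 0.10, 0.15, 0.20, 0.25),
         alpha: float = 0.05) -> tuple:
    """k-nearest-neighbour batch-effect test rejection rates.

    For each fraction f, every cell's k0 = round(f·n) neighborhood (self
    included) is compared to the global batch composition with a Pearson χ²
    test (dof = batches − 1); the rejection rate is the fraction of cells
    with p < alpha. Returns (median over fractions, {fraction: rate}).

    The statistic carries a finite-population correction (n−1)/(n−k0):
    a k0-neighborhood is a without-replacement draw from the n cells, whose
    counts have hypergeometric (not binomial) variance, and at the largest
    tested fractions the uncorrected test would be markedly conservative.
    """
    X = np.asarray(embedding, float)
    batch_labels = np.asarray(batch_labels, dtype=object)
    n = len(X)
    cats, counts = np.unique(batch_labels, return_counts=True)
    if len(cats) < 2:
        raise ValueError("need at least 2 batches")
    freqs = counts / n
    codes = pd.Categorical(batch_labels, categories=cats).codes
    by_fraction = {}
    max_k = max(int(round(f * n)) for f in test_fractions)
    nn = NearestNeighbors(n_neighbors=min(max_k, n)).fit(X)
    _, all_idx = nn.kneighbors(X)
    for f in test_fractions:
        k0 = int(round(f * n))
        if k0 < 10:
            warnings.warn(f"fraction {f} gives neighborhood size {k0} < 10; skipped")
            continue
        expected = k0 * freqs
        nbr_codes = codes[all_idx[:, :k0]]
        obs = np.stack([(nbr_codes == c).sum(axis=1) for c in range(len(cats))],
                       axis=1)
        fpc = (n - 1) / (n - k0) if k0 < n else 1.0
        stat = fpc * ((obs - expected) ** 2 / expected).sum(axis=1)
        pvals = chi2.sf(stat, df=len(cats) - 1)
        by_fraction[f] = float((pvals < alpha).mean())
    if not by_fraction:
        raise ValueError("no usable test fraction (all neighborhoods < 10)")
    return float(np.median(list(by_fraction.values()))), by_fraction


# ---------------------------------------------------------------------------
# isolated labels
# ---------------------------------------------------------------------------

def _leiden_grid(embedding: np.ndarray, resolutions: Sequence[float],
                 n_neighbors: int = 15, seed: int = 0) -> list:
    """Leiden partitions of a kNN graph over a resolution grid."""
    import igraph as ig
    import leidenalg

    X = np.asarray(embedding, float)
    k = min(n_neighbors, len(X) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    edges = {(min(i, j), max(i, j)) for i in range(len(X)) for j in idx[i, 1:]}
    g = ig.Graph(n=len(X), edges=sorted(edges))
    parts = []
    for r in resolutions:
        p = leidenalg.find_partition(g, leidenalg.RBConfigurationVertexPartition,
                                     resolution_parameter=r, seed=seed)
        parts.append(np.asarray(p.membership))
    return parts


def isolated_label_score(embedding: np.ndarray, cell_labels: Sequence,
                         batch_labels: Sequence,
                         resolutions: Sequence[float] | None = None) -> float:
    """Mean of the isolated-label F1 and rescaled-ASW scores.

    Isolated labels are those present in the fewest batches. The F1 part is,
    per isolated label, the best one-cluster-vs-label F1 over a Leiden
    resolution grid; the ASW part is the mean silhouette of the label's
    cells against the rest, rescaled to [0, 1] via (s+1)/2.
    """
    cell_labels = np.asarray(cell_labels, dtype=object)
    batch_labels = np.asarray(batch_labels, dtype=object)
    if len(set(cell_labels)) < 2:
        raise ValueError("need at least 2 cell labels")
    if resolutions is None:
        resolutions = np.round(np.arange(0.1, 2.01, 0.1), 2)
    n_batches = {t: len(set(batch_labels[cell_labels == t]))
                 for t in set(cell_labels)}
    m = min(n_batches.values())
    isolated = sorted(t for t, c in n_batches.items() if c == m)
    if len(isolated) == len(n_batches):
        warnings.warn("every label is present in the same number of batches; "
                      "all labels treated as isolated")
    parts = _leiden_grid(embedding, resolutions)
    scores = []
    X = np.asarray(embedding, float)
    for t in isolated:
        mask = cell_labels == t
        best_f1 = 0.0
        for membership in parts:
            for c in np.unique(membership):
                in_c = membership == c
                tp = float((in_c & mask).sum())
                if tp == 0:
                    continue
                prec = tp / in_c.sum()
                rec = tp / mask.sum()
                best_f1 = max(best_f1, 2 * prec * rec / (prec + rec))
        binary = np.where(mask, "isolated", "rest")
        sil = silhouette_samples(X, binary)[mask].mean()
        scores.append((best_f1 + (sil + 1) / 2) / 2)
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# HVG conservation
# ---------------------------------------------------------------------------

def hvg_overlap(x: GeneSet, y: GeneSet) -> float:
    """Overlap coefficient |X ∩ Y| / min(|X|, |Y|)."""
    if len(x) == 0 or len(y) == 0:
        raise ValueError("gene sets must be non-empty")
    return len(x.genes & y.genes) / min(len(x), len(y))


def _top_dispersion_genes(X: np.ndarray, gene_ids: Sequence[str], n: int) -> GeneSet:
    scores = dispersion_scores(X)
    order = sorted(range(len(gene_ids)), key=lambda i: (-scores[i], gene_ids[i]))
    return GeneSet(gene_ids[i] for i in order[:n])


def hvg_conservation(before: Sequence[ExpressionMatrix],
                     after: ExpressionMatrix, n_hvg: int = 500) -> float | None:
    """Mean per-batch overlap of dispersion-flavoured HVGs before vs after.

    Per batch, the top 500 dispersion HVGs (or half the batch's genes when
    fewer than 500 remain in the integrated object) are computed before and
    after integration and compared with the overlap coefficient. Returns
    None when the integrated object carries no gene-space values.
    """
    if after.n_genes == 0:
        warnings.warn("integrated object has no gene space; HVG score absent")
        return None
    genes_after = list(after.gene_ids)
    overlaps = []
    for b in before:
        bid = str(b.batch_ids[0])
        shared = [g for g in genes_after if g in set(b.gene_ids)]
        n = n_hvg if len(shared) >= n_hvg else max(1, len(shared) // 2)
        hvg_before = _top_dispersion_genes(b.subset_genes(shared).dense(), shared, n)
        rows = after.batch_ids == bid
        hvg_after = _top_dispersion_genes(
            after.subset_cells(np.flatnonzero(rows)).subset_genes(shared).dense(),
            shared, n)
        overlaps.append(hvg_overlap(hvg_before, hvg_after))
    return float(np.mean(overlaps))


# ---------------------------------------------------------------------------
# cell-cycle conservation
# ---------------------------------------------------------------------------

def score_gene_set(m: ExpressionMatrix, genes: GeneSet, n_bins: int = 25,
                   ctrl_size: int = 50, seed: int = 0) -> np.ndarray:
    """Per-cell signature score: mean expression of the set minus a
    size-matched random background drawn from expression-level bins."""
    found = [g for g in genes if g in set(m.gene_ids)]
    if len(found) < 20:
        warnings.warn(f"only {len(found)} signature genes found in the panel")
    if not found:
        raise ValueError("no signature genes present")
    X = m.dense()
    gene_ids = list(m.gene_ids)
    mean_expr = X.mean(axis=0)
    order = np.argsort(mean_expr, kind="stable")
    n_bins = min(n_bins, max(1, m.n_genes // 2))
    bins = np.empty(m.n_genes, dtype=int)
    bins[order] = np.arange(m.n_genes) * n_bins // m.n_genes
    idx_of = {g: i for i, g in enumerate(gene_ids)}
    target = [idx_of[g] for g in found]
    rng = np.random.default_rng(seed)
    ctrl: set = set()
    for gi in target:
        pool = np.flatnonzero(bins == bins[gi])
        take = rng.choice(pool, size=min(ctrl_size, len(pool)), replace=False)
        ctrl.update(int(t) for t in take)
    ctrl -= set(target)
    if not ctrl:
        raise ValueError("empty control pool for signature scoring")
    return X[:, target].mean(axis=1) - X[:, sorted(ctrl)].mean(axis=1)


def _variance_explained(X: np.ndarray, covars: np.ndarray) -> float:
    """Fraction of total variance of (centered) X explained by a linear fit
    on the covariates."""
    Xc = X - X.mean(axis=0)
    C = np.column_stack([np.ones(len(X)), covars])
    beta, *_ = np.linalg.lstsq(C, Xc, rcond=None)
    resid = Xc - C @ beta
    total = (Xc ** 2).sum()
    if total <= 0:
        return 0.0
    return float(1 - (resid ** 2).sum() / total)


def cell_cycle_conservation(before: ExpressionMatrix, after: ExpressionMatrix,
                            s_genes: GeneSet, g2m_genes: GeneSet,
                            seed: int = 0) -> float | None:
    """Agreement of variance explained by cell-cycle scores before vs after.

    Per batch: S and G2M scores are computed on the pre-integration data,
    the variance they explain is measured in the before and after matrices,
    and the batch score is max(0, 1 − |var_after − var_before|/var_before);
    the mean over batches is returned (None when var_before is 0).
    """
    if before.n_cells != after.n_cells:
        raise ValueError("before/after must contain the same cells")
    scores_batch = []
    for b in pd.unique(before.batch_ids):
        rows = np.flatnonzero(before.batch_ids == b)
        sub_b = before.subset_cells(rows)
        sub_a = after.subset_cells(rows)
        s = score_gene_set(sub_b, s_genes, seed=seed)
        g2m = score_gene_set(sub_b, g2m_genes, seed=seed + 1)
        covars = np.column_stack([s, g2m])
        vb = _variance_explained(sub_b.dense(), covars)
        va = _variance_explained(sub_a.dense(), covars)
        if vb <= 0:
            warnings.warn(f"cell-cycle variance is 0 in batch {b}; score absent")
            return None
        scores_batch.append(max(0.0, 1 - abs(va - vb) / vb))
    return float(np.mean(scores_batch))


# ---------------------------------------------------------------------------
# all-in-one report
# ---------------------------------------------------------------------------

def compute_report(merged: ExpressionMatrix, cell_labels: Sequence,
                   before: Sequence[ExpressionMatrix] | None = None,
                   cluster_labels: Sequence | None = None,
                   n_comps: int = 20, perplexity: float = 30.0,
                   isolated: bool = True) -> MetricReport:
    """Compute the full metric suite on a corrected dataset.

    ``cell_labels`` are the (true or predicted) per-cell types aligned with
    ``merged``; ``cluster_labels`` default to k-means at the number of
    distinct cell labels on the PCA embedding.
    """
    emb = pca_embedding(merged, n_comps)
    batch_labels = merged.batch_ids
    report = MetricReport()
    report.kbet_median_rejection, report.kbet_by_fraction = kbet(emb, batch_labels)
    report.ilisi = median_lisi(emb, batch_labels, perplexity)
    report.clisi = median_lisi(emb, cell_labels, perplexity)
    report.asw_batch = silhouette_asw(emb, batch_labels, "batch")
    report.asw_celltype = silhouette_asw(emb, cell_labels, "celltype")
    if cluster_labels is None:
        from sklearn.cluster import KMeans

        k = len(set(cell_labels))
        cluster_labels = KMeans(n_clusters=k, n_init=10,
                                random_state=0).fit_predict(emb)
    report.ari = ari(cell_labels, cluster_labels)
    if isolated:
        report.isolated_label = isolated_label_score(emb, cell_labels, batch_labels)
    if before is not None:
        report.hvg = hvg_conservation(before, merged)
    return report
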