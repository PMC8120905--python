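"""Synthetic multi-batch scRNA-seq generator with known ground truth.

Cells are drawn from negative-binomial count distributions whose log-means
are a per-type expression program (a baseline plus a block of exclusive
marker genes) plus an additive per-batch shift. The shift direction mixes a
random component orthogonalized against the biological subspace with the
difference between two designated type programs, controlled by
``non_orthogonality`` ∈ [0, 1] — at 0 the batch effect is orthogonal to the
biology (the regime where unconstrained mutual-nearest-neighbor anchoring
works), at high values cross-batch neighbors increasingly pair different
cell types, the failure mode the type-constrained method is built for.
Library-size jitter and Bernoulli dropout add the usual technical noise.
All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_preprocess import ExpressionMatrix


@dataclass(frozen=True)
class PresenceMatrix:
    """Batches × types boolean design: which types each batch contains."""

    table: pd.DataFrame    # index = batch ids, columns = type labels, bool

    def __post_init__(self):
        t = self.table.astype(bool)
        if not t.any(axis=1).all():
            raise ValueError("every batch needs at least one type")
        if not t.any(axis=0).all():
            raise ValueError("every type needs at least one batch")

    @classmethod
    def from_dict(cls, d: Mapping[str, Sequence[str]],
                  types: Sequence[str] | None = None) -> "PresenceMatrix":
        """Build from {batch: [types present]}."""
        if types is None:
            types = sorted({t for ts in d.values() for t in ts})
        tbl = pd.DataFrame(False, index=sorted(d), columns=list(types))
        for b, ts in d.items():
            tbl.loc[b, list(ts)] = True
        return cls(tbl)

    @property
    def batches(self) -> list:
        return list(self.table.index)

    @property
    def types(self) -> list:
        return list(self.table.columns)

    def types_in(self, batch: str) -> list:
        row = self.table.loc[batch]
        return [t for t in self.table.columns if row[t]]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; ``seed`` is mandatory.

    ``cells_per_type`` may be an int (same everywhere) or a nested mapping
    {batch: {type: n}}. ``similar_pairs`` lists type pairs that share
    ``shared_marker_fraction`` of their marker genes (hard-to-separate
    types). ``bio_axis`` names the two types whose program difference forms
    the biological component of a non-orthogonal batch shift (defaults to
    the first two types).
    """

    seed: int
    n_genes: int = 1000
    cells_per_type: int | Mapping = 100
    n_markers: int = 50
    marker_strength: float = 2.0
    baseline_sd: float = 0.5
    batch_shift_magnitude: float = 6.0
    non_orthogonality: float = 0.0
    dropout_rate: float = 0.2
    dispersion: float = 0.1
    libsize_sigma: float = 0.3
    similar_pairs: tuple = ()
    shared_marker_fraction: float = 0.8
    bio_axis: tuple | None = None

    def __post_init__(self):
        if not (0.0 <= self.non_orthogonality <= 1.0):
            raise ValueError("non_orthogonality must be in [0, 1]")
        for name in ("batch_shift_magnitude", "dropout_rate", "dispersion",
                     "marker_strength", "libsize_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def n_cells(self, batch: str, ctype: str) -> int:
        if isinstance(self.cells_per_type, Mapping):
            return int(self.cells_per_type[batch][ctype])
        return int(self.cells_per_type)


def _type_programs(config: SimulationConfig, types: Sequence[str],
                   rng: np.random.Generator) -> dict:
    """Per-type log-mean vectors: common baseline + marker blocks.

    Marker blocks are disjoint by default; for each pair in
    ``similar_pairs`` the second type reuses the leading fraction of the
    first type's markers.
    """
    G, M = config.n_genes, config.n_markers
    if len(types) * M > G:
        raise ValueError("n_genes too small for the marker blocks")
    baseline = rng.normal(0.0, config.baseline_sd, G)
    blocks = {t: np.arange(i * M, (i + 1) * M) for i, t in enumerate(types)}
    for second, first in [(b, a) for a, b in config.similar_pairs]:
        n_shared = int(round(config.shared_marker_fraction * M))
        blocks[second] = np.concatenate([blocks[first][:n_shared],
                                         blocks[second][n_shared:]])
    programs = {}
    for t in types:
        p = baseline.copy()
        p[blocks[t]] += config.marker_strength
        programs[t] = p
    return programs


def _batch_shift(config: SimulationConfig, programs: Mapping[str, np.ndarray],
                 rng: np.random.Generator) -> dict:
    """Additive log-mean shift for one batch, per type.

    The orthogonal component — a random direction orthogonalized against the
    span of the centered type programs — is common to every type and scaled
    by (1−q)·magnitude. The non-orthogonal component (q·magnitude) moves
    each of the two ``bio_axis`` types *toward the other's program*, a
    type-dependent displacement along the biological axis: exactly the
    regime in which cross-batch nearest neighbors pair wrong cell types.
    With q = 0 every type receives the identical, biology-orthogonal shift.
    """
    types = list(programs)
    if config.batch_shift_magnitude == 0:
        return {t: np.zeros(config.n_genes) for t in types}
    q = config.non_orthogonality
    P = np.stack(list(programs.values()))
    B = P - P.mean(axis=0)                       # biological subspace basis
    raw = rng.normal(0.0, 1.0, config.n_genes)
    Q, _ = np.linalg.qr(B.T)
    orth = raw - Q @ (Q.T @ raw)
    orth /= np.linalg.norm(orth)
    common = (1 - q) * config.batch_shift_magnitude * orth
    shifts = {t: common.copy() for t in types}
    if q > 0:
        a, b = config.bio_axis or (types[0], types[1])
        axis = programs[b] - programs[a]
        axis = axis / np.linalg.norm(axis)
        shifts[a] = common + q * config.batch_shift_magnitude * axis
        shifts[b] = common - q * config.batch_shift_magnitude * axis
    return shifts


def simulate_counts(config: SimulationConfig, presence: PresenceMatrix,
                    zero_shift_first: bool = True):
    """Draw per-batch count matrices with ground-truth type labels.

    Returns ``(batches, truth, shifts)``: dicts keyed by batch id holding a
    counts-layer :class:`ExpressionMatrix`, the per-cell true type array,
    and the applied log-mean shift vectors (one per type, identical across
    types when the shift is orthogonal). The first batch in sorted order
    gets a zero shift (it plays the role of the unshifted reference frame)
    unless ``zero_shift_first=False``.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 + len(presence.batches))
    rng_prog = np.random.default_rng(children[0])
    programs = _type_programs(config, presence.types, rng_prog)
    rng_shift = np.random.default_rng(children[1])

    shifts = {}
    for i, batch in enumerate(sorted(presence.batches)):
        if i == 0 and zero_shift_first:
            shifts[batch] = {t: np.zeros(config.n_genes)
                             for t in presence.types}
        else:
            shifts[batch] = _batch_shift(config, programs, rng_shift)

    batches, truth = {}, {}
    r = 1.0 / config.dispersion if config.dispersion > 0 else None
    for bi, batch in enumerate(sorted(presence.batches)):
        rng = np.random.default_rng(children[2 + bi])
        rows, labels, ids = [], [], []
        for t in presence.types_in(batch):
            n = config.n_cells(batch, t)
            logmean = programs[t] + shifts[batch][t]
            lib = np.exp(rng.normal(0.0, config.libsize_sigma, n))
            mu = np.exp(logmean)[None, :] * lib[:, None]
            if r is not None:
                counts = rng.negative_binomial(r, r / (r + mu)).astype(float)
            else:
                counts = rng.poisson(mu).astype(float)
            if config.dropout_rate > 0:
                counts *= rng.random(counts.shape) >= config.dropout_rate
            # a cell must keep at least one transcript for normalization
            empty = counts.sum(axis=1) == 0
            counts[empty, int(np.argmax(logmean))] = 1.0
            rows.append(counts)
            labels += [t] * n
            ids += [f"{batch}|{t}|{i}" for i in range(n)]
        batches[batch] = ExpressionMatrix(
            np.vstack(rows), np.asarray(ids, dtype=object),
            np.asarray([f"g{j}" for j in range(config.n_genes)], dtype=object),
            np.repeat(batch, len(ids)).astype(object), "counts")
        truth[batch] = np.asarray(labels, dtype=object)
    return batches, truth, shifts


def simulate_reference(config: SimulationConfig, types: Sequence[str],
                       cells_per_type: int = 60, batch_id: str = "reference"):
    """A labeled, shift-free reference batch sharing the scenario's programs.

    Drawn with the same type programs as :func:`simulate_counts` under the
    same config seed, but with its own sampling noise — the training set for
    the supervised annotator.
    """
    pres = PresenceMatrix.from_dict({batch_id: list(types)}, types=list(types))
    cfg = replace(config, cells_per_type=cells_per_type,
                  batch_shift_magnitude=0.0)
    batches, truth, _ = simulate_counts(cfg, pres)
    return batches[batch_id], truth[batch_id]


def simulate_lognorm_shift(n_genes: int = 200, types: Sequence[str] = ("A", "B"),
                           cells_per_type: int = 500, marker_strength: float = 3.0,
                           n_markers: int = 30, shift_sd: float = 0.5,
                           noise_sd: float = 0.3, seed: int = 0):
    """Two Gaussian lognorm-layer batches with an exact per-type additive shift.

    Batch 2 cells of type t are displaced by a known vector δ_t in the very
    space corrections are computed in, so correction recovery can be
    measured against an exact target. ``shift_sd`` is the per-gene standard
    deviation of δ — by default somewhat larger than the within-type noise,
    the regime where a batch effect visibly displaces clusters and
    correction is warranted. Returns ``(batches, truth, deltas)`` with δ
    keyed by type.
    """
    rng = np.random.default_rng(seed)
    programs = {}
    for i, t in enumerate(types):
        p = rng.normal(1.0, 0.5, n_genes).clip(min=0.1)
        p[i * n_markers:(i + 1) * n_markers] += marker_strength
        programs[t] = p
    deltas = {t: rng.normal(0.0, shift_sd, n_genes) for t in types}
    gene_ids = np.asarray([f"g{j}" for j in range(n_genes)], dtype=object)
    batches, truth = {}, {}
    for b, shift_on in (("batch1", False), ("batch2", True)):
        rows, labels, ids = [], [], []
        for t in types:
            mu = programs[t] + (deltas[t] if shift_on else 0.0)
            rows.append(rng.normal(mu, noise_sd, (cells_per_type, n_genes)))
            labels += [t] * cells_per_type
            ids += [f"{b}|{t}|{i}" for i in range(cells_per_type)]
        # values stay unclipped: truncating at zero would attenuate the
        # effective shift on low-expression genes and bias recovery checks
        batches[b] = ExpressionMatrix(np.vstack(rows),
                                      np.asarray(ids, dtype=object), gene_ids,
                                      np.repeat(b, len(ids)).astype(object),
                                      "lognorm")
        truth[b] = np.asarray(labels, dtype=object)
    return batches, truth, deltas


# ---------------------------------------------------------------------------
# named scenarios
# ---------------------------------------------------------------------------

_PANCREAS_PRESENCE = {
    # printed three-platform pancreas design: per-batch type removals leave
    # one type in all batches, three in two batches and four batch-exclusive
    "celseq":    ["acinar", "beta", "delta", "activated", "alpha"],
    "celseq2":   ["delta", "activated", "ductal", "gamma", "endothelial"],
    "smartseq2": ["acinar", "beta", "delta", "ductal"],
}
_PANCREAS_TYPES = ["acinar", "beta", "delta", "activated", "alpha",
                   "ductal", "gamma", "endothelial"]

SCENARIOS = ("scenario1_structure", "scenario2_similar", "scenario3_unbalanced",
             "nonorthogonal_shift", "null_no_effect", "threebatch_order")


@dataclass(frozen=True)
class ScenarioBundle:
    """A fully parameterized named stress scenario."""

    name: str
    config: SimulationConfig
    presence: PresenceMatrix
    description: str

    def generate(self, with_reference: bool = True, seed: int | None = None):
        """Materialize the scenario (optionally overriding the seed).

        Returns a dict with ``batches``, ``truth``, ``shifts`` and, when
        requested, a labeled ``reference`` for classifier training.
        """
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        batches, truth, shifts = simulate_counts(cfg, self.presence)
        out = {"batches": batches, "truth": truth, "shifts": shifts,
               "config": cfg, "presence": self.presence}
        if with_reference:
            ref, ref_labels = simulate_reference(cfg, self.presence.types)
            out["reference"], out["reference_labels"] = ref, ref_labels
        return out


def scenario_fixture(name: str) -> ScenarioBundle:
    """Named stress scenarios with fixed parameters and seeds.

    - ``scenario1_structure``: three batches / eight types with the pancreas
      presence design (non-identical type structure across batches).
    - ``scenario2_similar``: two type pairs sharing 80% of their markers.
    - ``scenario3_unbalanced``: two types at 1:9 vs 5:5 batch proportions.
    - ``nonorthogonal_shift``: a batch shift pointing largely along the
      between-type axis (q = 0.8), the anchor-mismatch regime.
    - ``null_no_effect``: two batches from identical distributions.
    - ``threebatch_order``: three partially overlapping batches for
      order-invariance checks.
    """
    if name == "scenario1_structure":
        return ScenarioBundle(
            name,
            SimulationConfig(seed=11, n_genes=1000, cells_per_type=80,
                             batch_shift_magnitude=6.0),
            PresenceMatrix.from_dict(_PANCREAS_PRESENCE, types=_PANCREAS_TYPES),
            "pancreas-style presence: 1 type in all batches, 4 exclusive")
    if name == "scenario2_similar":
        # marker blocks cover ~1/3 of the genome so that sweeping the HVG
        # panel from 500 to all genes varies the feature set, not the
        # amount of biological information available to clustering
        return ScenarioBundle(
            name,
            SimulationConfig(seed=12, n_genes=5000, cells_per_type=100,
                             n_markers=400, batch_shift_magnitude=6.0,
                             similar_pairs=(("A1", "A2"), ("B1", "B2"))),
            PresenceMatrix.from_dict({"batch1": ["A1", "A2", "B1", "B2"],
                                      "batch2": ["A1", "A2", "B1", "B2"]}),
            "two hard type pairs sharing 80% of markers")
    if name == "scenario3_unbalanced":
        cells = {"batch1": {"t293": 20, "jurkat": 180},
                 "batch2": {"t293": 100, "jurkat": 100}}
        return ScenarioBundle(
            name,
            SimulationConfig(seed=13, n_genes=800, cells_per_type=cells,
                             batch_shift_magnitude=6.0),
            PresenceMatrix.from_dict({"batch1": ["t293", "jurkat"],
                                      "batch2": ["t293", "jurkat"]}),
            "1:9 vs 5:5 type proportions across two batches")
    if name == "nonorthogonal_shift":
        return ScenarioBundle(
            name,
            SimulationConfig(seed=7, n_genes=800, cells_per_type=150,
                             batch_shift_magnitude=18.0, non_orthogonality=0.8,
                             bio_axis=("C1", "C2")),
            PresenceMatrix.from_dict({"batch1": ["C1", "C2"],
                                      "batch2": ["C1", "C2"]}),
            "batch shift largely along the C1→C2 biological axis")
    if name == "null_no_effect":
        return ScenarioBundle(
            name,
            SimulationConfig(seed=15, n_genes=500, cells_per_type=150,
                             batch_shift_magnitude=0.0),
            PresenceMatrix.from_dict({"batch1": ["A", "B"],
                                      "batch2": ["A", "B"]}),
            "two batches drawn from identical distributions")
    if name == "threebatch_order":
        return ScenarioBundle(
            name,
            SimulationConfig(seed=16, n_genes=800, cells_per_type=80,
                             batch_shift_magnitude=5.0),
            PresenceMatrix.from_dict({"b1": ["T1", "T2", "T3"],
                                      "b2": ["T1", "T2", "T4"],
                                      "b3": ["T1", "T3", "T4"]}),
            "three partially overlapping batches (order-invariance check)")
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")


def split_reference_query(batch: ExpressionMatrix, truth: Sequence[str],
                          holdout_fraction: float = 0.5, seed: int = 0):
    """Stratified-by-type split into (reference, ref_labels, query, query_labels).

    Types with a single cell stay in the reference (with a warning).
    """
    import warnings

    if not (0 < holdout_fraction < 1):
        raise ValueError("holdout_fraction must be in (0, 1)")
    truth = np.asarray(truth, dtype=object)
    rng = np.random.default_rng(seed)
    ref_idx, query_idx = [], []
    for t in sorted(set(truth)):
        idx = np.flatnonzero(truth == t)
        if len(idx) == 1:
            warnings.warn(f"type {t!r} has a single cell; kept in reference")
            ref_idx += list(idx)
            continue
        perm = rng.permutation(idx)
        n_q = int(round(holdout_fraction * len(idx)))
        n_q = min(max(n_q, 1), len(idx) - 1)
        query_idx += list(perm[:n_q])
        ref_idx += list(perm[n_q:])
    ref_idx, query_idx = np.sort(ref_idx), np.sort(query_idx)
    return (batch.subset_cells(ref_idx), truth[ref_idx],
            batch.subset_cells(query_idx), truth[query_idx])
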