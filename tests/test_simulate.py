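import numpy as np
import pytest

from ssber.annotate import oracle_annotations
from ssber.anchors import KnnParams, anchor_mismatch_rate, find_anchors
from ssber.io_preprocess import normalize_log, scale_zscore, select_hvg
from ssber.metrics import kbet, pca_embedding
from ssber.simulate import (SCENARIOS, PresenceMatrix, SimulationConfig,
                            scenario_fixture, simulate_counts,
                            simulate_lognorm_shift, simulate_reference,
                            split_reference_query)


class TestPresenceMatrix:
    def test_from_dict_round_trip(self):
        p = PresenceMatrix.from_dict({"b1": ["x", "y"], "b2": ["y"]})
        assert p.types_in("b1") == ["x", "y"]
        assert p.types_in("b2") == ["y"]

    def test_empty_batch_rejected(self):
        import pandas as pd
        tbl = pd.DataFrame([[True, False], [False, False]],
                           index=["b1", "b2"], columns=["x", "y"])
        with pytest.raises(ValueError, match="batch"):
            PresenceMatrix(tbl)

    def test_orphan_type_rejected(self):
        import pandas as pd
        tbl = pd.DataFrame([[True, False]], index=["b1"], columns=["x", "y"])
        with pytest.raises(ValueError, match="type"):
            PresenceMatrix(tbl)


class TestSimulateCounts:
    def test_same_seed_bitwise_identical(self):
        cfg = SimulationConfig(seed=9, n_genes=300, cells_per_type=20)
        pres = PresenceMatrix.from_dict({"b1": ["A", "B"], "b2": ["A"]})
        r1 = simulate_counts(cfg, pres)
        r2 = simulate_counts(cfg, pres)
        for b in ("b1", "b2"):
            np.testing.assert_array_equal(r1[0][b].dense(), r2[0][b].dense())
            np.testing.assert_array_equal(r1[1][b], r2[1][b])

    def test_counts_layer_with_positive_cell_totals(self):
        cfg = SimulationConfig(seed=2, n_genes=200, cells_per_type=15,
                               dropout_rate=0.6)
        pres = PresenceMatrix.from_dict({"b1": ["A", "B"]})
        batches, _, _ = simulate_counts(cfg, pres)
        X = batches["b1"].dense()
        assert X.min() >= 0
        assert (X.sum(axis=1) > 0).all()

    def test_orthogonal_shift_uncorrelated_with_biology(self):
        cfg = SimulationConfig(seed=6, n_genes=500, cells_per_type=10,
                               batch_shift_magnitude=5.0, non_orthogonality=0.0)
        pres = PresenceMatrix.from_dict({"b1": ["A", "B", "C"],
                                         "b2": ["A", "B", "C"]})
        _, _, shifts = simulate_counts(cfg, pres)
        from ssber.simulate import _type_programs
        rng = np.random.default_rng(np.random.SeedSequence(6).spawn(3)[0])
        programs = _type_programs(cfg, ["A", "B", "C"], rng)
        shift = shifts["b2"]["A"]
        # identical for every type when q = 0
        np.testing.assert_array_equal(shift, shifts["b2"]["B"])
        for t1, t2 in (("A", "B"), ("A", "C"), ("B", "C")):
            diff = programs[t1] - programs[t2]
            corr = np.dot(shift, diff) / (np.linalg.norm(shift)
                                          * np.linalg.norm(diff))
            assert abs(corr) < 0.1

    def test_unbalanced_cell_counts_honored(self):
        bundle = scenario_fixture("scenario3_unbalanced").generate(
            with_reference=False)
        t1 = bundle["truth"]["batch1"]
        assert (t1 == "t293").sum() == 20
        assert (t1 == "jurkat").sum() == 180
        t2 = bundle["truth"]["batch2"]
        assert (t2 == "t293").sum() == (t2 == "jurkat").sum() == 100


class TestScenarios:
    def test_all_names_resolve(self):
        for name in SCENARIOS:
            bundle = scenario_fixture(name)
            assert bundle.name == name

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario_fixture("nope")

    def test_pancreas_presence_pattern(self):
        # one type in all three batches, three in two, four batch-exclusive
        p = scenario_fixture("scenario1_structure").presence
        tbl = p.table.astype(int)
        assert list(tbl.index) == ["celseq", "celseq2", "smartseq2"]
        per_type = tbl.sum(axis=0)
        assert per_type["delta"] == 3
        assert sorted(t for t in per_type.index if per_type[t] == 2) == \
            ["acinar", "activated", "beta", "ductal"]
        assert sorted(t for t in per_type.index if per_type[t] == 1) == \
            ["alpha", "endothelial", "gamma"]
        assert set(p.types_in("celseq")) == {"acinar", "beta", "delta",
                                             "activated", "alpha"}
        assert "beta" not in p.types_in("celseq2")

    def test_null_scenario_has_no_shift(self):
        bundle = scenario_fixture("null_no_effect")
        assert bundle.config.batch_shift_magnitude == 0.0
        data = bundle.generate(with_reference=False)
        for shift in data["shifts"]["batch2"].values():
            assert np.all(shift == 0.0)

    def test_reference_shares_type_programs(self):
        bundle = scenario_fixture("null_no_effect")
        data = bundle.generate(with_reference=True)
        ref, labels = data["reference"], data["reference_labels"]
        assert set(labels) == set(bundle.presence.types)
        assert ref.n_genes == bundle.config.n_genes


class TestSplitReferenceQuery:
    def test_even_split_per_type(self, rng):
        cfg = SimulationConfig(seed=1, n_genes=100, cells_per_type=100)
        pres = PresenceMatrix.from_dict({"b": ["A", "B"]})
        batches, truth, _ = simulate_counts(cfg, pres)
        ref, ref_t, q, q_t = split_reference_query(batches["b"], truth["b"],
                                                   0.5, seed=0)
        assert (ref_t == "A").sum() == (q_t == "A").sum() == 50
        assert ref.n_cells + q.n_cells == 200
        assert set(ref.cell_ids) | set(q.cell_ids) == set(batches["b"].cell_ids)

    def test_proportions_preserved_within_one_cell(self, rng):
        cfg = SimulationConfig(seed=1, n_genes=100,
                               cells_per_type={"b": {"A": 31, "B": 17}})
        pres = PresenceMatrix.from_dict({"b": ["A", "B"]})
        batches, truth, _ = simulate_counts(cfg, pres)
        ref, ref_t, q, q_t = split_reference_query(batches["b"], truth["b"],
                                                   0.3, seed=0)
        assert abs((q_t == "A").sum() - round(0.3 * 31)) <= 1
        assert abs((q_t == "B").sum() - round(0.3 * 17)) <= 1

    def test_invalid_fraction_rejected(self, rng):
        cfg = SimulationConfig(seed=1, n_genes=50, cells_per_type=5)
        pres = PresenceMatrix.from_dict({"b": ["A"]})
        batches, truth, _ = simulate_counts(cfg, pres)
        with pytest.raises(ValueError):
            split_reference_query(batches["b"], truth["b"], 1.5)


class TestStressProperties:
    def test_kbet_rejection_grows_with_shift_magnitude(self):
        pres = PresenceMatrix.from_dict({"b1": ["A", "B"], "b2": ["A", "B"]})
        meds = []
        for mag in (0.0, 4.0, 12.0):
            cfg = SimulationConfig(seed=8, n_genes=300, cells_per_type=60,
                                   batch_shift_magnitude=mag)
            batches, _, _ = simulate_counts(cfg, pres)
            from ssber.io_preprocess import concat
            ln = concat([normalize_log(batches[b]) for b in sorted(batches)])
            emb = pca_embedding(ln, 10)
            meds.append(kbet(emb, ln.batch_ids)[0])
        assert meds[0] <= meds[1] <= meds[2]
        assert meds[2] > meds[0]

    def test_unconstrained_mismatch_grows_with_non_orthogonality(self):
        rates = []
        for q in (0.0, 0.5, 0.9):
            per_seed = []
            for seed in (7, 8, 9):
                cfg = SimulationConfig(seed=seed, n_genes=300,
                                       cells_per_type=60,
                                       batch_shift_magnitude=14.0,
                                       non_orthogonality=q,
                                       bio_axis=("A", "B"))
                pres = PresenceMatrix.from_dict({"b1": ["A", "B"],
                                                 "b2": ["A", "B"]})
                batches, truth, _ = simulate_counts(cfg, pres)
                ln = {b: normalize_log(m) for b, m in batches.items()}
                hvg = select_hvg(list(ln.values()), 200).sorted()
                sc = {b: scale_zscore(m.subset_genes(hvg))
                      for b, m in ln.items()}
                anns = {b: oracle_annotations(batches[b], truth[b])
                        for b in batches}
                anchors = find_anchors(sc["b1"], sc["b2"], anns["b1"],
                                       anns["b2"], None, KnnParams(k=10),
                                       d=10, constrain_types=False)
                per_seed.append(anchor_mismatch_rate(anchors, truth["b1"],
                                                     truth["b2"]))
            rates.append(np.mean(per_seed))
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]

    def test_lognorm_shift_fixture_reports_exact_deltas(self):
        batches, truth, deltas = simulate_lognorm_shift(
            n_genes=50, cells_per_type=200, noise_sd=1e-9, seed=5)
        # with vanishing noise the batch-2 type means differ from batch-1
        # means by exactly delta
        for t in ("A", "B"):
            m1 = batches["batch1"].dense()[truth["batch1"] == t].mean(0)
            m2 = batches["batch2"].dense()[truth["batch2"] == t].mean(0)
            np.testing.assert_allclose(m2 - m1, deltas[t], atol=1e-7)
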