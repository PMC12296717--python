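"""Fusion contracts: partitioning, concatenation, selectors, MLDF/HLDF."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from mbfusion import (
    BlockSpec,
    FeatureBlock,
    FusionConfig,
    SampleManifest,
    SyntheticSpec,
    generate_study,
    hldf_gini_fusion,
    lldf_concatenate,
    mldf_fuse,
    partition_model_set,
    select_importance_features,
    select_pca_features,
    select_plsda_features,
    train_classifier,
    zscore_block,
)
from mbfusion.core import child_seed

from conftest import sparse_study_spec


def standardized_training_data(seed=7):
    """Sparse four-block study, z-scored, split — shared across fusion tests."""
    study = generate_study(sparse_study_spec(seed))
    man = study.manifest
    zb = {p: zscore_block(b, man.model_ids)[0] for p, b in study.tabular.items()}
    tr_ids, te_ids = partition_model_set(man, 0.7, seed=seed)
    y = man.groups
    return (
        {p: b.data.loc[tr_ids] for p, b in zb.items()},
        {p: b.data.loc[te_ids] for p, b in zb.items()},
        y.loc[tr_ids].to_numpy(),
        y.loc[te_ids].to_numpy(),
        study,
    )


class TestPartition:
    def test_seventy_samples_split_49_21(self, paper_manifest):
        train, test = partition_model_set(paper_manifest, 0.7, seed=0)
        assert (len(train), len(test)) == (49, 21)
        assert set(train).isdisjoint(test)

    def test_split_is_stratified(self, paper_manifest):
        train, test = partition_model_set(paper_manifest, 0.7, seed=3)
        g = paper_manifest.groups
        assert sorted(g.loc[train].value_counts()) == [24, 25]
        assert sorted(g.loc[test].value_counts()) == [10, 11]

    def test_full_fraction_rejected(self, paper_manifest):
        with pytest.raises(ValueError):
            partition_model_set(paper_manifest, 1.0, seed=0)

    def test_same_seed_same_membership(self, paper_manifest):
        a = partition_model_set(paper_manifest, 0.7, seed=11)
        b = partition_model_set(paper_manifest, 0.7, seed=11)
        assert a == b

    def test_too_few_samples_rejected(self):
        man = SampleManifest.from_counts([("A", 4), ("B", 4)])
        with pytest.raises(ValueError, match="10"):
            partition_model_set(man, 0.7, seed=0)


class TestLLDF:
    def _blocks(self, widths, n=6):
        idx = [f"s{i}" for i in range(n)]
        rng = np.random.default_rng(0)
        return [
            FeatureBlock(f"B{k}", pd.DataFrame(
                rng.normal(size=(n, w)), index=idx, columns=[f"f{j}" for j in range(w)]))
            for k, w in enumerate(widths)
        ]

    def test_width_additivity_and_prefixing(self):
        fused = lldf_concatenate(self._blocks([5, 7, 11, 13]))
        assert fused.width == 36
        assert fused.data.columns[0] == "B0:f0"

    def test_single_block_identity_modulo_prefix(self):
        (b,) = self._blocks([4])
        fused = lldf_concatenate([b])
        assert np.array_equal(fused.data.to_numpy(), b.data.to_numpy())

    def test_misaligned_samples_rejected(self):
        b1, b2 = self._blocks([3, 3])
        b2 = FeatureBlock(b2.platform, b2.data.iloc[::-1])
        with pytest.raises(ValueError, match="alignment"):
            lldf_concatenate([b1, b2])

    def test_block_order_irrelevant_for_distance_classifier(self):
        """Permuting block order permutes columns; a kNN classifier's
        predictions are invariant because distances are."""
        blocks = self._blocks([5, 7, 3], n=20)
        y = np.array(["A", "B"] * 10)
        f1 = lldf_concatenate(blocks)
        f2 = lldf_concatenate(blocks[::-1])
        m1 = train_classifier(f1.data.iloc[:14], y[:14], "KNN")
        m2 = train_classifier(f2.data.iloc[:14], y[:14], "KNN")
        assert np.array_equal(m1.predict(f1.data.iloc[14:]), m2.predict(f2.data.iloc[14:]))


class TestSelectors:
    def test_pca_rank_two_data(self, rng):
        basis = rng.normal(size=(2, 15))
        scores = rng.normal(size=(30, 2))
        X = pd.DataFrame(scores @ basis)
        sel = select_pca_features(X, 0.95, block_id="T")
        assert sel.k == 2
        assert sel.transform(X).shape == (30, 2)

    def test_pca_target_one_gives_rank(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 4)))
        sel = select_pca_features(X, 1.0)
        assert sel.k == 4

    def test_pca_isotropic_needs_nearly_all_components(self, rng):
        """An isotropic 10-D Gaussian spreads variance evenly, so a 95%
        target keeps k=10 at large n (eigenvalues nearly equal)."""
        X = pd.DataFrame(rng.normal(size=(4000, 10)))
        sel = select_pca_features(X, 0.95)
        assert sel.k == 10

    def test_plsda_tiny_target_one_lv(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 8)))
        y = np.array(["A", "B"] * 10)
        sel = select_plsda_features(X, y, variance_target=1e-6)
        assert sel.k == 1

    def test_plsda_lv1_tracks_a_strong_class_direction(self, rng):
        # a 6σ shift on one axis caps the point-biserial correlation of the
        # ideal direction at 3/√10 ≈ 0.95; LV1 should come close
        y = np.array(["A"] * 30 + ["B"] * 30)
        X = rng.normal(size=(60, 10))
        X[:, 0] += np.where(y == "B", 6.0, 0.0)
        sel = select_plsda_features(pd.DataFrame(X), y, variance_target=0.5)
        lv1 = sel.transform(pd.DataFrame(X)).iloc[:, 0]
        r = np.corrcoef(lv1, (y == "B").astype(float))[0, 1]
        assert abs(r) > 0.9

    def test_plsda_single_class_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError, match="two classes"):
            select_plsda_features(X, np.array(["A"] * 10))

    def test_importance_full_budget_is_permutation(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 12)), columns=[f"f{i}" for i in range(12)])
        y = np.array(["A", "B"] * 15)
        ranked = select_importance_features(X, y, "RF", budget=12, seed=0)
        assert sorted(r.feature_id for r in ranked) == sorted(X.columns)
        assert [r.rank for r in ranked] == list(range(1, 13))

    def test_perfect_feature_ranks_first(self, rng):
        y = np.array(["A"] * 20 + ["B"] * 20)
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(40, 30)), columns=[f"f{i}" for i in range(30)])
            X["f7"] = np.where(y == "B", 5.0, -5.0) + r.normal(0, 0.1, 40)
            ranked = select_importance_features(X, y, "RF", budget=5, seed=seed)
            hits += ranked[0].feature_id == "f7"
        assert hits >= 9

    def test_rf_importances_sum_to_one(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 10)))
        y = np.array(["A", "B"] * 15)
        ranked = select_importance_features(X, y, "RF", budget=10, seed=1)
        assert np.isclose(sum(r.raw_importance for r in ranked), 1.0, atol=1e-9)

    def test_budget_capped_with_warning(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 4)))
        y = np.array(["A", "B"] * 10)
        with pytest.warns(UserWarning, match="capped"):
            ranked = select_importance_features(X, y, "DT", budget=40, seed=0)
        assert len(ranked) == 4


class TestClassifiers:
    def test_all_seven_fit_a_separable_toy(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(np.vstack([rng.normal(-3, 0.3, (15, 2)), rng.normal(3, 0.3, (15, 2))]))
        y = np.array(["A"] * 15 + ["B"] * 15)
        for name in ("PCA", "PLSDA", "SVM", "KNN", "NN", "DT", "RF"):
            m = train_classifier(X, y, name, seed=0)
            assert (m.predict(X.to_numpy()) == y).mean() == 1.0, name

    def test_knn_unanimous_neighbourhood(self):
        X = pd.DataFrame([[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]])
        y = np.array(["A", "A", "A", "B", "B", "B"])
        m = train_classifier(X, y, "KNN")
        assert m.predict([[0.05]])[0] == "A"

    def test_non_finite_rejected(self):
        X = pd.DataFrame([[1.0], [np.nan]])
        with pytest.raises(ValueError, match="finite"):
            train_classifier(X, np.array(["A", "B"]), "RF")

    def test_single_class_rejected(self):
        X = pd.DataFrame([[1.0], [2.0]])
        with pytest.raises(ValueError, match="two classes"):
            train_classifier(X, np.array(["A", "A"]), "SVM")


class TestMLDF:
    def test_rf_selector_over_four_blocks_gives_width_160(self):
        tr, te, ytr, yte, _ = standardized_training_data()
        fm = mldf_fuse(tr, ytr, "RF_top40", "RF", FusionConfig(seed=0))
        assert fm.fuse(tr).shape == (49, 160)
        assert fm.name == "RF–RF"

    def test_pca_selector_width_is_sum_of_ks(self, rng):
        idx = [f"s{i}" for i in range(30)]
        y = np.array(["A", "B"] * 15)
        blocks = {}
        for p in ("X1", "X2"):
            basis = rng.normal(size=(2, 9))
            blocks[p] = pd.DataFrame(rng.normal(size=(30, 2)) @ basis, index=idx)
        fm = mldf_fuse(blocks, y, "PCA_95", "KNN", FusionConfig(seed=0))
        assert fm.fuse(blocks).shape[1] == 4  # two rank-2 blocks → 2 + 2

    def test_score_selector_has_no_traceable_ranking(self, rng):
        idx = [f"s{i}" for i in range(20)]
        y = np.array(["A", "B"] * 10)
        blocks = {p: pd.DataFrame(rng.normal(size=(20, 6)), index=idx) for p in ("X1", "X2")}
        fm = mldf_fuse(blocks, y, "PCA_95", "RF", FusionConfig(seed=0))
        with pytest.raises(ValueError, match="score-based"):
            fm.ranked_features()

    def test_fewer_than_two_blocks_rejected(self, rng):
        X = {"only": pd.DataFrame(rng.normal(size=(10, 4)))}
        with pytest.raises(ValueError, match="two blocks"):
            mldf_fuse(X, np.array(["A", "B"] * 5), "RF_top40", "RF")


class TestHLDF:
    def test_pool_and_final_budget_arithmetic(self):
        tr, te, ytr, yte, _ = standardized_training_data()
        res = hldf_gini_fusion(tr, ytr, FusionConfig(seed=0))
        assert len(res.merged) == 160  # 4 blocks × top-40 merged
        assert len(res.selected) == 40
        assert res.model.n_features_in_ == 40
        assert res.weight == 0.25

    def test_fused_importances_bounded(self):
        tr, _, ytr, _, _ = standardized_training_data()
        res = hldf_gini_fusion(tr, ytr, FusionConfig(seed=1))
        assert all(0.0 <= r.fused_importance <= res.weight + 1e-12 for r in res.merged)
        assert sum(r.fused_importance for r in res.merged) <= 1.0 + 1e-9

    def test_within_block_order_preserved_by_weighting(self):
        tr, _, ytr, _, _ = standardized_training_data()
        res = hldf_gini_fusion(tr, ytr, FusionConfig(seed=2))
        for plat in tr:
            sub = [r for r in res.merged if r.block_id == plat]
            raws = [r.raw_importance for r in sub]
            assert raws == sorted(raws, reverse=True)

    def test_merged_ranking_equals_brute_force_reimplementation(self):
        """Oracle equivalence on a 2-block toy: explicitly fit, sort,
        multiply and merge with plain scikit-learn calls."""
        rng = np.random.default_rng(9)
        idx = [f"s{i}" for i in range(40)]
        y = np.array(["A", "B"] * 20)
        blocks = {
            "P1": pd.DataFrame(rng.normal(size=(40, 6)), index=idx,
                               columns=[f"a{i}" for i in range(6)]),
            "P2": pd.DataFrame(rng.normal(size=(40, 6)), index=idx,
                               columns=[f"b{i}" for i in range(6)]),
        }
        blocks["P1"]["a2"] += np.where(y == "B", 2.0, 0.0)
        blocks["P2"]["b4"] += np.where(y == "B", 1.5, 0.0)
        cfg = FusionConfig(seed=5, hldf_budgets=(4, 3), hldf_final_budget=4)
        res = hldf_gini_fusion(blocks, y, cfg)

        # brute force: same RNG streams, independent ranking logic
        weight = 0.5
        pool = []
        for bi, (plat, df) in enumerate(blocks.items()):
            rf1 = RandomForestClassifier(
                n_estimators=100, criterion="gini", oob_score=True,
                random_state=child_seed(cfg.seed, f"hldf:{plat}:stage1"),
            ).fit(df.to_numpy(), y)
            imp1 = rf1.feature_importances_
            top1 = sorted(range(6), key=lambda j: (-imp1[j], j))[:4]
            cols = [df.columns[j] for j in top1]
            rf2 = RandomForestClassifier(
                n_estimators=100, criterion="gini", oob_score=True,
                random_state=child_seed(cfg.seed, f"hldf:{plat}:stage2"),
            ).fit(df[cols].to_numpy(), y)
            imp2 = rf2.feature_importances_
            top2 = sorted(range(4), key=lambda j: (-imp2[j], j))[:3]
            for j in top2:
                col = cols[j]
                pool.append((plat, col, imp2[j], weight * imp2[j],
                             bi, list(df.columns).index(col)))
        pool.sort(key=lambda t: (-t[3], t[4], t[5]))
        assert [(r.block_id, r.feature_id) for r in res.merged] == [
            (p, c) for p, c, *_ in pool
        ]
        assert np.allclose([r.fused_importance for r in res.merged], [t[3] for t in pool])

    def test_single_block_signal_tops_the_merged_ranking(self):
        """With all planted signal in one block, the planted variables
        dominate the head of the merged ranking and land in the final 40.

        Note the block *share* of the final selection stays roughly even:
        Gini importances are normalized per forest, so a pure-noise
        block's refit importances average 1/budget — the equal 0.25
        weighting cannot down-rank an uninformative block wholesale.
        """
        recovered, head = [], []
        for seed in range(7):
            spec = SyntheticSpec(
                seed=seed,
                groups=[("YN", 25), ("GX", 25)],
                blocks=[
                    BlockSpec("LCMS", n_features=130, n_informative=10, effect_size=2.5),
                    BlockSpec("GCMS", n_features=130, n_informative=0),
                    BlockSpec("NMR", n_features=130, n_informative=0),
                    BlockSpec("MIR", n_features=130, n_informative=0),
                ],
            )
            study = generate_study(spec)
            man = study.manifest
            zb = {p: zscore_block(b, man.model_ids)[0] for p, b in study.tabular.items()}
            y = man.groups.loc[man.model_ids].to_numpy()
            tr = {p: b.data.loc[man.model_ids] for p, b in zb.items()}
            res = hldf_gini_fusion(tr, y, FusionConfig(seed=seed))
            planted = {("LCMS", f) for f in study.truth["blocks"]["LCMS"]["informative"]}
            selected = {(r.block_id, r.feature_id) for r in res.selected}
            recovered.append(len(planted & selected) / len(planted))
            head.append(
                sum(1 for r in res.merged[:10] if (r.block_id, r.feature_id) in planted)
            )
        assert np.median(recovered) >= 0.9  # planted variables reach the final 40
        assert np.median(head) >= 7  # and occupy the top of the merged ranking

    def test_stage1_capped_for_narrow_blocks(self, rng):
        idx = [f"s{i}" for i in range(20)]
        y = np.array(["A", "B"] * 10)
        blocks = {p: pd.DataFrame(rng.normal(size=(20, 8)), index=idx) for p in ("X1", "X2")}
        with pytest.warns(UserWarning, match="capped"):
            res = hldf_gini_fusion(blocks, y, FusionConfig(seed=0))
        assert len(res.merged) == 16

    def test_end_to_end_determinism(self):
        tr, te, ytr, yte, _ = standardized_training_data()
        a = hldf_gini_fusion(tr, ytr, FusionConfig(seed=4))
        b = hldf_gini_fusion(tr, ytr, FusionConfig(seed=4))
        assert [(r.block_id, r.feature_id, r.rank) for r in a.merged] == [
            (r.block_id, r.feature_id, r.rank) for r in b.merged
        ]
        assert np.array_equal(a.predict(te), b.predict(te))


class TestConfig:
    def test_invalid_budgets_rejected(self):
        with pytest.raises(ValueError):
            FusionConfig(hldf_budgets=(40, 120))
        with pytest.raises(ValueError):
            FusionConfig(train_fraction=1.2)
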