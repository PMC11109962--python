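"""Feature assembly, splits, forest training/selection, and evaluation."""

import numpy as np
import pandas as pd
import pytest

from notchdyn.annotation import SiteAnnotation
from notchdyn.consensus import ConsensusSite
from notchdyn.dynamics import BindingDynamics
from notchdyn.genomic_io import GenomicInterval
from notchdyn.model import (
    SplitSpec,
    build_feature_table,
    encode_features,
    error_report,
    evaluate,
    predict,
    split_data,
    train_and_select,
)
from notchdyn.motifs import SiteMotifFlags


def _consensus(site_id, norm):
    return ConsensusSite(
        interval=GenomicInterval("chr1", 0, 100),
        support=3,
        combined_p=1e-8,
        norm_score=norm,
        site_id=site_id,
    )


def _inputs(n, rng):
    """n sites with label-correlated norm_p, category, and motifs."""
    sites, anns, flags, labels = [], [], [], []
    for i in range(n):
        sid = f"s{i:04d}"
        dynamic = rng.random() < 0.3
        norm = float(np.clip(rng.normal(0.7 if dynamic else 0.3, 0.15), 0, 1))
        category = (
            "intergenic" if (dynamic and rng.random() < 0.8) or rng.random() < 0.3
            else "promoter"
        )
        sites.append(_consensus(sid, norm))
        anns.append(SiteAnnotation(sid, category, "g0", 100))
        canonical = rng.random() < (0.6 if dynamic else 0.15)
        flags.append(
            SiteMotifFlags(
                sid,
                has_sp1=rng.random() < (0.05 if dynamic else 0.5),
                has_rbpj_canonical=canonical,
                has_rbpj_degenerate=canonical
                or rng.random() < (0.3 if dynamic else 0.1),
                has_dimer=False,
            )
        )
        labels.append(
            BindingDynamics(sid, 1, 1, 0, "dynamic" if dynamic else "static")
        )
    return sites, anns, flags, labels


class TestBuildFeatureTable:
    def test_row_assembly(self):
        sites = [_consensus("s1", 0.9)]
        anns = [SiteAnnotation("s1", "gene_body", "g1", 20_000)]
        flags = [SiteMotifFlags("s1", False, True, True, False)]
        labels = [BindingDynamics("s1", 10, 5, -1.0, "dynamic")]
        table = build_feature_table(sites, anns, flags, labels)
        row = table.loc["s1"]
        assert row["norm_p"] == 0.9
        assert row["category"] == "gene_body"
        assert (row["has_sp1"], row["has_rbpj_canonical"],
                row["has_rbpj_degenerate"]) == (False, True, True)
        assert row["label"] == "dynamic"

    def test_unlabeled_table_has_no_label_column(self):
        sites = [_consensus("s1", 0.5)]
        anns = [SiteAnnotation("s1", "promoter", "g1", 10)]
        flags = [SiteMotifFlags("s1", True, False, False, False)]
        table = build_feature_table(sites, anns, flags)
        assert "label" not in table.columns

    def test_duplicate_site_id_rejected(self):
        sites = [_consensus("s1", 0.5), _consensus("s1", 0.6)]
        anns = [SiteAnnotation("s1", "promoter", "g1", 10)]
        flags = [SiteMotifFlags("s1", True, False, False, False)]
        with pytest.raises(ValueError, match="duplicated"):
            build_feature_table(sites, anns, flags)

    def test_key_mismatch_names_offenders(self):
        sites = [_consensus("s1", 0.5)]
        anns = [SiteAnnotation("s2", "promoter", "g1", 10)]
        flags = [SiteMotifFlags("s1", True, False, False, False)]
        with pytest.raises(ValueError, match="s2"):
            build_feature_table(sites, anns, flags)


class TestSplitData:
    def _table(self, n=1000):
        rng = np.random.default_rng(0)
        sites, anns, flags, labels = _inputs(n, rng)
        return build_feature_table(sites, anns, flags, labels)

    def test_split_sizes(self):
        table = self._table(1000)
        train, val, test = split_data(table, SplitSpec(seed=0))
        assert abs(len(test) - 150) <= 1
        assert abs(len(val) - 170) <= 1
        assert abs(len(train) - 680) <= 1
        ids = set(train.index) | set(val.index) | set(test.index)
        assert len(ids) == 1000

    def test_same_seed_same_partition(self):
        table = self._table(200)
        a = split_data(table, SplitSpec(seed=3))
        b = split_data(table, SplitSpec(seed=3))
        for x, y in zip(a, b):
            assert list(x.index) == list(y.index)

    def test_stratified_by_label(self):
        table = self._table(1000)
        frac = (table["label"] == "dynamic").mean()
        _, val, test = split_data(table, SplitSpec(seed=1))
        for part in (val, test):
            assert abs((part["label"] == "dynamic").mean() - frac) < 0.02

    def test_single_class_rejected(self):
        table = self._table(100)
        table["label"] = "static"
        with pytest.raises(ValueError):
            split_data(table, SplitSpec(seed=0))


class TestTrainSelectPredict:
    def test_separable_features_first_candidate_qualifies(self):
        rng = np.random.default_rng(1)
        sites, anns, flags, labels = _inputs(300, rng)
        # make the classes perfectly separable on norm_p
        table = build_feature_table(sites, anns, flags, labels)
        table["norm_p"] = np.where(table["label"] == "dynamic", 0.9, 0.1)
        train, val, _ = split_data(table, SplitSpec(seed=0))
        model = train_and_select(train, val, n_candidates=3, seed_base=0,
                                 n_trees=100)
        assert model.qualified
        assert model.seed == 0
        assert model.validation_metrics["accuracy"] == 1.0

    def test_permuted_labels_never_qualify(self):
        rng = np.random.default_rng(2)
        sites, anns, flags, labels = _inputs(400, rng)
        table = build_feature_table(sites, anns, flags, labels)
        table["label"] = rng.permutation(table["label"].values)
        train, val, _ = split_data(table, SplitSpec(seed=0))
        model = train_and_select(train, val, n_candidates=3, seed_base=0,
                                 n_trees=100)
        assert not model.qualified

    def test_predictions_align_and_probabilities_are_complementary(self):
        rng = np.random.default_rng(3)
        sites, anns, flags, labels = _inputs(200, rng)
        table = build_feature_table(sites, anns, flags, labels)
        train, val, test = split_data(table, SplitSpec(seed=0))
        model = train_and_select(train, val, n_candidates=1, seed_base=0,
                                 n_trees=100)
        preds = predict(model, test)
        assert len(preds) == len(test)
        assert list(preds.index) == list(test.index)
        assert ((preds["p_dynamic"] >= 0) & (preds["p_dynamic"] <= 1)).all()
        assert (
            (preds["predicted"] == "dynamic") == (preds["p_dynamic"] >= 0.5)
        ).all()

    def test_deterministic_given_seeds(self):
        rng = np.random.default_rng(4)
        sites, anns, flags, labels = _inputs(200, rng)
        table = build_feature_table(sites, anns, flags, labels)
        outs = []
        for _ in range(2):
            train, val, test = split_data(table, SplitSpec(seed=5))
            model = train_and_select(train, val, n_candidates=2, seed_base=5,
                                     n_trees=100)
            outs.append(predict(model, test)["p_dynamic"].values)
        assert np.array_equal(outs[0], outs[1])


class TestEvaluate:
    def test_accuracy_is_correct_over_total(self):
        idx = [f"s{i}" for i in range(10)]
        truth = pd.Series(["dynamic"] * 5 + ["static"] * 5, index=idx)
        pred = truth.copy()
        pred.iloc[0] = "static"
        pred.iloc[5] = "dynamic"
        scores = pd.Series(np.linspace(1, 0, 10), index=idx)
        m = evaluate(pred, scores, truth)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["tpr_dynamic"] == pytest.approx(0.8)
        assert m["tpr_static"] == pytest.approx(0.8)

    def test_auc_by_pair_counting(self):
        idx = list("abcd")
        truth = pd.Series(["dynamic", "static", "dynamic", "static"], index=idx)
        scores = pd.Series([0.9, 0.8, 0.4, 0.2], index=idx)
        pred = pd.Series(
            np.where(scores >= 0.5, "dynamic", "static"), index=idx
        )
        assert evaluate(pred, scores, truth)["auc"] == pytest.approx(0.75)

    def test_perfect_ranking(self):
        idx = list("abcd")
        truth = pd.Series(["dynamic", "dynamic", "static", "static"], index=idx)
        scores = pd.Series([0.9, 0.8, 0.4, 0.2], index=idx)
        pred = pd.Series(["dynamic"] * 2 + ["static"] * 2, index=idx)
        assert evaluate(pred, scores, truth)["auc"] == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate(pd.Series(dtype=object), pd.Series(dtype=float),
                     pd.Series(dtype=object))


class TestFeatureAblation:
    def test_motif_and_strength_features_carry_signal(self):
        """Dropping norm_p and the motif flags lowers validation AUC."""
        full_aucs, reduced_aucs = [], []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            sites, anns, flags, labels = _inputs(500, rng)
            table = build_feature_table(sites, anns, flags, labels)
            train, val, _ = split_data(table, SplitSpec(seed=seed))
            from notchdyn.model import evaluate_forest, _fit_forest

            forest = _fit_forest(train, seed, 100, "balanced")
            full_aucs.append(evaluate_forest(forest, val)["auc"])
            reduced = table.copy()
            reduced["norm_p"] = 0.0
            for col in ("has_sp1", "has_rbpj_canonical", "has_rbpj_degenerate"):
                reduced[col] = False
            rtrain, rval, _ = split_data(reduced, SplitSpec(seed=seed))
            rforest = _fit_forest(rtrain, seed, 100, "balanced")
            reduced_aucs.append(evaluate_forest(rforest, rval)["auc"])
        assert np.mean(full_aucs) > np.mean(reduced_aucs)


class TestErrorReport:
    def test_both_error_directions_present_with_categories(self):
        # mixed placement: the position feature is deliberately uninformative,
        # so misclassifications of both directions land in intergenic space
        rng = np.random.default_rng(6)
        sites, anns, flags, labels = _inputs(600, rng)
        for ann in anns:
            ann.category = "intergenic" if rng.random() < 0.5 else "promoter"
        table = build_feature_table(sites, anns, flags, labels)
        train, val, test = split_data(table, SplitSpec(seed=0))
        model = train_and_select(train, val, n_candidates=1, seed_base=0,
                                 n_trees=100)
        preds = predict(model, test)
        report = error_report(preds, test)
        assert set(report.columns) == {"truth", "predicted", "category"}
        # overlapping feature distributions guarantee both error directions
        assert {"dynamic", "static"} <= set(report["truth"])
        assert "intergenic" in set(report["category"])
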