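import numpy as np
import pandas as pd
import pytest

from mqtrans.detection import (
    DarkBiomarkerSet,
    classify_dark,
    detect_dark,
    intersect_dark,
    robustness_overlap_table,
    robustness_scan,
    unpaired_ttest,
    venn_counts,
)
from mqtrans.io_cohort import Label, SampleAnnotation
from mqtrans.regression import (
    compute_mqtrans,
    filter_models,
    fit_gene_models,
    split_train_test,
)
from mqtrans.synthetic import gene_feature_id, tf_feature_id


class TestUnpairedTtest:
    def test_toy_vectors_match_pooled_closed_form(self):
        t, p = unpaired_ttest([1, 2, 3], [4, 5, 6])
        # pooled variance 1, se = sqrt(2/3), df = 4
        assert t == pytest.approx(-3.6742, abs=5e-5)
        assert p == pytest.approx(0.0214, abs=5e-4)

    def test_identical_groups(self):
        assert unpaired_ttest([2.0, 3.0, 4.0], [2.0, 3.0, 4.0]) == (
            pytest.approx(0.0),
            pytest.approx(1.0),
        )

    def test_within_group_permutation_invariance(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=6)
        base = unpaired_ttest(a, b)
        shuffled = unpaired_ttest(rng.permutation(a), rng.permutation(b))
        assert shuffled == (pytest.approx(base[0]), pytest.approx(base[1]))

    def test_both_constant_equal_is_null(self):
        assert unpaired_ttest([5.0, 5.0], [5.0, 5.0]) == (0.0, 1.0)

    def test_both_constant_unequal_is_zero_p_limit(self):
        t, p = unpaired_ttest([5.0, 5.0], [4.0, 4.0])
        assert p == 0.0 and t == np.inf

    def test_welch_differs_under_unequal_variances(self, rng):
        a = rng.normal(0, 5, size=20)
        b = rng.normal(0, 0.5, size=5)
        t_pooled, _ = unpaired_ttest(a, b, equal_var=True)
        t_welch, _ = unpaired_ttest(a, b, equal_var=False)
        assert t_pooled != t_welch

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            unpaired_ttest([1.0], [2.0, 3.0])


class TestClassifyDark:
    def test_reported_worked_example_is_dark(self):
        assert classify_dark(0.7722, 0.0022) is True

    def test_expression_significant_is_not_dark(self):
        assert classify_dark(0.01, 0.01) is False

    def test_mq_nonsignificant_is_not_dark(self):
        assert classify_dark(0.50, 0.50) is False

    def test_thresholds_are_strict(self):
        assert classify_dark(0.05, 0.01) is False
        assert classify_dark(0.50, 0.05) is False

    def test_missing_p_is_not_dark(self):
        assert classify_dark(None, 0.01) is False
        assert classify_dark(0.5, float("nan")) is False


def cohort_pipeline(matrix, annotations, n_tf, n_genes, seed, fraction=0.6,
                    n_predictors=10):
    """Train on the primary split and return the dual-space table + test IDs."""
    train, test = split_train_test(annotations, fraction, seed)
    tfs = [tf_feature_id(i) for i in range(n_tf)]
    genes = [gene_feature_id(i) for i in range(n_genes)]
    models = filter_models(
        fit_gene_models(matrix[train], tfs, genes, n_predictors=n_predictors)
    )
    mq = compute_mqtrans(models, matrix[test])
    return detect_dark(matrix[test], mq, annotations), train, test


class TestDetectDark:
    def test_injected_dark_genes_are_found(self, small_cohort, small_config):
        matrix, annotations, truth = small_cohort
        program, spec = small_config
        table, _, _ = cohort_pipeline(matrix, annotations, program.n_tf,
                                      spec.n_genes, seed=7)
        table["cls"] = table["feature"].map(truth.gene_class)
        dark = table[table.cls == "dark"]
        assert dark.is_dark.mean() > 0.5  # small cohort, most still recovered

    def test_dark_never_overlaps_expression_significant(self, small_cohort,
                                                        small_config):
        matrix, annotations, _ = small_cohort
        program, spec = small_config
        table, _, _ = cohort_pipeline(matrix, annotations, program.n_tf,
                                      spec.n_genes, seed=7)
        assert not ((table.p_orig <= 0.05) & table.is_dark).any()

    def test_no_metastatic_group_rejected(self, small_cohort):
        matrix, annotations, _ = small_cohort
        primary_only = [a for a in annotations if a.label is Label.PRIMARY]
        mq = matrix.iloc[:5]
        with pytest.raises(ValueError, match="metastatic"):
            detect_dark(matrix, mq, primary_only)

    def test_degenerate_feature_gets_reason_not_error(self, small_cohort):
        matrix, annotations, _ = small_cohort
        m = matrix.copy()
        m.iloc[0] = 5.0  # constant row in expression space
        mq = m.iloc[:3].copy()
        table = detect_dark(m, mq, annotations)
        row = table.iloc[0]
        assert not row.is_dark
        assert "constant" in row.reason


class TestIntersectDark:
    @staticmethod
    def dbs(name, feats):
        return DarkBiomarkerSet(name, set(feats))

    def test_basic_set_algebra(self):
        sets = [self.dbs("d1", "ABC"), self.dbs("d2", "BC"), self.dbs("d3", "C")]
        assert intersect_dark(sets) == {"C"}

    def test_idempotent_on_identical_sets(self):
        sets = [self.dbs("d1", "XY"), self.dbs("d2", "XY")]
        assert intersect_dark(sets) == {"X", "Y"}

    def test_empty_set_absorbs(self):
        assert intersect_dark([self.dbs("d1", "AB"), self.dbs("d2", "")]) == set()

    def test_monotone_adding_datasets(self, rng):
        universe = [f"g{i}" for i in range(30)]
        sets = [
            self.dbs(f"d{j}", rng.choice(universe, size=15, replace=False))
            for j in range(4)
        ]
        for k in range(2, 5):
            assert intersect_dark(sets[:k]) <= intersect_dark(sets[: k - 1])

    def test_venn_counts_layout(self):
        df = venn_counts([self.dbs("d1", "AB"), self.dbs("d2", "B")])
        assert list(df["set"]) == ["d1", "d2", "intersection"]
        assert list(df["n_dark"]) == [2, 1, 1]


class TestRobustnessScan:
    def scan(self, small_cohort, small_config, fractions, seed=7):
        matrix, annotations, _ = small_cohort
        program, spec = small_config
        train, test = split_train_test(annotations, 0.6, seed)
        tfs = [tf_feature_id(i) for i in range(program.n_tf)]
        genes = [gene_feature_id(i) for i in range(spec.n_genes)]
        return (
            robustness_scan(
                matrix, annotations, tfs, genes,
                train_pool=train, fixed_test=test,
                fractions=fractions, seed=seed, main_fraction=0.6,
                n_predictors=10,
            ),
            train,
            test,
        )

    def test_identity_fraction_reproduces_main_run(self, small_cohort, small_config):
        matrix, annotations, _ = small_cohort
        program, spec = small_config
        table, train, test = cohort_pipeline(
            matrix, annotations, program.n_tf, spec.n_genes, seed=7
        )
        main_dark = set(table.loc[table.is_dark, "feature"])
        scans, _, _ = self.scan(small_cohort, small_config, [0.6])
        assert scans[0.6].features == main_dark

    def test_reduced_fractions_reported_with_overlap(self, small_cohort, small_config):
        scans, _, _ = self.scan(small_cohort, small_config, [0.5, 0.4, 0.2])
        assert set(scans) == {0.5, 0.4, 0.2}
        main = DarkBiomarkerSet("main", scans[0.5].features)
        tab = robustness_overlap_table(main, scans)
        assert list(tab.columns) == ["fraction", "n_dark", "n_overlap_main"]
        assert len(tab) == 4  # main + three fractions
        assert (tab.n_overlap_main <= tab.n_dark).all()

    def test_fraction_above_main_rejected(self, small_cohort, small_config):
        with pytest.raises(ValueError, match="exceeds"):
            self.scan(small_cohort, small_config, [0.7])

    def test_empty_fraction_list_gives_empty_map(self, small_cohort, small_config):
        scans, _, _ = self.scan(small_cohort, small_config, [])
        assert scans == {}

    def test_overlapping_pool_and_test_rejected(self, small_cohort, small_config):
        matrix, annotations, _ = small_cohort
        program, spec = small_config
        train, test = split_train_test(annotations, 0.6, seed=7)
        with pytest.raises(ValueError, match="disjoint"):
            robustness_scan(
                matrix, annotations,
                [tf_feature_id(i) for i in range(program.n_tf)],
                [gene_feature_id(i) for i in range(spec.n_genes)],
                train_pool=train, fixed_test=train[:1] + test,
                fractions=[0.5], seed=7,
            )
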