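"""Correlation pruning, permutation importance, and nested forward selection."""

import numpy as np
import pandas as pd
import pytest

from raaindex.aaindex import RESIDUES, IndexTable, to_property_indices
from raaindex.errors import DegenerateLabelsError, EmptySelectionError
from raaindex.reduction import (
    HydropathyLabels,
    RFConfig,
    filter_by_mean_vim,
    nested_selection,
    permutation_vim,
    prune_correlated,
    reduce_pipeline,
    single_tree_vim,
)

from conftest import make_random_table

LABELS = HydropathyLabels.kyte_doolittle()


def separator_column(labels: HydropathyLabels = LABELS) -> np.ndarray:
    """A property that separates the two hydropathy classes perfectly."""
    return labels.as_array().astype(float)


def table_from_columns(**cols) -> IndexTable:
    return IndexTable(pd.DataFrame(cols, index=list(RESIDUES)))


class TestHydropathyLabels:
    def test_default_scheme_is_kyte_doolittle_dichotomy(self):
        hydrophobic = {r for r, c in LABELS.labels.items() if c == "hydrophobic"}
        assert hydrophobic == set("ACFILMV")
        assert LABELS.scheme_name == "kyte-doolittle"

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            HydropathyLabels({r: "hydrophobic" for r in RESIDUES})


class TestPruneCorrelated:
    def test_duplicate_column_removed(self, rng):
        x = rng.normal(size=20)
        table = table_from_columns(AAA=x, BBB=x.copy(), CCC=rng.normal(size=20))
        pruned, log = prune_correlated(table)
        assert pruned.n_properties == 2
        assert len(log) == 1
        assert log[0]["abs_r"] == pytest.approx(1.0)
        assert "CCC" in pruned.properties

    def test_uncorrelated_table_untouched(self, rng):
        table = make_random_table(rng, m=5)
        if table.to_frame().corr().abs().to_numpy().max() < 2:  # always true; clarity
            pruned, log = prune_correlated(table, threshold=0.999)
        assert pruned.properties == table.properties
        assert log == []

    @pytest.mark.parametrize("seed", range(10))
    def test_output_max_correlation_bounded(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(20, 10))
        # correlated block: noisy copies of the first few columns
        extra = base[:, :10] + rng.normal(scale=0.3, size=(20, 10))
        mat = np.hstack([base, extra, rng.normal(size=(20, 10))])
        table = IndexTable(
            pd.DataFrame(mat, index=list(RESIDUES), columns=[f"C{j:02d}" for j in range(30)])
        )
        pruned, _ = prune_correlated(table, threshold=0.85)
        corr = pruned.to_frame().corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.85 + 1e-12

    def test_idempotent(self, rng):
        x = rng.normal(size=20)
        table = table_from_columns(
            AAA=x, BBB=x + rng.normal(scale=0.2, size=20), CCC=rng.normal(size=20)
        )
        once, _ = prune_correlated(table)
        twice, log = prune_correlated(once)
        assert twice.properties == once.properties
        assert log == []

    def test_threshold_validated(self, rng):
        table = make_random_table(rng, m=3)
        with pytest.raises(ValueError):
            prune_correlated(table, threshold=0.0)
        with pytest.raises(ValueError):
            prune_correlated(table, threshold=1.5)


class TestSingleTreeVIM:
    """Exact oracle for the importance formula on a six-sample toy.

    Feature 0 equals the class label; feature 1 is irrelevant.  With in-bag
    samples {0, 1, 3} the fitted tree is the perfect single split on feature
    0, so every prediction is known analytically and the permuted-minus-intact
    OOB misclassification difference can be counted by hand.
    """

    X = np.array(
        [[0, 5.0], [0, 1.0], [0, 4.0], [1, 2.0], [1, 3.0], [1, 6.0]], dtype=float
    )
    y = np.array([0, 0, 0, 1, 1, 1])
    in_bag = np.array([0, 1, 3, 0, 1, 3])  # OOB = {2, 4, 5}

    def test_permuting_the_separating_feature_counts_two_errors(self):
        # OOB feature-0 values (0, 1, 1) rearranged by permutation (1, 2, 0)
        # become (1, 1, 0): predictions (1, 1, 0) vs labels (0, 1, 1) -> 2
        # errors; unpermuted predictions are perfect -> difference is 2.
        vim = single_tree_vim(
            self.X, self.y, self.in_bag, column=0, permutation=[1, 2, 0]
        )
        assert vim == 2

    def test_permuting_the_irrelevant_feature_changes_nothing(self):
        vim = single_tree_vim(
            self.X, self.y, self.in_bag, column=1, permutation=[2, 0, 1]
        )
        assert vim == 0

    def test_identity_permutation_scores_zero(self):
        assert (
            single_tree_vim(self.X, self.y, self.in_bag, column=0, permutation=[0, 1, 2])
            == 0
        )


class TestPermutationVIM:
    def test_constant_property_scores_exactly_zero(self, rng):
        table = table_from_columns(
            SEP=separator_column(), CONST=np.full(20, 3.14), NSE=rng.normal(size=20)
        )
        report = permutation_vim(table, LABELS, RFConfig(ntree=20, n_trials=5, seed=0))
        assert (report.trials["CONST"] == 0).all()

    def test_separator_outranks_noise_across_seeds(self):
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            table = table_from_columns(
                SEP=separator_column(),
                NSE0=rng.normal(size=20),
                NSE1=rng.normal(size=20),
                NSE2=rng.normal(size=20),
            )
            report = permutation_vim(table, LABELS, RFConfig(ntree=10, n_trials=5, seed=seed))
            hits += int(report.summary.index[0] == "SEP")
        assert hits >= 0.95 * n_seeds

    def test_deterministic_under_same_seed(self, rng):
        table = make_random_table(rng, m=6)
        cfg = RFConfig(ntree=15, n_trials=4, seed=42)
        r1 = permutation_vim(table, LABELS, cfg)
        r2 = permutation_vim(table, LABELS, cfg)
        pd.testing.assert_frame_equal(r1.trials, r2.trials)
        pd.testing.assert_frame_equal(r1.summary, r2.summary)

    def test_ranks_are_a_permutation(self, rng):
        table = make_random_table(rng, m=8)
        report = permutation_vim(table, LABELS, RFConfig(ntree=10, n_trials=3, seed=1))
        assert sorted(report.summary["rank"]) == list(range(1, 9))
        assert (report.summary["sd"] >= 0).all()


class TestFilterByMeanVIM:
    def _report_from_trials(self, trials: pd.DataFrame):
        from raaindex.reduction import VIMReport

        return VIMReport(trials=trials, scheme_name="test", config=RFConfig(ntree=1, n_trials=len(trials), seed=0))

    def test_all_negative_means_empty(self):
        trials = pd.DataFrame({"AAA": [-1.0, -2.0], "BBB": [-0.5, -0.1]})
        assert filter_by_mean_vim(self._report_from_trials(trials)) == []

    def test_single_positive_property(self):
        trials = pd.DataFrame({"AAA": [1.0, 2.0], "BBB": [-0.5, -0.1]})
        assert filter_by_mean_vim(self._report_from_trials(trials)) == ["AAA"]

    def test_matches_brute_force_filter_and_sort(self, rng):
        cols = {f"P{j:02d}": rng.normal(size=10) for j in range(12)}
        trials = pd.DataFrame(cols)
        got = filter_by_mean_vim(self._report_from_trials(trials))
        means = trials.mean()
        expected = sorted(
            [c for c in trials.columns if means[c] > 0], key=lambda c: (-means[c], c)
        )
        assert got == expected

    def test_zero_mean_is_dropped(self):
        trials = pd.DataFrame({"AAA": [1.0, -1.0], "BBB": [0.5, 0.5]})
        assert filter_by_mean_vim(self._report_from_trials(trials)) == ["BBB"]


class TestNestedSelection:
    def test_threshold_100_selects_everything(self, rng):
        table = make_random_table(rng, m=4)
        result = nested_selection(
            table.properties, table, LABELS, threshold_pct=100.0,
            trials_per_step=3, config=RFConfig(ntree=10, seed=0),
        )
        assert result.selected == table.properties

    def test_single_separating_property_selected_with_zero_error(self):
        table = table_from_columns(SEP=separator_column())
        result = nested_selection(
            ["SEP"], table, LABELS, threshold_pct=2.0,
            trials_per_step=5, config=RFConfig(ntree=30, seed=0),
        )
        assert result.selected == ["SEP"]
        assert result.mean_step_errors[1] == 0.0

    def test_noise_only_first_step_raises_with_diagnostics(self, rng):
        table = table_from_columns(NSE=rng.normal(size=20))
        with pytest.raises(EmptySelectionError) as err:
            nested_selection(
                ["NSE"], table, LABELS, threshold_pct=2.0,
                trials_per_step=5, config=RFConfig(ntree=20, seed=0),
            )
        assert err.value.step_errors is not None

    @pytest.mark.parametrize("seed", range(10))
    def test_separator_then_noise_stops_within_threshold(self, seed):
        rng = np.random.default_rng(seed)
        table = table_from_columns(
            SEP=separator_column(),
            NSE0=rng.normal(size=20),
            NSE1=rng.normal(size=20),
            NSE2=rng.normal(size=20),
        )
        result = nested_selection(
            ["SEP", "NSE0", "NSE1", "NSE2"], table, LABELS, threshold_pct=2.0,
            trials_per_step=5, config=RFConfig(ntree=25, seed=seed),
        )
        assert "SEP" in result.selected
        # every accepted prefix stays within the threshold
        for k in range(1, len(result.selected) + 1):
            assert result.mean_step_errors[k] <= 2.0

    def test_selected_is_prefix_of_ranking(self, rng):
        table = make_random_table(rng, m=5)
        ranked = table.properties
        result = nested_selection(
            ranked, table, LABELS, threshold_pct=100.0,
            trials_per_step=2, config=RFConfig(ntree=5, seed=3),
        )
        assert result.selected == ranked[: len(result.selected)]

    def test_raising_threshold_never_shrinks_selection(self, rng):
        table = table_from_columns(
            SEP=separator_column(),
            NSE0=rng.normal(size=20),
            NSE1=rng.normal(size=20),
        )
        sizes = []
        for thr in (5.0, 20.0, 100.0):
            result = nested_selection(
                ["SEP", "NSE0", "NSE1"], table, LABELS, threshold_pct=thr,
                trials_per_step=4, config=RFConfig(ntree=15, seed=7),
            )
            sizes.append(len(result.selected))
        assert sizes == sorted(sizes)

    def test_unknown_accessions_rejected(self, rng):
        table = make_random_table(rng, m=3)
        with pytest.raises(ValueError, match="absent"):
            nested_selection(["NOPE"], table, LABELS)


class TestReducePipeline:
    def test_single_separating_property_is_selected(self):
        table = table_from_columns(SEP=separator_column())
        result = reduce_pipeline(
            to_property_indices(table),
            LABELS,
            RFConfig(ntree=20, n_trials=5, seed=0),
            trials_per_step=5,
        )
        assert result.table.properties == ["SEP"]

    def test_stage_counts_are_consistent(self, rng):
        x = rng.normal(size=20)
        table = table_from_columns(
            SEP=separator_column(),
            DUP0=x,
            DUP1=x.copy(),
            NSE=rng.normal(size=20),
        )
        result = reduce_pipeline(
            to_property_indices(table),
            LABELS,
            RFConfig(ntree=20, n_trials=5, seed=1),
            error_threshold_pct=100.0,
            trials_per_step=3,
        )
        counts = result.report["stage_counts"]
        assert counts["input"] == 4
        assert counts["dropped_na"] + counts["after_na_removal"] == counts["input"]
        assert (
            counts["dropped_correlated"] + counts["after_correlation_pruning"]
            == counts["after_na_removal"]
        )
        assert counts["selected"] <= counts["positive_mean_vim"]
        assert result.report["selected"] == result.nested.selected

    def test_deterministic_end_to_end(self, rng):
        table = make_random_table(rng, m=6)
        indices = to_property_indices(table)
        args = dict(
            labels=LABELS,
            config=RFConfig(ntree=10, n_trials=4, seed=9),
            error_threshold_pct=100.0,
            trials_per_step=2,
        )
        r1 = reduce_pipeline(indices, **args)
        r2 = reduce_pipeline(indices, **args)
        assert r1.report["selected"] == r2.report["selected"]
        pd.testing.assert_frame_equal(r1.vim_report.trials, r2.vim_report.trials)
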