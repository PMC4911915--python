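"""Normalization, contribution decomposition and the rank correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from selhier.datasets import ExpressionDataset
from selhier.hierarchy import (
    HierarchyError,
    exact_spearman_pvalue,
    hierarchy_table,
    normalize_to_reference,
    spearman_hierarchy_correlation,
    total_change_contributions,
)
from selhier.synthetic import make_gene_panel, simulate_dataset


def toy_dataset(gene_means: dict[str, dict[float, float]], n_reps: int = 2) -> ExpressionDataset:
    """Exact-mean dataset: replicates symmetric around the requested mean."""
    rows = []
    for gene, by_cond in gene_means.items():
        for cond, mean in by_cond.items():
            for rep in range(1, n_reps + 1):
                eps = 0.01 * mean * (1 if rep % 2 else -1)
                rows.append(
                    {
                        "gene_id": gene,
                        "selenite_nM": cond,
                        "replicate": rep,
                        "abundance": mean + eps,
                    }
                )
    return ExpressionDataset(pd.DataFrame(rows))


class TestNormalization:
    def test_constant_gene_normalizes_to_one(self):
        ds = toy_dataset({"A": {0.0: 5.0, 40.0: 5.0}})
        out = normalize_to_reference(ds)
        means = out.df.groupby(["gene_id", "selenite_nM"])["normalized"].mean()
        assert np.allclose(means, 1.0)

    def test_threefold_gene_normalizes_to_three(self):
        ds = toy_dataset({"A": {0.0: 2.0, 40.0: 6.0}})
        out = normalize_to_reference(ds)
        assert out.df[out.df.selenite_nM == 40.0]["normalized"].mean() == pytest.approx(3.0)

    def test_idempotent_on_normalized_data(self, dataset):
        once = normalize_to_reference(dataset)
        twice = normalize_to_reference(once)
        pd.testing.assert_series_equal(once.df["normalized"], twice.df["normalized"])

    def test_strong_gene_plateau_in_class_window(self, dataset, panel_truth):
        _, truth = panel_truth
        out = normalize_to_reference(dataset)
        for g in truth.genes:
            if g.class_label != "strong_up":
                continue
            plateau = out.df[
                (out.df.gene_id == g.features.gene_id) & (out.df.selenite_nM == 40.0)
            ]["normalized"].mean()
            assert 2.0 < plateau < 4.0  # class window plus sampling noise

    def test_missing_reference_rejected(self):
        ds = toy_dataset({"A": {5.0: 1.0, 40.0: 2.0}})
        with pytest.raises(HierarchyError):
            normalize_to_reference(ds)


class TestContributions:
    def test_single_gene_gets_full_share(self):
        ds = toy_dataset({"A": {0.0: 1.0, 40.0: 3.0}})
        assert total_change_contributions(ds)["A"] == pytest.approx(1.0)

    def test_equal_increases_split_evenly(self):
        ds = toy_dataset({"A": {0.0: 1.0, 40.0: 2.0}, "B": {0.0: 5.0, 40.0: 6.0}})
        shares = total_change_contributions(ds)
        assert shares["A"] == pytest.approx(0.5)
        assert shares["B"] == pytest.approx(0.5)

    def test_decreasing_gene_contributes_negatively(self, dataset, panel_truth):
        _, truth = panel_truth
        shares = total_change_contributions(dataset)
        assert shares.sum() == pytest.approx(1.0)
        for g in truth.genes:
            if g.class_label == "inverse":
                assert shares[g.features.gene_id] < 0

    def test_invariant_to_common_rescaling(self, dataset):
        shares = total_change_contributions(dataset)
        scaled = ExpressionDataset(dataset.df.assign(abundance=dataset.df.abundance * 7.3))
        pd.testing.assert_series_equal(shares, total_change_contributions(scaled))

    def test_zero_total_change_rejected(self):
        ds = toy_dataset({"A": {0.0: 1.0, 40.0: 2.0}, "B": {0.0: 2.0, 40.0: 1.0}})
        with pytest.raises(HierarchyError):
            total_change_contributions(ds)


class TestHierarchyTable:
    def test_ranks_are_permutations(self, dataset):
        table = hierarchy_table(dataset)
        n = len(table)
        for col in ("abundance_rank", "hierarchy_rank"):
            assert sorted(table[col]) == list(range(1, n + 1))

    def test_ratio_column_matches_means(self, dataset):
        table = hierarchy_table(dataset).set_index("gene_id")
        means = dataset.df.groupby(["gene_id", "selenite_nM"])["abundance"].mean()
        for gene in table.index:
            assert table.loc[gene, "ratio_high_low"] == pytest.approx(
                means[gene][40.0] / means[gene][0.0]
            )


class TestSpearman:
    def test_identical_rankings_give_unit_rho(self):
        ds = toy_dataset(
            {g: {0.0: 1.0, 10.0: m, 40.0: m} for g, m in zip("ABCDE", [1, 2, 3, 4, 5])}
        )
        rho, p = spearman_hierarchy_correlation(ds)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)  # two one-sided extremes out of 5!

    def test_reversed_rankings_give_minus_one(self):
        ds = toy_dataset(
            {
                g: {0.0: 1.0, 10.0: m, 40.0: 6 - m}
                for g, m in zip("ABCDE", [1.0, 2.0, 3.0, 4.0, 5.0])
            }
        )
        rho, _ = spearman_hierarchy_correlation(ds)
        assert rho == pytest.approx(-1.0)

    def test_exact_pvalue_matches_brute_force_enumeration(self):
        """Independent oracle: recompute the permutation p-value with a plain
        loop over all 5040 orderings using scipy's rho."""
        rng = np.random.default_rng(23)
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        p_fast = exact_spearman_pvalue(x, y)
        observed = abs(sps.spearmanr(x, y).statistic)
        hits = 0
        for perm in itertools.permutations(y):
            if abs(sps.spearmanr(x, perm).statistic) >= observed - 1e-12:
                hits += 1
        assert p_fast == pytest.approx(hits / 5040, abs=1e-12)

    def test_too_few_genes_rejected(self):
        ds = toy_dataset({"A": {0.0: 1, 10.0: 1, 40.0: 1}, "B": {0.0: 1, 10.0: 2, 40.0: 2}})
        with pytest.raises(HierarchyError):
            spearman_hierarchy_correlation(ds)

    def test_independent_class_and_abundance_gives_weak_correlation(self):
        """Class assignment and abundance scale are sampled independently in
        the generator, so the abundance-vs-hierarchy correlation should be
        weak on average over panels (no abundance effect on the hierarchy)."""
        rhos = []
        for seed in range(10):
            _, truth = make_gene_panel(n_genes=7, seed=200 + seed)
            ds = simulate_dataset(truth, n_reps=4, seed=seed)
            rho, _ = spearman_hierarchy_correlation(ds)
            rhos.append(abs(rho))
        assert np.mean(rhos) < 0.55
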