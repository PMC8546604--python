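"""RPKM computation and two-way ANOVA variance partitioning."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cdgscan.expression import (
    CountTable,
    anova_partition,
    log2_transform,
    rpkm,
)
from cdgscan.synth import make_counts


def _table(counts, lengths, conditions):
    return CountTable(
        counts=counts,
        gene_lengths=pd.Series(lengths, index=counts.index),
        library_conditions=pd.Series(conditions, index=counts.columns),
    )


class TestRpkm:
    def test_closed_form_cell(self):
        counts = pd.DataFrame({"lib1": [10]}, index=["g1"])
        table = _table(counts, [1000], {"lib1": "c1"})
        out = rpkm(table, library_totals={"lib1": 1e6})
        assert out.loc["g1", "lib1"] == pytest.approx(10.0)

    def test_zero_count_is_zero_rpkm(self):
        counts = pd.DataFrame({"lib1": [0, 90]}, index=["g1", "g2"])
        table = _table(counts, [500, 2000], {"lib1": "c1"})
        assert rpkm(table).loc["g1", "lib1"] == 0.0

    def test_matches_cellwise_formula_on_random_table(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 5000, size=(100, 6)),
            index=[f"g{i}" for i in range(100)],
            columns=[f"lib{j}" for j in range(6)],
        )
        lengths = rng.integers(200, 8000, size=100)
        table = _table(counts, lengths, {f"lib{j}": "c" for j in range(6)})
        out = rpkm(table)
        totals = counts.sum(axis=0)
        for g, l in itertools.product(range(100), range(6)):
            expected = counts.iat[g, l] / (
                (lengths[g] / 1e3) * (totals.iloc[l] / 1e6)
            )
            assert out.iat[g, l] == expected  # exact same arithmetic

    def test_scale_consistent_within_library(self):
        counts = pd.DataFrame(
            {"lib1": [10, 30], "lib2": [5, 5]}, index=["g1", "g2"]
        )
        table = _table(counts, [1000, 1000], {"lib1": "c", "lib2": "c"})
        doubled = counts.copy()
        doubled["lib1"] *= 2
        table2 = _table(doubled, [1000, 1000], {"lib1": "c", "lib2": "c"})
        pd.testing.assert_frame_equal(rpkm(table), rpkm(table2))

    def test_zero_total_library_flagged(self):
        counts = pd.DataFrame({"lib1": [0, 0]}, index=["g1", "g2"])
        table = _table(counts, [1000, 1000], {"lib1": "c"})
        with pytest.warns(UserWarning):
            out = rpkm(table)
        assert out["lib1"].isna().all()

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame({"lib1": [-1]}, index=["g1"])
        with pytest.raises(ValueError):
            _table(counts, [1000], {"lib1": "c"})


def _expr_frame(cells, r):
    """Expression table from a {gene: {condition: mean}} dict with
    replicate values supplied explicitly as lists."""
    libs, data = [], {}
    for cond in next(iter(cells.values())):
        for k in range(r):
            libs.append(f"{cond}_r{k + 1}")
    for gene, per_cond in cells.items():
        row = []
        for cond, values in per_cond.items():
            row.extend(values)
        data[gene] = row
    df = pd.DataFrame(data, index=libs).T
    conditions = pd.Series({lib: lib.rsplit("_r", 1)[0] for lib in libs})
    return df, conditions


def termwise_ss_oracle(long):
    """Brute-force two-factor SS decomposition by literal term-wise
    summation of squared deviations (independent of the implementation)."""
    grand = long["value"].mean()
    ss = {"gene": 0.0, "condition": 0.0, "interaction": 0.0, "residual": 0.0,
          "total": 0.0}
    gene_mean = long.groupby("gene")["value"].mean()
    cond_mean = long.groupby("condition")["value"].mean()
    cell_mean = long.groupby(["gene", "condition"])["value"].mean()
    for _, row in long.iterrows():
        g, c, y = row["gene"], row["condition"], row["value"]
        ss["gene"] += (gene_mean[g] - grand) ** 2
        ss["condition"] += (cond_mean[c] - grand) ** 2
        ss["interaction"] += (
            cell_mean[(g, c)] - gene_mean[g] - cond_mean[c] + grand
        ) ** 2
        ss["residual"] += (y - cell_mean[(g, c)]) ** 2
        ss["total"] += (y - grand) ** 2
    return ss


class TestAnovaPartition:
    def test_constructed_cells_match_termwise_oracle(self):
        expr, conditions = _expr_frame(
            {"g1": {"c1": [10, 10], "c2": [10, 10]},
             "g2": {"c1": [10, 10], "c2": [30, 30]}},
            r=2,
        )
        # perturb one replicate so the residual SS is non-zero
        expr.iloc[0, 0] += 2.0
        part = anova_partition(expr, conditions)
        long = expr.stack().rename("value").reset_index()
        long.columns = ["gene", "library", "value"]
        long["condition"] = long["library"].map(conditions)
        oracle = termwise_ss_oracle(long)
        for key in ("gene", "condition", "interaction", "residual", "total"):
            assert part.ss[key] == pytest.approx(oracle[key], abs=1e-9)
        assert sum(
            part.pct_ss[k] for k in ("gene", "condition", "interaction", "residual")
        ) == pytest.approx(100.0, abs=1e-9)

    def test_all_cells_equal_not_available(self):
        expr, conditions = _expr_frame(
            {"g1": {"c1": [5, 5], "c2": [5, 5]},
             "g2": {"c1": [5, 5], "c2": [5, 5]}},
            r=2,
        )
        part = anova_partition(expr, conditions)
        assert all(math.isnan(v) for v in part.pct_ss.values())

    def test_matches_statsmodels_on_random_balanced_design(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        expr, conditions = _expr_frame(
            {
                g: {c: list(rng.normal(100, 20, size=3)) for c in ("c1", "c2", "c3")}
                for g in ("g1", "g2", "g3", "g4")
            },
            r=3,
        )
        part = anova_partition(expr, conditions)
        long = expr.stack().rename("value").reset_index()
        long.columns = ["gene", "library", "value"]
        long["condition"] = long["library"].map(conditions)
        fit = ols("value ~ C(gene) * C(condition)", data=long).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert part.ss["gene"] == pytest.approx(table.loc["C(gene)", "sum_sq"])
        assert part.ss["condition"] == pytest.approx(
            table.loc["C(condition)", "sum_sq"]
        )
        assert part.ss["interaction"] == pytest.approx(
            table.loc["C(gene):C(condition)", "sum_sq"]
        )
        assert part.ss["residual"] == pytest.approx(table.loc["Residual", "sum_sq"])
        assert part.f_statistics["gene"] == pytest.approx(table.loc["C(gene)", "F"])
        assert part.p_values["interaction"] == pytest.approx(
            table.loc["C(gene):C(condition)", "PR(>F)"]
        )

    def test_unbalanced_design_rejected(self):
        expr = pd.DataFrame(
            {"c1_r1": [1.0, 2.0], "c1_r2": [1.5, 2.5], "c2_r1": [3.0, 4.0]},
            index=["g1", "g2"],
        )
        conditions = pd.Series(
            {"c1_r1": "c1", "c1_r2": "c1", "c2_r1": "c2"}
        )
        with pytest.raises(ValueError, match="balanced|unbalanced"):
            anova_partition(expr, conditions)

    def test_permutation_invariant_to_replicate_order(self, rng):
        expr, conditions = _expr_frame(
            {
                g: {c: list(rng.normal(50, 10, size=3)) for c in ("c1", "c2")}
                for g in ("g1", "g2", "g3")
            },
            r=3,
        )
        part1 = anova_partition(expr, conditions)
        shuffled_cols = list(rng.permutation(expr.columns))
        part2 = anova_partition(expr[shuffled_cols], conditions[shuffled_cols])
        for key in part1.pct_ss:
            assert part1.pct_ss[key] == pytest.approx(part2.pct_ss[key])

    def test_pct_ss_converges_to_noise_free_partition(self):
        """With Gaussian noise around fixed cell means, the estimated %SS
        approaches the noise-free partition as replication grows."""
        rng = np.random.default_rng(99)
        genes = [f"g{i}" for i in range(4)]
        conds = ["c1", "c2", "c3"]
        gene_fx = {g: v for g, v in zip(genes, [0.0, 20.0, 40.0, 60.0])}
        cond_fx = {c: v for c, v in zip(conds, [0.0, 15.0, 30.0])}
        r = 50
        cells = {
            g: {c: list(100 + gene_fx[g] + cond_fx[c] + rng.normal(0, 5, r))
                for c in conds}
            for g in genes
        }
        expr, conditions = _expr_frame(cells, r=r)
        part = anova_partition(expr, conditions)
        exact_cells = {
            g: {c: [100 + gene_fx[g] + cond_fx[c]] * 2 for c in conds}
            for g in genes
        }
        exact_expr, exact_conditions = _expr_frame(exact_cells, r=2)
        long = exact_expr.stack().rename("value").reset_index()
        long.columns = ["gene", "library", "value"]
        long["condition"] = long["library"].map(exact_conditions)
        oracle = termwise_ss_oracle(long)
        denom = sum(oracle[k] for k in ("gene", "condition", "interaction"))
        for effect in ("gene", "condition"):
            # compare shares among the systematic effects (noise-free
            # reference has no residual component)
            systematic = sum(
                part.pct_ss[k] for k in ("gene", "condition", "interaction")
            )
            estimated_share = 100 * part.pct_ss[effect] / systematic
            expected_share = 100 * oracle[effect] / denom
            assert abs(estimated_share - expected_share) < 5.0

    def test_gene_subset_selection(self, rng):
        expr, conditions = _expr_frame(
            {
                g: {c: list(rng.normal(50, 5, size=2)) for c in ("c1", "c2")}
                for g in ("g1", "g2", "g3")
            },
            r=2,
        )
        part = anova_partition(expr, conditions, genes=["g1", "g2"])
        assert part.df["gene"] == 1
        with pytest.raises(ValueError):
            anova_partition(expr, conditions, genes=["gX"])


class TestBonferroni:
    def test_family_is_per_condition_pairs(self, rng):
        expr, conditions = _expr_frame(
            {
                g: {c: list(rng.normal(100, 10, size=3)) for c in ("c1", "c2")}
                for g in ("g1", "g2", "g3", "g4")
            },
            r=3,
        )
        part = anova_partition(expr, conditions)
        n_pairs = math.comb(4, 2)
        assert len(part.pairwise) == 2 * n_pairs  # both condition families
        for _, row in part.pairwise.iterrows():
            assert row["p_bonferroni"] == pytest.approx(
                min(1.0, row["p_raw"] * n_pairs)
            )

    def test_uses_pooled_residual_ms(self, rng):
        expr, conditions = _expr_frame(
            {
                g: {c: list(rng.normal(100, 10, size=3)) for c in ("c1", "c2")}
                for g in ("g1", "g2")
            },
            r=3,
        )
        part = anova_partition(expr, conditions)
        ms_e = part.ss["residual"] / part.df["residual"]
        row = part.pairwise.iloc[0]
        cond = row["condition"]
        m1 = expr.loc[row["gene1"], conditions[conditions == cond].index].mean()
        m2 = expr.loc[row["gene2"], conditions[conditions == cond].index].mean()
        t_expected = (m1 - m2) / math.sqrt(ms_e * 2 / 3)
        assert row["t"] == pytest.approx(t_expected)


class TestSyntheticCounts:
    def test_null_simulation_small_pct_ss(self):
        table, _ = make_counts(
            5, [0.0] * 6, [0.0] * 3, r=40, dispersion=0.02
        )
        part = anova_partition(rpkm(table), table.library_conditions)
        for effect in ("gene", "condition", "interaction"):
            assert part.pct_ss[effect] < 5.0

    def test_planted_gene_effect_dominates(self):
        table, _ = make_counts(
            6, [0.0, 1.0, 2.0, 3.0], [0.0, 0.0], r=20, dispersion=0.02
        )
        part = anova_partition(rpkm(table), table.library_conditions)
        assert part.pct_ss["gene"] > 50.0

    def test_log2_option(self):
        expr = pd.DataFrame({"lib": [0.0, 3.0]}, index=["g1", "g2"])
        out = log2_transform(expr)
        assert out.loc["g1", "lib"] == 0.0
        assert out.loc["g2", "lib"] == 2.0
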