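"""RPKM expression summaries and two-way ANOVA variance partitioning.

RPKM (reads per kilobase of gene per million mapped reads) is computed
per gene and library from a count table:

    RPKM[g, l] = count[g, l] / ((length_bp[g] / 1e3) * (total[l] / 1e6))

where the per-library total defaults to the column sum of the provided
table (per-library overrides are accepted).

For a set of genes profiled under several conditions with a balanced
complete replicate design, the classical two-factor factorial
decomposition partitions the total sum of squares into gene, condition,
gene x condition interaction, and residual components; the percentage
of total variation explained by each effect is reported together with F
statistics and p values.  Pairwise gene comparisons within each
condition use the pooled residual mean square with Bonferroni
correction, each condition corrected as its own family.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CountTable:
    """Gene x library matrix of read counts with lengths and a design."""

    counts: pd.DataFrame  # genes x libraries, non-negative integers
    gene_lengths: pd.Series  # bp per gene
    library_conditions: pd.Series  # condition label per library

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any() or (self.gene_lengths < 1).any():
            raise ValueError("every gene needs a length >= 1 bp")
        self.library_conditions = self.library_conditions.reindex(self.counts.columns)
        if self.library_conditions.isna().any():
            raise ValueError("every library needs a condition label")


@dataclass(frozen=True)
class AnovaPartition:
    """Two-way ANOVA variance partition plus Bonferroni comparisons."""

    pct_ss: dict[str, float]  # gene / condition / interaction / residual
    ss: dict[str, float]
    df: dict[str, int]
    f_statistics: dict[str, float]
    p_values: dict[str, float]
    pairwise: pd.DataFrame  # per-condition gene pairs, raw + adjusted p
    grand_mean: float


def rpkm(
    table: CountTable, library_totals: dict[str, float] | None = None
) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads, per gene and library.

    A zero-count cell yields RPKM 0 whatever the length and total; a
    zero-total library yields a NaN column with a warning.
    """
    totals = table.counts.sum(axis=0).astype(float)
    if library_totals:
        for lib, tot in library_totals.items():
            totals[lib] = float(tot)
    zero = totals[totals == 0].index
    if len(zero):
        warnings.warn(f"libraries with zero total reads: {list(zero)}")
        totals[zero] = np.nan
    denom = np.outer(
        table.gene_lengths.to_numpy(dtype=float) / 1e3,
        totals.to_numpy(dtype=float) / 1e6,
    )
    return pd.DataFrame(
        table.counts.to_numpy(dtype=float) / denom,
        index=table.counts.index,
        columns=table.counts.columns,
    )


def _long_form(expr: pd.DataFrame, conditions: pd.Series) -> pd.DataFrame:
    long = expr.stack().rename("value").reset_index()
    long.columns = ["gene", "library", "value"]
    long["condition"] = long["library"].map(conditions)
    return long


def anova_partition(
    expr: pd.DataFrame,
    conditions: pd.Series,
    genes: list[str] | None = None,
) -> AnovaPartition:
    """Two-factor (gene x condition) factorial ANOVA on expression values.

    Requires a balanced complete design: every gene x condition cell
    observed with the same replicate count r >= 2.  Returns the %SS of
    each component (summing to 100), F and p per effect, and the
    Bonferroni-adjusted pairwise gene comparisons within each condition
    (pooled residual MS, one family per condition).
    """
    if genes is not None:
        missing = sorted(set(genes) - set(expr.index))
        if missing:
            raise ValueError(f"genes not in expression table: {missing}")
        expr = expr.loc[genes]
    conditions = pd.Series(conditions).reindex(expr.columns)
    long = _long_form(expr, conditions)

    cell_sizes = long.groupby(["gene", "condition"]).size()
    a = long["gene"].nunique()
    b = long["condition"].nunique()
    r_values = cell_sizes.unique()
    if len(cell_sizes) != a * b or len(r_values) != 1:
        raise ValueError(
            "unbalanced or incomplete design: every gene x condition cell "
            "must have the same replicate count (subsample libraries first)"
        )
    r = int(r_values[0])
    if r < 2:
        raise ValueError("need r >= 2 replicates per cell")

    y = long["value"].to_numpy(dtype=float)
    grand = y.mean()
    gene_means = long.groupby("gene")["value"].mean()
    cond_means = long.groupby("condition")["value"].mean()
    cell_means = long.groupby(["gene", "condition"])["value"].mean()

    ss_a = b * r * float(((gene_means - grand) ** 2).sum())
    ss_b = a * r * float(((cond_means - grand) ** 2).sum())
    ss_cells = r * float(((cell_means - grand) ** 2).sum())
    ss_ab = ss_cells - ss_a - ss_b
    ss_t = float(((y - grand) ** 2).sum())
    ss_e = ss_t - ss_cells

    df = {
        "gene": a - 1,
        "condition": b - 1,
        "interaction": (a - 1) * (b - 1),
        "residual": a * b * (r - 1),
        "total": a * b * r - 1,
    }
    ss = {
        "gene": ss_a,
        "condition": ss_b,
        "interaction": ss_ab,
        "residual": ss_e,
        "total": ss_t,
    }
    if ss_t == 0:
        nan = float("nan")
        pct = {k: nan for k in ("gene", "condition", "interaction", "residual")}
        f_stats = dict(pct)
        p_vals = dict(pct)
    else:
        pct = {
            k: 100.0 * ss[k] / ss_t
            for k in ("gene", "condition", "interaction", "residual")
        }
        ms_e = ss_e / df["residual"]
        f_stats, p_vals = {}, {}
        for k in ("gene", "condition", "interaction"):
            if df[k] == 0 or ms_e == 0:
                f_stats[k] = float("nan")
                p_vals[k] = float("nan")
                continue
            f = (ss[k] / df[k]) / ms_e
            f_stats[k] = float(f)
            p_vals[k] = float(stats.f.sf(f, df[k], df["residual"]))

    pairwise = _bonferroni_pairwise(long, ss_e, df["residual"], r)
    return AnovaPartition(
        pct_ss=pct,
        ss=ss,
        df=df,
        f_statistics=f_stats,
        p_values=p_vals,
        pairwise=pairwise,
        grand_mean=float(grand),
    )


def _bonferroni_pairwise(
    long: pd.DataFrame, ss_e: float, df_e: int, r: int
) -> pd.DataFrame:
    """All gene pairs within each condition; Bonferroni per condition family.

    The test statistic uses the ANOVA's pooled residual mean square:
    t = (mean_i - mean_j) / sqrt(MS_E * 2 / r), df = residual df.
    """
    ms_e = ss_e / df_e if df_e > 0 else float("nan")
    cell_means = long.groupby(["condition", "gene"])["value"].mean()
    rows = []
    for condition in sorted(long["condition"].unique()):
        means = cell_means.loc[condition]
        pairs = list(itertools.combinations(sorted(means.index), 2))
        n_family = len(pairs)
        for g1, g2 in pairs:
            diff = means[g1] - means[g2]
            if ms_e > 0:
                t = diff / np.sqrt(ms_e * 2.0 / r)
                p = 2.0 * stats.t.sf(abs(t), df_e)
            else:
                t, p = float("nan"), float("nan")
            rows.append(
                {
                    "condition": condition,
                    "gene1": g1,
                    "gene2": g2,
                    "mean_diff": float(diff),
                    "t": float(t),
                    "p_raw": float(p),
                    "p_bonferroni": float(min(1.0, p * n_family))
                    if np.isfinite(p)
                    else float("nan"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "condition", "gene1", "gene2", "mean_diff", "t", "p_raw",
            "p_bonferroni",
        ],
    )


def log2_transform(expr: pd.DataFrame) -> pd.DataFrame:
    """Optional log2(x + 1) response transform for the ANOVA."""
    return np.log2(expr + 1.0)
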