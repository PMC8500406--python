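"""Expression breadth, group comparisons, and WGT-retention stratification.

A gene is *expressed* in a tissue when its FPKM reaches the threshold
(default 1.0; always recorded in outputs since the breadth classes depend
on it). Breadth classes over the six tissues: specific (exactly one),
constitutive (all six), silent (none), intermediate (2-5).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import TISSUES

DEFAULT_EXPRESSED_THRESHOLD = 1.0


def classify_tissue_pattern(matrix: pd.DataFrame,
                            expressed_threshold: float = DEFAULT_EXPRESSED_THRESHOLD
                            ) -> pd.DataFrame:
    """Breadth class per gene; columns gene_id, n_expressed_tissues,
    expression_class, specific_tissue."""
    missing = set(TISSUES) - set(matrix.columns)
    if missing:
        raise ValueError(f"expression matrix lacks tissues: {sorted(missing)}")
    expressed = matrix[list(TISSUES)] >= expressed_threshold
    n = expressed.sum(axis=1)
    cls = pd.Series(
        np.select([n == 0, n == 1, n == 6], ["silent", "specific", "constitutive"],
                  default="intermediate"),
        index=matrix.index,
    )
    specific = pd.Series("", index=matrix.index, dtype=object)
    only_one = n == 1
    if only_one.any():
        specific[only_one] = expressed[only_one].idxmax(axis=1)
    return pd.DataFrame({
        "gene_id": matrix.index,
        "n_expressed_tissues": n.to_numpy(),
        "expression_class": cls.to_numpy(),
        "specific_tissue": specific.to_numpy(),
    })


def compare_expression_groups(group_a, group_b, test: str = "mann_whitney",
                              alternative: str = "two-sided"
                              ) -> tuple[float, float]:
    """Two-group location test on expression (or any level) values.

    ``test`` is one of mann_whitney, kruskal_wallis, welch_t; for Welch the
    one-sided ``alternative`` ('less'/'greater', meaning group_a vs
    group_b) mirrors per-comparison directional hypotheses.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative=alternative)
    elif test == "kruskal_wallis":
        if min(a.size, b.size) < 2:
            raise ValueError("Kruskal-Wallis needs >= 2 values per group")
        res = stats.kruskal(a, b)
    elif test in ("welch_t", "welch_t_one_sided"):
        if min(a.size, b.size) < 2:
            raise ValueError("Welch t needs >= 2 values per group")
        res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def wgt_retention_analysis(results: pd.DataFrame, retention: pd.Series,
                           matrix: pd.DataFrame, B: int = 2000,
                           seed: int = 0) -> dict:
    """PSG proportion and PSG expression by WGT retention class (1/2/3).

    Returns a summary frame (per class: n_genes, n_psg, psg_fraction,
    mean/SE of PSG mean-FPKM), a Fisher test on the 2 x 3 PSG/non-PSG by
    class table, and a Kruskal-Wallis test of PSG expression across
    classes. Classes with no genes are flagged undefined.
    """
    from .distribution import contingency_fisher

    merged = results[results["psg_status"].isin(["PSG", "non-PSG"])].copy()
    merged["retention_class"] = merged["gene_id"].map(retention)
    merged = merged.dropna(subset=["retention_class"])
    merged["retention_class"] = merged["retention_class"].astype(int)
    mean_expr = matrix.mean(axis=1)

    rows, expr_groups = [], []
    for cls in (1, 2, 3):
        sub = merged[merged["retention_class"] == cls]
        n_genes, n_psg = len(sub), int(sub["is_psg"].sum())
        psgs = sub.loc[sub["is_psg"], "gene_id"]
        expr = mean_expr.reindex(psgs).dropna().to_numpy()
        expr_groups.append(expr)
        rows.append({
            "retention_class": cls,
            "n_genes": n_genes,
            "n_psg": n_psg,
            "psg_fraction": n_psg / n_genes if n_genes else float("nan"),
            "psg_fraction_defined": n_genes > 0,
            "psg_mean_fpkm": float(np.mean(expr)) if expr.size else float("nan"),
            "psg_se_fpkm": float(np.std(expr, ddof=1) / math.sqrt(expr.size))
            if expr.size > 1 else float("nan"),
        })
    summary = pd.DataFrame(rows)
    table = np.array([
        summary["n_psg"].to_numpy(),
        (summary["n_genes"] - summary["n_psg"]).to_numpy(),
    ])
    nonzero = table.sum(axis=0) > 0
    fisher_p = (contingency_fisher(table[:, nonzero], B=B, seed=seed)
                if nonzero.sum() >= 2 and table.sum(axis=1).min() > 0
                else float("nan"))
    usable = [g for g in expr_groups if g.size >= 2]
    if len(usable) >= 2:
        kw_stat, kw_p = stats.kruskal(*usable)
    else:
        kw_stat = kw_p = float("nan")
    return {"summary": summary, "fisher_p": fisher_p,
            "kw_statistic": float(kw_stat), "kw_p": float(kw_p)}


def expression_by_chromosome(matrix: pd.DataFrame, gene_chroms: pd.Series,
                             genes=None) -> dict:
    """Per-chromosome, per-tissue expression summaries + a KW test.

    ``genes`` restricts the analysis (e.g. to PSGs); default all genes with
    a chromosome. The Kruskal-Wallis test compares mean FPKM across
    chromosomes and is skipped (with a note) when fewer than two
    chromosomes have >= 2 genes.
    """
    if genes is not None:
        matrix = matrix.loc[matrix.index.intersection(set(genes))]
    chrom = gene_chroms.reindex(matrix.index)
    matrix = matrix[chrom.notna()]
    chrom = chrom.dropna()
    long = matrix.copy()
    long["chrom"] = chrom
    summary = long.groupby("chrom")[list(TISSUES)].agg(["mean", "median"])
    summary.columns = [f"{t}_{s}" for t, s in summary.columns]
    summary = summary.reset_index()
    mean_expr = matrix.mean(axis=1)
    groups = [g.to_numpy() for _, g in mean_expr.groupby(chrom) if len(g) >= 2]
    if len(groups) >= 2:
        stat, p = stats.kruskal(*groups)
        note = ""
    else:
        stat = p = float("nan")
        note = "fewer than two chromosomes with >= 2 genes; KW skipped"
    return {"summary": summary, "kw_statistic": float(stat),
            "kw_p": float(p), "note": note}
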