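"""Chromosomal-distribution tests for gene sets.

Whether PSGs fall on chromosomes in proportion to gene content is tested
three ways: a Pearson chi-square on the 2 x C (PSG / non-PSG by
chromosome) contingency table, a Fisher exact probability test (exact for
2 x 2, Monte-Carlo over fixed-margin tables otherwise), and a
randomization test that redraws equally sized gene sets uniformly from the
universe and compares the chi-square summary of per-chromosome counts
against its null distribution. Empirical p-values use the plus-one rule,
(1 + #{null >= observed}) / (B + 1), and therefore never return zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln


@dataclass
class PermutationResult:
    observed_statistic: float
    null_samples: np.ndarray
    empirical_p: float
    B: int
    seed: int
    per_chromosome: pd.DataFrame


def chromosome_counts(psg_genes, gene_chroms: pd.Series):
    """Per-chromosome PSG/background counts and the 2 x C table.

    ``gene_chroms`` maps every gene of the universe to its chromosome;
    genes in ``psg_genes`` missing from it are an error.
    """
    psg_genes = set(psg_genes)
    missing = psg_genes - set(gene_chroms.index)
    if missing:
        raise KeyError(f"genes without a chromosome assignment: {sorted(missing)[:10]}")
    chroms = sorted(gene_chroms.unique())
    is_psg = gene_chroms.index.isin(psg_genes)
    tab = pd.crosstab(np.where(is_psg, "psg", "background"), gene_chroms)
    for row in ("psg", "background"):
        if row not in tab.index:
            tab.loc[row] = 0
    tab = tab.loc[["psg", "background"], chroms]
    dist = pd.DataFrame({
        "chrom": chroms,
        "n_psg": tab.loc["psg"].to_numpy(),
        "n_background": tab.loc["background"].to_numpy(),
    })
    dist["n_total"] = dist["n_psg"] + dist["n_background"]
    dist["density"] = dist["n_psg"] / dist["n_total"]
    return dist, tab.to_numpy()


def _check_table(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    return table


def contingency_chisq(table) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction: (stat, df, p)."""
    table = _check_table(table)
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def _log_table_probability(table: np.ndarray) -> float:
    """Log multivariate hypergeometric probability of a table given margins."""
    table = np.asarray(table, dtype=np.int64)
    n = table.sum()
    return float(
        gammaln(table.sum(axis=1) + 1).sum()
        + gammaln(table.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def contingency_fisher(table, B: int = 2000, seed: int = 0,
                       method: str = "auto") -> float:
    """Fisher exact probability test for an r x C table.

    With ``method="auto"`` 2 x 2 tables use the exact two-sided
    hypergeometric test and larger tables a Monte-Carlo estimate over B
    fixed-margin tables (Patefield sampling),
    p = (1 + #{P(sampled) <= P(observed)}) / (B + 1).
    ``method="monte_carlo"`` forces the Monte-Carlo route on any shape.
    """
    if method not in ("auto", "exact", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")
    table = _check_table(table)
    if table.shape == (2, 2) and method in ("auto", "exact"):
        return float(stats.fisher_exact(table).pvalue)
    if method == "exact":
        raise ValueError("exact test only implemented for 2x2 tables")
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    samples = sampler.rvs(B, random_state=rng)
    obs_logp = _log_table_probability(table)
    logps = np.array([_log_table_probability(t) for t in samples])
    hits = int((logps <= obs_logp + 1e-9).sum())
    return (1 + hits) / (B + 1)


def permutation_distribution_test(psg_genes, gene_chroms: pd.Series,
                                  B: int = 10000, seed: int = 0) -> PermutationResult:
    """Randomization test of the per-chromosome distribution of a gene set.

    The statistic is the Pearson chi-square of observed per-chromosome PSG
    counts against expectation proportional to per-chromosome gene totals.
    The null redraws B equally sized gene sets uniformly from the universe
    (realized as multivariate hypergeometric count draws, which is the
    identical distribution). Per-chromosome two-sided enrichment/depletion
    p-values come from the same null draws.
    """
    psg_genes = set(psg_genes)
    if not psg_genes:
        raise ValueError("need at least one gene in the set")
    if B < 100:
        warnings.warn(f"B={B} permutations gives an unstable p-value",
                      RuntimeWarning, stacklevel=2)
    dist, _ = chromosome_counts(psg_genes, gene_chroms)
    totals = dist["n_total"].to_numpy()
    observed = dist["n_psg"].to_numpy()
    m = observed.sum()
    expected = m * totals / totals.sum()

    def chisq(counts):
        return ((counts - expected) ** 2 / expected).sum(axis=-1)

    obs_stat = float(chisq(observed))
    rng = np.random.default_rng(seed)
    null_counts = rng.multivariate_hypergeometric(totals, m, size=B)
    null_stats = chisq(null_counts)
    p = (1 + int((null_stats >= obs_stat - 1e-12).sum())) / (B + 1)

    ge = (null_counts >= observed).mean(axis=0)
    le = (null_counts <= observed).mean(axis=0)
    per_chrom = pd.DataFrame({
        "chrom": dist["chrom"],
        "n_psg": observed,
        "expected": expected,
        "p_two_sided": np.minimum(1.0, 2 * np.minimum(
            (1 + ge * B) / (B + 1), (1 + le * B) / (B + 1))),
    })
    return PermutationResult(observed_statistic=obs_stat,
                             null_samples=null_stats, empirical_p=p,
                             B=B, seed=seed, per_chromosome=per_chrom)
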