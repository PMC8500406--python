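"""Hypergeometric term enrichment and the gene-family contingency analysis.

Over-representation of annotation terms in a study set (the PSGs) against
a background universe (the Ks-filtered ortholog pairs) is scored with the
hypergeometric upper tail, P(X >= k) for X ~ Hypergeom(N, K, n), and
adjusted across terms by Benjamini-Hochberg. The family analysis builds
the PSG / non-PSG by six-family contingency table (resistance genes,
protein kinases, transcription factors, flower, auxin, glucosinolate) and
delegates its chi-square and Fisher tests to the distribution module.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .distribution import contingency_chisq, contingency_fisher

GENE_FAMILIES: tuple[str, ...] = (
    "R", "kinase", "TF", "flower", "auxin", "glucosinolate"
)


def hypergeometric_enrichment(study, background, terms,
                              direction: str = "over") -> pd.DataFrame:
    """Term enrichment of ``study`` within ``background``.

    Parameters
    ----------
    terms
        Iterable of :class:`AnnotationMap`. Term genes outside the
        background are ignored for counting (K is the in-background size).
    direction
        "over" (default) scores over-representation, "under" depletion.

    Returns a DataFrame sorted by q then p with columns term_id, term_name,
    k, n, K, N, p, q.
    """
    study, background = set(study), set(background)
    offenders = study - background
    if offenders:
        raise ValueError(
            f"study genes outside the background: {sorted(offenders)[:10]}"
        )
    if direction not in ("over", "under"):
        raise ValueError("direction must be 'over' or 'under'")
    N, n = len(background), len(study)
    rows = []
    for term in terms:
        genes = set(term.genes) & background
        K = len(genes)
        if K == 0:
            continue
        k = len(genes & study)
        if direction == "over":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            p = float(stats.hypergeom.cdf(k, N, K, n))
        rows.append({"term_id": term.term_id, "term_name": term.term_name,
                     "k": k, "n": n, "K": K, "N": N, "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "n", "K",
                                     "N", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df = df.sort_values(["q", "p", "term_id"], ignore_index=True)
    else:
        df["q"] = []
    return df


def family_contingency(results: pd.DataFrame, family_map: pd.Series,
                       B: int = 2000, seed: int = 0) -> dict:
    """Gene-family association analysis of the screen.

    ``family_map`` maps gene_id -> family over :data:`GENE_FAMILIES`;
    genes without a family are excluded. Returns the 2 x 6 table (rows
    PSG / non-PSG), the chi-square and Monte-Carlo Fisher results, and the
    transcription-factor share of family-assigned PSGs.
    """
    bad = set(family_map.unique()) - set(GENE_FAMILIES)
    if bad:
        raise ValueError(f"unknown families: {sorted(bad)}")
    merged = results[results["psg_status"].isin(["PSG", "non-PSG"])].copy()
    merged["family"] = merged["gene_id"].map(family_map)
    merged = merged.dropna(subset=["family"])
    if merged.empty:
        raise ValueError("no family-assigned genes in the screen results")
    table = np.zeros((2, len(GENE_FAMILIES)), dtype=int)
    for j, fam in enumerate(GENE_FAMILIES):
        sub = merged[merged["family"] == fam]
        table[0, j] = int(sub["is_psg"].sum())
        table[1, j] = int((~sub["is_psg"]).sum())
    return family_table_tests(table, B=B, seed=seed)


def family_table_tests(table, B: int = 2000, seed: int = 0) -> dict:
    """Chi-square + Monte-Carlo Fisher + TF share for a 2 x 6 family table.

    The table rows are PSG / non-PSG and the columns follow
    :data:`GENE_FAMILIES` order; usable directly on a published table.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, len(GENE_FAMILIES)):
        raise ValueError(f"expected a 2x{len(GENE_FAMILIES)} table, got {table.shape}")
    stat, dof, p_chi = contingency_chisq(table)
    p_fisher = contingency_fisher(table, B=B, seed=seed)
    n_psg = int(table[0].sum())
    tf_idx = GENE_FAMILIES.index("TF")
    tf_share = 100.0 * table[0, tf_idx] / n_psg if n_psg else float("nan")
    return {
        "table": pd.DataFrame(table, index=["PSG", "non-PSG"],
                              columns=list(GENE_FAMILIES)),
        "chisq_statistic": stat,
        "chisq_df": dof,
        "chisq_p": p_chi,
        "fisher_p": p_fisher,
        "fisher_B": B,
        "tf_share_pct": round(tf_share, 1),
    }
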