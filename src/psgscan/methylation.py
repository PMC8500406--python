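"""Genic-region methylation profiling.

A gene is divided into five parts — promoter, 5' UTR, exon, intron and
3' UTR — and per region x context (CG/CHG/CHH) the *weighted* methylation
level is computed: total methylated reads over total reads across the
region's cytosines. The weighted level is the standard aggregate for WGBS
data because it lets deeply covered sites dominate in proportion to their
evidence; a per-site mean is available behind ``site_average=True``.

Region definitions (internal 0-based half-open coordinates):

* promoter: ``promoter_length`` bp immediately 5' of the TSS, strand-aware,
  truncated at the chromosome start;
* UTR5 / UTR3: exonic segments 5' / 3' of the CDS span (strand-aware);
* exon: exonic segments inside the CDS span (i.e. coding exon parts);
* intron: gaps between consecutive exons.

UTR5, exon, intron and UTR3 tile the transcript span exactly, which gives
the read-count conservation invariant: summing their read totals per
context reproduces the transcript-span totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import CONTEXTS, GeneModel

REGIONS: tuple[str, ...] = ("promoter", "UTR5", "exon", "intron", "UTR3")


@dataclass(frozen=True)
class RegionSet:
    """Per-gene mapping region -> list of (start, end) half-open intervals."""

    gene_id: str
    chrom: str
    intervals: dict

    def all_intervals(self):
        for region, ivs in self.intervals.items():
            for s, e in ivs:
                yield region, s, e


def partition_gene_regions(model: GeneModel, promoter_length: int = 2000) -> RegionSet:
    """Split one gene model into the five genic regions."""
    if promoter_length < 0:
        raise ValueError("promoter_length must be non-negative")
    if model.strand == "+":
        prom_start = model.tx_start - promoter_length
        if prom_start < 0:
            warnings.warn(
                f"{model.gene_id}: promoter truncated at chromosome start",
                RuntimeWarning, stacklevel=2,
            )
            prom_start = 0
        promoter = [(prom_start, model.tx_start)] if prom_start < model.tx_start else []
    else:
        promoter = [(model.tx_end, model.tx_end + promoter_length)] if promoter_length else []

    low_utr, high_utr, exonic, introns = [], [], [], []
    prev_end = None
    for s, e in model.exons:
        if prev_end is not None and prev_end < s:
            introns.append((prev_end, s))
        prev_end = e
        # split the exon against the CDS span
        if s < model.cds_start:
            low_utr.append((s, min(e, model.cds_start)))
        cs, ce = max(s, model.cds_start), min(e, model.cds_end)
        if cs < ce:
            exonic.append((cs, ce))
        if e > model.cds_end:
            high_utr.append((max(s, model.cds_end), e))
    utr5, utr3 = (low_utr, high_utr) if model.strand == "+" else (high_utr, low_utr)
    return RegionSet(
        gene_id=model.gene_id, chrom=model.chrom,
        intervals={"promoter": promoter, "UTR5": utr5, "exon": exonic,
                   "intron": introns, "UTR3": utr3},
    )


# ---------------------------------------------------------------------------
# weighted level computation
# ---------------------------------------------------------------------------

def weighted_methylation(calls: pd.DataFrame, intervals, context: str,
                         site_average: bool = False) -> dict:
    """Aggregate methylation of one context over a list of intervals.

    Returns dict with methylated_reads, total_reads, n_sites and level
    (NaN when no covered site falls in the intervals). ``site_average``
    switches to the unweighted mean of per-site levels.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    sub = calls[calls["context"] == context]
    mask = np.zeros(len(sub), dtype=bool)
    pos = sub["pos"].to_numpy()
    for s, e in intervals:
        mask |= (pos >= s) & (pos < e)
    sub = sub[mask]
    meth = int(sub["count_methylated"].sum())
    total = int(sub["count_total"].sum())
    covered = sub[sub["count_total"] > 0]
    if site_average:
        level = (
            float((covered["count_methylated"] / covered["count_total"]).mean())
            if len(covered) else float("nan")
        )
    else:
        level = meth / total if total > 0 else float("nan")
    return {"methylated_reads": meth, "total_reads": total,
            "n_sites": int(len(sub)), "level": level}


def profile_genes(calls: pd.DataFrame, region_sets, contexts=CONTEXTS,
                  site_average: bool = False) -> pd.DataFrame:
    """Full gene x region x context methylation profile.

    Returns a tidy DataFrame (gene_id, region, context, methylated_reads,
    total_reads, n_sites, level). Calls are assigned to regions with an
    interval tree per chromosome; a cytosine inside two genes' regions
    counts toward both.
    """
    trees: dict[str, IntervalTree] = {}
    for rs in region_sets:
        tree = trees.setdefault(rs.chrom, IntervalTree())
        for region, s, e in rs.all_intervals():
            tree.addi(s, e, (rs.gene_id, region))

    acc: dict[tuple, list] = {}
    for rs in region_sets:
        for region in REGIONS:
            for ctx in contexts:
                acc[(rs.gene_id, region, ctx)] = [0, 0, 0, []]

    by_chrom = dict(tuple(calls.groupby("chrom", sort=False)))
    for chrom, tree in trees.items():
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        ctxs = sub["context"].to_numpy()
        meth = sub["count_methylated"].to_numpy()
        tot = sub["count_total"].to_numpy()
        for i in range(len(sub)):
            for hit in tree.at(int(pos[i])):
                key = (*hit.data, ctxs[i])
                if key in acc:
                    rec = acc[key]
                    rec[0] += int(meth[i])
                    rec[1] += int(tot[i])
                    rec[2] += 1
                    if site_average and tot[i] > 0:
                        rec[3].append(meth[i] / tot[i])
    rows = []
    for (gid, region, ctx), (m, t, n, site_levels) in acc.items():
        if site_average:
            level = float(np.mean(site_levels)) if site_levels else float("nan")
        else:
            level = m / t if t > 0 else float("nan")
        rows.append({"gene_id": gid, "region": region, "context": ctx,
                     "methylated_reads": m, "total_reads": t,
                     "n_sites": n, "level": level})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def compare_methylation_groups(profiles: pd.DataFrame, group_a, group_b,
                               test: str = "kruskal_wallis",
                               alternative: str = "greater") -> pd.DataFrame:
    """Per region x context comparison of gene-level methylation.

    ``group_a``/``group_b`` are gene-id collections (e.g. PSGs vs a random
    background). Delegates to the shared two-group tests; rows with fewer
    than two defined levels per group are flagged and given NaN p.
    """
    from .expression import compare_expression_groups

    group_a, group_b = set(group_a), set(group_b)
    rows = []
    for (region, ctx), grp in profiles.groupby(["region", "context"], sort=True):
        levels = grp.dropna(subset=["level"])
        a = levels[levels["gene_id"].isin(group_a)]["level"].to_numpy()
        b = levels[levels["gene_id"].isin(group_b)]["level"].to_numpy()
        row = {"region": region, "context": ctx,
               "n_a": len(a), "n_b": len(b),
               "mean_a": float(np.mean(a)) if len(a) else float("nan"),
               "mean_b": float(np.mean(b)) if len(b) else float("nan")}
        if len(a) >= 2 and len(b) >= 2:
            stat, p = compare_expression_groups(a, b, test=test,
                                                alternative=alternative)
            row.update(statistic=stat, p=p, note="")
        else:
            row.update(statistic=float("nan"), p=float("nan"),
                       note="insufficient_genes")
        rows.append(row)
    return pd.DataFrame(rows)


def te_overlap_stratification(profiles: pd.DataFrame, region_sets,
                              te_intervals: pd.DataFrame) -> pd.DataFrame:
    """Split per-region methylation by TE overlap of that same region.

    A gene's region is "with TE" when any of its intervals shares >= 1 bp
    with a TE (half-open adjacency is no overlap). Output: per region x
    context mean levels with/without, their difference, gene counts, and a
    Kruskal-Wallis p (NaN + note when a side is empty).
    """
    from scipy.stats import kruskal

    te_trees: dict[str, IntervalTree] = {}
    for r in te_intervals.itertuples(index=False):
        te_trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
    overlap: dict[tuple, bool] = {}
    for rs in region_sets:
        tree = te_trees.get(rs.chrom)
        for region in REGIONS:
            has = False
            if tree is not None:
                for s, e in rs.intervals[region]:
                    if tree.overlap(s, e):
                        has = True
                        break
            overlap[(rs.gene_id, region)] = has

    rows = []
    for (region, ctx), grp in profiles.groupby(["region", "context"], sort=True):
        levels = grp.dropna(subset=["level"])
        flag = levels.apply(
            lambda r: overlap.get((r["gene_id"], r["region"]), False), axis=1
        ) if len(levels) else pd.Series(dtype=bool)
        with_te = levels[flag.to_numpy()]["level"].to_numpy() if len(levels) else np.array([])
        without = levels[~flag.to_numpy()]["level"].to_numpy() if len(levels) else np.array([])
        row = {"region": region, "context": ctx,
               "n_with_te": len(with_te), "n_without_te": len(without),
               "mean_with_te": float(np.mean(with_te)) if len(with_te) else float("nan"),
               "mean_without_te": float(np.mean(without)) if len(without) else float("nan")}
        row["difference"] = row["mean_with_te"] - row["mean_without_te"]
        if len(with_te) >= 2 and len(without) >= 2:
            stat, p = kruskal(with_te, without)
            row.update(statistic=float(stat), p=float(p), note="")
        else:
            row.update(statistic=float("nan"), p=float("nan"),
                       note="empty_group" if min(len(with_te), len(without)) == 0
                       else "insufficient_genes")
        rows.append(row)
    return pd.DataFrame(rows)


def methylation_expression_correlation(profiles: pd.DataFrame,
                                       matrix: pd.DataFrame,
                                       context: str = "CG",
                                       regions=None) -> tuple[float, float]:
    """Spearman correlation of gene methylation with gene expression.

    Gene methylation is the read-weighted level of ``context`` over the
    chosen ``regions`` (default: the four transcribed regions, i.e. gene
    body); expression is the mean FPKM across the six tissues.
    """
    from scipy.stats import spearmanr

    if regions is None:
        regions = ("UTR5", "exon", "intron", "UTR3")
    sub = profiles[(profiles["context"] == context)
                   & (profiles["region"].isin(regions))]
    agg = sub.groupby("gene_id")[["methylated_reads", "total_reads"]].sum()
    agg = agg[agg["total_reads"] > 0]
    meth_level = agg["methylated_reads"] / agg["total_reads"]
    expr = matrix.mean(axis=1)
    common = meth_level.index.intersection(expr.index)
    if len(common) < 3:
        raise ValueError(
            f"need >= 3 genes with defined methylation and expression, "
            f"got {len(common)}"
        )
    rho, p = spearmanr(meth_level.loc[common], expr.loc[common])
    return float(rho), float(p)
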