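"""End-to-end orchestration: simulate/load -> kaks -> screen -> distribution
-> enrichment -> expression -> methylation, from one YAML config.

Each stage writes its TSV artifacts into the report directory so any stage
can be rerun in isolation; ``summary.tsv`` carries the accounting chain
(pairs in, Ks-removed, retained, PSGs, breadth class counts) and
``pipeline.log`` records thresholds and seeds. All randomness derives from
the single configured seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .distribution import (chromosome_counts, contingency_chisq,
                           contingency_fisher, permutation_distribution_test)
from .enrichment import family_contingency, hypergeometric_enrichment
from .expression import (classify_tissue_pattern, compare_expression_groups,
                         expression_by_chromosome, wgt_retention_analysis)
from .io_formats import (gene_chromosomes, read_annotation_map,
                         read_bed_intervals, read_cytosine_report,
                         read_expression_matrix, read_gff3,
                         read_ortholog_fasta, read_retention_classes,
                         read_tsv, write_bed_intervals, write_cytosine_report,
                         write_expression_matrix, write_gff3,
                         write_ortholog_fasta, write_tsv)
from .kaks import kaks_table
from .methylation import (compare_methylation_groups,
                          methylation_expression_correlation,
                          partition_gene_regions, profile_genes,
                          te_overlap_stratification)
from .screen import (apply_ks_filter, classify_psg, sample_background,
                     screen_summary)
from .synthetic import (SimulationConfig, simulate_family_map, simulate_study)


@dataclass
class PipelineConfig:
    """Thresholds, Monte-Carlo sizes and seeds for a full run."""

    seed: int = 0
    max_ks: float = 0.3
    omega_threshold: float = 1.2
    expressed_threshold: float = 1.0
    promoter_length: int = 2000
    kaks_method: str = "NG86"
    fisher_B: int = 2000
    permutation_B: int = 2000
    background_size: int | None = None  # default: same size as PSG set
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    inputs: dict = field(default_factory=dict)  # paths when not simulating

    def __post_init__(self):
        for name in ("max_ks", "omega_threshold", "expressed_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


def _load_inputs(cfg: PipelineConfig, outdir: Path):
    inputs = cfg.inputs
    required = ["fasta_a", "fasta_b", "pairing", "gff3", "expression"]
    missing = [k for k in required if k not in inputs]
    if missing:
        raise PipelineError("inputs", f"missing input paths: {missing}")
    for key, path in inputs.items():
        if not Path(path).exists():
            raise PipelineError("inputs", f"{key} file not found: {path}")
    pairs = read_ortholog_fasta(inputs["fasta_a"], inputs["fasta_b"],
                                inputs["pairing"])
    models = read_gff3(inputs["gff3"])
    expression = read_expression_matrix(inputs["expression"])
    te = (read_bed_intervals(inputs["te_bed"]) if "te_bed" in inputs
          else pd.DataFrame(columns=["chrom", "start", "end"]))
    calls = (read_cytosine_report(inputs["cytosine_report"])
             if "cytosine_report" in inputs else None)
    retention = (read_retention_classes(inputs["retention"])
                 if "retention" in inputs else None)
    terms = (read_annotation_map(inputs["annotation"])
             if "annotation" in inputs else None)
    family_map = None
    if "families" in inputs:
        fam = read_tsv(inputs["families"])
        family_map = fam.set_index("gene_id")["family"]
    return dict(pairs=pairs, models=models, expression=expression, te=te,
                calls=calls, retention=retention, terms=terms,
                family_map=family_map, truth=None)


def _simulate_inputs(cfg: PipelineConfig, outdir: Path):
    sim_kwargs = dict(cfg.simulation)
    sim_kwargs.setdefault("seed", cfg.seed)
    sim_kwargs.setdefault("promoter_length", cfg.promoter_length)
    sim = SimulationConfig(**sim_kwargs)
    study = simulate_study(sim)
    datadir = outdir / "inputs"
    datadir.mkdir(parents=True, exist_ok=True)
    write_ortholog_fasta(study.pairs, datadir / "genome_a.cds.fasta",
                         datadir / "genome_b.cds.fasta",
                         datadir / "pairing.tsv")
    write_gff3(study.models, datadir / "genes.gff3")
    write_bed_intervals(study.te_intervals, datadir / "te.bed")
    write_expression_matrix(study.expression, datadir / "expression.tsv")
    write_cytosine_report(study.methylation_calls,
                          datadir / "cytosine_report.tsv")
    write_tsv(study.retention.reset_index(), datadir / "retention.tsv")
    write_tsv(study.omega_truth, datadir / "ground_truth_omega.tsv")
    write_tsv(study.expression_truth, datadir / "ground_truth_expression.tsv")
    write_tsv(study.te_truth, datadir / "ground_truth_te.tsv")
    write_tsv(study.methylation_truth, datadir / "ground_truth_methylation.tsv")
    family_map = simulate_family_map(
        [m.gene_id for m in study.models], seed=sim.seed + 5
    )
    write_tsv(family_map.reset_index(), datadir / "families.tsv")
    return dict(pairs=study.pairs, models=study.models,
                expression=study.expression, te=study.te_intervals,
                calls=study.methylation_calls, retention=study.retention,
                terms=None, family_map=family_map, truth=study)


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run every stage and return the report directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"psgscan {__version__}",
                 f"seed={config.seed} max_ks={config.max_ks} "
                 f"omega_threshold={config.omega_threshold} "
                 f"expressed_threshold={config.expressed_threshold} "
                 f"promoter_length={config.promoter_length} "
                 f"kaks_method={config.kaks_method} "
                 f"fisher_B={config.fisher_B} "
                 f"permutation_B={config.permutation_B}"]
    t0 = time.time()
    summary: dict = {}

    data = (_simulate_inputs(config, outdir) if config.simulation or not config.inputs
            else _load_inputs(config, outdir))
    log_lines.append(f"inputs ready ({len(data['pairs'])} pairs) "
                     f"t={time.time() - t0:.1f}s")

    # --- kaks ---
    try:
        estimates = kaks_table(data["pairs"], method=config.kaks_method)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError("kaks", str(exc)) from exc
    write_tsv(estimates, outdir / "kaks.tsv",
              {"method": config.kaks_method})
    summary["pairs_input"] = len(estimates)

    # --- screen ---
    retained, acc = apply_ks_filter(estimates, max_ks=config.max_ks)
    results = classify_psg(retained, omega_threshold=config.omega_threshold)
    write_tsv(results, outdir / "screen_results.tsv",
              {"max_ks": config.max_ks,
               "omega_threshold": config.omega_threshold,
               "counts_are": "pairs"})
    summary.update(screen_summary(acc, results, config.max_ks,
                                  config.omega_threshold))
    psg_genes = sorted(results.loc[results["is_psg"], "gene_id"])
    n_bg = config.background_size or len(psg_genes)
    n_bg = min(n_bg, int((results["psg_status"] == "non-PSG").sum()))
    background = sample_background(results, n_bg, seed=config.seed + 11)
    log_lines.append(f"screen: {len(psg_genes)} PSGs, background n={n_bg} "
                     f"t={time.time() - t0:.1f}s")

    gene_chroms = gene_chromosomes(data["models"])

    # --- distribution ---
    if psg_genes:
        try:
            dist, table = chromosome_counts(psg_genes, gene_chroms)
        except KeyError as exc:
            raise PipelineError("distribution", str(exc)) from exc
        write_tsv(dist, outdir / "chrom_distribution.tsv")
        tests = []
        stat, dof, p = contingency_chisq(table)
        tests.append({"test": "chisq", "statistic": stat, "df": dof, "p": p,
                      "B": "", "seed": ""})
        p_f = contingency_fisher(table, B=config.fisher_B,
                                 seed=config.seed + 21)
        tests.append({"test": "fisher_mc", "statistic": "", "df": "",
                      "p": p_f, "B": config.fisher_B,
                      "seed": config.seed + 21})
        perm = permutation_distribution_test(psg_genes, gene_chroms,
                                             B=config.permutation_B,
                                             seed=config.seed + 22)
        tests.append({"test": "permutation", "statistic": perm.observed_statistic,
                      "df": "", "p": perm.empirical_p,
                      "B": config.permutation_B, "seed": config.seed + 22})
        write_tsv(pd.DataFrame(tests), outdir / "distribution_tests.tsv")
        summary["distribution_chisq_p"] = p
        summary["distribution_permutation_p"] = perm.empirical_p

    # --- enrichment ---
    universe = set(results["gene_id"])
    if data["terms"] is not None and psg_genes:
        enr = hypergeometric_enrichment(set(psg_genes), universe, data["terms"])
        write_tsv(enr, outdir / "enrichment.tsv",
                  {"background": "ks_filtered_pairs", "adjustment": "BH"})
        summary["enriched_terms_q05"] = int((enr["q"] < 0.05).sum())
    if data["family_map"] is not None and psg_genes:
        fam = family_contingency(results, data["family_map"],
                                 B=config.fisher_B, seed=config.seed + 31)
        write_tsv(fam["table"].reset_index(names="group"),
                  outdir / "family_table.tsv",
                  {"chisq_p": fam["chisq_p"], "fisher_p": fam["fisher_p"],
                   "tf_share_pct": fam["tf_share_pct"]})
        summary["family_chisq_p"] = fam["chisq_p"]

    # --- expression ---
    classes = classify_tissue_pattern(
        data["expression"], expressed_threshold=config.expressed_threshold)
    write_tsv(classes, outdir / "expression_classes.tsv",
              {"expressed_threshold": config.expressed_threshold})
    cls_counts = classes["expression_class"].value_counts()
    for name in ("specific", "constitutive", "intermediate", "silent"):
        summary[f"genes_{name}"] = int(cls_counts.get(name, 0))
    mean_expr = data["expression"].mean(axis=1)
    group_tests = []
    if psg_genes and background:
        a = mean_expr.reindex(psg_genes).dropna()
        b = mean_expr.reindex(background).dropna()
        if len(a) and len(b):
            stat, p = compare_expression_groups(a, b, test="mann_whitney")
            group_tests.append({"comparison": "psg_vs_background",
                                "test": "mann_whitney", "statistic": stat,
                                "p": p, "n_a": len(a), "n_b": len(b)})
    if group_tests:
        write_tsv(pd.DataFrame(group_tests), outdir / "group_tests.tsv")
        summary["psg_vs_background_mw_p"] = group_tests[0]["p"]
    if data["retention"] is not None and psg_genes:
        wgt = wgt_retention_analysis(results, data["retention"],
                                     data["expression"], B=config.fisher_B,
                                     seed=config.seed + 41)
        write_tsv(wgt["summary"], outdir / "wgt_summary.tsv",
                  {"fisher_p": wgt["fisher_p"], "kw_p": wgt["kw_p"]})
        summary["wgt_fisher_p"] = wgt["fisher_p"]
    chrom_expr = expression_by_chromosome(data["expression"], gene_chroms,
                                          genes=psg_genes or None)
    write_tsv(chrom_expr["summary"], outdir / "expression_by_chromosome.tsv",
              {"kw_p": chrom_expr["kw_p"], "note": chrom_expr["note"]})
    log_lines.append(f"expression done t={time.time() - t0:.1f}s")

    # --- methylation ---
    if data["calls"] is not None and len(data["calls"]) and psg_genes:
        focus = set(psg_genes) | set(background)
        region_sets = [partition_gene_regions(m, config.promoter_length)
                       for m in data["models"] if m.gene_id in focus]
        profiles = profile_genes(data["calls"], region_sets)
        write_tsv(profiles, outdir / "region_methylation.tsv",
                  {"promoter_length": config.promoter_length,
                   "level": "weighted"})
        comp = compare_methylation_groups(profiles, psg_genes, background)
        write_tsv(comp, outdir / "methylation_group_tests.tsv")
        strat = te_overlap_stratification(profiles, region_sets, data["te"])
        write_tsv(strat, outdir / "te_stratification.tsv")
        try:
            rho, p = methylation_expression_correlation(
                profiles, data["expression"])
            write_tsv(pd.DataFrame([{"context": "CG", "scope": "gene_body",
                                     "spearman_rho": rho, "p": p}]),
                      outdir / "meth_expr_correlation.tsv")
            summary["meth_expr_spearman_rho"] = rho
        except ValueError as exc:
            log_lines.append(f"methylation-expression correlation skipped: {exc}")
        log_lines.append(f"methylation done t={time.time() - t0:.1f}s")

    write_tsv(pd.DataFrame([summary]), outdir / "summary.tsv")
    log_lines.append(f"finished t={time.time() - t0:.1f}s")
    (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return outdir
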