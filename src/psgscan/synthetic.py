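"""Synthetic study-data generator with known ground truth.

Every downstream stage of the screen is exercised on data produced here:
codon alignments evolved under a GY94-style Markov process with known omega
and kappa, gene models with promoter/UTR/exon/intron structure on ten
chromosomes, TE insertions, a six-tissue FPKM matrix with planted breadth
classes, retention classes for the whole-genome triplication, and
binomially sampled cytosine methylation calls with region- and
TE-dependent rates. Each generator emits a ground-truth ledger so
parameter-recovery tests can compare estimate against truth.

All randomness flows through ``numpy.random.default_rng`` seeded from the
configuration; outputs are byte-identical across runs with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_code import SENSE_CODONS, is_transition
from .io_formats import CONTEXTS, TISSUES, GeneModel, OrthologPair

REGIONS: tuple[str, ...] = ("promoter", "UTR5", "exon", "intron", "UTR3")

#: default per-region x per-context mean methylation rates. Chosen to echo
#: the qualitative genic profile of plant WGBS data: CG body methylation
#: concentrated in introns/UTRs, CHG mostly intronic, CHH near zero.
DEFAULT_METHYLATION_RATES: dict[tuple[str, str], float] = {
    ("promoter", "CG"): 0.10, ("UTR5", "CG"): 0.32, ("exon", "CG"): 0.08,
    ("intron", "CG"): 0.35, ("UTR3", "CG"): 0.31,
    ("promoter", "CHG"): 0.05, ("UTR5", "CHG"): 0.04, ("exon", "CHG"): 0.03,
    ("intron", "CHG"): 0.30, ("UTR3", "CHG"): 0.05,
    ("promoter", "CHH"): 0.02, ("UTR5", "CHH"): 0.01, ("exon", "CHH"): 0.01,
    ("intron", "CHH"): 0.02, ("UTR3", "CHH"): 0.02,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the package's reference
    desk-scale conditions (documented in the methods note)."""

    seed: int = 0
    n_genes: int = 1000
    n_chroms: int = 10
    n_codons: int = 300
    # molecular evolution
    kappa: float = 2.0
    # pairwise expected substitutions per neutral nucleotide site; the
    # default emulates a recently diverged congeneric pair whose typical
    # synonymous divergence sits well below the Ks=0.3 screening cutoff
    t: float = 0.15
    psg_fraction: float = 0.02  # fraction of pairs evolved with omega_psg
    omega_psg: float = 2.0
    omega_background: float = 0.2
    # genome layout
    promoter_length: int = 2000
    chrom_weights: tuple | None = None  # None = uniform over chromosomes
    te_insertion_rate: float = 0.1  # per gene region
    # expression
    fraction_specific: float = 0.2
    fraction_constitutive: float = 0.3
    fraction_intermediate: float = 0.4  # remainder is silent
    fpkm_scale: float = 8.0
    expressed_threshold: float = 1.0
    # methylation
    methylation_rates: dict = field(
        default_factory=lambda: dict(DEFAULT_METHYLATION_RATES)
    )
    beta_concentration: float = 30.0  # site-rate Beta concentration a+b
    coverage_mean: float = 20.0
    site_spacing: int = 15  # one cytosine per this many bp, per region
    te_methylation_effect: float = 0.2  # additive rate shift in TE regions
    meth_expr_coupling: float = 0.0  # >0 plants a negative meth~expr trend
    # WGT retention
    retention_fractions: tuple = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self):
        for name in ("psg_fraction", "fraction_specific", "fraction_constitutive",
                     "fraction_intermediate", "te_insertion_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.fraction_specific + self.fraction_constitutive + self.fraction_intermediate > 1 + 1e-9:
            raise ValueError("expression class fractions exceed 1")
        if abs(sum(self.retention_fractions) - 1) > 1e-9:
            raise ValueError("retention fractions must sum to 1")
        if self.n_genes < self.n_chroms:
            raise ValueError("need at least one gene per chromosome")


# ---------------------------------------------------------------------------
# codon-pair simulation (GY94-style, exact stochastic)
# ---------------------------------------------------------------------------

class _RateTable:
    """Per-codon jump rates for fixed (omega, kappa).

    Rate of the single-nucleotide change i->j is
    kappa^{transition} * omega^{nonsynonymous} / (2 + kappa),
    so a fully neutral position has unit substitution rate and branch time
    is measured in expected neutral substitutions per nucleotide site.
    Changes to stop codons have rate zero.
    """

    def __init__(self, omega: float, kappa: float):
        n = len(SENSE_CODONS)
        self.targets = np.zeros((n, 9), dtype=np.int64)
        self.cum = np.ones((n, 9))  # padded with 1.0 beyond real targets
        self.total_rate = np.zeros(n)
        from .genetic_code import single_mutations, translate, is_sense

        idx = {c: i for i, c in enumerate(SENSE_CODONS)}
        norm = 2.0 + kappa
        for i, codon in enumerate(SENSE_CODONS):
            aa = translate(codon)
            rates, tgts = [], []
            for pos, nt, mutant in single_mutations(codon):
                if not is_sense(mutant):
                    continue
                r = (kappa if is_transition(codon[pos], nt) else 1.0) / norm
                if translate(mutant) != aa:
                    r *= omega
                if r > 0:
                    rates.append(r)
                    tgts.append(idx[mutant])
            total = float(sum(rates))
            self.total_rate[i] = total
            if total > 0:
                cum = np.cumsum(rates) / total
                self.cum[i, : len(cum)] = cum
                self.targets[i, : len(tgts)] = tgts


_TABLE_CACHE: dict[tuple[float, float], _RateTable] = {}


def _rate_table(omega: float, kappa: float) -> _RateTable:
    key = (float(omega), float(kappa))
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = _RateTable(*key)
    return _TABLE_CACHE[key]


def _evolve(states: np.ndarray, time: float, table: _RateTable,
            rng: np.random.Generator) -> np.ndarray:
    """Evolve independent codons for `time` by vectorized Gillespie jumps."""
    states = states.copy()
    clock = np.zeros(states.shape[0])
    active = np.arange(states.shape[0])
    while active.size:
        rates = table.total_rate[states[active]]
        movable = rates > 0
        active = active[movable]
        if not active.size:
            break
        clock[active] += rng.exponential(1.0 / table.total_rate[states[active]])
        jumping = active[clock[active] < time]
        if jumping.size:
            u = rng.random(jumping.size)
            choice = (table.cum[states[jumping]] < u[:, None]).sum(axis=1)
            states[jumping] = table.targets[states[jumping], choice]
        active = jumping
    return states


def simulate_codon_pair(omega: float, kappa: float, t: float, n_codons: int,
                        seed) -> OrthologPair:
    """Evolve one ortholog pair from a random ancestor.

    The ancestor's codons are uniform over the 61 sense codons; each lineage
    evolves independently for t/2 so the expected pairwise divergence at a
    neutral site is t substitutions. ``seed`` may be an int or a Generator.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    if min(omega, kappa, t) < 0:
        raise ValueError("omega, kappa and t must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    table = _rate_table(omega, kappa)
    ancestor = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    a = _evolve(ancestor, t / 2.0, table, rng)
    b = _evolve(ancestor, t / 2.0, table, rng)
    seq_a = "".join(SENSE_CODONS[i] for i in a)
    seq_b = "".join(SENSE_CODONS[i] for i in b)
    return OrthologPair("pair", "gene_a", "gene_b", seq_a, seq_b)


def simulate_ortholog_pairs(config: SimulationConfig, rng=None):
    """All ortholog pairs of the study plus the omega ground-truth ledger.

    Genes of the focal genome are named ``g0001``..; partners ``o0001``...
    A fraction ``psg_fraction`` of pairs evolves at ``omega_psg`` (the
    planted positive-selection class), the rest at ``omega_background``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_genes
    is_psg_true = rng.random(n) < config.psg_fraction
    omegas = np.where(is_psg_true, config.omega_psg, config.omega_background)
    pairs, rows = [], []
    width = len(str(n))
    for i in range(n):
        ga, gb = f"g{i + 1:0{width}d}", f"o{i + 1:0{width}d}"
        p = simulate_codon_pair(omegas[i], config.kappa, config.t,
                                config.n_codons, rng)
        pairs.append(OrthologPair(f"{ga}__{gb}", ga, gb, p.codons_a, p.codons_b))
        rows.append({"pair_id": f"{ga}__{gb}", "gene_id": ga,
                     "omega_true": omegas[i], "is_psg_true": bool(is_psg_true[i])})
    return pairs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genome annotation + TEs
# ---------------------------------------------------------------------------

def simulate_genome_annotation(config: SimulationConfig, gene_ids=None, rng=None):
    """Gene models on n_chroms chromosomes plus TE intervals.

    Returns ``(models, te_intervals, te_truth)`` where ``te_truth`` is a
    DataFrame (gene_id, region, has_te) recording the planted overlaps.
    Chromosome assignment is uniform unless ``chrom_weights`` plants known
    clustering.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = config.n_genes
    if gene_ids is None:
        width = len(str(n))
        gene_ids = [f"g{i + 1:0{width}d}" for i in range(n)]
    chroms = [f"Chr{c + 1:02d}" for c in range(config.n_chroms)]
    w = (np.ones(config.n_chroms) if config.chrom_weights is None
         else np.asarray(config.chrom_weights, dtype=float))
    w = w / w.sum()
    # one gene per chromosome guaranteed, remainder by weight
    assignment = list(range(config.n_chroms))
    assignment += list(rng.choice(config.n_chroms, size=n - config.n_chroms, p=w))
    assignment = np.array(assignment)

    models: list[GeneModel] = []
    te_rows, truth_rows = [], []
    cursor = {c: 1000 for c in chroms}
    order = np.argsort(assignment, kind="stable")
    for gi in order:
        gid = gene_ids[gi]
        chrom = chroms[assignment[gi]]
        strand = "+" if rng.random() < 0.5 else "-"
        u5 = int(rng.integers(80, 300))
        u3 = int(rng.integers(80, 300))
        n_cds_exons = int(rng.integers(1, 5))
        cds_lens = rng.integers(150, 600, size=n_cds_exons)
        intron_lens = rng.integers(80, 500, size=max(0, n_cds_exons - 1))
        # gap fits two promoters (this gene's and a minus-strand neighbor's)
        # so promoter intervals of adjacent genes can never overlap
        start = cursor[chrom] + 2 * config.promoter_length + int(rng.integers(500, 1500))
        # assemble exons in genomic order; UTRs are exonic extensions of the
        # terminal coding exons (5' low/high end depends on strand)
        low_utr, high_utr = (u5, u3) if strand == "+" else (u3, u5)
        blocks = []
        pos = start
        for k in range(n_cds_exons):
            length = int(cds_lens[k])
            if k == 0:
                length += low_utr
            if k == n_cds_exons - 1:
                length += high_utr
            blocks.append((pos, pos + length))
            pos += length
            if k < n_cds_exons - 1:
                pos += int(intron_lens[k])
        tx_start, tx_end = blocks[0][0], blocks[-1][1]
        cds_start, cds_end = tx_start + low_utr, tx_end - high_utr
        model = GeneModel(gene_id=gid, chrom=chrom, strand=strand,
                          tx_start=tx_start, tx_end=tx_end,
                          exons=tuple(blocks), cds_start=cds_start,
                          cds_end=cds_end)
        models.append(model)
        cursor[chrom] = tx_end

        from .methylation import partition_gene_regions

        regions = partition_gene_regions(model, config.promoter_length)
        for region in REGIONS:
            intervals = regions.intervals[region]
            has_te = bool(intervals) and rng.random() < config.te_insertion_rate
            if has_te:
                s, e = intervals[int(rng.integers(0, len(intervals)))]
                te_len = int(min(e - s, rng.integers(50, 200)))
                te_start = int(rng.integers(s, e - te_len + 1))
                te_rows.append({"chrom": chrom, "start": te_start,
                                "end": te_start + te_len})
            truth_rows.append({"gene_id": gid, "region": region,
                               "has_te": has_te})
    # restore input gene order for reproducibility of downstream joins
    models.sort(key=lambda m: m.gene_id)
    te = pd.DataFrame(te_rows, columns=["chrom", "start", "end"])
    truth = pd.DataFrame(truth_rows).sort_values(
        ["gene_id", "region"], ignore_index=True
    )
    return models, te, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(gene_ids, config: SimulationConfig, rng=None):
    """Six-tissue FPKM matrix with planted breadth classes.

    Expressed entries are ``fpkm_scale * (1 + Lognormal(0, 0.6))`` and
    unexpressed entries Uniform(0, half the threshold), so planted labels
    are exactly recoverable whenever ``fpkm_scale >= expressed_threshold``.
    Returns ``(matrix, truth)`` with truth columns gene_id, class_true,
    specific_tissue_true.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    u = rng.random(n)
    f_sp, f_co = config.fraction_specific, config.fraction_constitutive
    f_in = config.fraction_intermediate
    classes = np.where(
        u < f_sp, "specific",
        np.where(u < f_sp + f_co, "constitutive",
                 np.where(u < f_sp + f_co + f_in, "intermediate", "silent")),
    )
    hi_cap = 0.5 * min(config.expressed_threshold, config.fpkm_scale)
    mat = rng.uniform(0, hi_cap if hi_cap > 0 else 0, size=(n, 6))

    def expressed_values(size):
        return config.fpkm_scale * (1.0 + rng.lognormal(0.0, 0.6, size=size))

    specific_tissue = np.full(n, "", dtype=object)
    for i, cls in enumerate(classes):
        if cls == "specific":
            j = int(rng.integers(0, 6))
            mat[i, j] = expressed_values(1)[0]
            specific_tissue[i] = TISSUES[j]
        elif cls == "constitutive":
            mat[i, :] = expressed_values(6)
        elif cls == "intermediate":
            k = int(rng.integers(2, 6))
            idx = rng.choice(6, size=k, replace=False)
            mat[i, idx] = expressed_values(k)
        else:  # silent
            mat[i, :] = 0.0
    matrix = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"),
                          columns=list(TISSUES))
    truth = pd.DataFrame({"gene_id": gene_ids, "class_true": classes,
                          "specific_tissue_true": specific_tissue})
    return matrix, truth


def simulate_retention(gene_ids, config: SimulationConfig, rng=None) -> pd.Series:
    """Retention class (1, 2 or 3 WGT copies) per gene."""
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    cls = rng.choice([1, 2, 3], size=len(gene_ids),
                     p=list(config.retention_fractions))
    return pd.Series(cls, index=pd.Index(list(gene_ids), name="gene_id"),
                     name="retention_class")


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def simulate_methylation(models, te_truth: pd.DataFrame,
                         config: SimulationConfig, rng=None,
                         expression_rank: pd.Series | None = None):
    """Binomially sampled cytosine calls over every gene region.

    One cytosine is placed per ``site_spacing`` bp of each region interval;
    its methylation probability is Beta-distributed around the configured
    region x context mean, shifted by ``te_methylation_effect`` inside
    regions the annotation planted a TE into, and (optionally) depressed in
    highly expressed genes when ``meth_expr_coupling > 0``. Reads per site
    are Poisson(coverage_mean); methylated reads Binomial(site rate).

    Returns ``(calls, ledger)``: calls is an io_formats-style DataFrame and
    the ledger records the realized per gene x region x context mean rate.
    """
    from .methylation import partition_gene_regions

    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    te_lookup = (
        {(r.gene_id, r.region): r.has_te for r in te_truth.itertuples(index=False)}
        if te_truth is not None and len(te_truth) else {}
    )
    conc = config.beta_concentration
    rows, ledger = [], []
    ctx_p = np.array([0.35, 0.30, 0.35])
    for model in models:
        regions = partition_gene_regions(model, config.promoter_length)
        expr_shift = 0.0
        if expression_rank is not None and config.meth_expr_coupling > 0:
            q = float(expression_rank.get(model.gene_id, 0.5))
            expr_shift = -config.meth_expr_coupling * (q - 0.5)
        for region in REGIONS:
            intervals = regions.intervals[region]
            if not intervals:
                continue
            has_te = te_lookup.get((model.gene_id, region), False)
            positions = np.concatenate(
                [np.arange(s, e, config.site_spacing) for s, e in intervals]
            )
            if positions.size == 0:
                continue
            contexts = rng.choice(CONTEXTS, size=positions.size, p=ctx_p)
            strands = np.where(rng.random(positions.size) < 0.5, "+", "-")
            coverage = rng.poisson(config.coverage_mean, size=positions.size)
            for ctx in CONTEXTS:
                mean = config.methylation_rates[(region, ctx)]
                if has_te:
                    mean = mean + config.te_methylation_effect
                mean = float(np.clip(mean + expr_shift, 1e-4, 0.99))
                mask = contexts == ctx
                k = int(mask.sum())
                if k == 0:
                    continue
                site_rates = rng.beta(mean * conc, (1 - mean) * conc, size=k)
                meth = rng.binomial(coverage[mask], site_rates)
                for pos, st, cov, m in zip(positions[mask], strands[mask],
                                           coverage[mask], meth):
                    rows.append((model.chrom, int(pos), st, ctx, int(m), int(cov)))
                ledger.append({"gene_id": model.gene_id, "region": region,
                               "context": ctx, "rate_true": mean,
                               "has_te": has_te, "n_sites": k})
    calls = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                        "count_methylated", "count_total"])
    calls["covered"] = calls["count_total"] > 0
    calls = calls.sort_values(["chrom", "pos"], ignore_index=True)
    return calls, pd.DataFrame(ledger)


# ---------------------------------------------------------------------------
# annotation terms and gene families
# ---------------------------------------------------------------------------

def simulate_annotation_terms(gene_ids, n_terms: int = 50,
                              term_size_range: tuple = (10, 100),
                              planted_term_genes=None, seed: int = 0):
    """Random annotation terms over a gene universe, for enrichment tests.

    Terms draw members uniformly; ``planted_term_genes`` (a gene set) adds
    one extra term with that exact membership, giving a term of known
    enrichment. Returns a list of :class:`io_formats.AnnotationMap`.
    """
    from .io_formats import AnnotationMap

    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    terms = []
    for i in range(n_terms):
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        members = rng.choice(gene_ids, size=min(size, len(gene_ids)),
                             replace=False)
        terms.append(AnnotationMap(f"TERM:{i + 1:04d}", f"random term {i + 1}",
                                   frozenset(members)))
    if planted_term_genes:
        terms.append(AnnotationMap("TERM:PLANTED", "planted enriched term",
                                   frozenset(planted_term_genes)))
    return terms


def simulate_family_map(gene_ids, seed: int = 0,
                        assigned_fraction: float = 0.25) -> pd.Series:
    """Assign a fraction of genes to the six curated gene families."""
    from .enrichment import GENE_FAMILIES

    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    n_assigned = int(round(assigned_fraction * len(gene_ids)))
    chosen = rng.choice(gene_ids, size=n_assigned, replace=False)
    fams = rng.choice(GENE_FAMILIES, size=n_assigned)
    return pd.Series(fams, index=pd.Index(chosen, name="gene_id"), name="family")


# ---------------------------------------------------------------------------
# planted substitution estimates (accounting-scale fixtures)
# ---------------------------------------------------------------------------

def simulate_substitution_estimates(n_pairs: int, n_high_ks: int,
                                    max_ks: float = 0.3,
                                    psg_fraction: float = 0.02,
                                    omega_threshold: float = 1.2,
                                    seed: int = 0) -> pd.DataFrame:
    """Directly draw a Ks/omega table with a planted filter outcome.

    Exactly ``n_high_ks`` pairs receive Ks strictly above ``max_ks`` — the
    population the Ks filter must discard — allowing genome-scale accounting
    checks without simulating millions of codons.
    """
    if n_high_ks > n_pairs:
        raise ValueError("n_high_ks cannot exceed n_pairs")
    rng = np.random.default_rng(seed)
    width = len(str(n_pairs))
    ks = rng.uniform(1e-3, max_ks, size=n_pairs)
    high = rng.choice(n_pairs, size=n_high_ks, replace=False)
    ks[high] = rng.uniform(max_ks * 1.01 + 1e-6, max_ks * 3, size=n_high_ks)
    is_psg = rng.random(n_pairs) < psg_fraction
    omega = np.where(is_psg,
                     rng.uniform(omega_threshold * 1.05, 3.0, size=n_pairs),
                     rng.uniform(0.02, omega_threshold * 0.9, size=n_pairs))
    return pd.DataFrame({
        "pair_id": [f"g{i + 1:0{width}d}__o{i + 1:0{width}d}" for i in range(n_pairs)],
        "gene_id": [f"g{i + 1:0{width}d}" for i in range(n_pairs)],
        "method": "NG86",
        "Ks": ks,
        "Ka": omega * ks,
        "omega": omega,
        "omega_true_psg": is_psg,
        "flags": "",
    })


# ---------------------------------------------------------------------------
# whole-study orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """All artifacts of one simulated study, plus ground-truth ledgers."""

    config: SimulationConfig
    pairs: list
    omega_truth: pd.DataFrame
    models: list
    te_intervals: pd.DataFrame
    te_truth: pd.DataFrame
    expression: pd.DataFrame
    expression_truth: pd.DataFrame
    retention: pd.Series
    methylation_calls: pd.DataFrame
    methylation_truth: pd.DataFrame


def simulate_study(config: SimulationConfig, with_sequences: bool = True) -> SyntheticStudy:
    """Generate one internally consistent study dataset.

    ``with_sequences=False`` skips codon-pair evolution (the slowest stage)
    for callers that only need annotation/expression/methylation layers.
    """
    if with_sequences:
        pairs, omega_truth = simulate_ortholog_pairs(config)
        gene_ids = list(omega_truth["gene_id"])
    else:
        width = len(str(config.n_genes))
        gene_ids = [f"g{i + 1:0{width}d}" for i in range(config.n_genes)]
        pairs, omega_truth = [], pd.DataFrame(
            {"pair_id": [], "gene_id": [], "omega_true": [], "is_psg_true": []}
        )
    models, te, te_truth = simulate_genome_annotation(config, gene_ids=gene_ids)
    expression, expr_truth = simulate_expression(gene_ids, config)
    retention = simulate_retention(gene_ids, config)
    rank = expression.mean(axis=1).rank(pct=True)
    calls, meth_truth = simulate_methylation(
        models, te_truth, config,
        expression_rank=rank if config.meth_expr_coupling > 0 else None,
    )
    return SyntheticStudy(
        config=config, pairs=pairs, omega_truth=omega_truth, models=models,
        te_intervals=te, te_truth=te_truth, expression=expression,
        expression_truth=expr_truth, retention=retention,
        methylation_calls=calls, methylation_truth=meth_truth,
    )
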