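# Methods

This note documents the models, estimators, numerical choices and known
limitations of `psgscan`, and what the synthetic-data generator does and
does not emulate.

## Substitution estimation

Both estimators operate on in-frame codon alignments under the standard
nuclear genetic code. Codon columns containing gaps, `N`, other ambiguity
codes, or a stop codon in either sequence are excluded pairwise before any
counting (pairwise deletion, the common convention of yn00-style tools).

**NG86.** Each sense codon contributes synonymous site fractions: for each
of its nine single-nucleotide mutations, the mutation is synonymous iff
the amino acid is unchanged; mutations *to* a stop codon count as
nonsynonymous. Site totals satisfy S + N = 3 per codon exactly, and pair
totals average the two sequences with equal weight. Differences between
codons differing at k positions are averaged over all k! mutational
pathways; pathways passing *through* a stop codon are dropped and the
remainder renormalized. If every pathway is blocked (possible for a few
three-difference pairs), each changed position is classified by direct
amino-acid comparison — a documented fallback, not an error. Proportions
pS = Sd/S and pN = Nd/N are corrected with the Jukes–Cantor formula
d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 is flagged `saturated` and the pair is
excluded downstream. ω = Ka/Ks is undefined (NaN, flag
`omega_undefined`) when Ks = 0.

**YN00-style.** κ is estimated from near-neutral site classes: codon
positions where both codons agree on being nondegenerate (no synonymous
change possible) or fourfold-degenerate, pooled over the dataset.
Transition/transversion proportions per class are corrected with the K80
formulas (A = −½ln(1−2P−Q) + ¼ln(1−2Q), B = −½ln(1−2Q)) and
κ̂ = 2A/B per class, combined with weights proportional to class site
counts; with no informative sites κ defaults to 2 with a warning. Site
counting weights each position's mutation flux by
κ^{transition} · π_pos(target), with π from F3x4 position-specific
nucleotide frequencies (estimated from the dataset, or per pair when used
standalone); the synonymous share of flux gives S with S + N = 3 per
codon preserved. Difference counting tracks the 2×2 split
(synonymous/nonsynonymous × transition/transversion); multi-step pathways
are weighted by the product of per-step factors
κ^{ts} · ω^{nonsyn} (a floor of 10⁻⁴ keeps weights positive as ω → 0).
The π factor is deliberately omitted from pathway weights so the
estimate is exactly symmetric in the two sequences. Distances apply the
K80 correction per site class (Ks from the transitional/transversional
synonymous proportions, Ka likewise), and ω is iterated to relative
convergence 10⁻⁶ with a cap of 100 iterations (flag `non_converged` on
the rare non-convergent pair; the last iterate is returned). No
bit-compatibility with any external implementation is claimed; the
estimator is validated by parameter recovery on simulated data (median
ω̂ within ±0.15 of truth at ω = 1, and within the documented bands at
ω = 0.2 and 2 for 500-codon pairs).

## The screen

Pairs with Ks strictly above `max_ks` (default 0.3) are discarded;
undefined (saturated) Ks is counted separately so that
|retained| + |removed| + |undefined| = |input| always holds. Among
retained pairs, PSG ⇔ ω defined and strictly above `omega_threshold`
(default 1.2); Ks = 0 pairs form an explicit `undefined` tier rather than
being dropped, keeping the accounting chain auditable. All counts are
pairs (one focal-genome gene per pair).

## Distribution tests

The 2×C (PSG/non-PSG × chromosome) table is tested with the Pearson
chi-square (no continuity correction, df = C−1) and a Fisher exact
probability test — exact for 2×2, otherwise Monte-Carlo: B tables with the
observed margins are drawn by Patefield sampling
(`scipy.stats.random_table`) and p = (1 + #{P(T) ≤ P(obs)})/(B + 1).
B defaults to 2000. The randomization test uses as statistic the Pearson
chi-square of per-chromosome PSG counts against expectation proportional
to per-chromosome gene totals; the null redraws equally sized gene sets
uniformly from the universe, realized as multivariate hypergeometric
count draws (the identical distribution, vectorized). Empirical p-values
use the plus-one rule and can never be 0. The published randomization
procedure this emulates is cited but not specified in detail anywhere we
could follow; the statistic and null above are this package's explicit
instantiation.

## Enrichment

Hypergeometric upper tail P(X ≥ k) for X ~ Hypergeom(N, K, n), with the
Ks-filtered pair set as the default background universe, and
Benjamini–Hochberg adjustment across terms (the raw p column is always
co-reported; depletion is available behind `direction="under"`). The
six-family analysis (resistance genes, protein kinases, transcription
factors, flower, auxin, glucosinolate) builds the 2×6 table in fixed
family order and reuses the distribution-module tests; it also reports
the transcription-factor share of family-assigned PSGs.

## Expression

A gene is *expressed* in a tissue when FPKM ≥ `expressed_threshold`. No
universal threshold exists for FPKM data; the default 1.0 is the common
pragmatic choice and every class-dependent output records the value used.
Breadth classes: specific (exactly 1 of 6 tissues), constitutive (6),
silent (0), intermediate (2–5). Group comparisons use Mann–Whitney
(two-sided, tie-corrected), Kruskal–Wallis, or one-sided Welch t with a
caller-specified direction. WGT stratification reports PSG fraction and
PSG mean FPKM ± SE per retention class (1/2/3 copies), a Monte-Carlo
Fisher test on the 2×3 count table and a KW test on expression across
classes; empty classes are flagged undefined rather than silently
omitted.

## Methylation

Genes are partitioned into five regions in 0-based half-open coordinates:
promoter (`promoter_length` bp immediately 5′ of the TSS, strand-aware,
truncated at position 0; default 2000 bp — a conventional span, always
recorded in outputs), UTR5/UTR3 (exonic segments outside the CDS span,
strand-aware), exon (coding exon segments) and intron (inter-exon gaps).
The four transcribed regions tile the transcript span exactly, which
yields an exact read-count conservation invariant used in tests. The
aggregate statistic is the *weighted* methylation level — total
methylated reads over total reads across a region's cytosines of one
context — the standard WGBS aggregate; an unweighted per-site mean is
available via `site_average=True`. Cytosine strand is ignored for
aggregation (contexts arrive annotated per cytosine). TE stratification
flags a gene's region "with TE" when ≥ 1 bp overlaps any TE interval
(half-open adjacency is no overlap), per region rather than per gene. The
methylation–expression association is the Spearman correlation of
gene-body weighted methylation (UTR5+exon+intron+UTR3 by default) against
mean FPKM over the six tissues, requiring ≥ 3 complete gene pairs.

## Synthetic data generator

The generator emulates the study's data layers at desk scale with full
determinism under one seed, and emits ground-truth ledgers (true ω per
pair, breadth class labels, TE overlaps, per-region methylation rates)
that drive parameter-recovery tests.

* **Codon pairs.** A uniform sense-codon ancestor evolves along two
  independent lineages for t/2 each under a GY94-style continuous-time
  process: single-nucleotide changes only, rate
  κ^{ts} · ω^{nonsyn} / (2 + κ), stop-codon targets forbidden. The
  normalization makes a fully neutral position evolve at unit rate, so t
  is the expected pairwise divergence per neutral site. Simulation is
  exact (vectorized per-codon exponential waiting times), not a matrix
  exponential. Defaults: 300 codons, κ = 2, t = 0.15 (a recently diverged
  congeneric pair whose typical Ks sits well below the 0.3 cutoff, so the
  Ks filter removes only outliers), 2% of pairs at ω = 2.0 and the rest at
  ω = 0.2 — echoing a screen where roughly 2% of retained pairs are
  called.
* **Genome layout.** Ten chromosomes by default; genes get 1–4 coding
  exons with UTRs attached to the terminal exons, and are spaced so that
  promoter intervals of adjacent genes can never overlap (keeping planted
  TE ground truth exact). Optional chromosome weights plant known
  clustering. TEs are dropped into a gene region with probability
  `te_insertion_rate` per region.
* **Expression.** Planted breadth classes (defaults 20% specific / 30%
  constitutive / 40% intermediate / 10% silent); expressed entries are
  `fpkm_scale·(1 + LogNormal(0, 0.6))` and unexpressed ones
  Uniform(0, threshold/2), so labels are exactly recoverable whenever
  `fpkm_scale ≥ expressed_threshold`.
* **Methylation.** One cytosine per `site_spacing` bp per region; context
  drawn (CG 35% / CHG 30% / CHH 35%); per-site rate Beta-distributed
  around the region×context mean (defaults echo plant genic profiles:
  CG concentrated in introns/UTRs ≈ 0.3, exon/promoter low, CHG mostly
  intronic, CHH near zero); coverage Poisson (default mean 20); counts
  binomial. A TE-overlapping region shifts its mean by
  `te_methylation_effect` (default +0.2), and `meth_expr_coupling > 0`
  plants a negative methylation–expression trend. Effect sizes for these
  couplings are free generator parameters, not estimates of any real
  genome.
* **Genome-scale accounting fixtures.** For checks at the 24,219-pair
  scale the generator draws Ks/ω tables directly with an exact planted
  number of above-cutoff pairs, instead of evolving millions of codons.

What the generator does **not** emulate: indels and alignment error,
recombination, realistic chromosome sequence (only cytosine positions and
contexts are placed), GO-DAG structure in annotation terms, tissue-level
methylomes, and any dependence of ω on gene function. Passing tests
therefore demonstrate correctness of the estimators and pipeline logic
under the stated generative model, not biological conclusions about real
genomes.

## Problem sizes and numerical choices

Test-suite and demo sizes are chosen for desk-scale runs: 100 replicates
of 500-codon pairs for ω recovery, 200 replicates at B = 499 for
permutation calibration, B = 2000 for Monte-Carlo Fisher (at which the
plus-one floor is 1/2001 ≈ 5.0e-4), ~10⁴ cytosines for rate-recovery
checks. Monte-Carlo table-probability comparisons use a 10⁻⁹ log-scale
tolerance for the ≤ test; the YN00 iteration tolerance is 10⁻⁶ (relative)
with a 100-iteration cap; Beta concentration for site rates defaults
to 30.

## Known limitations

* The YN00-style estimator is a faithful counting scheme in the YN00
  family, not a reimplementation of any specific program; small systematic
  offsets from other implementations are expected, and NG86 is always
  available for cross-reporting.
* NG86 pathway averaging can assign small fractional nonsynonymous counts
  between synonymous serine codons of the TCx and AGy blocks even when no
  amino-acid change occurred.
* With very small PSG sets the per-chromosome permutation test has low
  power, and methylation group tests are skipped (flagged) when a side has
  fewer than two genes.
* The first mRNA of a multi-transcript gene defines its model; alternative
  isoforms are ignored.
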