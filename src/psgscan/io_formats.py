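"""Readers and writers for every external file format the pipeline touches.

Coordinate conventions
----------------------
Internally every genomic interval is **0-based, half-open** ``[start, end)``.
GFF3 (1-based inclusive) and cytosine-report positions (1-based) are
converted at this boundary; BED is already 0-based half-open and passes
through unchanged. A GFF3 feature ``start=1, end=10`` and a BED line
``0 10`` therefore denote the same internal interval ``(0, 10)``.

All tabular outputs are TSV with a header line; an optional comment block of
``# key=value`` lines records the parameters that produced the file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TISSUES: tuple[str, ...] = ("root", "stem", "leaf", "flower", "silique", "callus")
CONTEXTS: tuple[str, ...] = ("CG", "CHG", "CHH")
_SEQ_ALPHABET = set("ACGTN-")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrthologPair:
    """A gene pair with an in-frame codon alignment."""

    pair_id: str
    gene_a: str
    gene_b: str
    codons_a: str
    codons_b: str

    def __post_init__(self):
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError(
                f"pair {self.pair_id}: length mismatch "
                f"({len(self.codons_a)} vs {len(self.codons_b)})"
            )
        if len(self.codons_a) % 3 != 0:
            raise ValueError(
                f"pair {self.pair_id}: length {len(self.codons_a)} not divisible by 3"
            )
        for name, seq in (("codons_a", self.codons_a), ("codons_b", self.codons_b)):
            bad = set(seq) - _SEQ_ALPHABET
            if bad:
                raise ValueError(
                    f"pair {self.pair_id}: {name} has invalid characters {sorted(bad)}"
                )

    @property
    def n_codons(self) -> int:
        return len(self.codons_a) // 3


@dataclass(frozen=True)
class GeneModel:
    """Gene structure in internal 0-based half-open coordinates.

    ``exons`` are sorted, non-overlapping ``(start, end)`` tuples;
    ``cds_start``/``cds_end`` delimit the CDS span (strand-agnostic
    genomic order: cds_start < cds_end regardless of strand).
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: empty transcript span")
        if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
            raise ValueError(f"{self.gene_id}: CDS outside transcript span")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon ({s},{e})")
            if s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene without exons")

    @property
    def tss(self) -> int:
        """Transcription start: tx_start on +, tx_end on - (half-open)."""
        return self.tx_start if self.strand == "+" else self.tx_end


class MethylationCall(NamedTuple):
    """One cytosine: position is internal 0-based."""

    chrom: str
    pos: int
    strand: str
    context: str
    count_methylated: int
    count_total: int

    @property
    def covered(self) -> bool:
        return self.count_total > 0


@dataclass
class AnnotationMap:
    """One functional term (GO/pathway/family) and its member genes."""

    term_id: str
    term_name: str
    genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"term {self.term_id}: empty gene set")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a TSV with an optional '# key=value' comment block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (params or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# ortholog FASTA pairs
# ---------------------------------------------------------------------------

def read_ortholog_fasta(path_a, path_b, pairing) -> list[OrthologPair]:
    """Load paired CDS alignments from two FASTAs and a pairing table.

    ``pairing`` is a TSV path or DataFrame with columns ``gene_a``,
    ``gene_b`` and optionally ``pair_id`` (default ``gene_a__gene_b``).
    Sequences are upper-cased; every contract violation is reported with the
    offending pair or gene id.
    """
    if not isinstance(pairing, pd.DataFrame):
        pairing = read_tsv(pairing)
    for col in ("gene_a", "gene_b"):
        if col not in pairing.columns:
            raise ValueError(f"pairing table lacks column {col!r}")
    seqs_a = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path_a), "fasta")}
    seqs_b = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path_b), "fasta")}
    pairs = []
    for row in pairing.itertuples(index=False):
        ga, gb = row.gene_a, row.gene_b
        pid = getattr(row, "pair_id", None) or f"{ga}__{gb}"
        if ga not in seqs_a:
            raise KeyError(f"gene {ga!r} absent from {path_a}")
        if gb not in seqs_b:
            raise KeyError(f"gene {gb!r} absent from {path_b}")
        pairs.append(OrthologPair(pid, ga, gb, seqs_a[ga], seqs_b[gb]))
    return pairs


def write_ortholog_fasta(pairs: Iterable[OrthologPair], path_a, path_b, pairing_path):
    """Inverse of :func:`read_ortholog_fasta` (byte-stable round trip)."""
    pairs = list(pairs)
    SeqIO.write(
        (SeqRecord(Seq(p.codons_a), id=p.gene_a, description="") for p in pairs),
        str(path_a), "fasta",
    )
    SeqIO.write(
        (SeqRecord(Seq(p.codons_b), id=p.gene_b, description="") for p in pairs),
        str(path_b), "fasta",
    )
    write_tsv(
        pd.DataFrame(
            {"pair_id": [p.pair_id for p in pairs],
             "gene_a": [p.gene_a for p in pairs],
             "gene_b": [p.gene_b for p in pairs]}
        ),
        pairing_path,
    )


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def _gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path) -> list[GeneModel]:
    """Parse gene models from GFF3 (gene/mRNA/exon/CDS features).

    The first mRNA of each gene is used. GFF3 1-based inclusive coordinates
    become internal 0-based half-open intervals.
    """
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            start0, end0 = int(start) - 1, int(end)
            a = _gff_attributes(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise ValueError("gene feature without ID")
                genes[gid] = {
                    "chrom": chrom, "strand": strand,
                    "tx_start": start0, "tx_end": end0,
                    "mrna": None, "exons": [], "cds": [],
                }
            elif ftype == "mRNA":
                gid = a.get("Parent")
                mid = a.get("ID")
                if gid in genes and genes[gid]["mrna"] is None:
                    genes[gid]["mrna"] = mid
                    mrna_to_gene[mid] = gid
            elif ftype in ("exon", "CDS"):
                parent = a.get("Parent")
                gid = mrna_to_gene.get(parent, parent if parent in genes else None)
                if gid is None:
                    continue
                if genes[gid]["mrna"] is not None and parent not in (
                    genes[gid]["mrna"], gid
                ):
                    continue  # secondary transcript
                genes[gid]["exons" if ftype == "exon" else "cds"].append(
                    (start0, end0)
                )
    models = []
    for gid, g in genes.items():
        exons = tuple(sorted(g["exons"]))
        if not exons:
            exons = ((g["tx_start"], g["tx_end"]),)
        if not g["cds"]:
            cds_start, cds_end = exons[0][0], exons[-1][1]
        else:
            cds_start = min(s for s, _ in g["cds"])
            cds_end = max(e for _, e in g["cds"])
        models.append(
            GeneModel(
                gene_id=gid, chrom=g["chrom"], strand=g["strand"],
                tx_start=g["tx_start"], tx_end=g["tx_end"],
                exons=exons, cds_start=cds_start, cds_end=cds_end,
            )
        )
    return models


def write_gff3(models: Iterable[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene + mRNA + exon + CDS rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            def row(ftype, s0, e0, attrs):
                fh.write(
                    f"{m.chrom}\t.\t{ftype}\t{s0 + 1}\t{e0}\t.\t{m.strand}\t.\t{attrs}\n"
                )

            mid = f"{m.gene_id}.1"
            row("gene", m.tx_start, m.tx_end, f"ID={m.gene_id}")
            row("mRNA", m.tx_start, m.tx_end, f"ID={mid};Parent={m.gene_id}")
            for s, e in m.exons:
                row("exon", s, e, f"Parent={mid}")
            for s, e in m.exons:
                cs, ce = max(s, m.cds_start), min(e, m.cds_end)
                if cs < ce:
                    row("CDS", cs, ce, f"Parent={mid}")


# ---------------------------------------------------------------------------
# cytosine report (Bismark CX dialect)
# ---------------------------------------------------------------------------

_CX_COLUMNS = ["chrom", "pos", "strand", "count_methylated", "count_unmethylated",
               "context"]


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a Bismark-style cytosine report into a calls DataFrame.

    Columns of the result: chrom, pos (0-based), strand, context,
    count_methylated, count_total, covered. Rows with zero total reads are
    retained but flagged ``covered=False``.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=_CX_COLUMNS,
                     dtype={"chrom": str})
    bad_ctx = set(df["context"]) - set(CONTEXTS)
    if bad_ctx:
        raise ValueError(f"unknown methylation context tokens: {sorted(bad_ctx)}")
    if (df["count_methylated"] < 0).any() or (df["count_unmethylated"] < 0).any():
        raise ValueError("negative read counts in cytosine report")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"].astype(int) - 1,
            "strand": df["strand"],
            "context": df["context"],
            "count_methylated": df["count_methylated"].astype(int),
            "count_total": (df["count_methylated"] + df["count_unmethylated"]).astype(int),
        }
    )
    out["covered"] = out["count_total"] > 0
    return out


def write_cytosine_report(calls: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "pos": calls["pos"] + 1,
            "strand": calls["strand"],
            "count_methylated": calls["count_methylated"],
            "count_unmethylated": calls["count_total"] - calls["count_methylated"],
            "context": calls["context"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def iter_calls(calls: pd.DataFrame):
    """Yield MethylationCall records from a calls DataFrame."""
    for row in calls.itertuples(index=False):
        yield MethylationCall(row.chrom, row.pos, row.strand, row.context,
                              row.count_methylated, row.count_total)


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_bed_intervals(path) -> pd.DataFrame:
    """Read BED3+ into a DataFrame (chrom, start, end), 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError("BED file needs at least 3 columns")
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    out["start"] = out["start"].astype(int)
    out["end"] = out["end"].astype(int)
    bad = out[out["start"] >= out["end"]]
    if len(bad):
        first = bad.iloc[0]
        raise ValueError(
            f"empty/inverted BED interval {first.chrom}:{first.start}-{first.end}"
        )
    return out


def write_bed_intervals(intervals: pd.DataFrame, path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# expression matrix, annotation maps, retention classes
# ---------------------------------------------------------------------------

def read_expression_matrix(path) -> pd.DataFrame:
    """FPKM matrix: gene rows x exactly the six canonical tissue columns.

    Extra or missing tissue columns are an error, not silently ignored:
    a mislabeled column would otherwise corrupt every breadth class.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    cols = list(df.columns)
    if set(cols) != set(TISSUES):
        raise ValueError(
            f"expression matrix must have exactly the tissue columns {TISSUES}, "
            f"got {cols}"
        )
    df = df[list(TISSUES)]
    if (df.values < 0).any():
        raise ValueError("negative FPKM values")
    if df.index.has_duplicates:
        raise ValueError("duplicate gene ids in expression matrix")
    return df


def write_expression_matrix(matrix: pd.DataFrame, path, params=None) -> None:
    out = matrix.reset_index(names="gene_id")
    write_tsv(out, path, params)


def read_annotation_map(path) -> list[AnnotationMap]:
    """TSV with columns term_id, term_name, gene_id (one row per membership)."""
    df = read_tsv(path)
    for col in ("term_id", "term_name", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"annotation map lacks column {col!r}")
    out = []
    for (tid, tname), grp in df.groupby(["term_id", "term_name"], sort=True):
        out.append(AnnotationMap(tid, tname, frozenset(grp["gene_id"])))
    return out


def read_retention_classes(path) -> pd.Series:
    """TSV with columns gene_id, retention_class in {1,2,3}."""
    df = read_tsv(path)
    for col in ("gene_id", "retention_class"):
        if col not in df.columns:
            raise ValueError(f"retention table lacks column {col!r}")
    cls = df.set_index("gene_id")["retention_class"].astype(int)
    bad = set(cls.unique()) - {1, 2, 3}
    if bad:
        raise ValueError(f"retention classes must be 1, 2 or 3; got {sorted(bad)}")
    return cls


def gene_chromosomes(models: Iterable[GeneModel]) -> pd.Series:
    """gene_id -> chromosome Series from a collection of gene models."""
    data = {m.gene_id: m.chrom for m in models}
    return pd.Series(data, name="chrom")
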