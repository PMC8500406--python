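"""Standard nuclear genetic code, codon classification, and mutation geometry.

The code table is plain data so an alternative table could be injected, but
every public entry point in the package uses the standard code: the pipeline
targets nuclear plant genes.
"""

from __future__ import annotations

from itertools import product

NUCLEOTIDES = "TCAG"

#: codon -> one-letter amino acid, '*' for stop (standard code, NCBI table 1)
CODON_TABLE: dict[str, str] = {
    "".join(c): aa
    for c, aa in zip(
        product(NUCLEOTIDES, repeat=3),
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG",
    )
}

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    if a == b:
        raise ValueError("identical nucleotides are not a change")
    return (a in _PURINES and b in _PURINES) or (
        a in _PYRIMIDINES and b in _PYRIMIDINES
    )


def translate(codon: str) -> str:
    """Amino acid for a codon; raises on ambiguous/gapped codons."""
    try:
        return CODON_TABLE[codon]
    except KeyError:
        raise ValueError(f"not an unambiguous codon: {codon!r}") from None


def is_sense(codon: str) -> bool:
    return CODON_TABLE.get(codon, "*") != "*"


def single_mutations(codon: str):
    """Yield (position, target_nt, mutant_codon) for all 9 single changes."""
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                yield pos, nt, codon[:pos] + nt + codon[pos + 1 :]


def differing_positions(a: str, b: str) -> list[int]:
    return [i for i in range(3) if a[i] != b[i]]
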