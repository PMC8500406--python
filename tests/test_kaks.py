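"""Unit and property tests for the Ka/Ks counting estimators."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq

from psgscan.genetic_code import SENSE_CODONS
from psgscan.io_formats import OrthologPair
from psgscan.kaks import (
    codon_sites_ng86,
    count_differences_ng86,
    estimate_codon_frequencies,
    estimate_kappa_yn00,
    kaks_ng86,
    kaks_table,
    kaks_yn00,
)
from psgscan.synthetic import simulate_codon_pair


def _brute_force_sites(codon):
    """Independent oracle: enumerate all 9 mutations with Biopython."""
    aa = str(Seq(codon).translate())
    syn = 0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1:]
            if str(Seq(mutant).translate()) == aa:
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def test_site_counts_match_enumeration_for_all_sense_codons():
    for codon in SENSE_CODONS:
        s, n = codon_sites_ng86(codon)
        s_ref, n_ref = _brute_force_sites(codon)
        assert s == pytest.approx(s_ref) and n == pytest.approx(n_ref)
        assert s + n == pytest.approx(3.0)


@pytest.mark.parametrize("codon,expected", [
    ("TTT", (1 / 3, 8 / 3)),
    ("GGG", (1.0, 2.0)),
    ("TGG", (0.0, 3.0)),  # Trp: no synonymous single change exists
])
def test_site_counts_worked_examples(codon, expected):
    assert codon_sites_ng86(codon) == pytest.approx(expected)


def test_site_counts_reject_stop_and_ambiguous_codons():
    with pytest.raises(ValueError):
        codon_sites_ng86("TAA")
    with pytest.raises(ValueError):
        codon_sites_ng86("ANT")


@pytest.mark.parametrize("a,b,expected", [
    ("TTT", "TTC", (1.0, 0.0)),  # single synonymous change
    ("AAA", "AAA", (0.0, 0.0)),
    # two pathways TTT->GTT->GTA and TTT->TTA->GTA, averaged
    ("TTT", "GTA", (0.5, 1.5)),
])
def test_pathway_averaged_differences(a, b, expected):
    assert count_differences_ng86(a, b) == pytest.approx(expected)


def test_difference_counts_sum_to_number_of_differing_positions(rng):
    codons = rng.choice(SENSE_CODONS, size=40)
    partners = rng.choice(SENSE_CODONS, size=40)
    for a, b in zip(codons, partners):
        sd, nd = count_differences_ng86(a, b)
        k = sum(x != y for x, y in zip(a, b))
        assert sd + nd == pytest.approx(k)
        assert count_differences_ng86(b, a) == pytest.approx((sd, nd))


def test_ng86_worked_pair():
    pair = OrthologPair("p", "a", "b", "TTTGGGGGG", "TTCGGGGGG")
    est = kaks_ng86(pair)
    assert est.S == pytest.approx(7 / 3)
    assert est.N == pytest.approx(20 / 3)
    assert (est.Sd, est.Nd) == pytest.approx((1.0, 0.0))
    assert est.pS == pytest.approx(3 / 7)
    assert est.Ks == pytest.approx(0.6355, abs=1e-4)
    assert est.Ka == 0.0


def test_identical_sequences_have_zero_distances_and_undefined_omega():
    pair = OrthologPair("p", "a", "b", "ATGGCT", "ATGGCT")
    est = kaks_ng86(pair)
    assert est.Ks == 0.0 and est.Ka == 0.0
    assert math.isnan(est.omega)
    assert "omega_undefined" in est.flags


def test_omega_zero_simulation_gives_negligible_ka():
    """With omega=0 both proteins are identical, so Ka collapses to ~0.

    Nd is not exactly zero in every replicate: pathway averaging between
    synonymous codons of serine's two disconnected codon blocks can assign
    fractional nonsynonymous counts even without amino-acid change.
    """
    for seed in range(4):
        pair = simulate_codon_pair(0.0, 2.0, 0.6, 200, seed=seed)
        est = kaks_ng86(pair)
        assert est.Nd <= 2.0
        assert est.Ka <= 0.01


def test_sites_and_differences_invariants_on_simulated_pairs(rng):
    for seed in range(5):
        pair = simulate_codon_pair(0.8, 2.0, 0.4, 120, seed=seed)
        est = kaks_ng86(pair)
        assert est.S + est.N == pytest.approx(3 * est.n_codons_used)
        # estimator symmetry in the two sequences
        swapped = OrthologPair(pair.pair_id, pair.gene_b, pair.gene_a,
                               pair.codons_b, pair.codons_a)
        est2 = kaks_ng86(swapped)
        for field in ("S", "N", "Sd", "Nd", "Ks", "Ka"):
            assert getattr(est, field) == pytest.approx(getattr(est2, field))


def test_ambiguous_and_gap_codons_are_dropped_pairwise():
    pair = OrthologPair("p", "a", "b", "ATGNNNGGG", "ATGAAAGG-")
    est = kaks_ng86(pair)
    assert est.n_codons_used == 1  # only the ATG column survives


def test_yn00_symmetry():
    pair = simulate_codon_pair(1.5, 3.0, 0.4, 150, seed=9)
    swapped = OrthologPair(pair.pair_id, pair.gene_b, pair.gene_a,
                           pair.codons_b, pair.codons_a)
    e1, e2 = kaks_yn00(pair), kaks_yn00(swapped)
    for field in ("S", "N", "Sd", "Nd", "Ks", "Ka"):
        assert getattr(e1, field) == pytest.approx(getattr(e2, field))


def test_yn00_sites_reduce_to_ng86_at_kappa_one_uniform_frequencies():
    pair = simulate_codon_pair(1.0, 1.0, 0.3, 300, seed=3)
    uniform = np.full(len(SENSE_CODONS), 1 / len(SENSE_CODONS))
    est_yn = kaks_yn00(pair, codon_frequencies=uniform, kappa=1.0)
    est_ng = kaks_ng86(pair)
    assert est_yn.S == pytest.approx(est_ng.S, rel=0.02)
    assert est_yn.N == pytest.approx(est_ng.N, rel=0.02)


@pytest.mark.parametrize("kappa_true,tol", [(1.0, 0.3), (4.0, 1.0)])
def test_kappa_recovery_at_ten_thousand_codons(kappa_true, tol):
    pairs = [simulate_codon_pair(1.0, kappa_true, 0.3, 2000, seed=s)
             for s in range(5)]
    assert estimate_kappa_yn00(pairs) == pytest.approx(kappa_true, abs=tol)


def test_kappa_defaults_when_no_differences():
    pair = OrthologPair("p", "a", "b", "ATGGCT", "ATGGCT")
    with pytest.warns(RuntimeWarning):
        assert estimate_kappa_yn00(pair) == 2.0


def test_f3x4_frequencies_sum_to_one_and_track_composition():
    pair = OrthologPair("p", "a", "b", "ATGATGATG", "ATGATGATG")
    freqs = estimate_codon_frequencies(pair)
    assert freqs.sum() == pytest.approx(1.0)
    # with only ATG codons the F3x4 estimate puts all mass on ATG
    assert freqs[SENSE_CODONS.index("ATG")] == pytest.approx(1.0)


def test_kaks_table_batches_both_methods():
    pairs = [simulate_codon_pair(0.5, 2.0, 0.3, 80, seed=s) for s in range(3)]
    pairs = [OrthologPair(f"p{i}", f"a{i}", f"b{i}", p.codons_a, p.codons_b)
             for i, p in enumerate(pairs)]
    for method in ("NG86", "YN00"):
        df = kaks_table(pairs, method=method)
        assert list(df["pair_id"]) == ["p0", "p1", "p2"]
        assert (df["method"] == method).all()
        assert (df["Ks"] >= 0).all()
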