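"""Pairwise Ka/Ks estimation by codon counting.

Two counting estimators are provided:

* **NG86** (Nei & Gojobori 1986): synonymous/nonsynonymous site fractions per
  codon, pathway-averaged difference counts, and a Jukes-Cantor correction
  applied separately to the synonymous and nonsynonymous proportions.
* **YN00-style** (after Yang & Nielsen 2000): sites weighted by the
  transition/transversion rate ratio kappa and F3x4 codon frequencies,
  differences split into transitional and transversional classes, a
  K80 two-parameter correction per site class, and iterative reweighting of
  multi-step pathways by the current omega estimate. No bit-compatibility
  with any external program is claimed; the estimator is validated by
  parameter recovery on simulated alignments.

Conventions shared by both methods (documented here once):

* mutations *to* a stop codon count as nonsynonymous in site counting;
* mutational pathways passing *through* a stop codon are skipped in
  difference counting and the remaining pathways renormalized (if every
  pathway is blocked, each differing position is classified by direct
  amino-acid comparison);
* codon columns containing gaps, N, other ambiguity codes, or a stop codon
  in either sequence are dropped pairwise before counting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .genetic_code import (
    NUCLEOTIDES,
    SENSE_CODONS,
    differing_positions,
    is_sense,
    is_transition,
    single_mutations,
    translate,
)
from .io_formats import OrthologPair

DEFAULT_KAPPA = 2.0  # fallback when no informative sites exist
_OMEGA_FLOOR = 1e-4  # keeps pathway weights positive inside the YN00 iteration


@dataclass
class SubstitutionEstimate:
    """Per-pair substitution summary; the unit record of the screen."""

    pair_id: str
    method: str  # "NG86" or "YN00"
    S: float  # synonymous sites
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences
    pS: float
    pN: float
    Ks: float  # NaN when saturated/undefined
    Ka: float
    omega: float  # NaN when Ks == 0 or Ks undefined
    kappa: float = math.nan  # estimated for YN00 only
    n_codons_used: int = 0
    flags: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

def codon_sites_ng86(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    Each of the nine single-nucleotide mutations contributes 1/3 of a site
    to the synonymous or nonsynonymous tally; S + N = 3 exactly.
    """
    aa = translate(codon)
    if aa == "*":
        raise ValueError(f"stop codon has no site decomposition: {codon}")
    syn = 0.0
    for _pos, _nt, mutant in single_mutations(codon):
        if translate(mutant) == aa:  # stop mutants translate to '*': nonsyn
            syn += 1.0
    s_sites = syn / 3.0
    return s_sites, 3.0 - s_sites


_NG86_SITES: dict[str, tuple[float, float]] = {
    c: codon_sites_ng86(c) for c in SENSE_CODONS
}


def _pathway_steps(a: str, b: str):
    """All orderings of the differing positions, as lists of codon steps."""
    diff = differing_positions(a, b)
    for order in permutations(diff):
        steps = []
        cur = a
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            steps.append((cur, nxt, pos))
            cur = nxt
        yield steps


def count_differences_ng86(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts.

    With k differing positions the k! mutational pathways are averaged with
    equal weight; pathways that pass through a stop codon are excluded and
    the remainder renormalized. Sd + Nd = k.
    """
    if not (is_sense(codon_a) and is_sense(codon_b)):
        raise ValueError(f"both codons must be sense codons: {codon_a}, {codon_b}")
    if codon_a == codon_b:
        return 0.0, 0.0
    syn_tot = nsyn_tot = 0.0
    n_valid = 0
    for steps in _pathway_steps(codon_a, codon_b):
        if any(not is_sense(nxt) for _cur, nxt, _pos in steps[:-1]):
            continue  # intermediate stop
        n_valid += 1
        for cur, nxt, _pos in steps:
            if translate(cur) == translate(nxt):
                syn_tot += 1.0
            else:
                nsyn_tot += 1.0
    k = len(differing_positions(codon_a, codon_b))
    if n_valid == 0:
        # documented fallback: classify each changed position directly
        syn = float(translate(codon_a) == translate(codon_b)) * k
        return syn, k - syn
    return syn_tot / n_valid, nsyn_tot / n_valid


_NG86_DIFFS: dict[tuple[str, str], tuple[float, float]] = {}


def _ng86_diffs_cached(a: str, b: str) -> tuple[float, float]:
    key = (a, b) if a <= b else (b, a)
    try:
        return _NG86_DIFFS[key]
    except KeyError:
        v = count_differences_ng86(key[0], key[1])
        _NG86_DIFFS[key] = v
        return v


def iter_codon_columns(pair: OrthologPair):
    """Yield analyzable (codon_a, codon_b) columns of an ortholog pair."""
    a, b = pair.codons_a, pair.codons_b
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if is_sense(ca) and is_sense(cb):
            yield ca, cb


def _jukes_cantor(p: float) -> float:
    """JC69 distance from a proportion of differences; NaN when saturated."""
    if p < 0:
        raise ValueError("negative proportion")
    if p == 0:
        return 0.0
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def kaks_ng86(pair: OrthologPair) -> SubstitutionEstimate:
    """NG86 Ka, Ks and omega for one in-frame ortholog pair."""
    S = N = Sd = Nd = 0.0
    n_used = 0
    for ca, cb in iter_codon_columns(pair):
        sa, na = _NG86_SITES[ca]
        sb, nb = _NG86_SITES[cb]
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        sd, nd = _ng86_diffs_cached(ca, cb)
        Sd += sd
        Nd += nd
        n_used += 1
    if n_used == 0:
        raise ValueError(f"pair {pair.pair_id}: no analyzable codon columns")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(pS)
    Ka = _jukes_cantor(pN)
    flags = []
    if math.isnan(Ks) or math.isnan(Ka):
        flags.append("saturated")
    omega = math.nan
    if not math.isnan(Ks) and not math.isnan(Ka):
        if Ks > 0:
            omega = Ka / Ks
        else:
            flags.append("omega_undefined")
    return SubstitutionEstimate(
        pair_id=pair.pair_id, method="NG86", S=S, N=N, Sd=Sd, Nd=Nd,
        pS=pS, pN=pN, Ks=Ks, Ka=Ka, omega=omega,
        n_codons_used=n_used, flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# YN00-style estimator
# ---------------------------------------------------------------------------

def estimate_codon_frequencies(pairs) -> np.ndarray:
    """F3x4 codon frequencies from one pair or a collection of pairs.

    Position-specific nucleotide frequencies are tallied over both sequences;
    the product over the three codon positions, restricted to sense codons
    and renormalized, gives the 61-vector of equilibrium codon frequencies.
    """
    if isinstance(pairs, OrthologPair):
        pairs = [pairs]
    counts = np.zeros((3, 4))  # position x nucleotide (order NUCLEOTIDES)
    nt_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    for pair in pairs:
        for seq in (pair.codons_a, pair.codons_b):
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if is_sense(codon):
                    for pos in range(3):
                        counts[pos, nt_index[codon[pos]]] += 1
    if counts.sum() == 0:
        raise ValueError("no sense codons to estimate frequencies from")
    pos_freq = counts / counts.sum(axis=1, keepdims=True)
    freqs = np.array(
        [
            pos_freq[0, nt_index[c[0]]]
            * pos_freq[1, nt_index[c[1]]]
            * pos_freq[2, nt_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    total = freqs.sum()
    if total <= 0:
        raise ValueError("degenerate F3x4 estimate")
    return freqs / total


def _position_degeneracy(codon: str, pos: int) -> int:
    """Number of the 3 possible changes at pos that are synonymous (0..3)."""
    aa = translate(codon)
    syn = 0
    for nt in NUCLEOTIDES:
        if nt == codon[pos]:
            continue
        mutant = codon[:pos] + nt + codon[pos + 1 :]
        if translate(mutant) == aa:
            syn += 1
    return syn


def _k80_distance(P: float, Q: float) -> tuple[float, float, float]:
    """K80 distance and its transition/transversion components.

    Returns (d, A, B): A transitions per site, B transversions per site,
    d = A + B. NaN components signal saturation.
    """
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return math.nan, math.nan, math.nan
    A = -0.5 * math.log(w1) + 0.25 * math.log(w2)
    B = -0.5 * math.log(w2)
    return A + B, A, B


def estimate_kappa_yn00(pairs) -> float:
    """Transition/transversion rate ratio from near-neutral site classes.

    Fourfold-degenerate and nondegenerate codon positions (where both codons
    of a column agree on the degeneracy class) are pooled separately;
    transition and transversion proportions in each class are corrected with
    the K80 formulas and kappa = 2A/B estimated per class, then averaged with
    weights proportional to the class site counts. Falls back to
    ``DEFAULT_KAPPA`` (with a warning) when neither class is informative.
    """
    if isinstance(pairs, OrthologPair):
        pairs = [pairs]
    if not pairs:
        raise ValueError("at least one pair required")
    # class 0: nondegenerate, class 1: fourfold-degenerate
    sites = [0.0, 0.0]
    ts = [0.0, 0.0]
    tv = [0.0, 0.0]
    for pair in pairs:
        for ca, cb in iter_codon_columns(pair):
            for pos in range(3):
                da, db = _position_degeneracy(ca, pos), _position_degeneracy(cb, pos)
                if da == 0 and db == 0:
                    cls = 0
                elif da == 3 and db == 3:
                    cls = 1
                else:
                    continue
                sites[cls] += 1.0
                if ca[pos] != cb[pos]:
                    if is_transition(ca[pos], cb[pos]):
                        ts[cls] += 1.0
                    else:
                        tv[cls] += 1.0
    kappas, weights = [], []
    for cls in (0, 1):
        if sites[cls] == 0:
            continue
        P, Q = ts[cls] / sites[cls], tv[cls] / sites[cls]
        _d, A, B = _k80_distance(P, Q)
        if math.isnan(A) or B <= 0 or A <= 0:
            continue
        kappas.append(2.0 * A / B)
        weights.append(sites[cls])
    if not kappas:
        warnings.warn(
            "no informative fourfold/nondegenerate sites; "
            f"kappa defaults to {DEFAULT_KAPPA}",
            RuntimeWarning,
            stacklevel=2,
        )
        return DEFAULT_KAPPA
    return float(np.average(kappas, weights=weights))


def _yn00_site_counts(
    codon: str, kappa: float, freqs: np.ndarray, nt_pos_freq: np.ndarray
) -> tuple[float, float]:
    """Mutation-flux-weighted S/N site counts for one codon.

    At each position the flux toward target nucleotide j is
    kappa^{ts(i,j)} * pi_pos(j); the synonymous share of that flux, summed
    over positions, gives S (stop targets count as nonsynonymous flux).
    S + N = 3 per codon.
    """
    aa = translate(codon)
    nt_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    s_sites = 0.0
    for pos in range(3):
        flux_syn = flux_tot = 0.0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            w = (kappa if is_transition(codon[pos], nt) else 1.0) * nt_pos_freq[
                pos, nt_index[nt]
            ]
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            flux_tot += w
            if translate(mutant) == aa:
                flux_syn += w
        if flux_tot > 0:
            s_sites += flux_syn / flux_tot
    return s_sites, 3.0 - s_sites


def _yn00_count_pair_diffs(
    codon_a: str, codon_b: str, kappa: float, omega: float
) -> np.ndarray:
    """Weighted (Sd_ts, Sd_tv, Nd_ts, Nd_tv) between two codons.

    Pathways are weighted by the product over steps of
    kappa^{ts} * omega^{nonsyn}; stop-codon intermediates invalidate a
    pathway. The NG86 direct-comparison fallback applies if all are blocked.
    """
    out = np.zeros(4)
    if codon_a == codon_b:
        return out
    acc = np.zeros(4)
    weight_sum = 0.0
    n_valid = 0
    for steps in _pathway_steps(codon_a, codon_b):
        if any(not is_sense(nxt) for _cur, nxt, _pos in steps[:-1]):
            continue
        n_valid += 1
        w = 1.0
        contrib = np.zeros(4)
        for cur, nxt, pos in steps:
            trans = is_transition(cur[pos], nxt[pos])
            syn = translate(cur) == translate(nxt)
            w *= (kappa if trans else 1.0) * (1.0 if syn else max(omega, _OMEGA_FLOOR))
            contrib[(0 if syn else 2) + (0 if trans else 1)] += 1.0
        acc += w * contrib
        weight_sum += w
    if n_valid == 0 or weight_sum <= 0:
        k = differing_positions(codon_a, codon_b)
        syn = translate(codon_a) == translate(codon_b)
        for pos in k:
            trans = is_transition(codon_a[pos], codon_b[pos])
            out[(0 if syn else 2) + (0 if trans else 1)] += 1.0
        return out
    return acc / weight_sum


def kaks_yn00(
    pair: OrthologPair,
    codon_frequencies: np.ndarray | None = None,
    kappa: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> SubstitutionEstimate:
    """YN00-style Ka, Ks and omega for one pair.

    Parameters
    ----------
    codon_frequencies
        F3x4 61-vector; estimated from the pair itself when omitted. Pass a
        genome-wide estimate when analyzing many pairs from one dataset.
    kappa
        Transition/transversion rate ratio; estimated from the pair when
        omitted.
    """
    if codon_frequencies is None:
        codon_frequencies = estimate_codon_frequencies(pair)
    if kappa is None:
        kappa = estimate_kappa_yn00(pair)

    # recover position-specific nucleotide frequencies from the codon vector
    nt_index = {n: i for i, n in enumerate(NUCLEOTIDES)}
    nt_pos_freq = np.zeros((3, 4))
    for c, f in zip(SENSE_CODONS, codon_frequencies):
        for pos in range(3):
            nt_pos_freq[pos, nt_index[c[pos]]] += f
    nt_pos_freq /= nt_pos_freq.sum(axis=1, keepdims=True)

    columns = list(iter_codon_columns(pair))
    if not columns:
        raise ValueError(f"pair {pair.pair_id}: no analyzable codon columns")
    site_cache: dict[str, tuple[float, float]] = {}
    S = N = 0.0
    for ca, cb in columns:
        for c in (ca, cb):
            if c not in site_cache:
                site_cache[c] = _yn00_site_counts(c, kappa, codon_frequencies, nt_pos_freq)
        sa, na = site_cache[ca]
        sb, nb = site_cache[cb]
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)

    from collections import Counter

    diff_columns = Counter(
        (ca, cb) if ca <= cb else (cb, ca) for ca, cb in columns if ca != cb
    )

    omega = 1.0
    flags: list[str] = []
    Ks = Ka = 0.0
    Sd = Nd = 0.0
    converged = False
    for _ in range(max_iter):
        d = np.zeros(4)
        for (ca, cb), mult in diff_columns.items():
            d += mult * _yn00_count_pair_diffs(ca, cb, kappa, omega)
        Sd_ts, Sd_tv, Nd_ts, Nd_tv = d
        Sd, Nd = Sd_ts + Sd_tv, Nd_ts + Nd_tv
        Ks, _, _ = _k80_distance(Sd_ts / S, Sd_tv / S) if S > 0 else (0.0, 0, 0)
        Ka, _, _ = _k80_distance(Nd_ts / N, Nd_tv / N) if N > 0 else (0.0, 0, 0)
        if math.isnan(Ks) or math.isnan(Ka):
            flags.append("saturated")
            break
        if Ks <= 0 or Ka <= 0:
            # omega hits a boundary; difference weighting cannot move further
            converged = True
            break
        new_omega = Ka / Ks
        if abs(new_omega - omega) <= tol * max(omega, 1e-12):
            omega = new_omega
            converged = True
            break
        omega = new_omega
    else:
        flags.append("non_converged")
    if not converged and "saturated" not in flags and "non_converged" not in flags:
        flags.append("non_converged")

    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    out_omega = math.nan
    if not math.isnan(Ks) and not math.isnan(Ka):
        if Ks > 0:
            out_omega = Ka / Ks
        else:
            flags.append("omega_undefined")
    return SubstitutionEstimate(
        pair_id=pair.pair_id, method="YN00", S=S, N=N, Sd=Sd, Nd=Nd,
        pS=pS, pN=pN, Ks=Ks, Ka=Ka, omega=out_omega, kappa=kappa,
        n_codons_used=len(columns), flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# batch interface
# ---------------------------------------------------------------------------

def kaks_table(pairs, method: str = "NG86", **kwargs):
    """Estimate all pairs and return a tidy DataFrame (one row per pair)."""
    import pandas as pd

    method = method.upper()
    if method == "NG86":
        estimates = [kaks_ng86(p) for p in pairs]
    elif method == "YN00":
        pairs = list(pairs)
        freqs = kwargs.pop("codon_frequencies", None)
        kappa = kwargs.pop("kappa", None)
        if freqs is None and pairs:
            freqs = estimate_codon_frequencies(pairs)
        if kappa is None and pairs:
            kappa = estimate_kappa_yn00(pairs)
        estimates = [
            kaks_yn00(p, codon_frequencies=freqs, kappa=kappa, **kwargs)
            for p in pairs
        ]
    else:
        raise ValueError(f"unknown method: {method}")
    return pd.DataFrame(
        [
            {
                "pair_id": e.pair_id,
                "method": e.method,
                "S": e.S,
                "N": e.N,
                "Sd": e.Sd,
                "Nd": e.Nd,
                "pS": e.pS,
                "pN": e.pN,
                "Ks": e.Ks,
                "Ka": e.Ka,
                "omega": e.omega,
                "kappa": e.kappa,
                "n_codons_used": e.n_codons_used,
                "flags": ";".join(e.flags),
            }
            for e in estimates
        ]
    )
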