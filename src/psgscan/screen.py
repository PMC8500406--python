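"""The positive-selection screen: Ks filtering and omega thresholding.

Candidate positively selected genes (PSGs) are ortholog pairs that survive
a synonymous-divergence filter (Ks <= max_ks, discarding likely saturated
or non-orthologous pairs) and exceed the omega cutoff (Ka/Ks > threshold).
Both comparisons are strict (>): a pair at exactly the cutoff is kept by
the Ks filter and called non-PSG by the omega rule. Counts at every step
are reported so the accounting chain (input -> retained -> PSG) is
auditable; pairs whose omega is undefined (Ks = 0) are kept in a separate
tier rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MAX_KS = 0.3
DEFAULT_OMEGA_THRESHOLD = 1.2


@dataclass
class FilterAccounting:
    n_input: int
    n_undefined_ks: int
    n_removed: int
    n_retained: int

    def __post_init__(self):
        assert self.n_input == self.n_undefined_ks + self.n_removed + self.n_retained


def apply_ks_filter(estimates: pd.DataFrame, max_ks: float = DEFAULT_MAX_KS
                    ) -> tuple[pd.DataFrame, FilterAccounting]:
    """Drop pairs with Ks strictly above ``max_ks``.

    Pairs with undefined (NaN) Ks — saturated estimates — are also removed
    but accounted separately. Returns the retained table plus the
    accounting record (|retained| + |removed| + |undefined| = |input|).
    """
    if "Ks" not in estimates.columns:
        raise ValueError("estimates table lacks a 'Ks' column")
    ks = estimates["Ks"]
    undefined = ks.isna()
    removed = ~undefined & (ks > max_ks)
    retained = estimates[~undefined & ~removed].copy()
    acc = FilterAccounting(
        n_input=len(estimates),
        n_undefined_ks=int(undefined.sum()),
        n_removed=int(removed.sum()),
        n_retained=len(retained),
    )
    return retained, acc


def classify_psg(estimates: pd.DataFrame,
                 omega_threshold: float = DEFAULT_OMEGA_THRESHOLD) -> pd.DataFrame:
    """Label each Ks-filtered pair PSG / non-PSG / undefined.

    ``undefined`` covers pairs whose omega does not exist (Ks = 0 with the
    pair otherwise fine). The result carries gene_id (parsed from pair_id
    as the focal-genome member unless already present), Ks, Ka, omega,
    is_psg and psg_status.
    """
    df = estimates.copy()
    if "gene_id" not in df.columns:
        df["gene_id"] = [pid.split("__")[0] for pid in df["pair_id"]]
    omega = df["omega"] if "omega" in df.columns else df["Ka"] / df["Ks"]
    defined = omega.notna() & np.isfinite(omega)
    df["omega"] = omega
    df["is_retained_after_ks_filter"] = True
    df["is_psg"] = defined & (omega > omega_threshold)
    df["psg_status"] = np.where(~defined, "undefined",
                                np.where(df["is_psg"], "PSG", "non-PSG"))
    return df


def sample_background(results: pd.DataFrame, n: int, seed: int) -> list[str]:
    """Uniform sample (without replacement) of n non-PSG gene ids."""
    pool = results.loc[results["psg_status"] == "non-PSG", "gene_id"].to_numpy()
    if n > len(pool):
        raise ValueError(f"requested {n} background genes, only {len(pool)} non-PSGs")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    return sorted(rng.choice(pool, size=n, replace=False))


def screen_summary(acc: FilterAccounting, results: pd.DataFrame,
                   max_ks: float = DEFAULT_MAX_KS,
                   omega_threshold: float = DEFAULT_OMEGA_THRESHOLD) -> dict:
    """One-line accounting of the whole screen (counts are pairs)."""
    return {
        "pairs_input": acc.n_input,
        "pairs_ks_undefined": acc.n_undefined_ks,
        "pairs_ks_removed": acc.n_removed,
        "pairs_retained": acc.n_retained,
        "pairs_psg": int(results["is_psg"].sum()),
        "pairs_omega_undefined": int((results["psg_status"] == "undefined").sum()),
        "max_ks": max_ks,
        "omega_threshold": omega_threshold,
    }
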