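"""Expression breadth classes, group tests, WGT stratification."""

import numpy as np
import pandas as pd
import pytest

from psgscan.expression import (
    classify_tissue_pattern,
    compare_expression_groups,
    expression_by_chromosome,
    wgt_retention_analysis,
)
from psgscan.io_formats import TISSUES


def _matrix(rows, genes=None):
    genes = genes or [f"g{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"),
                        columns=list(TISSUES))


class TestClassify:
    def test_single_tissue_gene_is_specific(self):
        df = classify_tissue_pattern(_matrix([[0, 0, 0, 5, 0, 0]]))
        row = df.iloc[0]
        assert row["expression_class"] == "specific"
        assert row["specific_tissue"] == "flower"

    def test_all_six_is_constitutive_and_none_is_silent(self):
        df = classify_tissue_pattern(_matrix([[2] * 6, [0] * 6, [2, 3, 0, 0, 0, 0]]))
        assert list(df["expression_class"]) == ["constitutive", "silent",
                                                "intermediate"]

    def test_threshold_boundary_counts_as_expressed(self):
        df = classify_tissue_pattern(_matrix([[1.0, 0, 0, 0, 0, 0]]),
                                     expressed_threshold=1.0)
        assert df.iloc[0]["expression_class"] == "specific"

    def test_classes_partition_the_universe(self, small_study):
        df = classify_tissue_pattern(small_study.expression)
        assert df["expression_class"].isin(
            ["specific", "constitutive", "intermediate", "silent"]).all()
        assert len(df) == len(small_study.expression)

    def test_rescaling_matrix_and_threshold_together_is_invariant(self):
        mat = _matrix([[0.5, 2, 0, 7, 1, 1.5], [3, 3, 3, 3, 3, 3]])
        a = classify_tissue_pattern(mat, expressed_threshold=1.0)
        b = classify_tissue_pattern(mat * 10, expressed_threshold=10.0)
        assert list(a["expression_class"]) == list(b["expression_class"])


class TestGroupComparisons:
    def test_identical_groups_not_significant(self):
        vals = np.arange(1, 21, dtype=float)
        _stat, p = compare_expression_groups(vals, vals, test="mann_whitney")
        assert p >= 0.99

    def test_large_shift_is_extreme(self):
        a = np.random.default_rng(0).lognormal(size=30)
        _stat, p = compare_expression_groups(a, a + 10, test="mann_whitney")
        assert p < 1e-6

    def test_welch_one_sided_direction(self):
        rng = np.random.default_rng(1)
        lo, hi = rng.normal(0, 1, 50), rng.normal(2, 1, 50)
        _s, p_less = compare_expression_groups(lo, hi, test="welch_t",
                                               alternative="less")
        _s, p_greater = compare_expression_groups(lo, hi, test="welch_t",
                                                  alternative="greater")
        assert p_less < 0.01 < 0.9 < p_greater

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_expression_groups([], [1.0, 2.0])

    def test_mann_whitney_statistic_matches_brute_force_ranks(self, rng):
        """Oracle: U = #{(i,j): a_i > b_j} + 0.5 #ties, by direct counting."""
        for _ in range(20):
            a = rng.integers(0, 15, size=rng.integers(3, 12)).astype(float)
            b = rng.integers(0, 15, size=rng.integers(3, 12)).astype(float)
            u_brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
            stat, _p = compare_expression_groups(a, b, test="mann_whitney")
            assert stat == pytest.approx(u_brute)

    def test_null_calibration_of_mann_whitney(self):
        """Type-I error close to nominal on same-distribution groups."""
        rng = np.random.default_rng(7)
        rejections = 0
        n_reps = 500
        for _ in range(n_reps):
            a = rng.lognormal(size=25)
            b = rng.lognormal(size=25)
            _s, p = compare_expression_groups(a, b, test="mann_whitney")
            rejections += p <= 0.05
        assert 0.03 <= rejections / n_reps <= 0.07


class TestWgtRetention:
    def _screen(self, n, psg_idx):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "is_psg": [i in psg_idx for i in range(n)],
            "psg_status": ["PSG" if i in psg_idx else "non-PSG"
                           for i in range(n)],
        })

    def test_planted_fractions_recovered(self, rng):
        n_per_class = 3000
        fractions = {1: 0.01, 2: 0.02, 3: 0.03}
        genes, classes, psg = [], {}, set()
        i = 0
        for cls, frac in fractions.items():
            for _ in range(n_per_class):
                g = f"g{i}"
                genes.append(g)
                classes[g] = cls
                if rng.random() < frac:
                    psg.add(i)
                i += 1
        screen = self._screen(len(genes), psg)
        retention = pd.Series(classes)
        matrix = _matrix([[2.0] * 6] * len(genes), genes)
        out = wgt_retention_analysis(screen, retention, matrix)
        for cls, frac in fractions.items():
            row = out["summary"].set_index("retention_class").loc[cls]
            assert row["psg_fraction"] == pytest.approx(frac, abs=0.01)

    def test_missing_classes_flagged_undefined(self):
        screen = self._screen(10, {0})
        retention = pd.Series({f"g{i}": 1 for i in range(10)})
        matrix = _matrix([[2.0] * 6] * 10, [f"g{i}" for i in range(10)])
        out = wgt_retention_analysis(screen, retention, matrix)
        summary = out["summary"].set_index("retention_class")
        assert not summary.loc[2, "psg_fraction_defined"]
        assert not summary.loc[3, "psg_fraction_defined"]
        assert np.isnan(summary.loc[3, "psg_fraction"])

    def test_no_psgs_gives_zero_fractions(self):
        screen = self._screen(9, set())
        retention = pd.Series({f"g{i}": (i % 3) + 1 for i in range(9)})
        matrix = _matrix([[2.0] * 6] * 9, [f"g{i}" for i in range(9)])
        out = wgt_retention_analysis(screen, retention, matrix)
        assert (out["summary"]["psg_fraction"] == 0).all()


class TestByChromosome:
    def test_single_chromosome_skips_kw(self):
        matrix = _matrix([[1.0] * 6] * 5)
        chroms = pd.Series({f"g{i}": "Chr01" for i in range(5)})
        out = expression_by_chromosome(matrix, chroms)
        assert np.isnan(out["kw_p"]) and "skipped" in out["note"]

    def test_planted_high_chromosome_ranks_first(self, rng):
        genes = [f"g{i}" for i in range(60)]
        chroms = pd.Series({g: f"Chr{(i % 3) + 1:02d}"
                            for i, g in enumerate(genes)})
        base = rng.lognormal(size=(60, 6))
        base[[i for i, g in enumerate(genes) if chroms[g] == "Chr02"]] *= 4
        matrix = _matrix(base, genes)
        out = expression_by_chromosome(matrix, chroms)
        means = out["summary"].set_index("chrom")[
            [f"{t}_mean" for t in TISSUES]].mean(axis=1)
        assert means.idxmax() == "Chr02"

    def test_all_zero_matrix_gives_zero_summaries(self):
        matrix = _matrix([[0.0] * 6] * 6)
        chroms = pd.Series({f"g{i}": f"Chr{(i % 2) + 1:02d}" for i in range(6)})
        out = expression_by_chromosome(matrix, chroms)
        means = out["summary"][[f"{t}_mean" for t in TISSUES]]
        assert (means.to_numpy() == 0).all()
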