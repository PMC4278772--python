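"""Tag-count digital expression: tpm, filters, ratios, rank-sum, proportions."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from patseq.errors import InputError
from patseq.expr import (
    SIX_COMPARISONS,
    baggerly_proportions_test,
    cam_dependent_filter,
    comparison_label,
    counts_to_tpm,
    filter_expressed,
    log2_ratio_matrix,
    rank_sum_test,
    wilcoxon_bin_test,
)

SAMPLES = ["wt", "oxt6", "c30g", "c30gm"]


def _counts(rows: dict[str, list[int]]) -> pd.DataFrame:
    return pd.DataFrame(rows, index=SAMPLES).T


class TestTpm:
    def test_scaling(self):
        counts = pd.DataFrame({"s": [10, 90]}, index=["g1", "g2"])
        tpm = counts_to_tpm(counts)
        assert tpm["s"].tolist() == [100000.0, 900000.0]

    def test_equal_counts_split_evenly(self):
        counts = pd.DataFrame({"s": [7] * 4}, index=list("abcd"))
        assert counts_to_tpm(counts)["s"].tolist() == [250000.0] * 4

    def test_column_sums_are_one_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 500, size=(50, 4)), columns=SAMPLES)
        tpm = counts_to_tpm(counts)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_total_sample_is_an_error(self):
        with pytest.raises(InputError):
            counts_to_tpm(pd.DataFrame({"s": [0, 0]}))


class TestExpressionFilter:
    def test_strictly_greater_than_threshold(self):
        tpm = pd.DataFrame(
            {"g_removed": [4.0, 4.9, 3.2, 5.0], "g_kept": [0.0, 0.0, 5.1, 0.0]},
            index=SAMPLES,
        ).T
        kept = filter_expressed(tpm, 5.0)
        assert list(kept) == ["g_kept"]

    def test_zero_threshold_keeps_any_expressed_gene(self):
        tpm = pd.DataFrame({"g1": [0.0, 0.1], "g2": [0.0, 0.0]}, index=SAMPLES[:2]).T
        assert list(filter_expressed(tpm, 0.0)) == ["g1"]

    def test_raising_threshold_never_adds_genes(self):
        rng = np.random.default_rng(1)
        tpm = pd.DataFrame(rng.uniform(0, 20, size=(100, 4)), columns=SAMPLES)
        previous = set(filter_expressed(tpm, 0.0))
        for thr in (1.0, 5.0, 10.0, 19.0):
            current = set(filter_expressed(tpm, thr))
            assert current <= previous
            previous = current


class TestRatios:
    def test_pseudocount_ratio_and_log2(self):
        tpm = _counts({"g": [31, 7, 0, 0]})
        ratios, log2r = log2_ratio_matrix(tpm, pseudocount=1.0)
        label = comparison_label("wt", "oxt6")
        assert ratios.loc["g", label] == pytest.approx(4.0)
        assert log2r.loc["g", label] == pytest.approx(2.0)

    def test_equal_tpm_gives_unit_ratio(self):
        tpm = _counts({"g": [10, 10, 10, 10]})
        ratios, log2r = log2_ratio_matrix(tpm)
        assert (ratios.loc["g"] == 1.0).all()
        assert (log2r.loc["g"] == 0.0).all()

    def test_both_zero_gives_unit_ratio(self):
        ratios, _ = log2_ratio_matrix(_counts({"g": [0, 0, 0, 0]}))
        assert (ratios.loc["g"] == 1.0).all()


class TestCamFilter:
    @staticmethod
    def _ratio_frame(folds: dict[str, float]) -> pd.DataFrame:
        # express fold changes as plain ratios (alternating > and < 1 to
        # exercise the symmetric fold-change reading)
        row = {}
        for i, ((num, den), fold) in enumerate(zip(SIX_COMPARISONS, folds.values())):
            row[comparison_label(num, den)] = fold if i % 2 == 0 else 1.0 / fold
        return pd.DataFrame(row, index=["g"])

    def test_passing_pattern(self):
        folds = dict(zip("abcdef", (3.0, 2.5, 2.2, 2.1, 1.1, 1.2)))
        result = cam_dependent_filter(self._ratio_frame(folds), cutoff=2.0)
        assert bool(result.loc["g", "pass"])

    def test_weak_discriminating_comparison_fails(self):
        folds = dict(zip("abcdef", (3.0, 1.8, 2.2, 2.1, 1.1, 1.2)))
        result = cam_dependent_filter(self._ratio_frame(folds), cutoff=2.0)
        assert not bool(result.loc["g", "pass"])

    def test_violated_control_comparison_fails(self):
        folds = dict(zip("abcdef", (3.0, 2.5, 2.2, 2.1, 1.1, 2.5)))
        result = cam_dependent_filter(self._ratio_frame(folds), cutoff=2.0)
        assert not bool(result.loc["g", "pass"])

    def test_missing_comparison_is_an_error(self):
        frame = self._ratio_frame(dict(zip("abcdef", (3, 2.5, 2.2, 2.1, 1.1, 1.2))))
        with pytest.raises(InputError):
            cam_dependent_filter(frame.drop(columns=[comparison_label("wt", "c30g")]))


def _enumerate_rank_sum_p(x, y) -> float:
    """Exhaustive-enumeration oracle for the two-sided rank-sum p-value."""
    vals = list(x) + list(y)
    n1 = len(x)
    ranks = sps.rankdata(vals)
    obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array(
        [
            sum(ranks[list(pick)]) - n1 * (n1 + 1) / 2
            for pick in itertools.combinations(range(len(vals)), n1)
        ]
    )
    return min(1.0, 2.0 * min((us >= obs).mean(), (us <= obs).mean()))


class TestRankSum:
    def test_spec_example_matches_enumeration(self):
        x = [1.2, 1.5, 0.9]
        y = [-0.1, 0.05, 0.0, -0.2]
        _, p = rank_sum_test(x, y)
        assert p == pytest.approx(_enumerate_rank_sum_p(x, y), abs=1e-12)

    @pytest.mark.parametrize("n1,n2,seed", [(2, 5, 0), (4, 6, 1), (8, 8, 2), (5, 9, 3)])
    def test_small_splits_match_enumeration(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n1)
        y = rng.normal(0.5, size=n2)
        _, p = rank_sum_test(x, y)
        assert p == pytest.approx(_enumerate_rank_sum_p(x, y), abs=1e-12)

    def test_ties_fall_back_to_average_rank_approximation(self):
        x = [1.0, 1.0, 2.0]
        y = [1.0, 3.0, 4.0, 5.0]
        stat, p = rank_sum_test(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert (stat, p) == (ref.statistic, ref.pvalue)


class TestBinTest:
    def test_enrichment_table_and_plotting_transform(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(40)]
        values = pd.Series(rng.normal(size=40), index=genes)
        values.iloc[:5] += 3.0  # binA strongly shifted
        bin_map = pd.DataFrame(
            {
                "gene_id": genes[:5] + genes[5:10],
                "bin_id": ["binA"] * 5 + ["binB"] * 5,
            }
        )
        table = wilcoxon_bin_test(values, bin_map).set_index("bin_id")
        assert table.loc["binA", "p_value"] < 0.01
        for bin_id in ("binA", "binB"):
            assert table.loc[bin_id, "log10_inverse_p"] == pytest.approx(
                math.log10(1.0 / table.loc[bin_id, "p_value"])
            )

    def test_empty_bin_skipped_with_warning(self):
        values = pd.Series([0.1, 0.2], index=["g1", "g2"])
        bin_map = pd.DataFrame({"gene_id": ["g1", "gX"], "bin_id": ["binA", "binZ"]})
        with pytest.warns(UserWarning, match="binZ"):
            table = wilcoxon_bin_test(values, bin_map)
        assert table["bin_id"].tolist() == ["binA"]


def _baggerly_oracle(xa, na, xb, nb):
    """Independent re-derivation of the weighted proportions statistic."""

    def moments(x, n):
        x, n = np.asarray(x, float), np.asarray(n, float)
        w = n / n.sum()
        p = float(np.dot(w, x / n))
        pq = p * (1 - p)
        if len(x) == 1:
            return p, pq / n[0], 1
        disp = float(np.dot(w, (x / n - p) ** 2))
        wfac = float(np.dot(w, 1 - w))
        sb2 = max(0.0, (disp - pq * float(np.dot(w * (1 - w), 1.0 / n))) / wfac)
        return p, float(np.dot(w**2, pq / n + sb2)), len(x)

    pa, va, ka = moments(xa, na)
    pb, vb, kb = moments(xb, nb)
    t = (pa - pb) / math.sqrt(va + vb)
    df = ka + kb - 2
    if df >= 1:
        p = 2 * sps.t.sf(abs(t), df)
    else:
        p = 2 * sps.norm.sf(abs(t))
    return t, min(1.0, p)


class TestBaggerly:
    def test_identical_proportions_give_null_result(self):
        stat, p = baggerly_proportions_test([10, 20], [1000, 2000], [5, 10], [500, 1000])
        assert stat == 0.0 and p == 1.0

    def test_group_swap_negates_statistic(self):
        a, na = [12, 30], [1000, 2500]
        b, nb = [4, 5], [900, 1100]
        s1, p1 = baggerly_proportions_test(a, na, b, nb)
        s2, p2 = baggerly_proportions_test(b, nb, a, na)
        assert s1 == pytest.approx(-s2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_two_replicate_case_matches_oracle(self):
        # proportions A ~ (0.010, 0.012), B ~ (0.002, 0.003)
        na, nb = [10000, 25000], [20000, 12000]
        xa = [100, 300]
        xb = [40, 36]
        stat, p = baggerly_proportions_test(xa, na, xb, nb)
        ostat, op = _baggerly_oracle(xa, na, xb, nb)
        assert stat == pytest.approx(ostat, abs=1e-10)
        assert p == pytest.approx(op, abs=1e-10)

    def test_single_replicate_case_matches_oracle(self):
        stat, p = baggerly_proportions_test([50], [10000], [20], [12000])
        ostat, op = _baggerly_oracle([50], [10000], [20], [12000])
        assert stat == pytest.approx(ostat, abs=1e-10)
        assert p == pytest.approx(op, abs=1e-10)

    def test_zero_library_size_is_an_error(self):
        with pytest.raises(InputError):
            baggerly_proportions_test([1], [0], [1], [100])
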