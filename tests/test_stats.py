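import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.stats import studentized_range

from fractalcin.datasets import reference_dbox_values
from fractalcin.multifractal import MultifractalSpectrum
from fractalcin.stats import (
    CaseRecord,
    aggregate_case,
    anova_tukey,
    classify_case,
    confusion,
    group_summaries,
    ks_normality,
    per_q_comparison,
    two_sample_t,
)


def reference_cases():
    return [
        CaseRecord(case_id=f"{g}_{i}", grade=g, roi_dbox=[v])
        for g, vals in reference_dbox_values().items()
        for i, v in enumerate(vals)
    ]


class TestAggregateCase:
    def test_singleton(self):
        assert aggregate_case([1.70]) == 1.70

    def test_even_n_mean_of_central_pair(self):
        assert aggregate_case([1.64, 1.62]) == pytest.approx(1.63)

    def test_permutation_invariance(self, rng):
        vals = list(rng.random(7))
        perm = list(rng.permutation(vals))
        assert aggregate_case(vals) == aggregate_case(perm)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_case([])

    def test_case_record_median_invariant(self):
        c = CaseRecord(case_id="x", grade="CIN1", roi_dbox=[1.6, 1.7, 1.5])
        assert c.case_dbox == pytest.approx(np.median([1.6, 1.7, 1.5]))


class TestGroupSummaries:
    def test_reference_cohort_four_group(self):
        by_group = {s.group: s for s in group_summaries(reference_cases())}
        assert {g: s.n for g, s in by_group.items()} == {
            "normal": 15, "CIN1": 8, "CIN2": 6, "CIN3": 17
        }
        assert by_group["normal"].median == pytest.approx(1.59)
        assert by_group["normal"].min == pytest.approx(1.46)
        assert by_group["normal"].max == pytest.approx(1.67)
        assert by_group["CIN2"].median == pytest.approx(1.71)

    def test_reference_cohort_low_high(self):
        by_group = {s.group: s for s in group_summaries(reference_cases(), "low_high")}
        assert by_group["low"].n == 8 and by_group["high"].n == 23
        assert by_group["high"].median == pytest.approx(1.78)

    def test_single_case_groups(self):
        cases = [CaseRecord(f"c{g}", g, [1.5 + 0.1 * i]) for i, g in enumerate(["normal", "CIN1"])]
        for s in group_summaries(cases):
            assert s.median == s.min == s.max

    def test_unknown_label(self):
        with pytest.raises(ValueError, match="unknown grade"):
            group_summaries([CaseRecord("c", "CIN9", [1.5])])


class TestAnovaTukey:
    def test_identical_groups_p_near_one(self):
        g = [1.0, 1.1, 0.9, 1.05]
        res = anova_tukey({"a": g, "b": list(g)})
        assert res.p_for("a", "b") > 0.9

    def test_matches_studentized_range_oracle(self, rng):
        """Adjusted p equals the direct Tukey-Kramer studentized-range formula."""
        groups = {k: list(rng.normal(mu, 1, n)) for k, mu, n in
                  [("a", 0.0, 5), ("b", 0.5, 8), ("c", 1.2, 4)]}
        res = anova_tukey(groups)
        k = len(groups)
        df = sum(len(v) for v in groups.values()) - k
        mse = sum(np.sum((np.array(v) - np.mean(v)) ** 2) for v in groups.values()) / df
        for a, b in [("a", "b"), ("a", "c"), ("b", "c")]:
            se = np.sqrt(mse / 2 * (1 / len(groups[a]) + 1 / len(groups[b])))
            q = abs(np.mean(groups[a]) - np.mean(groups[b])) / se
            p_oracle = studentized_range.sf(q, k, df)
            assert res.p_for(a, b) == pytest.approx(p_oracle, abs=1e-8)

    def test_invariance_to_order_and_shift(self, rng):
        groups = {k: list(rng.normal(0, 1, 6)) for k in "abc"}
        res1 = anova_tukey(groups)
        reordered = {k: groups[k] for k in reversed(list(groups))}
        shifted = {k: [v + 5.0 for v in vals] for k, vals in groups.items()}
        for res2 in (anova_tukey(reordered), anova_tukey(shifted)):
            for pair, p in res1.pairwise_p.items():
                assert res2.pairwise_p[pair] == pytest.approx(p, abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n < 2"):
            anova_tukey({"a": [1.0, 2.0], "b": [1.0]})


class TestTwoSampleT:
    def test_equal_samples(self):
        t, p = two_sample_t([1.0, 1.2, 0.8], [1.0, 1.2, 0.8])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_closed_form_oracle(self, rng):
        a, b = list(rng.normal(0, 1, 9)), list(rng.normal(0.7, 1.3, 12))
        t, p = two_sample_t(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        t_oracle = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        p_oracle = 2 * sps.t.sf(abs(t_oracle), na + nb - 2)
        assert t == pytest.approx(t_oracle, rel=1e-10)
        assert p == pytest.approx(p_oracle, rel=1e-10)

    def test_reference_low_vs_high_highly_significant(self):
        ref = reference_dbox_values()
        _, p = two_sample_t(ref["CIN1"], ref["CIN2"] + ref["CIN3"])
        assert p < 0.01

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [1.0, 2.0])


class TestKsNormality:
    def test_normal_draws_rarely_flagged(self):
        # at the nominal 5% level the expected pass count over 100
        # replicates is exactly 95, so the bound allows binomial noise
        hits = sum(
            ks_normality(np.random.default_rng(s).normal(0, 1, 500)) > 0.05
            for s in range(100)
        )
        assert hits >= 90

    def test_uniform_draws_flagged(self):
        hits = sum(
            ks_normality(np.random.default_rng(s).uniform(0, 10, 500)) < 0.05
            for s in range(100)
        )
        assert hits >= 90

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ks_normality([1.0] * 10)

    def test_reference_groups_pass_normality(self):
        # the reference cohort's groups were all reported normally distributed
        for vals in reference_dbox_values().values():
            assert ks_normality(vals) > 0.05


def flat_spectrum(level, noise, seed, q=None):
    q = np.arange(-10, 10.75 + 1e-9, 0.25) if q is None else q
    rng = np.random.default_rng(seed)
    d = level + rng.normal(0, noise, q.size)
    return MultifractalSpectrum(
        q_values=q, d_q=d, per_q_slope=np.zeros_like(q),
        per_q_r2=np.ones_like(q), scales=[8, 4], mass_counts=[1, 1],
    )


class TestPerQComparison:
    def make_table(self, specs_by_label):
        from fractalcin.multifractal import spectrum_table

        specs, labels = [], []
        for lab, specs_list in specs_by_label.items():
            specs += specs_list
            labels += [lab] * len(specs_list)
        return spectrum_table(specs, labels, [f"c{i}" for i in range(len(specs))])

    def test_distinct_levels_significant_everywhere(self):
        table = self.make_table({
            "a": [flat_spectrum(2.0, 0.01, s) for s in range(4)],
            "b": [flat_spectrum(1.5, 0.01, 100 + s) for s in range(4)],
        })
        per_q, intervals = per_q_comparison(table)
        assert (per_q["p_adj"] < 0.05).all()
        assert intervals[("a", "b")] == (-10.0, 10.75)

    def test_identical_groups_nowhere_significant(self):
        specs = [flat_spectrum(1.8, 0.05, s) for s in range(4)]
        table = self.make_table({"a": specs, "b": [flat_spectrum(1.8, 0.05, s) for s in range(4)]})
        per_q, intervals = per_q_comparison(table)
        assert (per_q["p_adj"] > 0.05).all()
        assert intervals[("a", "b")] is None

    def test_tail_difference_confined_to_large_q(self):
        """Groups differing only in the high-q tail are significant only there."""
        q = np.arange(-10, 10.75 + 1e-9, 0.25)
        def tail_spectrum(drop, seed):
            s = flat_spectrum(2.0, 0.01, seed, q=q)
            s.d_q = s.d_q - drop * (q > 5)
            return s
        table = self.make_table({
            "a": [tail_spectrum(0.0, s) for s in range(4)],
            "b": [tail_spectrum(0.5, 50 + s) for s in range(4)],
        })
        per_q, intervals = per_q_comparison(table)
        lo, hi = intervals[("a", "b")]
        assert lo > 5.0 and hi == 10.75
        # self-consistency: the reported interval is the longest contiguous
        # significant run, recomputed here directly from the per-q p-values
        # (isolated false positives among the 49 null q-points are expected
        # at the 5% level and must not win)
        sub = per_q.sort_values("q").reset_index(drop=True)
        sig = (sub["p_adj"] < 0.05).to_numpy()
        best, start = None, None
        for i, s in enumerate(list(sig) + [False]):
            if s and start is None:
                start = i
            elif not s and start is not None:
                span = (sub["q"][start], sub["q"][i - 1])
                if best is None or span[1] - span[0] > best[1] - best[0]:
                    best = span
                start = None
        assert (lo, hi) == (float(best[0]), float(best[1]))

    def test_misaligned_grids_rejected(self):
        table = self.make_table({
            "a": [flat_spectrum(2.0, 0.01, s) for s in range(2)],
            "b": [flat_spectrum(1.5, 0.01, s) for s in range(2)],
        })
        with pytest.raises(ValueError):
            per_q_comparison(table.drop(columns=["Dq"]))


class TestClassification:
    MEDIANS = {"normal": 1.59, "CIN1": 1.63, "CIN2": 1.71, "CIN3": 1.80}

    def test_reference_median_maps_to_own_group(self):
        for grade, med in self.MEDIANS.items():
            assert classify_case(med, self.MEDIANS) == grade

    def test_nearest_median(self):
        assert classify_case(1.95, self.MEDIANS) == "CIN3"
        assert classify_case(1.60, self.MEDIANS) == "normal"

    def test_tie_breaks_to_less_severe(self):
        # binary-exact midpoint between two reference medians
        assert classify_case(1.75, {"normal": 1.5, "CIN2": 2.0}) == "normal"
        assert classify_case(1.75, {"CIN2": 1.5, "CIN3": 2.0}) == "CIN2"

    def test_errors(self):
        with pytest.raises(ValueError):
            classify_case(1.5, {})
        with pytest.raises(ValueError, match="distinct"):
            classify_case(1.5, {"a": 1.6, "b": 1.6})


class TestConfusion:
    def test_two_group_reference_counts(self):
        # counts (7,1; 3,20): published low/high-grade agreement table
        truth = ["low"] * 8 + ["high"] * 23
        pred = ["low"] * 7 + ["high"] * 1 + ["low"] * 3 + ["high"] * 20
        cm = confusion(truth, pred, labels=["low", "high"])
        assert cm.overall_percent == pytest.approx(100 * 27 / 31)
        assert round(cm.overall_percent, 1) == 87.1
        assert cm.row_percent("low")[0] == pytest.approx(87.5)
        assert round(cm.row_percent("high")[1], 2) == 86.96

    def test_four_group_reference_counts(self):
        counts = np.array([[9, 4, 2, 0], [3, 4, 1, 0], [0, 1, 3, 2], [0, 1, 2, 14]])
        labels = ["normal", "CIN1", "CIN2", "CIN3"]
        truth, pred = [], []
        for i, ti in enumerate(labels):
            for j, pj in enumerate(labels):
                truth += [ti] * counts[i, j]
                pred += [pj] * counts[i, j]
        cm = confusion(truth, pred, labels=labels)
        assert round(cm.overall_percent, 1) == 65.2
        assert round(cm.row_percent("CIN3")[3], 2) == 82.35
        np.testing.assert_array_equal(cm.counts, counts)
        assert cm.counts.sum() == len(truth)
        np.testing.assert_allclose(cm.row_percents.sum(axis=1), 100.0, atol=0.01)

    def test_perfect_prediction(self):
        labels = ["normal", "CIN1", "CIN2"]
        cm = confusion(labels * 3, labels * 3)
        assert cm.overall_percent == 100.0
        np.testing.assert_array_equal(cm.counts, 3 * np.eye(3, dtype=int))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            confusion(["a"], ["a", "b"])
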