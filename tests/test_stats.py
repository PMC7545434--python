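"""Estimation statistics: paired differences, BCa bootstrap, permutation, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as ss

from evokedlfp import (
    PairedSample,
    bca_bootstrap_ci,
    paired_contrast,
    paired_mean_difference,
    pairwise_sidak,
    permutation_p,
    sidak_adjust,
    two_way_rm_anova,
)


def sample_from_diffs(diffs):
    d = np.asarray(diffs, float)
    return PairedSample(np.zeros_like(d), d)


class TestPairedMeanDifference:
    def test_identical_conditions_give_zero(self, rng):
        x = rng.standard_normal(8)
        assert paired_mean_difference(PairedSample(x, x)) == 0.0

    def test_arithmetic(self):
        assert paired_mean_difference(sample_from_diffs([1.0, 2.0, 3.0])) == 2.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            PairedSample(np.zeros(3), np.zeros(4))

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            PairedSample(np.zeros(1), np.ones(1))

    def test_shift_recovery_in_large_samples(self, rng):
        delta = 0.7
        a = rng.standard_normal(1000)
        b = a + delta + rng.standard_normal(1000)
        s = PairedSample(a, b)
        se = s.diffs.std(ddof=1) / np.sqrt(s.n)
        assert abs(paired_mean_difference(s) - delta) < 3 * se


class TestBCaBootstrap:
    def test_degenerate_differences_collapse_interval(self):
        s = sample_from_diffs([2.0] * 6)
        r = bca_bootstrap_ci(s, n_boot=500, seed=0)
        assert (r.ci_low, r.ci_high) == (2.0, 2.0)

    def test_interval_brackets_point_estimate(self, rng):
        s = sample_from_diffs(rng.standard_normal(15) + 1.0)
        r = bca_bootstrap_ci(s, n_boot=2000, seed=1)
        assert r.ci_low <= paired_mean_difference(s) <= r.ci_high

    def test_symmetric_data_bca_close_to_percentile(self, rng):
        d = rng.standard_normal(40)
        d = np.concatenate([d, -d])  # exactly symmetric diffs
        s = sample_from_diffs(d + 0.5)
        r = bca_bootstrap_ci(s, n_boot=4000, seed=2)
        lo, hi = np.quantile(r.distribution, [0.025, 0.975])
        width = hi - lo
        assert abs(r.z0) < 0.1 and abs(r.acceleration) < 0.05
        assert abs(r.ci_low - lo) < 0.1 * width
        assert abs(r.ci_high - hi) < 0.1 * width

    def test_matches_scipy_bca_oracle(self, rng):
        """Independent implementation check on skewed paired differences."""
        d = rng.exponential(1.0, 20)
        s = sample_from_diffs(d)
        r = bca_bootstrap_ci(s, n_boot=4000, seed=7)
        res = ss.bootstrap(
            (d,), np.mean, n_resamples=4000, confidence_level=0.95,
            method="BCa", random_state=3,
        )
        width = r.ci_high - r.ci_low
        assert abs(r.ci_low - res.confidence_interval.low) < 0.15 * width
        assert abs(r.ci_high - res.confidence_interval.high) < 0.15 * width

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError, match="at least 3"):
            bca_bootstrap_ci(sample_from_diffs([1.0, 2.0]))

    def test_tiny_bootstrap_count_warns(self):
        with pytest.warns(UserWarning, match="n_boot"):
            bca_bootstrap_ci(sample_from_diffs([1.0, 2.0, 3.0]), n_boot=50, seed=0)

    def test_seeded_reproducibility(self, rng):
        s = sample_from_diffs(rng.standard_normal(12))
        r1 = bca_bootstrap_ci(s, n_boot=1000, seed=42)
        r2 = bca_bootstrap_ci(s, n_boot=1000, seed=42)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)


class TestPermutationP:
    def test_identical_conditions_give_p_one(self, rng):
        x = rng.standard_normal(6)
        assert permutation_p(PairedSample(x, x), n_perm=500, seed=0) == 1.0

    def test_exact_enumeration_three_equal_diffs(self):
        # all 2^3 sign patterns: only the two all-same-sign ones reach |mean|=1
        assert permutation_p(sample_from_diffs([1.0, 1.0, 1.0]), mode="exact") == 0.25

    def test_sampled_agrees_with_exact_within_monte_carlo_error(self, rng):
        for seed in range(5):
            d = np.random.default_rng(seed).normal(0.4, 1.0, 10)
            s = sample_from_diffs(d)
            p_exact = permutation_p(s, mode="exact")
            n_perm = 5000
            p_sampled = permutation_p(s, n_perm=n_perm, seed=seed)
            se = np.sqrt(p_exact * (1 - p_exact) / n_perm) + 1.0 / n_perm
            assert abs(p_sampled - p_exact) <= 3 * se + 1e-12

    def test_exact_mode_limited_to_twenty_pairs(self, rng):
        with pytest.raises(ValueError, match="n <= 20"):
            permutation_p(sample_from_diffs(rng.standard_normal(21)), mode="exact")

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_aligning_difference_signs_cannot_increase_p(self, seed):
        """The sign-flip null depends only on |d|; aligning all signs maximizes
        the observed statistic, so the exact p can only shrink."""
        r = np.random.default_rng(seed)
        d = r.standard_normal(8)
        p_mixed = permutation_p(sample_from_diffs(d), mode="exact")
        p_aligned = permutation_p(sample_from_diffs(np.abs(d)), mode="exact")
        assert p_aligned <= p_mixed + 1e-12

    def test_ci_and_test_roughly_coherent(self, rng):
        """When the 95% BCa interval excludes 0, p_perm is usually < 0.05."""
        agree = total = 0
        for seed in range(40):
            r = np.random.default_rng(100 + seed)
            d = r.normal(1.0, 1.0, 16)
            s = sample_from_diffs(d)
            res = paired_contrast(s, n_boot=4000, n_perm=4000, seed=seed)
            if res.ci_low > 0 or res.ci_high < 0:
                total += 1
                agree += res.p_perm < 0.05
        assert total > 10
        assert agree / total >= 0.9


class TestSidakAndANOVA:
    def test_sidak_formula(self):
        assert sidak_adjust(0.05, 1) == pytest.approx(0.05)
        assert sidak_adjust(0.01, 3) == pytest.approx(1 - 0.99**3)
        assert sidak_adjust(0.9, 10) == pytest.approx(1.0, abs=1e-9)

    def test_all_equal_values_give_f_zero_p_one(self):
        rows = [
            {"subject": s, "cond": c, "bin": b, "y": 5.0}
            for s in range(4) for c in ("A", "AC") for b in ("b1", "b2")
        ]
        aov, _ = two_way_rm_anova(pd.DataFrame(rows), "y", "subject", within=["cond", "bin"])
        assert (aov["F"] == 0.0).all()
        assert (aov["p_unc"] == 1.0).all()

    def test_two_way_rm_f_matches_manual_sums_of_squares(self):
        # 2x2 within design, n=3 subjects: verify against explicit SS arithmetic
        data = []
        y = {  # subject -> (A,b1), (A,b2), (AC,b1), (AC,b2)
            0: (3.0, 4.0, 6.0, 9.0),
            1: (2.0, 5.0, 7.0, 8.0),
            2: (4.0, 3.0, 5.0, 10.0),
        }
        for s, vals in y.items():
            for (c, b), v in zip([("A", "b1"), ("A", "b2"), ("AC", "b1"), ("AC", "b2")], vals):
                data.append({"subject": s, "cond": c, "bin": b, "y": v})
        df = pd.DataFrame(data)
        aov, _ = two_way_rm_anova(df, "y", "subject", within=["cond", "bin"])

        arr = np.array([y[s] for s in range(3)], dtype=float)  # subjects x 4 cells
        grand = arr.mean()
        cond_means = np.array([arr[:, :2].mean(), arr[:, 2:].mean()])
        bin_means = np.array([arr[:, [0, 2]].mean(), arr[:, [1, 3]].mean()])
        cell_means = arr.mean(axis=0).reshape(2, 2)  # cond x bin
        n, a, b = 3, 2, 2
        ss_cond = n * b * ((cond_means - grand) ** 2).sum()
        ss_bin = n * a * ((bin_means - grand) ** 2).sum()
        ss_inter = (
            n * ((cell_means - cond_means[:, None] - bin_means[None, :] + grand) ** 2).sum()
        )
        subj_means = arr.mean(axis=1)
        # error terms: subject x factor interactions
        subj_cond = np.stack([arr[:, :2].mean(1), arr[:, 2:].mean(1)], axis=1)
        ss_err_cond = (
            b * ((subj_cond - subj_means[:, None] - cond_means[None, :] + grand) ** 2).sum()
        )
        subj_bin = np.stack([arr[:, [0, 2]].mean(1), arr[:, [1, 3]].mean(1)], axis=1)
        ss_err_bin = (
            a * ((subj_bin - subj_means[:, None] - bin_means[None, :] + grand) ** 2).sum()
        )
        ss_total = ((arr - grand) ** 2).sum()
        ss_subj = a * b * ((subj_means - grand) ** 2).sum()
        ss_err_inter = (
            ss_total - ss_subj - ss_cond - ss_bin - ss_inter - ss_err_cond - ss_err_bin
        )
        f_expected = {
            "cond": (ss_cond / (a - 1)) / (ss_err_cond / ((a - 1) * (n - 1))),
            "bin": (ss_bin / (b - 1)) / (ss_err_bin / ((b - 1) * (n - 1))),
            "cond * bin": (ss_inter / ((a - 1) * (b - 1)))
            / (ss_err_inter / ((a - 1) * (b - 1) * (n - 1))),
        }
        got = dict(zip(aov["Source"], aov["F"]))
        for src, f in f_expected.items():
            assert got[src] == pytest.approx(f, rel=1e-6), src

    def test_mixed_design_detects_between_effect(self, rng):
        rows = []
        for age, mu in (("P14", 0.0), ("P30", 3.0)):
            for s in range(6):
                for cond in ("A", "AC"):
                    rows.append(
                        {"subject": f"{age}{s}", "age": age, "cond": cond,
                         "y": rng.normal(mu, 1.0)}
                    )
        aov, ph = two_way_rm_anova(
            pd.DataFrame(rows), "y", "subject", within="cond", between="age"
        )
        p_age = float(aov.loc[aov["Source"] == "age", "p_unc"].iloc[0])
        assert p_age < 0.01
        assert {"p_sidak", "mean_diff"} <= set(ph.columns)

    def test_unbalanced_design_rejected_with_cell_map(self):
        rows = [
            {"subject": 0, "cond": "A", "bin": "b1", "y": 1.0},
            {"subject": 0, "cond": "A", "bin": "b2", "y": 2.0},
            {"subject": 0, "cond": "AC", "bin": "b1", "y": 3.0},
            # (0, AC, b2) missing
            {"subject": 1, "cond": "A", "bin": "b1", "y": 1.0},
            {"subject": 1, "cond": "A", "bin": "b2", "y": 2.0},
            {"subject": 1, "cond": "AC", "bin": "b1", "y": 3.0},
            {"subject": 1, "cond": "AC", "bin": "b2", "y": 4.0},
        ]
        with pytest.raises(ValueError, match="balanced"):
            two_way_rm_anova(pd.DataFrame(rows), "y", "subject", within=["cond", "bin"])
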