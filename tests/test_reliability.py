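import numpy as np
import pandas as pd
import pytest

import aomosaic as am
from aomosaic.reliability import (
    anova_mean_squares,
    icc_absolute_agreement_k,
    lin_ccc,
    normalized_sd,
    reliability_label,
)


class TestIcc:
    def test_hand_anova_oracle(self):
        # rows (8,9),(4,5),(2,3): MS_R=18.667, MS_C=1.5, MS_E=0 →
        # ICC(A,2) = 18.667/(18.667+1.5/3) = 0.9739…
        table = np.array([[8, 9], [4, 5], [2, 3]], dtype=float)
        msr, msc, mse = anova_mean_squares(table)
        assert msr == pytest.approx(56.0 / 3.0)
        assert msc == pytest.approx(1.5)
        assert mse == pytest.approx(0.0, abs=1e-12)
        r = icc_absolute_agreement_k(table)
        assert r.estimate == pytest.approx(0.974, abs=5e-4)

    def test_identical_columns_unity(self):
        col = np.array([3.0, 7.0, 11.0, 2.0])
        table = np.column_stack([col, col, col])
        assert icc_absolute_agreement_k(table).estimate == pytest.approx(1.0)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        table = rng.normal(10, 2, (8, 3))
        a = icc_absolute_agreement_k(table)
        b = icc_absolute_agreement_k(table[rng.permutation(8)])
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)
        assert a.ci_low == pytest.approx(b.ci_low, abs=1e-12)

    def test_matches_brute_force_anova_oracle(self):
        # oracle built from explicit loops over the two-way decomposition,
        # sharing no code with the implementation
        rng = np.random.default_rng(11)
        for _ in range(20):
            table = rng.normal(50, 5, (5, 3)) + rng.normal(0, 3, (5, 1))
            n, k = table.shape
            grand = sum(table[i, j] for i in range(n) for j in range(k)) / (n * k)
            ss_r = sum(k * (sum(table[i]) / k - grand) ** 2 for i in range(n))
            ss_c = sum(n * (sum(table[:, j]) / n - grand) ** 2 for j in range(k))
            ss_e = (
                sum(
                    (
                        table[i, j]
                        - sum(table[i]) / k
                        - sum(table[:, j]) / n
                        + grand
                    )
                    ** 2
                    for i in range(n)
                    for j in range(k)
                )
            )
            msr, msc, mse = ss_r / (n - 1), ss_c / (k - 1), ss_e / ((n - 1) * (k - 1))
            expected = (msr - mse) / (msr + (msc - mse) / n)
            got = icc_absolute_agreement_k(table).estimate
            assert got == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin_icc2k(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        for _ in range(5):
            data = rng.normal(100, 10, (6, 3)) + rng.normal(0, 6, (6, 1))
            df = pd.DataFrame(data, columns=["s1", "s2", "s3"]).reset_index(names="subject")
            long = df.melt(id_vars="subject", var_name="session", value_name="value")
            icc_tab = pingouin.intraclass_corr(
                data=long, targets="subject", raters="session", ratings="value"
            ).set_index("Type")
            ours = icc_absolute_agreement_k(data)
            assert ours.estimate == pytest.approx(icc_tab.loc["ICC(A,k)", "ICC"], abs=1e-9)
            lo, hi = icc_tab.loc["ICC(A,k)", "CI95"]  # reported to 2 decimals
            assert ours.ci_low == pytest.approx(lo, abs=0.011)
            assert ours.ci_high == pytest.approx(hi, abs=0.011)

    def test_icc_decreases_with_within_noise(self):
        # median ICC strictly decreases as session noise grows
        medians = []
        for within in (0.005, 0.02, 0.08):
            vals = []
            for rep in range(100):
                t = am.generate_repeat_sessions(
                    100.0, k=3, within_cv=within, n_subjects=7, between_cv=0.1,
                    seed=1000 + rep,
                )
                vals.append(icc_absolute_agreement_k(t).estimate)
            medians.append(np.median(vals))
        assert medians[0] > medians[1] > medians[2]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement_k(np.full((4, 3), 7.0))

    def test_labels(self):
        assert reliability_label(0.95) == "excellent"
        assert reliability_label(0.8) == "good"
        assert reliability_label(0.6) == "moderate"
        assert reliability_label(0.3) == "poor"


class TestLinCcc:
    def test_identity_perfect_concordance(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert lin_ccc(x, x).estimate == pytest.approx(1.0)

    def test_closed_form_oracle(self):
        # x=(1,2,3), y=(2,4,6): ρc = 2·(4/3)/(2/3 + 8/3 + 4) = 8/22
        r = lin_ccc([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert r.estimate == pytest.approx(8.0 / 22.0, abs=1e-12)

    def test_antisymmetry_zero_mean(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        r = lin_ccc(x, -x)
        assert r.estimate == pytest.approx(-1.0)

    def test_never_exceeds_pearson(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(0, 1, 30)
            y = 0.8 * x + rng.normal(0.5, 0.7, 30)
            r = lin_ccc(x, y).estimate
            pearson = np.corrcoef(x, y)[0, 1]
            assert abs(r) <= abs(pearson) + 1e-12

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(9)
        x = rng.normal(10, 2, 50)
        y = x + rng.normal(0, 0.5, 50)
        r = lin_ccc(x, y)
        assert r.ci_low <= r.estimate <= r.ci_high


class TestNormalizedSd:
    def test_identical_sessions_zero(self):
        t = np.tile(np.array([[4.0], [9.0], [6.0]]), (1, 3))
        assert normalized_sd(t) == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        t = rng.normal(40, 1, (6, 3))
        assert normalized_sd(t) == pytest.approx(normalized_sd(10 * t), abs=1e-12)

    def test_zero_mean_rejected(self):
        t = np.array([[1.0, -1.0], [2.0, 3.0], [2.0, 2.0]])
        with pytest.raises(ValueError):
            normalized_sd(t)
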