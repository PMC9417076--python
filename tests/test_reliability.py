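import numpy as np
import pandas as pd
import pytest

from imuagree.reliability import (
    IntraclassCorrelation,
    SampleSizeSpec,
    classification_summary,
    classify_icc,
    reliability_sample_size,
    sem_from_icc,
)
from imuagree.synthetic import simulate_range_matrix


def _anova_oracle(y):
    """Independent two-way ANOVA mean squares by explicit sums."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    grand = y.mean()
    ss_rows = k * sum((y[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = n * sum((y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_err = sum(
        (y[i, j] - y[i].mean() - y[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


class TestICC:
    def test_identical_sessions_give_one(self):
        y = np.column_stack([np.arange(5.0), np.arange(5.0)])
        res = IntraclassCorrelation(y).fit()
        assert res.icc == 1.0
        assert res.sem == 0.0

    def test_consistency_ignores_fixed_shift(self):
        base = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        y = np.column_stack([base, base + 3.0])
        assert IntraclassCorrelation(y).fit().icc == pytest.approx(1.0, abs=1e-12)

    def test_matches_anova_oracle(self):
        y = np.array([[1, 2], [3, 5], [5, 9], [7, 11], [9, 14]], dtype=float)
        res = IntraclassCorrelation(y).fit()
        assert res.icc == pytest.approx(_anova_oracle(y), abs=1e-12)

    def test_matches_pingouin_icc_c1(self):
        pg = pytest.importorskip("pingouin")
        y = simulate_range_matrix(20, 3, 1.0, 0.5, rng=1)
        res = IntraclassCorrelation(y).fit()
        df = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(20), 3),
                "sess": np.tile(np.arange(3), 20),
                "y": y.ravel(),
            }
        )
        tab = pg.intraclass_corr(df, targets="subj", raters="sess", ratings="y")
        row = tab[tab["Type"] == "ICC(C,1)"].iloc[0]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        lo, hi = row["CI95"]
        assert res.ci95[0] == pytest.approx(lo, abs=0.005)
        assert res.ci95[1] == pytest.approx(hi, abs=0.005)

    def test_average_measures_form(self):
        y = simulate_range_matrix(15, 3, 1.0, 1.0, rng=2)
        single = IntraclassCorrelation(y, form="single").fit().icc
        avg = IntraclassCorrelation(y, form="average").fit().icc
        k = 3
        assert avg == pytest.approx(k * single / (1 + (k - 1) * single), abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            IntraclassCorrelation(np.zeros((1, 2)))
        with pytest.raises(ValueError):
            IntraclassCorrelation(np.array([[1.0, np.nan], [2.0, 3.0]]))
        with pytest.raises(ValueError, match="zero total variance"):
            IntraclassCorrelation(np.full((4, 2), 7.0)).fit()

    def test_from_dataframe_pivot(self):
        y = simulate_range_matrix(6, 2, 1.0, 0.2, rng=3)
        df = pd.DataFrame(
            {
                "participant_id": np.repeat([f"P{i}" for i in range(6)], 2),
                "session": np.tile([1, 2], 6),
                "range_value": y.ravel(),
            }
        )
        res = IntraclassCorrelation.from_dataframe(df).fit()
        assert res.icc == pytest.approx(IntraclassCorrelation(y).fit().icc, abs=1e-12)

    def test_ci_brackets_estimate(self):
        y = simulate_range_matrix(30, 2, 2.0, 1.0, rng=4)
        res = IntraclassCorrelation(y).fit()
        assert res.ci95[0] <= res.icc <= res.ci95[1]

    def test_sem_within_subject_sd_on_simulated_cohort(self):
        # SEM should approximate the within-subject SD for large n
        sw2 = 1.44
        y = simulate_range_matrix(200, 2, 4.0, sw2, rng=5)
        res = IntraclassCorrelation(y).fit()
        assert res.sem == pytest.approx(np.sqrt(sw2), rel=0.10)


class TestSEM:
    @pytest.mark.parametrize("sd, icc, expected", [(5.0, 1.0, 0.0), (2.0, 0.75, 1.0), (0.0, 0.3, 0.0)])
    def test_formula(self, sd, icc, expected):
        assert sem_from_icc(sd, icc) == pytest.approx(expected, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sem_from_icc(1.0, 1.5)
        with pytest.raises(ValueError):
            sem_from_icc(-1.0, 0.5)


class TestClassification:
    @pytest.mark.parametrize(
        "icc, expected",
        [(0.75, "excellent"), (0.74, "fair_to_high"), (0.40, "fair_to_high"),
         (0.39, "poor"), (-0.1, "poor")],
    )
    def test_bands(self, icc, expected):
        assert classify_icc(icc) == expected

    def test_case_grid_percentages(self):
        # 1 poor among 45 -> 2.2%, 7 among 45 -> 15.6%
        one = classification_summary(["poor"] + ["excellent"] * 44)
        assert one.set_index("class").loc["poor", "percent"] == 2.2
        seven = classification_summary(["poor"] * 7 + ["fair_to_high"] * 38)
        assert seven.set_index("class").loc["poor", "percent"] == 15.6

    def test_all_excellent(self):
        df = classification_summary(["excellent"] * 45)
        assert df["percent"].tolist() == [100.0]

    def test_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(9)
        labels = rng.choice(["excellent", "fair_to_high", "poor"], size=45).tolist()
        df = classification_summary(labels)
        assert df["percent"].sum() == pytest.approx(100.0, abs=0.1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classification_summary([])


class TestSampleSize:
    def test_monotone_in_expected_reliability(self):
        ns = [
            reliability_sample_size(SampleSizeSpec(rho0=0.4, rho1=r1), method="approx")
            for r1 in (0.6, 0.7, 0.8, 0.9)
        ]
        assert ns == sorted(ns, reverse=True)

    def test_more_sessions_never_need_more_subjects(self):
        for method in ("approx", "exact"):
            n2 = reliability_sample_size(
                SampleSizeSpec(k_observations=2, rho0=0.4, rho1=0.7), method=method
            )
            n3 = reliability_sample_size(
                SampleSizeSpec(k_observations=3, rho0=0.4, rho1=0.7), method=method
            )
            assert n2 >= n3

    def test_exact_size_attains_power_by_simulation(self):
        # Monte-Carlo power oracle: one-way F test of H0: rho = rho0 at
        # the returned n should reject with probability >= 1 - beta
        from scipy.stats import f as fdist

        spec = SampleSizeSpec(alpha=0.05, beta=0.2, k_observations=3, rho0=0.4, rho1=0.7)
        n = reliability_sample_size(spec, method="exact")
        k = spec.k_observations
        rng = np.random.default_rng(2024)
        sb2 = spec.rho1 / (1 - spec.rho1)  # sw2 = 1
        rejections = 0
        n_sim = 2000
        fcrit = fdist.ppf(1 - spec.alpha, n - 1, n * (k - 1))
        thresh = fcrit * (1 + k * spec.rho0 / (1 - spec.rho0))
        for _ in range(n_sim):
            y = simulate_range_matrix(n, k, sb2, 1.0, rng=rng)
            mean_i = y.mean(axis=1)
            msb = k * ((mean_i - y.mean()) ** 2).sum() / (n - 1)
            msw = ((y - mean_i[:, None]) ** 2).sum() / (n * (k - 1))
            if msb / msw > thresh:
                rejections += 1
        power = rejections / n_sim
        assert power >= 1 - spec.beta - 0.03  # MC slack

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            SampleSizeSpec(rho0=0.8, rho1=0.7)
        with pytest.raises(ValueError):
            SampleSizeSpec(alpha=0.0)
        with pytest.raises(ValueError):
            SampleSizeSpec(k_observations=1)
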