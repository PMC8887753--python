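"""Variance components, CV/ICC, Bland–Altman and averaging-of-n statistics."""

import numpy as np
import pandas as pd
import pytest

from fhrv.reliability import (
    AcceptabilityRule,
    MeasurementPairs,
    analyze_pairs,
    bland_altman,
    extrapolate_average_of_n,
    fit_variance_components,
    ga_group,
    icc,
    reliability_report,
    within_cv,
)
from fhrv.synthetic import ReliabilitySimConfig, generate_paired_measurements
from tests.oracles import reml_oracle


def pairs_from_logs(y1, y2):
    y1, y2 = np.asarray(y1, float), np.asarray(y2, float)
    return MeasurementPairs(np.arange(y1.size), np.exp(y1), np.exp(y2))


def simulated_pairs(cfg: ReliabilitySimConfig) -> MeasurementPairs:
    df = generate_paired_measurements(cfg)
    wide = df.pivot(index="subject", columns="replicate", values="value")
    return MeasurementPairs(wide.index.to_numpy(), wide[0].to_numpy(),
                           wide[1].to_numpy())


class TestVarianceComponents:
    def test_identical_replicates_give_zero_within_variance(self):
        p = pairs_from_logs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        _, sb2, se2 = fit_variance_components(p)
        assert se2 == 0.0
        assert sb2 == pytest.approx(1.0)

    def test_two_subject_hand_example(self):
        p = pairs_from_logs([1.0, 2.0], [1.2, 1.8])
        mu, sb2, se2 = fit_variance_components(p)
        assert se2 == pytest.approx(0.02)
        assert sb2 == pytest.approx(0.31)
        assert mu == pytest.approx(1.5)

    def test_parameter_recovery_at_large_m(self):
        p = simulated_pairs(ReliabilitySimConfig(
            n_subjects=1000, sigma_b=0.5, sigma_e=0.2, seed=7))
        _, sb2, se2 = fit_variance_components(p)
        assert sb2 == pytest.approx(0.25, abs=0.03)
        assert se2 == pytest.approx(0.04, abs=0.005)

    def test_negative_between_variance_truncated(self):
        # anti-correlated means cannot produce sigma_b2 < 0
        p = pairs_from_logs([1.0, 1.1, 0.9], [1.1, 0.9, 1.0])
        _, sb2, _ = fit_variance_components(p)
        assert sb2 == 0.0

    def test_nonpositive_values_rejected_with_subjects_named(self):
        with pytest.raises(ValueError, match="subjects"):
            MeasurementPairs(np.array(["a", "b", "c"]),
                             np.array([1.0, -2.0, 3.0]),
                             np.array([1.0, 2.0, 3.0]))

    def test_matches_iterative_reml_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            m = int(rng.integers(10, 60))
            sb, se = rng.uniform(0.3, 1.0), rng.uniform(0.05, 0.3)
            b = rng.normal(0, sb, m)
            y = b[:, None] + rng.normal(0, se, (m, 2))
            _, sb2, se2 = fit_variance_components(pairs_from_logs(y[:, 0], y[:, 1]))
            osb2, ose2 = reml_oracle(y[:, 0], y[:, 1])
            assert sb2 == pytest.approx(osb2, abs=1e-8)
            assert se2 == pytest.approx(ose2, abs=1e-8)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        p = simulated_pairs(ReliabilitySimConfig(n_subjects=60, sigma_b=0.5,
                                                 sigma_e=0.2, seed=3))
        _, sb2, se2 = fit_variance_components(p)
        long = pd.DataFrame({
            "y": np.log(np.concatenate([p.value_first, p.value_second])),
            "subject": np.tile(p.subject, 2),
        })
        fit = smf.mixedlm("y ~ 1", long, groups=long["subject"]).fit(reml=True)
        assert sb2 == pytest.approx(float(fit.cov_re.iloc[0, 0]), abs=1e-4)
        assert se2 == pytest.approx(float(fit.scale), abs=1e-4)

    def test_icc_matches_pingouin(self):
        import pingouin as pg

        p = simulated_pairs(ReliabilitySimConfig(n_subjects=80, sigma_b=0.6,
                                                 sigma_e=0.15, seed=9))
        _, sb2, se2 = fit_variance_components(p)
        long = pd.DataFrame({
            "subject": np.tile(p.subject, 2),
            "rater": np.repeat(["A", "B"], len(p)),
            "y": np.log(np.concatenate([p.value_first, p.value_second])),
        })
        table = pg.intraclass_corr(long, targets="subject", raters="rater",
                                   ratings="y")
        icc1 = float(table["ICC"].iloc[0])  # ICC(1,1): one-way single rater
        assert icc(sb2, se2) == pytest.approx(icc1, abs=0.02)


class TestScalarStatistics:
    @pytest.mark.parametrize(
        "se2,expected",
        [(0.0, 0.0), (0.04, 0.20201), (np.log(1.0676), 0.26)],
    )
    def test_within_cv_lognormal_formula(self, se2, expected):
        assert within_cv(se2) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize(
        "sb2,se2,expected",
        [(0.3, 0.1, 0.75), (0.25, 0.04, 0.8620689655), (0.0, 0.5, 0.0), (0.5, 0.0, 1.0)],
    )
    def test_icc_values(self, sb2, se2, expected):
        assert icc(sb2, se2) == pytest.approx(expected)

    def test_icc_undefined_for_degenerate_input(self):
        with pytest.raises(ValueError):
            icc(0.0, 0.0)


class TestBlandAltman:
    def test_identical_pairs(self):
        p = pairs_from_logs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        mean_d, _, median_ratio, loa_ratio = bland_altman(p)
        assert mean_d == 0.0
        assert median_ratio == 1.0
        assert loa_ratio == (1.0, 1.0)

    def test_systematic_bias_detected(self):
        rng = np.random.default_rng(5)
        base = rng.normal(2.0, 0.5, 200)
        p = pairs_from_logs(base + np.log(1.1), base)
        mean_d, _, _, _ = bland_altman(p)
        assert mean_d == pytest.approx(np.log(1.1), abs=1e-9)

    def test_loa_width_tracks_within_sd(self):
        p = simulated_pairs(ReliabilitySimConfig(
            n_subjects=4000, sigma_b=0.4, sigma_e=0.198, seed=21))
        _, _, _, loa_ratio = bland_altman(p)
        half_width = np.sqrt(loa_ratio[1] / loa_ratio[0])
        assert half_width == pytest.approx(np.exp(1.96 * np.sqrt(2) * 0.198),
                                           rel=0.05)


class TestAveragingOfN:
    def test_n1_reproduces_base_statistics(self):
        sb2, se2 = 0.3, 0.08
        cv1, icc1, pi1 = extrapolate_average_of_n(sb2, se2, 1)
        assert cv1 == within_cv(se2)
        assert icc1 == icc(sb2, se2)
        assert pi1[1] == pytest.approx(np.exp(1.96 * np.sqrt(se2)))

    def test_known_icc_at_n2(self):
        _, icc2, _ = extrapolate_average_of_n(0.25, 0.04, 2)
        assert icc2 == pytest.approx(0.925925926, abs=1e-6)

    def test_monotonicity(self):
        cvs, iccs = [], []
        for n in range(1, 7):
            cv_n, icc_n, _ = extrapolate_average_of_n(0.25, 0.04, n)
            cvs.append(cv_n)
            iccs.append(icc_n)
        assert all(a > b for a, b in zip(cvs, cvs[1:]))
        assert all(a < b for a, b in zip(iccs, iccs[1:]))

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_average_of_n(0.1, 0.1, 0)


class TestGaGroups:
    @pytest.mark.parametrize(
        "ga,group",
        [(20.0, "A"), (27.8, "A"), (28.0, "B"), (34.8, "B"),
         (35.0, "C"), (41.0, "C"), (19.0, None), (42.0, None)],
    )
    def test_group_boundaries(self, ga, group):
        assert ga_group(ga) == group


class TestReport:
    @staticmethod
    def long_table(cfg, parameter="sdnn_ms", klass="SHRP", length=120.0,
                   ga_weeks=30.0):
        df = generate_paired_measurements(cfg)
        return pd.DataFrame({
            "recording_id": df["subject"].map("r{:03d}".format),
            "ga_weeks": ga_weeks,
            "class": klass,
            "length_s": length,
            "replicate": df["replicate"] + 1,
            "parameter": parameter,
            "value": df["value"],
        })

    def test_acceptable_group_flagged(self):
        # sigma chosen so CV ≈ 0.13 and ICC ≈ 0.93 → acceptable
        se = np.sqrt(np.log(1 + 0.13**2))
        sb = np.sqrt(0.93 / 0.07 * se**2)
        cfg = ReliabilitySimConfig(n_subjects=400, sigma_b=sb, sigma_e=se, seed=2)
        main, _ = reliability_report(self.long_table(cfg))
        row = main.iloc[0]
        assert row["status"] == "ok"
        assert bool(row["acceptable"])
        assert row["cv"] == pytest.approx(0.13, abs=0.02)
        assert row["icc"] == pytest.approx(0.93, abs=0.03)

    def test_small_group_reported_insufficient(self):
        cfg = ReliabilitySimConfig(n_subjects=2, sigma_b=0.3, sigma_e=0.1, seed=3)
        main, per_n = reliability_report(self.long_table(cfg))
        assert (main["status"] == "insufficient").all()
        assert per_n.empty

    def test_report_schema(self):
        cfg = ReliabilitySimConfig(n_subjects=30, sigma_b=0.4, sigma_e=0.2, seed=4)
        main, per_n = reliability_report(self.long_table(cfg))
        expected = {"parameter", "class", "length_s", "n", "median", "range_low",
                    "range_high", "cv", "cv_ci_low", "cv_ci_high", "loa_low",
                    "loa_high", "icc", "acceptable"}
        assert expected <= set(main.columns)
        assert set(per_n["n"]) == {1, 2, 3, 4, 5, 6}

    def test_outlier_sensitivity_exclusion(self):
        cfg = ReliabilitySimConfig(n_subjects=40, sigma_b=0.3, sigma_e=0.1, seed=6)
        table = self.long_table(cfg)
        # one wild pair, >10x the group median
        med = table["value"].median()
        table.loc[table.index[:2], "value"] = 1000 * med
        kept, _ = reliability_report(table)
        dropped, _ = reliability_report(table, exclude_outliers=True)
        assert dropped.iloc[0]["n"] == kept.iloc[0]["n"] - 1

    def test_ga_grouping(self):
        cfg_a = ReliabilitySimConfig(n_subjects=20, sigma_b=0.4, sigma_e=0.2, seed=7)
        cfg_c = ReliabilitySimConfig(n_subjects=20, sigma_b=0.4, sigma_e=0.2, seed=8)
        table = pd.concat([
            self.long_table(cfg_a, ga_weeks=25.0),
            self.long_table(cfg_c, ga_weeks=38.0).assign(
                recording_id=lambda d: d["recording_id"] + "c"),
        ])
        main, _ = reliability_report(table, by_ga_group=True)
        assert set(main["ga_group"]) == {"A", "C"}

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            reliability_report(pd.DataFrame({"value": [1.0]}))


class TestAnalyzePairs:
    def test_full_result_consistency(self):
        p = simulated_pairs(ReliabilitySimConfig(n_subjects=100, sigma_b=0.5,
                                                 sigma_e=0.2, seed=11))
        res = analyze_pairs(p)
        assert res.icc == icc(res.sigma_b2, res.sigma_e2)
        assert res.cv_within == within_cv(res.sigma_e2)
        assert res.cv_ci[0] < res.cv_within < res.cv_ci[1]
        assert res.loa_ratio[0] < 1.0 < res.loa_ratio[1]
        assert res.per_n.shape[0] == 6
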