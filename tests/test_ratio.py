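import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainaccel.ratio import (acceleration_estimate, delta_ratio_ci,
                              fieller_ratio_ci, overlap_correlation)
from brainaccel.synthetic import (AtrophySpec, CohortSpec, generate_cohort,
                                  generate_region_volumes)


def fieller_set_by_scan(b1, b2, v11, v22, v12, df, level=0.95,
                        span=None, n_grid=20001, refine=60):
    """Oracle: evaluate the defining quadratic inequality on a grid and
    bisect each sign change, never using the closed-form roots."""
    tcrit = stats.t.ppf(0.5 + level / 2.0, df)

    def inside(rho):
        return ((b2 * rho - b1) ** 2
                - tcrit ** 2 * (v22 * rho ** 2 - 2 * v12 * rho + v11)) <= 0

    if span is None:
        # Cauchy bound on the magnitude of any root of the boundary quadratic
        lead = abs(b2 * b2 - tcrit ** 2 * v22)
        others = abs(2 * (b1 * b2 - tcrit ** 2 * v12)) + abs(
            b1 * b1 - tcrit ** 2 * v11)
        span = 2.0 * (1.0 + others / lead) if lead > 0 else 1e6
    center = b1 / b2 if b2 != 0 else 0.0
    grid = center + np.linspace(-span, span, n_grid)
    flags = inside(grid)
    edges = []
    for i in np.nonzero(flags[:-1] != flags[1:])[0]:
        lo, hi = grid[i], grid[i + 1]
        for _ in range(refine):
            mid = 0.5 * (lo + hi)
            if inside(mid) == flags[i]:
                lo = mid
            else:
                hi = mid
        edges.append(0.5 * (lo + hi))
    return flags, edges


class TestFiellerAgainstScanOracle:
    def test_derived_example(self):
        """b1=2, b2=4, v=0.01 diagonal, large df: CI ~ [0.446, 0.556]."""
        res = fieller_ratio_ci(2.0, 4.0, 0.01, 0.01, 0.0, df=10_000)
        _, edges = fieller_set_by_scan(2.0, 4.0, 0.01, 0.01, 0.0, df=10_000,
                                       span=2.0)
        assert res.bounded
        assert res.ratio == pytest.approx(0.5)
        assert [res.ci_low, res.ci_high] == pytest.approx(edges, abs=1e-9)
        assert res.ci_low == pytest.approx(0.446, abs=5e-4)
        assert res.ci_high == pytest.approx(0.556, abs=5e-4)

    def test_random_draws_match_oracle(self):
        rng = np.random.default_rng(2024)
        n_bounded = 0
        for _ in range(200):
            b1, b2 = rng.normal(0, 2, 2)
            a = rng.normal(0, 1, (2, 2))
            v = a @ a.T * 10 ** rng.uniform(-4, -1)
            df = int(rng.integers(5, 500))
            res = fieller_ratio_ci(b1, b2, v[0, 0], v[1, 1], v[0, 1], df)
            flags, edges = fieller_set_by_scan(b1, b2, v[0, 0], v[1, 1],
                                               v[0, 1], df)
            if res.bounded:
                n_bounded += 1
                assert len(edges) == 2
                assert [res.ci_low, res.ci_high] == pytest.approx(edges, abs=1e-6)
                assert not flags[0] and not flags[-1]
            else:
                # unbounded or exclusive: the scan must reach the window edge
                assert flags[0] or flags[-1]
        assert n_bounded > 20  # both regimes exercised


class TestFiellerEdgeCases:
    def test_degenerate_no_uncertainty(self):
        res = fieller_ratio_ci(1.0, 2.0, 0.0, 0.0, 0.0, df=10)
        assert (res.ratio, res.ci_low, res.ci_high) == (0.5, 0.5, 0.5)
        assert res.bounded

    def test_insignificant_denominator_unbounded(self):
        res = fieller_ratio_ci(1.0, 0.1, 0.01, 25.0, 0.0, df=100)
        assert not res.bounded

    def test_zero_denominator_no_variance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            fieller_ratio_ci(1.0, 0.0, 0.1, 0.0, 0.0, df=10)

    def test_inconsistent_covariance_rejected(self):
        with pytest.raises(ValueError):
            fieller_ratio_ci(1.0, 2.0, 0.01, 0.01, 1.0, df=10)

    def test_point_estimate_always_inside_bounded_interval(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            b1, b2 = rng.normal(0, 3, 2)
            a = rng.normal(0, 1, (2, 2))
            v = a @ a.T * 0.01
            res = fieller_ratio_ci(b1, b2, v[0, 0], v[1, 1], v[0, 1], df=50)
            if res.bounded:
                assert res.ci_low <= res.ratio <= res.ci_high


class TestDeltaAgreement:
    def test_high_snr_agreement_within_one_percent(self):
        """|b2|/SE > 50: Fieller and delta widths differ by < 1%."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            b2 = rng.uniform(1, 10)
            se2 = b2 / rng.uniform(60, 500)
            b1 = rng.uniform(-5, 5)
            se1 = abs(b1) / 80 + 1e-3
            rho = rng.uniform(-0.5, 0.5)
            v12 = rho * se1 * se2
            f = fieller_ratio_ci(b1, b2, se1 ** 2, se2 ** 2, v12, df=1000)
            d = delta_ratio_ci(b1, b2, se1 ** 2, se2 ** 2, v12, df=1000)
            wf = f.ci_high - f.ci_low
            wd = d.ci_high - d.ci_low
            assert abs(wf - wd) / wd < 0.01


class TestFiellerCoverage:
    def test_empirical_coverage_near_nominal(self):
        """Gaussian coefficient pairs: 95% interval covers at ~95%."""
        rng = np.random.default_rng(12)
        b1_true, b2_true = 0.8, 2.0
        cov = np.array([[0.04, 0.01], [0.01, 0.09]])
        chol = np.linalg.cholesky(cov)
        hits = total = 0
        for _ in range(2000):
            b1, b2 = np.array([b1_true, b2_true]) + chol @ rng.normal(size=2)
            res = fieller_ratio_ci(b1, b2, cov[0, 0], cov[1, 1], cov[0, 1],
                                   df=10_000)
            truth = b1_true / b2_true
            if res.bounded:
                covered = res.ci_low <= truth <= res.ci_high
            elif res.exclusive:
                covered = not (res.ci_low < truth < res.ci_high)
            else:
                covered = True
            hits += covered
            total += 1
        assert abs(hits / total - 0.95) < 0.02


class TestOverlapCorrelation:
    def test_identity(self):
        m = pd.Series([1.0, -2.0, 3.0, 0.5], index=list("abcd"))
        res = overlap_correlation(m, m)
        assert res.r == pytest.approx(1.0)
        assert res.n == 4

    def test_affine_anticorrelation(self):
        m = pd.Series([1.0, -2.0, 3.0, 0.5], index=list("abcd"))
        res = overlap_correlation(m, -2.0 * m + 7.0)
        assert res.r == pytest.approx(-1.0)

    def test_affine_rescaling_invariance_up_to_sign(self):
        rng = np.random.default_rng(0)
        a = pd.Series(rng.normal(size=20))
        b = pd.Series(rng.normal(size=20) + 0.5 * a)
        r0 = overlap_correlation(a, b).r
        r1 = overlap_correlation(3.0 * a - 1.0, -0.5 * b + 2.0).r
        assert abs(r1) == pytest.approx(abs(r0), rel=1e-12)

    def test_too_few_entries_rejected(self):
        m = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            overlap_correlation(m, m)

    def test_zero_variance_rejected(self):
        a = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        b = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ValueError):
            overlap_correlation(a, b)

    def test_p_value_matches_t_transform(self):
        rng = np.random.default_rng(6)
        a = pd.Series(rng.normal(size=45))
        b = pd.Series(0.6 * a + rng.normal(size=45))
        res = overlap_correlation(a, b)
        t = res.r * np.sqrt((res.n - 2) / (1 - res.r ** 2))
        p_ref = 2 * stats.t.sf(abs(t), res.n - 2)
        assert res.p == pytest.approx(p_ref, rel=1e-6)


class TestAccelerationEstimate:
    def test_noiseless_recovery_is_exact(self):
        cohort = generate_cohort(CohortSpec(n_subjects=1500, t2dm_prevalence=0.5,
                                            seed=21, onset_report_sd=0.0))
        aspec = AtrophySpec(noise_sd=np.zeros(45), acceleration=0.26)
        vols = generate_region_volumes(cohort, aspec, seed=1)
        cols = [c for c in vols.columns if c != "id"]
        whole = vols[cols].sum(axis=1).to_numpy() / cohort["head_size"].to_numpy()
        res = acceleration_estimate(cohort, whole)
        assert res.ratio == pytest.approx(0.26, abs=1e-9)

    def test_null_acceleration_covered(self):
        cohort = generate_cohort(CohortSpec(n_subjects=4000, t2dm_prevalence=0.5,
                                            seed=33))
        aspec = AtrophySpec(acceleration=0.0)
        vols = generate_region_volumes(cohort, aspec, seed=2)
        cols = [c for c in vols.columns if c != "id"]
        whole = vols[cols].sum(axis=1).to_numpy() / cohort["head_size"].to_numpy()
        res = acceleration_estimate(cohort, whole)
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_collinear_duration_rejected(self):
        cohort = generate_cohort(CohortSpec(n_subjects=200, t2dm_prevalence=1.0,
                                            seed=4))
        cohort["duration"] = cohort["age"] - 40.0  # exactly collinear
        with pytest.raises(ValueError, match="collinear"):
            acceleration_estimate(cohort, np.ones(len(cohort)))
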