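"""Monte Carlo engine: degenerate oracle, CPDFs, compliance, pairing."""

import numpy as np
import pytest

from cecburden.distributions import DistributionSpec
from cecburden.mc import (
    compliance_fraction,
    convergence_check,
    cpdf,
    paired_benefit,
    run_mc,
    sample,
    summarize,
)
from cecburden.risk import ExposureContext

from conftest import chain_oracle, point_cec, point_train


class TestSample:
    def test_point_constant(self):
        spec = DistributionSpec.point(5.0)
        assert np.all(sample(spec, np.linspace(0, 1, 11)) == 5.0)

    def test_triangular_median(self):
        assert sample(DistributionSpec.triangular(0, 0.5, 1), 0.5) == pytest.approx(0.5)


class TestRunMC:
    def test_degenerate_mc_equals_deterministic_chain(self, ctx):
        cec = point_cec("a", "DBP", 4.6, ef_cancer=11.9, ef_noncancer=0.5)
        train = point_train("t", [{"a": 0.5}, {"a": 0.2}])
        res = run_mc([cec], [train], ctx, n_iter=50, seed=1)
        expected = chain_oracle(
            11.9, ctx.df_cancer, ctx.sp, ctx.ir_daily, ctx.years, 4.6, [0.5, 0.2]
        )
        totals = res["t"].totals["cancer"]
        assert np.all(totals == totals[0])
        assert totals[0] == pytest.approx(expected, rel=1e-12)

    def test_same_seed_bit_identical(self, ctx):
        cec = point_cec("a", "PCP", 10.0, ef_noncancer=1.0)
        cec = cec.__class__(**{**cec.__dict__, "cs": DistributionSpec.triangular(5, 10, 15)})
        train = point_train("t", [{"a": 0.5}])
        a = run_mc([cec], [train], ctx, n_iter=100, seed=3)
        b = run_mc([cec], [train], ctx, n_iter=100, seed=3)
        assert np.array_equal(a["t"].totals["noncancer"], b["t"].totals["noncancer"])

    def test_shared_cs_across_trains(self, ctx):
        """Per-iteration source draws must be identical for both trains."""
        cec = point_cec("a", "PCP", 10.0, ef_noncancer=1.0)
        cec = cec.__class__(**{**cec.__dict__, "cs": DistributionSpec.triangular(5, 10, 15)})
        t1 = point_train("t1", [{"a": 0.0}])
        t2 = point_train("t2", [{"a": 0.0}])
        res = run_mc([cec], [t1, t2], ctx, n_iter=200, seed=5, record_inputs=True)
        assert np.array_equal(res["t1"].inputs["cs:a"], res["t2"].inputs["cs:a"])

    def test_source_water_key(self, ctx):
        cec = point_cec("a", "PCP", 10.0, ef_noncancer=1.0)
        res = run_mc([cec], [None], ctx, n_iter=10, seed=0)
        assert "source" in res

    def test_invalid_n_iter(self, ctx):
        with pytest.raises(ValueError):
            run_mc([point_cec("a", "PCP", 1.0, ef_noncancer=1.0)], [None], ctx, n_iter=0)


class TestCPDF:
    def test_three_point_example(self):
        pts = cpdf([3, 1, 2])
        assert pts == [(1.0, pytest.approx(1 / 3)), (2.0, pytest.approx(2 / 3)), (3.0, 1.0)]

    def test_constant_samples_single_step(self):
        pts = cpdf([5.0, 5.0, 5.0])
        assert pts[-1] == (5.0, 1.0)

    def test_consistent_with_compliance_fraction(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 2e-6, 1000)
        thr = 1e-6
        pct = compliance_fraction(x, thr)
        below = max(p for v, p in cpdf(x) if v <= thr)
        assert pct == pytest.approx(100 * below)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cpdf([])


class TestCompliance:
    def test_all_below(self):
        assert compliance_fraction([1e-8, 1e-7], 1e-6) == 100.0

    def test_zero_threshold_positive_burdens(self):
        assert compliance_fraction([1e-8, 1e-7], 0.0) == 0.0

    def test_inclusive_at_threshold(self):
        assert compliance_fraction([1e-6], 1e-6) == 100.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 500)
        fracs = [compliance_fraction(x, t) for t in np.linspace(0, 1, 20)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_planted_half_split(self):
        rng = np.random.default_rng(2)
        n = 10_000
        x = np.where(rng.random(n) < 0.5, 0.5e-6, 2e-6)
        pct = compliance_fraction(x, 1e-6)
        assert abs(pct - 50.0) < 3 * 100 * np.sqrt(0.25 / n)


class TestPairedBenefit:
    def _mc(self, totals, seed=0):
        from cecburden.mc import MCResult

        return MCResult(
            train_id="x", n_iter=len(totals), seed=seed, mixture_mode="additive",
            totals={"cancer": np.asarray(totals, dtype=float)}, per_cec={},
            categories={},
        )

    def test_identical_runs_zero_benefit(self):
        a = self._mc([1e-7, 2e-7, 3e-7])
        _, pct = paired_benefit(a, a, "cancer")
        assert pct == 0.0

    def test_uniform_worsening_zero_benefit(self):
        ref = self._mc([1e-7, 2e-7])
        alt = self._mc([1e-7 + 1e-9, 2e-7 + 1e-9])
        _, pct = paired_benefit(ref, alt, "cancer")
        assert pct == 0.0

    def test_dominating_alternative_full_benefit(self, ctx):
        spec = DistributionSpec.triangular(5, 10, 15)
        cec = point_cec("a", "PCP", 10.0, ef_noncancer=1.0)
        cec = cec.__class__(**{**cec.__dict__, "cs": spec})
        ref = point_train("ref", [{"a": 0.1}])
        alt = point_train("alt", [{"a": 0.9}])
        res = run_mc([cec], [ref, alt], ctx, n_iter=500, seed=7)
        diff, pct = paired_benefit(res["ref"], res["alt"], "noncancer")
        assert pct == 100.0 and np.all(diff < 0)

    def test_mismatched_n_iter_rejected(self):
        with pytest.raises(ValueError):
            paired_benefit(self._mc([1.0, 2.0]), self._mc([1.0]), "cancer")


class TestSummaries:
    def test_quantiles_linear_interpolation(self):
        s = summarize(np.arange(1, 101, dtype=float))
        assert s.median == pytest.approx(50.5)
        assert s.p5 == pytest.approx(5.95)
        assert s.p95 == pytest.approx(95.05)

    def test_constant_samples(self):
        s = summarize([2.0, 2.0, 2.0])
        assert s.median == s.p5 == s.p95 == s.mean == 2.0
        assert s.interval95 == (2.0, 2.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 1000)
        s1, s3 = summarize(x), summarize(3.0 * x)
        for name in ("median", "p5", "p95", "mean"):
            assert getattr(s3, name) == pytest.approx(3 * getattr(s1, name), rel=1e-12)

    def test_invariant_ordering(self):
        rng = np.random.default_rng(5)
        s = summarize(rng.lognormal(size=500))
        assert s.p5 <= s.median <= s.p95
        assert s.interval95[0] <= s.mean <= s.interval95[1]


class TestConvergence:
    def _run(self, seed, n=2000, ctx=None):
        ctx = ctx or ExposureContext()
        cec = point_cec("a", "PCP", 10.0, ef_noncancer=1.0)
        cec = cec.__class__(**{**cec.__dict__, "cs": DistributionSpec.triangular(5, 10, 15)})
        train = point_train("t", [{"a": 0.5}])
        return run_mc([cec], [train], ctx, n_iter=n, seed=seed)["t"]

    def test_point_runs_deviate_zero(self, ctx):
        cec = point_cec("a", "PCP", 10.0, ef_noncancer=1.0)
        train = point_train("t", [{"a": 0.5}])
        a = run_mc([cec], [train], ctx, n_iter=50, seed=1)["t"]
        b = run_mc([cec], [train], ctx, n_iter=50, seed=2)["t"]
        dev, ok = convergence_check(a, b)
        assert dev == 0.0 and ok

    def test_stochastic_runs_converge(self):
        dev, ok = convergence_check(self._run(1), self._run(2))
        assert ok and dev < 0.05

    def test_identical_seeds_rejected(self):
        with pytest.raises(ValueError):
            convergence_check(self._run(1), self._run(1))
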