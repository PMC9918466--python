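"""Growth-curve evaluation, fitting, AIC selection, bootstrap bands."""

import math

import numpy as np
import pytest

from bluecarbon.data_io import Pathway, SiteRecord
from bluecarbon.growth_models import (
    FitError,
    GrowthFamily,
    GrowthFit,
    InsufficientDataError,
    bootstrap_prediction_band,
    control_baseline,
    eval_growth,
    fit_curve,
    fit_growth_model,
    increment_since_baseline,
    log_age_pathway_model,
    select_by_aic,
)
from bluecarbon.synthetic_data import (
    CONTROL_PRIOR_USE,
    GeneratorSpec,
    PoolCurve,
    simulate_chronosequence,
)

G = GrowthFamily.gompertz
VB = GrowthFamily.von_bertalanffy
CR = GrowthFamily.chapman_richards


class TestEvalGrowth:
    def test_gompertz_at_zero(self):
        # c^0 = 1 so C(0) = asym * e^{-b}
        assert eval_growth(G, 100, 1, 0.5, age=0) == pytest.approx(100 * math.exp(-1))

    def test_gompertz_limit(self):
        assert eval_growth(G, 100, 1, 0.5, age=500) == pytest.approx(100.0)

    def test_chapman_richards_hand_value(self):
        assert eval_growth(CR, 50, 0.2, 1, age=5) == pytest.approx(
            50 * (1 - math.exp(-1)))

    def test_baseline_additive(self):
        assert eval_growth(G, 100, 1, 0.5, baseline=40, age=0) == pytest.approx(
            40 + 100 * math.exp(-1))

    def test_chapman_richards_rejects_baseline(self):
        with pytest.raises(ValueError, match="baseline"):
            eval_growth(CR, 50, 0.2, 1, baseline=10, age=5)

    @pytest.mark.parametrize("family,params", [
        (G, dict(asym=-1, b=1, c=0.5)),
        (G, dict(asym=100, b=1, c=1.5)),   # increasing gompertz needs c in (0,1)
        (CR, dict(asym=100, b=1, c=-1)),
        (VB, dict(asym=100, b=-1, c=0)),
    ])
    def test_invalid_params(self, family, params):
        with pytest.raises(ValueError):
            eval_growth(family, age=1, **params)

    @pytest.mark.parametrize("family,kw", [
        (G, dict(asym=120, b=1.2, c=0.9)),
        (VB, dict(asym=120, b=0.1, c=-2)),
        (CR, dict(asym=120, b=0.1, c=1.5)),
    ])
    def test_curves_bounded_and_nondecreasing(self, family, kw):
        ages = np.linspace(0, 80, 200)
        vals = eval_growth(family, age=ages, baseline=0.0, **kw)
        assert np.all(np.diff(vals) >= -1e-9)
        assert np.all(vals <= kw["asym"] + 1e-9)


def chronosequence(curve, n=30, seed=0, cv=0.0, pathway="reforestation"):
    spec = GeneratorSpec(seed=seed, n_sites=n, n_controls=0, region_sd=0.0,
                         noise_cv=cv, curves={("agc", pathway): curve})
    return simulate_chronosequence(spec)


class TestFitting:
    def test_noise_free_recovery(self):
        curve = PoolCurve(G, asym=120, b=1.2, c=0.9)
        recs = chronosequence(curve, n=30, seed=1)
        fit = fit_growth_model(recs, "agc", "reforestation", G)
        assert fit.converged
        assert fit.asym == pytest.approx(120, rel=1e-4)
        assert fit.b == pytest.approx(1.2, rel=1e-4)
        assert fit.c == pytest.approx(0.9, rel=1e-4)

    def test_baseline_recovery(self):
        curve = PoolCurve(G, asym=140, b=5, c=0.85, baseline=100)
        spec = GeneratorSpec(seed=2, n_sites=60, n_controls=0, region_sd=0.0,
                             noise_cv=0.05, curves={("scs", "reforestation"): curve})
        recs = simulate_chronosequence(spec)
        fit = fit_growth_model(recs, "scs", "reforestation", G, with_baseline=True)
        assert fit.converged and fit.baseline_fitted
        # baseline recovered within a noise-scaled tolerance
        assert fit.baseline == pytest.approx(100, abs=15)
        assert fit.predict(40) == pytest.approx(curve.value(40), rel=0.05)

    def test_control_sites_fix_baseline(self):
        curve = PoolCurve(G, asym=140, b=5, c=0.85, baseline=100)
        spec = GeneratorSpec(seed=3, n_sites=40, n_controls=10, region_sd=0.0,
                             noise_cv=0.05, curves={("scs", "reforestation"): curve})
        recs = simulate_chronosequence(spec)
        base = control_baseline(recs, "scs", "reforestation")
        assert base == pytest.approx(100, rel=0.1)
        fit = fit_growth_model(recs, "scs", "reforestation", G)
        assert not fit.baseline_fitted
        assert fit.baseline == pytest.approx(base)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_curve(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]), G)

    def test_degenerate_ages(self):
        with pytest.raises(InsufficientDataError):
            fit_curve(np.full(10, 5.0), np.arange(10.0), G)

    def test_constant_density_flagged_degenerate(self):
        ages = np.linspace(1, 40, 20)
        values = np.full(20, 50.0)
        fit = fit_curve(ages, values, G)
        # either non-convergence or a flat fit: growth indistinguishable from 0
        if fit.converged:
            spread = fit.predict(40) - fit.predict(1)
            assert abs(spread) < 1.0

    def test_chapman_richards_no_baseline_fit(self):
        with pytest.raises(ValueError, match="baseline"):
            fit_curve(np.linspace(1, 40, 10), np.linspace(1, 40, 10), CR,
                      with_baseline=True)


class TestSelection:
    def test_argmin(self):
        f1 = GrowthFit(family=G, asym=1, b=1, c=0.5, aic=210.1, converged=True)
        f2 = GrowthFit(family=VB, asym=1, b=1, c=0.5, aic=215.3, converged=True)
        assert select_by_aic([f1, f2]) is f1

    def test_single_fit(self):
        f1 = GrowthFit(family=G, asym=1, b=1, c=0.5, aic=10, converged=True)
        assert select_by_aic([f1]) is f1

    def test_nonconverged_excluded(self):
        f1 = GrowthFit(family=G, asym=1, b=1, c=0.5, aic=5, converged=False)
        f2 = GrowthFit(family=VB, asym=1, b=1, c=0.5, aic=99, converged=True)
        assert select_by_aic([f1, f2]) is f2
        with pytest.raises(FitError):
            select_by_aic([f1])

    def test_tie_breaks_to_fewer_params(self):
        f1 = GrowthFit(family=G, asym=1, b=1, c=0.5, aic=10.0, converged=True,
                       baseline_fitted=True)
        f2 = GrowthFit(family=VB, asym=1, b=1, c=0.5, aic=10.0, converged=True)
        assert select_by_aic([f1, f2]) is f2


class TestIncrement:
    def test_zero_at_age_zero(self):
        fit = GrowthFit(family=G, asym=100, b=1, c=0.5, converged=True)
        assert increment_since_baseline(fit, 0) == 0.0

    def test_gompertz_hand_value(self):
        fit = GrowthFit(family=G, asym=100, b=1, c=0.5, converged=True)
        assert increment_since_baseline(fit, 200) == pytest.approx(
            100 - 100 * math.exp(-1), rel=1e-6)

    def test_monotone_in_age(self):
        fit = GrowthFit(family=G, asym=100, b=2, c=0.8, baseline=30, converged=True)
        incs = [increment_since_baseline(fit, a) for a in range(0, 41)]
        assert all(b >= a for a, b in zip(incs, incs[1:]))

    def test_baseline_cancels(self):
        plain = GrowthFit(family=G, asym=100, b=2, c=0.8, converged=True)
        offset = GrowthFit(family=G, asym=100, b=2, c=0.8, baseline=50, converged=True)
        assert increment_since_baseline(plain, 25) == pytest.approx(
            increment_since_baseline(offset, 25))


class TestBootstrapBand:
    def records(self, cv=0.2, n=40, seed=5):
        return chronosequence(PoolCurve(G, asym=120, b=1.2, c=0.9), n=n,
                              seed=seed, cv=cv)

    def test_reproducible_given_seed(self):
        recs = self.records()
        kw = dict(n_boot=10, seed=99, ages=np.arange(0.0, 41.0, 5.0))
        b1 = bootstrap_prediction_band(recs, "agc", "reforestation", G, **kw)
        b2 = bootstrap_prediction_band(recs, "agc", "reforestation", G, **kw)
        np.testing.assert_array_equal(b1.lo2p5, b2.lo2p5)
        np.testing.assert_array_equal(b1.hi97p5, b2.hi97p5)

    def test_noise_free_band_collapses(self):
        recs = self.records(cv=0.0)
        band = bootstrap_prediction_band(recs, "agc", "reforestation", G,
                                         n_boot=20, seed=1,
                                         ages=np.arange(0.0, 41.0, 10.0))
        assert np.all(band.hi97p5 - band.lo2p5 < 1e-3)

    def test_band_orders_and_covers_generating_curve(self):
        curve = PoolCurve(G, asym=120, b=1.2, c=0.9)
        recs = chronosequence(curve, n=60, seed=11, cv=0.3)
        ages = np.arange(0.0, 41.0, 4.0)
        band = bootstrap_prediction_band(recs, "agc", "reforestation", G,
                                         n_boot=300, seed=2, ages=ages)
        assert np.all(band.lo2p5 <= band.hi97p5)
        truth = np.array([curve.value(a) for a in ages])
        covered = np.mean((band.lo2p5 <= truth) & (truth <= band.hi97p5))
        assert covered >= 0.9

    def test_band_shrinks_with_sample_size(self):
        ages = np.arange(5.0, 41.0, 5.0)
        widths = []
        for n in (25, 200):
            recs = self.records(cv=0.3, n=n, seed=21)
            band = bootstrap_prediction_band(recs, "agc", "reforestation", G,
                                             n_boot=150, seed=3, ages=ages)
            widths.append(np.mean(band.hi97p5 - band.lo2p5))
        assert widths[1] < widths[0]


class TestLogAgeModel:
    @staticmethod
    def records(slope_r=2.0, slope_a=1.0, n=200, seed=8):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(n):
            pw = "reforestation" if i % 2 else "afforestation"
            slope = slope_r if pw == "reforestation" else slope_a
            age = float(rng.uniform(1, 40))
            agc = 5 + slope * math.log(age) + float(rng.normal(0, 0.5))
            recs.append(SiteRecord(site_id=f"s{i}", pathway=pw, age_years=age,
                                   agc=max(agc, 0.0),
                                   region=["east", "west"][i % 2]))
        return recs

    def test_recovers_interaction(self):
        res = log_age_pathway_model(self.records(), "agc")
        assert res.interaction_coef == pytest.approx(1.0, abs=0.3)
        assert res.interaction_p < 0.05

    def test_null_interaction(self):
        res = log_age_pathway_model(self.records(slope_r=1.5, slope_a=1.5, seed=9), "agc")
        assert res.interaction_coef == pytest.approx(0.0, abs=0.3)
        assert res.interaction_p > 0.05

    def test_age_zero_rows_excluded_with_notice(self):
        recs = self.records() + [SiteRecord(site_id="z", pathway="reforestation",
                                            age_years=0.0, agc=1.0)]
        with pytest.warns(UserWarning, match="age-0"):
            res = log_age_pathway_model(recs, "agc")
        assert res.n_dropped_age0 == 1

    def test_single_pathway_rejected(self):
        recs = [r for r in self.records() if r.pathway is Pathway.reforestation]
        with pytest.raises(ValueError, match="pathway"):
            log_age_pathway_model(recs, "agc")


def test_control_pairing_convention():
    assert CONTROL_PRIOR_USE["reforestation"] == "abandoned_pond"
    assert CONTROL_PRIOR_USE["afforestation"] == "mudflat"
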