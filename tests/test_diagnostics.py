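"""Residuals, pc-VPC and NPDE: definitions, identities and calibration."""

import math

import numpy as np
import pytest

import daptopk as d
from daptopk.dataio import Observation, StudyDataset, SubjectRecord
from tests.conftest import make_dataset


@pytest.fixture(scope="module")
def fitted(pm):
    ds = make_dataset(pm, n_subjects=20, cohort_seed=61, data_seed=62)
    fit = d.fit_population(ds, n_starts=1, compute_se=False)
    return ds, fit


class TestGofResiduals:
    def test_residual_definition_hand_computed(self, fitted):
        ds, fit = fitted
        table = d.gof_residuals(ds, fit)
        row = table.iloc[0]
        assert row["residual"] == pytest.approx(
            math.log(row["dv"]) - math.log(row["pred"]), rel=1e-10)
        assert row["wres"] == pytest.approx(
            row["residual"] / fit.estimates.sigma, rel=1e-10)
        assert len(table) == ds.n_obs

    def test_near_perfect_fit_gives_near_zero_residuals(self):
        truth = d.PopulationModel(
            typical=d.StructuralParameters(6.98, 0.95, 1.96, 21.0),
            binding=d.BindingParameters.single_site(160.0, 3.56),
            clcr_exponent=0.19, omega_cl=0.0, omega_v2=0.0, sigma=1e-5)
        ds = make_dataset(truth, n_subjects=8, cohort_seed=63, data_seed=64)
        fake_fit = type("F", (), {})()
        fake_fit.estimates = truth
        fake_fit.cov_coef = None
        fake_fit.ebe = {s.id: (0.0, 0.0) for s in ds.subjects}
        table = d.gof_residuals(ds, fake_fit)
        # only residual error (1e-5) and 6-digit rounding separate DV from PRED
        assert np.max(np.abs(table["residual"])) < 1e-3

    def test_weighted_residuals_normal_under_true_model(self, pm):
        """WRES from a correctly specified model with no IIV pass a
        Kolmogorov-Smirnov normality check."""
        from scipy import stats

        truth = d.PopulationModel(typical=pm.typical, binding=pm.binding,
                                  clcr_exponent=0.19, omega_cl=0.0,
                                  omega_v2=0.0, sigma=0.22)
        ds = make_dataset(truth, n_subjects=120, cohort_seed=65, data_seed=66)
        fake_fit = type("F", (), {})()
        fake_fit.estimates = truth
        fake_fit.cov_coef = None
        fake_fit.ebe = {s.id: (0.0, 0.0) for s in ds.subjects}
        table = d.gof_residuals(ds, fake_fit)
        assert len(table) > 300
        _, p = stats.kstest(table["wres"], "norm")
        assert p > 0.01


class TestPcVpc:
    def test_uniform_design_correction_is_identity(self, pm):
        """With identical dosing, covariates and sampling times across
        subjects, PRED is constant within each bin and the prediction
        correction is exactly the identity."""
        times = [72.0, 73.0, 74.0, 80.0, 96.0]
        doses = tuple(d.DoseEvent(24.0 * k, 675.0, 0.5) for k in range(4))
        cov = d.SubjectCovariates(weight=75.0, clcr=92.8)
        rng = np.random.default_rng(11)
        subs = []
        for i in range(12):
            pred = d.total_profile(pm.typical, pm.binding, list(doses),
                                   np.array(times))
            dv = pred * np.exp(rng.normal(0, 0.2, size=len(times)))
            subs.append(SubjectRecord(
                id=str(i), covariates=cov, doses=doses,
                observations=tuple(Observation(t, v)
                                   for t, v in zip(times, dv))))
        ds = StudyDataset(subjects=tuple(subs))
        edges = [-0.5, 0.5, 1.5, 3.0, 20.0, 25.0]   # one sampling time per bin
        corr = d.pc_vpc(ds, pm, n_sim=200, bins=edges, seed=9,
                        prediction_corrected=True)
        plain = d.pc_vpc(ds, pm, n_sim=200, bins=edges, seed=9,
                         prediction_corrected=False)
        for bc, bp_ in zip(corr.bins, plain.bins):
            assert bc.observed == pytest.approx(bp_.observed, rel=1e-12)
            assert bc.band_lo == pytest.approx(bp_.band_lo, rel=1e-12)

    def test_self_consistency_median_in_band(self, pm):
        """Data simulated from the model itself: the observed median falls in
        the simulated 95% band for most bins (pooled over replicates)."""
        cov = []
        for s in range(6):
            ds = make_dataset(pm, cohort_seed=70 + s, data_seed=80 + s)
            res = d.pc_vpc(ds, pm, n_sim=300, seed=90 + s)
            cov.append(res.median_coverage())
        assert np.mean(cov) >= 0.75

    def test_correction_matters_under_saturable_binding(self, pm):
        """Doubling all doses and prediction-correcting does NOT reproduce the
        original percentiles: saturable binding breaks dose-proportionality
        of total concentrations."""
        spec = d.CohortSpec(n_subjects=30, seed=71)
        cohort = d.generate_cohort(spec)
        rng = np.random.default_rng(3)
        dpk = np.clip(rng.normal(9.0, 1.0, size=30), 4, 12)
        ds1 = d.generate_dataset(cohort, d.DesignSpec(), pm, seed=72, dose_per_kg=dpk)
        ds2 = d.generate_dataset(cohort, d.DesignSpec(), pm, seed=72,
                                 dose_per_kg=2.0 * dpk)
        r1 = d.pc_vpc(ds1, pm, n_sim=150, bins=4, seed=73)
        r2 = d.pc_vpc(ds2, pm, n_sim=150, bins=4, seed=73)
        med1 = np.array([b.observed[1] for b in r1.bins])
        med2 = np.array([b.observed[1] for b in r2.bins])
        # doubled doses give less than double the corrected totals, and the
        # ratio is visibly different from both 1 and 2
        assert not np.allclose(med2 / med1, 2.0, rtol=0.05)
        assert np.all(med2 / med1 > 1.05)

    def test_reproducible_and_order_invariant(self, pm, tiny_dataset):
        r1 = d.pc_vpc(tiny_dataset, pm, n_sim=150, seed=4)
        r2 = d.pc_vpc(tiny_dataset, pm, n_sim=150, seed=4)
        assert r1 == r2
        rev = StudyDataset(subjects=tuple(reversed(tiny_dataset.subjects)))
        r3 = d.pc_vpc(rev, pm, n_sim=150, seed=4)
        for b1, b3 in zip(r1.bins, r3.bins):
            assert b1.observed == pytest.approx(b3.observed, rel=1e-9)

    def test_nsim_floor(self, pm, tiny_dataset):
        with pytest.raises(ValueError):
            d.pc_vpc(tiny_dataset, pm, n_sim=50)


class TestNpde:
    def test_calibration_under_true_model(self, pm):
        zs = []
        for s in range(3):
            ds = make_dataset(pm, cohort_seed=75 + s, data_seed=85 + s)
            zs.append(d.npde(ds, pm, n_sim=400, seed=95 + s)["npde"].values)
        z = np.concatenate(zs)
        assert abs(z.mean()) < 0.1
        assert 0.8 < z.var() < 1.2

    def test_sensitive_to_gross_misspecification(self, pm):
        bad = d.PopulationModel(
            typical=d.StructuralParameters(6.98 / 2, 0.95, 1.96, 21.0),
            binding=pm.binding, clcr_exponent=0.19, clcr_reference=92.8,
            omega_cl=0.32, omega_v2=0.47, sigma=0.22)
        ds = make_dataset(pm, cohort_seed=78, data_seed=88)
        z = d.npde(ds, bad, n_sim=400, seed=98)["npde"].values
        assert abs(z.mean()) > 0.5

    def test_degenerate_single_observation_single_replicate(self, pm):
        subj = SubjectRecord(
            id="1", covariates=d.SubjectCovariates(weight=75, clcr=92.8),
            doses=(d.DoseEvent(0.0, 675.0, 0.5),),
            observations=(Observation(2.0, 40.0),))
        ds = StudyDataset(subjects=(subj,))
        table = d.npde(ds, pm, n_sim=1, seed=0)
        assert len(table) == 1
        assert np.isfinite(table["npde"].iloc[0])
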