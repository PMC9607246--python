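"""Mixed-effects machinery: likelihood oracles, OFV invariances, LRT,
covariate scan and bootstrap plumbing."""

import math

import numpy as np
import pytest

import daptopk as d
from daptopk.dataio import Observation, StudyDataset, SubjectRecord
from daptopk.estimation import LikelihoodError, _model_to_params
from daptopk.population import individual_params
from tests.conftest import make_dataset

SP = d.StructuralParameters(CL=6.98, V1=0.95, Q=1.96, V2=21.0)
BP = d.BindingParameters.single_site(160.0, 3.56)


def subject_with_obs(times, dvs, doses=None, clcr=92.8):
    doses = doses or (d.DoseEvent(0.0, 675.0, 0.5),)
    return SubjectRecord(
        id="s1",
        covariates=d.SubjectCovariates(weight=75.0, clcr=clcr),
        doses=tuple(doses),
        observations=tuple(Observation(t, v) for t, v in zip(times, dvs)),
    )


class TestIndividualLikelihood:
    def test_zero_residual_single_observation(self):
        sigma = 0.22
        pred = d.total_profile(SP, BP, [d.DoseEvent(0.0, 675.0, 0.5)], [2.0])[0]
        subj = subject_with_obs([2.0], [pred])
        val = d.neg2ll_individual(subj, SP, BP, sigma)
        assert val == pytest.approx(math.log(2 * math.pi * sigma ** 2), rel=1e-12)

    def test_additivity_over_observations(self):
        pred = d.total_profile(SP, BP, [d.DoseEvent(0.0, 675.0, 0.5)], [2.0])[0]
        one = d.neg2ll_individual(subject_with_obs([2.0], [0.8 * pred]), SP, BP, 0.22)
        two = d.neg2ll_individual(
            subject_with_obs([2.0, 2.0], [0.8 * pred, 0.8 * pred]), SP, BP, 0.22)
        assert two == pytest.approx(2.0 * one, rel=1e-12)

    def test_matches_straight_line_reimplementation(self):
        """Independent arithmetic oracle for the -2LL formula."""
        sigma = 0.3
        times = [1.0, 6.0, 23.9]
        dvs = [55.0, 22.0, 13.0]
        subj = subject_with_obs(times, dvs)
        pred = d.total_profile(SP, BP, list(subj.doses), np.array(times))
        expected = sum(
            math.log(2 * math.pi * sigma ** 2)
            + ((math.log(dv) - math.log(p)) / sigma) ** 2
            for dv, p in zip(dvs, pred)
        )
        assert d.neg2ll_individual(subj, SP, BP, sigma) == \
            pytest.approx(expected, rel=1e-12)


class TestMarginalOfv:
    def test_zero_omega_limit_is_eta0_likelihood(self, tiny_dataset):
        pm0 = d.PopulationModel(typical=SP, binding=BP, omega_cl=0.0,
                                omega_v2=0.0, sigma=0.22)
        total = sum(
            d.neg2ll_individual(
                s, individual_params(pm0, s.covariates, 0.0, 0.0), BP, 0.22)
            for s in tiny_dataset.subjects
        )
        assert d.marginal_ofv(tiny_dataset, pm0) == pytest.approx(total, rel=1e-10)

    def test_laplace_close_to_dense_quadrature_oracle(self, pm, tiny_dataset):
        """Brute-force 2-D quadrature of the marginal likelihood."""
        om = (pm.omega_cl, pm.omega_v2)
        ofv_dense = 0.0
        g = np.linspace(-5.0, 5.0, 81)
        for s in tiny_dataset.subjects:
            like = 0.0
            for z1 in g:
                e1 = z1 * om[0]
                for z2 in g:
                    e2 = z2 * om[1]
                    sp = individual_params(pm, s.covariates, e1, e2)
                    n2 = d.neg2ll_individual(s, sp, pm.binding, pm.sigma)
                    phi = math.exp(-0.5 * (z1 ** 2 + z2 ** 2)) / (
                        2 * math.pi * om[0] * om[1])
                    like += math.exp(-0.5 * n2) * phi
            h2 = (g[1] - g[0]) ** 2 * om[0] * om[1]
            ofv_dense += -2.0 * math.log(like * h2)
        assert d.marginal_ofv(tiny_dataset, pm) == pytest.approx(ofv_dense, abs=0.5)
        assert d.marginal_ofv(tiny_dataset, pm, method="agh", agh_nodes=9) == \
            pytest.approx(ofv_dense, abs=0.05)

    def test_subject_with_no_observations_is_neutral(self, pm, tiny_dataset):
        empty = SubjectRecord(
            id="empty", covariates=d.SubjectCovariates(weight=70, clcr=80),
            doses=(d.DoseEvent(0.0, 500.0, 0.5),), observations=())
        extended = StudyDataset(subjects=tiny_dataset.subjects + (empty,))
        assert d.marginal_ofv(extended, pm) == \
            pytest.approx(d.marginal_ofv(tiny_dataset, pm), abs=1e-8)

    def test_subject_order_invariance_and_duplication(self, pm, tiny_dataset):
        base = d.marginal_ofv(tiny_dataset, pm)
        from dataclasses import replace
        rev = StudyDataset(subjects=tuple(reversed(tiny_dataset.subjects)))
        assert d.marginal_ofv(rev, pm) == pytest.approx(base, abs=1e-8)
        doubled = StudyDataset(subjects=tiny_dataset.subjects + tuple(
            replace(s, id=s.id + "dup") for s in tiny_dataset.subjects))
        assert d.marginal_ofv(doubled, pm) == pytest.approx(2 * base, abs=1e-7)


class TestFit:
    def test_noise_free_recovery_of_identifiable_fixed_effects(self):
        """With near-zero noise and the binding dissociation constant pinned,
        the fit recovers the remaining fixed effects to the noise floor.
        (With KD free the likelihood has a flat scale/binding ridge and the
        fixed effects are not separately identifiable from total data.)"""
        truth = d.PopulationModel(typical=SP, binding=BP, clcr_exponent=0.19,
                                  omega_cl=0.0, omega_v2=0.0, sigma=0.002)
        ds = make_dataset(truth, n_subjects=46, cohort_seed=5, data_seed=6)
        start = d.PopulationModel(
            typical=d.StructuralParameters(5.0, 1.0, 2.0, 20.0),
            binding=d.BindingParameters.single_site(100.0, 3.56),
            clcr_exponent=0.1, omega_cl=0.0, omega_v2=0.0, sigma=0.002)
        fit = d.fit_population(ds, start=start,
                               fixed={"kd", "omega_cl", "omega_v2", "sigma"},
                               n_starts=1, compute_se=False, maxiter=3000,
                               fd_scheme="3-point", ftol=1e-10)
        for _ in range(8):   # polish restarts until the OFV stabilises
            again = d.fit_population(ds, start=fit.estimates,
                                     fixed={"kd", "omega_cl", "omega_v2", "sigma"},
                                     n_starts=1, compute_se=False, maxiter=3000,
                                     fd_scheme="3-point", ftol=1e-10)
            if again.ofv >= fit.ofv - 1e-8:
                break
            fit = again
        for name, val in [("cl", 6.98), ("v1", 0.95), ("q", 1.96),
                          ("v2", 21.0), ("bmax", 160.0)]:
            assert fit.params[name] == pytest.approx(val, rel=0.05), name
        assert fit.params["clcr_exp"] == pytest.approx(0.19, abs=0.01)

    def test_full_fit_improves_on_reduced_fit(self, pm):
        """Nested models: adding the covariate exponent can only lower the OFV."""
        ds = make_dataset(pm, n_subjects=20, cohort_seed=11, data_seed=12)
        reduced_start = d.PopulationModel(
            typical=d.StructuralParameters(5.0, 1.0, 2.0, 20.0),
            binding=d.BindingParameters.single_site(100.0, 5.0),
            clcr_exponent=0.0, omega_cl=0.3, omega_v2=0.3, sigma=0.2)
        reduced = d.fit_population(ds, start=reduced_start, fixed={"clcr_exp"},
                                   n_starts=1, compute_se=False)
        full = d.fit_population(ds, start=reduced.estimates, n_starts=1,
                                compute_se=False)
        assert full.ofv <= reduced.ofv + 1e-6

    def test_shrinkage_definition(self, pm):
        ds = make_dataset(pm, n_subjects=20, cohort_seed=13, data_seed=14)
        fit = d.fit_population(ds, n_starts=1, compute_se=False)
        eta = np.array([fit.ebe[s.id] for s in ds.subjects])
        expected = 100.0 * (1.0 - np.std(eta[:, 0], ddof=1) / fit.params["omega_cl"])
        assert fit.shrinkage["omega_cl"] == pytest.approx(expected, abs=1e-6)

    def test_standard_errors_reported(self, pm):
        ds = make_dataset(pm, n_subjects=20, cohort_seed=15, data_seed=16)
        fit = d.fit_population(ds, n_starts=1, compute_se=True)
        if fit.se_rse is not None:     # PD Hessian not guaranteed on a ridge
            assert set(fit.se_rse) == set(fit.params)
            for se, rse in fit.se_rse.values():
                assert se >= 0 and rse >= 0


class TestLrt:
    @pytest.mark.parametrize("delta, df, expected", [
        (3.84, 1, True),
        (0.0, 1, False),
        (5.99, 2, True),        # conventional table cutoff
        (5.50, 2, False),
        (10.0, 3, True),
    ])
    def test_threshold(self, delta, df, expected):
        got_delta, sig = d.lrt_compare(100.0, 100.0 - delta, df=df)
        assert got_delta == pytest.approx(delta)
        assert sig is expected

    def test_df_validation(self):
        with pytest.raises(ValueError):
            d.lrt_compare(10.0, 9.0, df=0)


class TestCovariateScan:
    def test_constant_covariate_skipped(self, pm):
        ds = make_dataset(pm, n_subjects=8, cohort_seed=21, data_seed=22)
        from dataclasses import replace
        flat = StudyDataset(subjects=tuple(
            replace(s, covariates=replace(s.covariates, albumin=2.9))
            for s in ds.subjects))
        base = d.fit_population(flat, n_starts=1, compute_se=False)
        table = d.covariate_scan(flat, base, [("cl", "albumin", "power-centered")])
        assert table.iloc[0]["note"].startswith("skipped")

    def test_detects_simulated_clcr_effect(self, pm):
        """Scanning CLCR-on-CL on data carrying the covariate effect recovers
        a positive exponent and an OFV drop."""
        ds = make_dataset(pm, n_subjects=46, cohort_seed=23, data_seed=24)
        base_start = d.PopulationModel(
            typical=d.StructuralParameters(5.0, 1.0, 2.0, 20.0),
            binding=d.BindingParameters.single_site(100.0, 5.0),
            clcr_exponent=0.0, omega_cl=0.3, omega_v2=0.3, sigma=0.2)
        base = d.fit_population(ds, start=base_start, fixed={"clcr_exp"},
                                n_starts=1, compute_se=False)
        table = d.covariate_scan(ds, base, [("cl", "clcr", "power-centered")],
                                 fixed={"clcr_exp"})
        row = table.iloc[0]
        assert row["delta_ofv"] > 0
        assert 0.0 < row["coefficient"] < 0.6


class TestBootstrap:
    def test_single_replicate_collapses(self, pm):
        ds = make_dataset(pm, n_subjects=8, cohort_seed=31, data_seed=32)
        res = d.bootstrap(ds, start=d.default_start(), n_boot=1, seed=0)
        if res.n_converged:
            t = res.table
            assert np.allclose(t["ci_lo"], t["median"])
            assert np.allclose(t["ci_hi"], t["median"])

    def test_percentile_bracketing_and_determinism(self, pm):
        ds = make_dataset(pm, n_subjects=8, cohort_seed=33, data_seed=34)
        res1 = d.bootstrap(ds, start=d.default_start(), n_boot=6, seed=5)
        res2 = d.bootstrap(ds, start=d.default_start(), n_boot=6, seed=5)
        assert res1.table.equals(res2.table)
        assert res1.n_converged >= 1
        t = res1.table
        assert np.all(t["ci_lo"] <= t["median"] + 1e-12)
        assert np.all(t["median"] <= t["ci_hi"] + 1e-12)
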