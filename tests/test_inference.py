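"""Posterior evaluation, Metropolis-Hastings sampling, z-tests."""

import numpy as np
import pytest
from dataclasses import replace

from meththerm import (
    FixedModel,
    MCMCSettings,
    ParamVectorW,
    TemperatureSeries,
    compare_groups,
    log_posterior,
    log_posterior_named,
    mcmc_sample,
    metropolis_hastings,
)
from meththerm.inference import PosteriorEnsemble, read_series, write_series
from meththerm.synthetic_data import noiseless_trajectory


@pytest.fixture(scope="module")
def clean_series(vehicle_truth, design):
    """Noiseless data equal to the model trajectory at the generating truth."""
    clean = noiseless_trajectory(vehicle_truth, design, meth_dose=5.0)
    return TemperatureSeries(design.times, clean, np.full_like(clean, 1.0),
                             n=7, sb_dose=0.0, meth_dose=5.0)


class TestLogPosterior:
    def test_exact_match_gives_zero(self, clean_series, fixed_model,
                                    vehicle_truth):
        assert log_posterior(vehicle_truth, [clean_series], fixed_model) == \
            pytest.approx(0.0, abs=1e-12)

    def test_single_point_perturbation(self, clean_series, fixed_model,
                                       vehicle_truth):
        # +1 degC at one point with sigma = 1 costs exactly 1/2
        mean = clean_series.mean.copy()
        mean[40] += 1.0
        bumped = replace(clean_series, mean=mean)
        assert log_posterior(vehicle_truth, [bumped], fixed_model) == \
            pytest.approx(-0.5, abs=1e-10)

    def test_brute_force_sum_matches_vectorized(self, meth5_series,
                                                fixed_model, vehicle_truth):
        from meththerm.inference import SIGMA_FLOOR
        from meththerm.thermodynamics import simulate_temperature

        lp = log_posterior(vehicle_truth, [meth5_series], fixed_model)
        traj = simulate_temperature(
            meth5_series.schedule, fixed_model.circuit, fixed_model.pk,
            fixed_model.thermo, meth5_series.times, dt=fixed_model.dt)
        total = 0.0
        for i in range(len(meth5_series.times)):
            s = max(meth5_series.sd[i], SIGMA_FLOOR)
            total -= (meth5_series.mean[i] - traj.temp[i]) ** 2 / (2 * s * s)
        assert lp == pytest.approx(total, abs=1e-12)

    def test_sigma_scaling_invariance(self, meth5_series, fixed_model,
                                      vehicle_truth):
        c = 3.0
        scaled = replace(meth5_series, sd=meth5_series.sd * c)
        lp = log_posterior(vehicle_truth, [meth5_series], fixed_model)
        lp_scaled = log_posterior(vehicle_truth, [scaled], fixed_model)
        assert lp_scaled == pytest.approx(lp / c**2, rel=1e-12)

    def test_outside_support_is_rejected(self, clean_series, fixed_model):
        assert log_posterior_named({"w_Exc": -0.1}, [clean_series],
                                   fixed_model) == -np.inf
        assert log_posterior_named({"tau_u": -1.0}, [clean_series],
                                   fixed_model) == -np.inf

    def test_param_vector_requires_exactly_one_hd_entry(self):
        with pytest.raises(ValueError):
            ParamVectorW(w_S=1, w_Exc=1, w_Inh=1)
        with pytest.raises(ValueError):
            ParamVectorW(w_S=1, w_Exc=1, w_Inh=1, w_HD=1, gamma_HD=-3)
        alt = ParamVectorW(w_S=1, w_Exc=1, w_Inh=1, gamma_HD=-3.0)
        assert "gamma_HD" in alt.as_dict()


class TestMetropolisHastings:
    def test_recovers_gaussian_moments(self):
        # known 1-D Gaussian target N(mu, sd^2)
        mu, sd = 3.0, 0.7

        def logpdf(x):
            return -0.5 * ((x[0] - mu) / sd) ** 2

        settings = MCMCSettings(n_steps=30_000, burn_in=5_000, thin=5, seed=11)
        samples, _, acc = metropolis_hastings(logpdf, np.array([0.0]),
                                              np.array([0.5]), settings)
        n_eff = len(samples)
        assert abs(samples.mean() - mu) < 3 * sd / np.sqrt(n_eff / 10)
        assert samples.var() == pytest.approx(sd**2, rel=0.2)
        assert 0.1 <= acc <= 0.6

    def test_split_half_means_agree(self):
        def logpdf(x):
            return -0.5 * float(x[0] ** 2 + x[1] ** 2)

        settings = MCMCSettings(n_steps=40_000, burn_in=5_000, thin=5, seed=2)
        samples, _, _ = metropolis_hastings(
            logpdf, np.zeros(2), np.full(2, 0.8), settings)
        half = len(samples) // 2
        gap = np.abs(samples[:half].mean(axis=0) - samples[half:].mean(axis=0))
        assert np.all(gap < 0.5 * samples.std(axis=0))

    def test_seeded_determinism(self, meth5_series, fixed_model):
        settings = MCMCSettings(n_steps=800, burn_in=200, thin=2, seed=5)
        a = mcmc_sample([meth5_series], fixed_model, {"tau_T": 70.0}, settings)
        b = mcmc_sample([meth5_series], fixed_model, {"tau_T": 70.0}, settings)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.log_post, b.log_post)

    def test_matches_affine_invariant_sampler(self, meth5_series, fixed_model):
        # independent cross-check of the posterior geometry with emcee
        emcee = pytest.importorskip("emcee")
        names = ("w_S", "w_Exc")

        def logp(vec):
            return log_posterior_named(dict(zip(names, vec)), [meth5_series],
                                       fixed_model)

        ens = mcmc_sample(
            [meth5_series], fixed_model, {"w_S": 1.0, "w_Exc": 1.0},
            MCMCSettings(n_steps=6_000, burn_in=2_000, thin=5, seed=3))
        rng = np.random.default_rng(0)
        walkers = 16
        p0 = np.array([1.2, 0.85]) + 0.01 * rng.standard_normal((walkers, 2))
        sampler = emcee.EnsembleSampler(walkers, 2, logp)
        state = sampler.run_mcmc(p0, 700, progress=False)
        flat = sampler.get_chain(discard=300, flat=True)
        for i, name in enumerate(names):
            se = max(ens.se()[name], flat[:, i].std())
            assert abs(ens.mean()[name] - flat[:, i].mean()) < 3 * se

    def test_bad_init_rejected(self, meth5_series, fixed_model):
        with pytest.raises(ValueError):
            mcmc_sample([meth5_series], fixed_model, {"w_Exc": -1.0},
                        MCMCSettings(n_steps=100, burn_in=10))


class TestZTest:
    @staticmethod
    def _ensemble(mean, se, name="w_S", label="g", n=4000, seed=0):
        rng = np.random.default_rng(seed)
        samples = rng.normal(mean, se, (n, 1))
        # shift/scale to the exact requested moments
        samples = (samples - samples.mean()) / samples.std(ddof=1) * se + mean
        return PosteriorEnsemble(names=(name,), samples=samples,
                                 log_post=np.zeros(n), acceptance_rate=0.3,
                                 seed=seed, label=label)

    def test_identical_groups(self):
        e = self._ensemble(1.0, 0.1, label="a")
        r = compare_groups(e, self._ensemble(1.0, 0.1, label="b"), "w_S")
        assert r.z == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)
        assert not r.significant

    def test_known_z_and_p(self):
        r = compare_groups(self._ensemble(1.5, 0.1, label="a"),
                           self._ensemble(1.0, 0.1, label="b"), "w_S")
        assert r.z == pytest.approx(3.5355, abs=1e-3)
        assert r.p_value == pytest.approx(4.07e-4, rel=0.01)
        assert r.significant

    def test_swap_symmetry(self):
        e1 = self._ensemble(1.5, 0.1, label="a", seed=1)
        e2 = self._ensemble(1.0, 0.12, label="b", seed=2)
        r12 = compare_groups(e1, e2, "w_S")
        r21 = compare_groups(e2, e1, "w_S")
        assert r21.z == pytest.approx(-r12.z)
        assert r21.p_value == pytest.approx(r12.p_value)

    def test_zero_se_rejected(self):
        e1 = self._ensemble(1.0, 0.1)
        e2 = self._ensemble(1.0, 0.1)
        e1.samples[:] = 1.0
        e2.samples[:] = 1.0
        with pytest.raises(ZeroDivisionError):
            compare_groups(e1, e2, "w_S")


def test_gamma_hd_parametrization_fit_path(clean_series, fixed_model):
    # the basal-tone parametrization scores identically to the base model at
    # the matching parameter values
    alt = ParamVectorW(w_S=1.2, w_Exc=0.85, w_Inh=0.66, gamma_HD=-3.69)
    assert log_posterior(alt, [clean_series], fixed_model) == \
        pytest.approx(0.0, abs=1e-12)
    assert log_posterior_named({"gamma_HD": -2.0}, [clean_series],
                               fixed_model) < -1.0


def test_xlsx_animal_layout_reader(tmp_path, design, vehicle_truth):
    import pandas as pd
    from meththerm.inference import read_series_xlsx

    clean = noiseless_trajectory(vehicle_truth, design, meth_dose=1.0)
    rng = np.random.default_rng(4)
    animals = clean[None, :] + rng.normal(0, 0.3, (6, clean.size))
    df = pd.DataFrame({"time_min": design.times}
                      | {f"rat{i}": animals[i] for i in range(6)})
    path = tmp_path / "group.xlsx"
    df.to_excel(path, index=False)
    series = read_series_xlsx(path, meth_dose=1.0)
    assert series.n == 6
    np.testing.assert_allclose(series.mean, animals.mean(axis=0), atol=1e-9)
    np.testing.assert_allclose(series.sd, animals.std(axis=0, ddof=1),
                               atol=1e-9)


def test_series_roundtrip_and_sem(tmp_path, meth5_series):
    path = tmp_path / "grp.csv"
    write_series(path, meth5_series)
    back = read_series(path, sb_dose=0.0, meth_dose=5.0)
    np.testing.assert_allclose(back.mean, meth5_series.mean, atol=1e-9)
    np.testing.assert_allclose(back.sd, meth5_series.sd, atol=1e-9)
    assert back.n == meth5_series.n
    np.testing.assert_allclose(meth5_series.sem,
                               meth5_series.sd / np.sqrt(7), atol=1e-12)
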