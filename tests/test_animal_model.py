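"""MCMC sampler correctness and convergence-diagnostic calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats, special

from socped import (
    DesignSpec,
    InverseWishartPrior,
    ModelSpec,
    ParameterExpandedPrior,
    PriorSpec,
    build_design,
    dic,
    effective_parameters,
    effective_sample_size,
    fit_animal_model,
    gelman_rubin,
    heidelberger_welch,
    hpd_interval,
    posterior_mode,
    run_chains,
)
from socped.animal_model import PosteriorChain


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

class TestGelmanRubin:
    def test_identical_chains_exactly_one(self, rng):
        x = rng.normal(size=1000)
        assert gelman_rubin([x, x.copy()]) == pytest.approx(1.0, abs=1e-9)

    def test_separated_chains_large(self, rng):
        a = rng.normal(0.0, 1.0, 1000)
        b = rng.normal(10.0, 1.0, 1000)
        assert gelman_rubin([a, b]) > 3.0

    def test_hand_computed_psrf(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 3.0, 4.0, 5.0, 7.0])
        # independent arithmetic: W = mean of chain variances, b = var of
        # chain means, pooled = W + 1.5 b, df correction from Brooks-Gelman
        m, n = 2, 5
        W = (a.var(ddof=1) + b.var(ddof=1)) / 2
        bb = np.var([a.mean(), b.mean()], ddof=1)
        vhat = W + (1 + 1 / m) * bb
        s2 = np.array([a.var(ddof=1), b.var(ddof=1)])
        means = np.array([a.mean(), b.mean()])
        var_vhat = (
            s2.var(ddof=1) / m
            + ((m + 1) / (m * n)) ** 2 * (2 / (m - 1)) * (n * bb) ** 2
            + 2 * ((m + 1) / (m * n)) * (n / m)
            * (np.cov(s2, means**2, ddof=1)[0, 1]
               - 2 * means.mean() * np.cov(s2, means, ddof=1)[0, 1])
        )
        d = 2 * vhat**2 / var_vhat
        expect = np.sqrt((d + 3) / (d + 1) * vhat / W)
        assert gelman_rubin([a, b]) == pytest.approx(expect, rel=1e-12)

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin([rng.normal(size=100)])

    def test_unequal_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin([rng.normal(size=100), rng.normal(size=99)])


class TestESS:
    def test_iid_near_n(self, rng):
        x = rng.normal(size=10000)
        assert 0.9 * 10000 <= effective_sample_size(x) <= 10000

    def test_ar1_matches_analytic(self, rng):
        phi, n = 0.9, 10000
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n) * np.sqrt(1 - phi**2)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        expect = n * (1 - phi) / (1 + phi)
        assert effective_sample_size(x) == pytest.approx(expect, rel=0.2)

    def test_antithetic_capped_at_n(self):
        x = np.tile([1.0, -1.0], 500)
        assert effective_sample_size(x) == 1000.0

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            effective_sample_size(np.ones(5))


class TestHeidelbergerWelch:
    def test_iid_pass_rate(self):
        rng = np.random.default_rng(2024)
        passes = sum(
            heidelberger_welch(rng.normal(size=5000))[0] for _ in range(200)
        )
        assert passes >= 180  # nominal 1 - alpha = 0.95

    def test_linear_drift_fails(self, rng):
        x = np.linspace(0.0, 5.0, 5000) + rng.normal(0, 0.5, 5000)
        stationary, _ = heidelberger_welch(x)
        assert not stationary

    def test_constant_chain_passes_at_zero(self):
        assert heidelberger_welch(np.full(500, 3.14)) == (True, 0)

    def test_burnin_recovered_by_discarding(self, rng):
        # stationary after an initial transient: passes with start > 0
        x = np.concatenate([np.full(800, 8.0), rng.normal(0, 1, 4200)])
        stationary, start = heidelberger_welch(x)
        assert stationary and start > 0


class TestDicModeHpd:
    def test_dic_arithmetic(self):
        ch = PosteriorChain(
            draws=pd.DataFrame({"deviance": [10.0, 12.0, 14.0]}),
            meta={"deviance_at_mean": 11.0},
        )
        assert dic(ch) == pytest.approx(13.0)
        assert effective_parameters(ch) == pytest.approx(1.0)

    def test_dic_constant_deviance(self):
        ch = PosteriorChain(
            draws=pd.DataFrame({"deviance": np.full(50, 42.0)}),
            meta={"deviance_at_mean": 42.0},
        )
        assert dic(ch) == pytest.approx(42.0)
        assert effective_parameters(ch) == pytest.approx(0.0)

    def test_missing_deviance(self):
        ch = PosteriorChain(
            draws=pd.DataFrame({"deviance": [np.nan, 1.0]}),
            meta={"deviance_at_mean": 1.0},
        )
        with pytest.raises(ValueError):
            dic(ch)

    def test_mode_and_hpd_constant(self):
        x = np.full(300, 2.5)
        assert posterior_mode(x) == 2.5
        assert hpd_interval(x) == (2.5, 2.5)

    def test_mode_and_hpd_gaussian(self, rng):
        x = rng.normal(3.0, 1.0, 100_000)
        assert posterior_mode(x) == pytest.approx(3.0, abs=0.05)
        lo, hi = hpd_interval(x, 0.95)
        assert lo == pytest.approx(3.0 - 1.96, abs=0.05)
        assert hi == pytest.approx(3.0 + 1.96, abs=0.05)

    def test_hpd_exponential_shorter_than_equal_tail(self, rng):
        x = rng.exponential(1.0, 100_000)
        lo, hi = hpd_interval(x, 0.95)
        assert lo == pytest.approx(0.0, abs=0.05)
        assert hi == pytest.approx(-np.log(0.05), abs=0.05)
        assert hi - lo < np.quantile(x, 0.975) - np.quantile(x, 0.025)

    def test_hpd_invalid_prob(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(10.0), prob=1.5)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def tiny_design(rng, n_subj=12, per=15, n_trials=40, v_id=1.0, v_res=1.0,
                intercept=0.0):
    """Small one-component binomial dataset with known truth."""
    rows = []
    u = rng.normal(0.0, np.sqrt(v_id), n_subj)
    for i in range(n_subj):
        for k in range(per):
            eta = intercept + u[i] + rng.normal(0.0, np.sqrt(v_res))
            y = rng.binomial(n_trials, 1.0 / (1.0 + np.exp(-eta)))
            rows.append(
                dict(subject=f"S{i:02d}", year=2000 + k // 12, month=1 + k % 12,
                     group="G", alpha="A", n_scans=n_trials, n_social=int(y),
                     total_partners=0, age_years=5.0, sex="F",
                     group_size=10.0, mei=0.0, mother=None)
            )
    return build_design(
        pd.DataFrame(rows),
        DesignSpec(age_sex_cubic=False, group_size=False, season=False,
                   enso=False),
    )


SMALL = dict(n_iter=3000, burnin=1000, thin=2)


class TestFit:
    def test_seed_determinism_and_exchangeability(self, rng):
        d = tiny_design(rng)
        spec = ModelSpec(family="binomial_logit", random_terms=("ID",))
        a = fit_animal_model(d, spec, seed=5, **SMALL)
        b = fit_animal_model(d, spec, seed=5, **SMALL)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        # permuting record order leaves the chain bitwise identical because
        # records are canonically sorted before sampling
        perm = np.random.default_rng(1).permutation(len(d.records))
        d2 = build_design(
            d.records.iloc[perm].reset_index(drop=True),
            DesignSpec(age_sex_cubic=False, group_size=False, season=False,
                       enso=False),
        )
        c = fit_animal_model(d2, spec, seed=5, **SMALL)
        pd.testing.assert_frame_equal(a.draws, c.draws)

    def test_different_seeds_differ(self, rng):
        d = tiny_design(rng)
        spec = ModelSpec(family="binomial_logit", random_terms=("ID",))
        a = fit_animal_model(d, spec, seed=5, **SMALL)
        b = fit_animal_model(d, spec, seed=6, **SMALL)
        assert not a.draws.equals(b.draws)

    def test_gaussian_limit_against_reference_gibbs(self, rng):
        # n_trials = 1000 per row: the logit of the observed proportion is a
        # nearly noiseless reading of eta, so a Gaussian-response Gibbs
        # sampler on logit(y/n) is a valid independent reference
        d = tiny_design(rng, n_subj=15, per=12, n_trials=1000)
        prior = PriorSpec(g_default=InverseWishartPrior(1.0, 0.002))
        spec = ModelSpec(family="binomial_logit", random_terms=("ID",))
        ch = fit_animal_model(d, spec, prior, n_iter=8000, burnin=2000,
                              thin=3, seed=3)

        rec = d.records.sort_values(["subject", "year", "month"])
        z = special.logit((rec["n_social"] + 0.5) / (rec["n_scans"] + 1.0)).to_numpy()
        codes = pd.factorize(rec["subject"])[0]
        nl = codes.max() + 1
        gen = np.random.default_rng(99)
        b0, u, vid, vres = 0.0, np.zeros(nl), 1.0, 1.0
        keep_vid, keep_vres = [], []
        for it in range(24000):
            r = z - u[codes]
            b0 = gen.normal(r.mean(), np.sqrt(vres / len(z)))
            r = z - b0
            cnt = np.bincount(codes, minlength=nl)
            s = np.bincount(codes, weights=r, minlength=nl)
            prec = cnt / vres + 1.0 / vid
            u = s / vres / prec + gen.normal(size=nl) / np.sqrt(prec)
            vid = (0.002 * 1.0 + u @ u) / 2 / gen.gamma((0.002 + nl) / 2)
            e = z - b0 - u[codes]
            vres = (0.002 * 1.0 + e @ e) / 2 / gen.gamma((0.002 + len(z)) / 2)
            if it >= 4000:
                keep_vid.append(vid)
                keep_vres.append(vres)
        ref_vid, ref_vres = np.mean(keep_vid), np.mean(keep_vres)
        se = 3 * max(np.std(keep_vid) / 30, 0.02)
        assert ch.draws["V_ID"].mean() == pytest.approx(ref_vid, abs=3 * se)
        assert ch.draws["V_residual"].mean() == pytest.approx(ref_vres, abs=0.15)

    def test_prior_only_matches_implied_scaled_f(self, rng):
        # with the likelihood disabled the sampled variance marginal must
        # reproduce the parameter-expanded prior: V / (alpha_V * V0) ~ F(1, nu)
        d = tiny_design(rng, n_subj=12, per=6)
        prior = PriorSpec(
            g_default=ParameterExpandedPrior(V=1.0, nu=1.0, alpha_mu=0.0,
                                             alpha_V=1000.0)
        )
        spec = ModelSpec(family="binomial_logit", random_terms=("ID",))
        ch = fit_animal_model(d, spec, prior, n_iter=5600, burnin=600, thin=1,
                              seed=8, likelihood=False)
        v = ch.draws["V_ID"].to_numpy() / 1000.0
        ks = stats.kstest(v, "f", args=(1.0, 1.0)).statistic
        assert ks < 0.05

    def test_poisson_family_recovers_rate(self, rng):
        rows = []
        for i in range(15):
            for k in range(10):
                n = 30
                y = rng.poisson(n * np.exp(0.5))
                rows.append(
                    dict(subject=f"S{i}", year=2000, month=1 + k % 12,
                         group="G", alpha="A", n_scans=n, n_social=0,
                         total_partners=int(y), age_years=5.0, sex="F",
                         group_size=10.0, mei=0.0, mother=None)
                )
        d = build_design(
            pd.DataFrame(rows),
            DesignSpec(age_sex_cubic=False, group_size=False, season=False,
                       enso=False, offset_log_scans=True),
        )
        spec = ModelSpec(family="poisson_log", random_terms=("ID",))
        ch = fit_animal_model(d, spec, seed=4, **SMALL)
        assert ch.draws["beta:intercept"].mean() == pytest.approx(0.5, abs=0.1)

    def test_dic_prefers_generating_model(self, rng):
        wins = 0
        for rep in range(20):
            d = tiny_design(rng, n_subj=12, per=10, v_id=1.5, v_res=0.5)
            full = fit_animal_model(
                d, ModelSpec(family="binomial_logit", random_terms=("ID",)),
                n_iter=2000, burnin=600, thin=2, seed=rep,
            )
            pruned = fit_animal_model(
                d, ModelSpec(family="binomial_logit", random_terms=()),
                n_iter=2000, burnin=600, thin=2, seed=rep,
            )
            wins += dic(full) < dic(pruned)
        assert wins >= 18

    def test_multiple_chains_and_diagnostics(self, rng):
        d = tiny_design(rng)
        spec = ModelSpec(family="binomial_logit", random_terms=("ID",))
        chains = run_chains(d, spec, n_chains=2, seed=0, n_iter=4000,
                            burnin=1500, thin=2)
        assert len({c.meta["seed"] for c in chains}) == 2
        psrf = gelman_rubin(chains, "V_ID")
        assert psrf < 1.1
        assert effective_sample_size(chains[0], "V_ID") > 50

    def test_model_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec(family="gaussian")
        with pytest.raises(ValueError):
            ModelSpec(family="binomial_logit", random_terms=("bogus",))
        with pytest.raises(ValueError):
            ModelSpec(family="binomial_logit", random_terms=("animal",))

    def test_prior_sensitivity_hpds_overlap(self, default_dataset):
        """The parameter-expanded prior and both inverse-Wishart variants
        give overlapping 95% HPDs for the heritability proportion."""
        ds = default_dataset
        spec = ModelSpec(family="binomial_logit", A=ds.pruned_amatrix())
        intervals = []
        for g in (ParameterExpandedPrior(1.0, 1.0, 0.0, 1000.0),
                  InverseWishartPrior(1.0, 0.002),
                  InverseWishartPrior(1.0, 0.02)):
            ch = fit_animal_model(ds.design, spec, PriorSpec(g_default=g),
                                  n_iter=3000, burnin=1000, thin=2, seed=12)
            comps = [c for c in ch.draws.columns if c.startswith("V_")]
            h2 = ch.draws["V_A"] / ch.draws[comps].sum(axis=1)
            intervals.append(hpd_interval(h2.to_numpy()))
        for (lo1, hi1) in intervals:
            for (lo2, hi2) in intervals:
                assert max(lo1, lo2) <= min(hi1, hi2)

    def test_chain_save_load_round_trip(self, rng, tmp_path):
        d = tiny_design(rng)
        spec = ModelSpec(family="binomial_logit", random_terms=("ID",))
        ch = fit_animal_model(d, spec, seed=2, n_iter=400, burnin=100, thin=2)
        path = tmp_path / "chain.csv"
        ch.save(path)
        back = type(ch).load(path)
        pd.testing.assert_frame_equal(ch.draws, back.draws)
        assert back.meta["seed"] == 2

    def test_fixed_residual_not_updated(self, rng):
        d = tiny_design(rng)
        spec = ModelSpec(family="binomial_logit", random_terms=("ID",),
                         residual=1.0)
        ch = fit_animal_model(d, spec, seed=2, n_iter=600, burnin=200, thin=1)
        assert (ch.draws["V_residual"] == 1.0).all()
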