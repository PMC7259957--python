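"""Unit and property tests for the spike-and-slab Poisson count model."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import gammaln
from scipy.stats import kstest

from erlumen import counts, simulate
from erlumen.counts import (
    CountTable,
    ModelSpec,
    ModelState,
    compute_lfsr,
    compute_mu_plugin,
    gibbs_update_conjugates,
    log_likelihood,
    run_mcmc,
    slab_inclusion_probability,
    update_alpha,
)
from erlumen.errors import ValidationError


def make_table(y):
    y = np.asarray(y)
    return CountTable(
        proteins=[f"P{i}" for i in range(y.shape[0])],
        blocks=[f"b{i}" for i in range(y.shape[1])],
        y=y,
    )


def make_state(table, beta=None, z=None, alpha=None, sigma2=None, tau2=1.0, pi0=0.5):
    p, C = table.n_proteins, table.n_blocks
    return ModelState(
        beta=np.zeros(p) if beta is None else np.asarray(beta, dtype=float),
        z=np.zeros(p, dtype=int) if z is None else np.asarray(z, dtype=int),
        alpha=np.zeros((p, C)) if alpha is None else np.asarray(alpha, dtype=float),
        sigma2=np.ones(C) if sigma2 is None else np.asarray(sigma2, dtype=float),
        tau2=tau2,
        pi0=pi0,
    )


class TestCountTable:
    def test_rejects_single_protein(self):
        with pytest.raises(ValidationError):
            make_table(np.zeros((1, 1, 2), dtype=int))

    def test_rejects_negative_and_fractional_counts(self):
        with pytest.raises(ValidationError):
            make_table([[[1, -1]], [[0, 0]]])
        with pytest.raises(ValidationError):
            make_table(np.array([[[1.5, 0]], [[0, 0]]]))

    def test_from_dataframe_missing_cell(self):
        df = pd.DataFrame(
            {
                "protein_id": ["A", "A", "B"],
                "block_id": ["c1", "c1", "c1"],
                "condition": [0, 1, 0],
                "count": [3, 5, 2],
            }
        )
        with pytest.raises(ValidationError, match="missing"):
            CountTable.from_dataframe(df)
        table = CountTable.from_dataframe(df, impute_missing=True)
        assert table.y[table.proteins.index("B"), 0, 1] == 0


class TestMuPlugin:
    def test_all_zero_counts_gives_one(self):
        table = make_table(np.zeros((5, 3, 2), dtype=int))
        assert np.allclose(compute_mu_plugin(table), 1.0)

    def test_hand_computed_example(self):
        # p=2, one block: ((3+5+2)/2 + (0+2+2)/2) / 2 = 3.5
        table = make_table([[[3, 5]], [[0, 2]]])
        assert compute_mu_plugin(table) == pytest.approx([3.5])


class TestLogLikelihood:
    def test_unit_rate_zero_count_cell(self):
        # y=0, pseudo-count 1, lambda=1: log Poisson(1; 1) = -1
        table = make_table([[[0, 0]], [[0, 0]]])
        spec = ModelSpec(mu=np.array([1.0]))
        state = make_state(table)
        assert log_likelihood(state, table, spec) == pytest.approx(-4.0)

    def test_condition_swap_symmetry_at_beta_zero(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(4.0, size=(6, 2, 2))
        table = make_table(y)
        swapped = make_table(y[:, :, ::-1])
        spec = ModelSpec()
        state = make_state(table, alpha=rng.normal(0, 0.3, (6, 2)))
        assert log_likelihood(state, table, spec) == pytest.approx(
            log_likelihood(state, swapped, spec)
        )

    def test_matches_brute_force_summed_poisson_mass(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(3.0, size=(4, 2, 2))
        table = make_table(y)
        mu = np.array([2.0, 3.5])
        spec = ModelSpec(mu=mu)
        state = make_state(
            table,
            beta=rng.normal(0, 1, 4),
            z=np.ones(4),
            alpha=rng.normal(0, 0.5, (4, 2)),
        )
        expected = 0.0
        for g in range(4):
            for c in range(2):
                for t in (0, 1):
                    lam = mu[c] * np.exp(state.alpha[g, c] + t * state.beta[g])
                    s = y[g, c, t] + 1
                    expected += s * np.log(lam) - lam - gammaln(s + 1)
        assert log_likelihood(state, table, spec) == pytest.approx(expected)


class TestConjugateUpdates:
    def test_empty_slab_pi0_posterior(self):
        table = make_table(np.ones((8, 2, 2), dtype=int))
        spec = ModelSpec()
        rng = np.random.default_rng(3)
        draws = []
        for _ in range(4000):
            state = make_state(table)
            gibbs_update_conjugates(state, table, spec, rng)
            draws.append(state.pi0)
        # pi0 | all z=0 ~ Beta(0.5 + 8, 0.5); mean 8.5/9
        mean = 8.5 / 9.0
        sd = np.sqrt(mean * (1 - mean) / 10.0)
        assert np.mean(draws) == pytest.approx(mean, abs=3 * sd / np.sqrt(4000))

    def test_tau_posterior_moments_single_slab_protein(self):
        # one protein with z=1, beta=2: tau^-2 ~ Gamma(1.5, rate 3), mean 0.5
        table = make_table(np.ones((2, 1, 2), dtype=int))
        spec = ModelSpec()
        rng = np.random.default_rng(4)
        n = 20000
        prec = []
        for _ in range(n):
            state = make_state(table, beta=[2.0, 0.0], z=[1, 0])
            gibbs_update_conjugates(state, table, spec, rng)
            prec.append(1.0 / state.tau2)
        mean, var = 1.5 / 3.0, 1.5 / 9.0
        assert np.mean(prec) == pytest.approx(mean, abs=3 * np.sqrt(var / n))

    def test_sigma_posterior_moments(self):
        # sigma_c^-2 ~ Gamma(1 + p/2, 1 + sum alpha^2 / 2) per block
        p = 6
        alpha = np.linspace(-1, 1, p).reshape(p, 1)
        table = make_table(np.ones((p, 1, 2), dtype=int))
        spec = ModelSpec()
        rng = np.random.default_rng(5)
        n = 20000
        prec = []
        for _ in range(n):
            state = make_state(table, alpha=alpha)
            gibbs_update_conjugates(state, table, spec, rng)
            prec.append(1.0 / state.sigma2[0])
        shape = 1 + p / 2.0
        rate = 1 + float(np.sum(alpha**2)) / 2.0
        mean, var = shape / rate, shape / rate**2
        assert np.mean(prec) == pytest.approx(mean, abs=3 * np.sqrt(var / n))


def oracle_inclusion_probability(b, c, tau2, pi0):
    """Brute-force P(z=1 | rest) by adaptive 1-D quadrature."""
    # stabilise: shift by the integrand's log maximum on a dense scan
    scan = np.linspace(-40, 40, 20001)
    logf = b * scan - c * np.exp(np.clip(scan, -30, 30)) - scan**2 / (2 * tau2)
    shift = logf.max()

    def integrand(beta):
        return np.exp(
            b * beta - c * np.exp(beta) - beta**2 / (2 * tau2) - shift
        )

    val, _ = quad(integrand, -40, 40, limit=400)
    log_m1 = np.log(val) + shift - 0.5 * np.log(2 * np.pi * tau2)
    log_m0 = -c
    logit = (np.log1p(-pi0) + log_m1) - (np.log(pi0) + log_m0)
    return 1.0 / (1.0 + np.exp(-logit))


class TestBetaZUpdate:
    def test_inclusion_probability_matches_quadrature_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            b = float(rng.integers(1, 60))
            c = float(rng.uniform(0.5, 40.0))
            tau2 = float(rng.uniform(0.1, 4.0))
            pi0 = float(rng.uniform(0.05, 0.95))
            got = slab_inclusion_probability(
                np.array([b]), np.array([c]), tau2, pi0
            )[0]
            want = oracle_inclusion_probability(b, c, tau2, pi0)
            assert got == pytest.approx(want, abs=1e-4)

    def test_spike_dominates_identical_conditions(self):
        # equal counts in both conditions and pi0 -> 1: P(z=1) -> 0
        p1 = slab_inclusion_probability(
            np.array([10.0]), np.array([10.0]), 1.0, 0.999
        )[0]
        assert p1 < 0.05

    def test_degenerate_slab_collapses_beta(self):
        table = make_table(np.full((3, 2, 2), 5, dtype=int))
        spec = ModelSpec(mu=compute_mu_plugin(make_table(np.full((3, 2, 2), 5))))
        state = make_state(table, tau2=1e-10, pi0=0.5)
        rng = np.random.default_rng(7)
        counts.update_beta_and_z(state, table, spec, rng)
        assert np.all(np.abs(state.beta) < 1e-3)


class TestAlphaUpdate:
    def test_tight_prior_pins_alpha(self):
        table = make_table(np.full((2, 1, 2), 3, dtype=int))
        spec = ModelSpec()
        state = make_state(table, alpha=np.full((2, 1), 2.0), sigma2=[1e-8])
        rng = np.random.default_rng(8)
        for _ in range(3000):
            update_alpha(state, table, spec, rng, step=np.full((2, 1), 0.05))
        assert np.all(np.abs(state.alpha) < 0.05)

    def test_stationary_law_matches_gridded_conditional(self):
        """Long RWM chain on one cell reproduces the exact conditional."""
        y = np.array([[[7, 9]], [[3, 3]]])
        table = make_table(y)
        mu = np.array([4.0])
        spec = ModelSpec(mu=mu)
        sigma2 = 0.8
        state = make_state(table, sigma2=[sigma2])
        rng = np.random.default_rng(9)
        step = np.full((2, 1), 0.6)
        samples = []
        for i in range(40000):
            update_alpha(state, table, spec, rng, step)
            if i % 2 == 0:
                samples.append(state.alpha[0, 0])
        samples = np.asarray(samples[500:])
        # gridded conditional: d*a - e*exp(a) - a^2/(2 sigma2)
        d = (y[0, 0, 0] + 1) + (y[0, 0, 1] + 1)
        e = mu[0] * 2.0  # beta = 0
        grid = np.linspace(-4, 4, 8001)
        logf = d * grid - e * np.exp(grid) - grid**2 / (2 * sigma2)
        pdf = np.exp(logf - logf.max())
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]

        def grid_cdf(x):
            return np.interp(x, grid, cdf)

        stat = kstest(samples, grid_cdf).statistic
        assert stat < 0.02

    def test_high_equal_counts_concentrate_at_poisson_mle(self):
        y = np.full((2, 1, 2), 400, dtype=int)
        table = make_table(y)
        mu = np.array([10.0])
        spec = ModelSpec(mu=mu)
        state = make_state(table, sigma2=[4.0])
        rng = np.random.default_rng(10)
        step = np.full((2, 1), 0.1)
        vals = []
        for i in range(6000):
            update_alpha(state, table, spec, rng, step)
            if i > 1000:
                vals.append(state.alpha[0, 0])
        assert np.mean(vals) == pytest.approx(np.log(401 / 10.0), abs=0.05)


class TestMcmc:
    def test_same_seed_bit_identical(self):
        cfg = simulate.CountSimConfig(p=12, n_blocks=2, pi0=0.7, seed=11)
        table, _ = simulate.simulate_counts(cfg)
        a = run_mcmc(table, n_iter=200, burn_in=100, seed=42)
        b = run_mcmc(table, n_iter=200, burn_in=100, seed=42)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.tau2, b.tau2)

    def test_parameter_recovery_on_simulated_data(self):
        cfg = simulate.CountSimConfig(
            p=60, n_blocks=3, pi0=0.8, tau=1.5, sigma=0.5, seed=12
        )
        table, truth = simulate.simulate_counts(cfg, shifted=True)
        draws = run_mcmc(
            table, ModelSpec(pseudo_count=0), n_iter=1200, burn_in=600, seed=13
        )
        r = np.corrcoef(draws.beta.mean(axis=0), truth["beta"])[0, 1]
        assert r > 0.8

    def test_null_data_pushes_pi0_up(self):
        cfg = simulate.CountSimConfig(p=50, n_blocks=3, pi0=1.0, seed=14)
        table, _ = simulate.simulate_counts(cfg, shifted=True)
        draws = run_mcmc(
            table, ModelSpec(pseudo_count=0), n_iter=800, burn_in=400, seed=15
        )
        assert draws.pi0.mean() > 0.5

    def test_block_permutation_leaves_inference_equivalent(self):
        cfg = simulate.CountSimConfig(p=40, n_blocks=3, pi0=0.8, tau=1.5, seed=16)
        table, _ = simulate.simulate_counts(cfg, shifted=True)
        permuted = CountTable(
            proteins=table.proteins,
            blocks=[table.blocks[i] for i in (2, 0, 1)],
            y=table.y[:, (2, 0, 1), :],
        )
        spec = ModelSpec(pseudo_count=0)
        # the (z, beta) conditional depends on blocks only through sums,
        # so the inclusion probability is exactly permutation invariant
        mu_a = compute_mu_plugin(table)
        mu_b = compute_mu_plugin(permuted)
        assert np.allclose(np.sort(mu_a), np.sort(mu_b))
        a = run_mcmc(table, spec, n_iter=1000, burn_in=500, seed=17)
        b = run_mcmc(permuted, spec, n_iter=1000, burn_in=500, seed=17)
        lfsr_a = compute_lfsr(a).table["lfsr"].to_numpy()
        lfsr_b = compute_lfsr(b).table["lfsr"].to_numpy()
        assert np.mean(np.abs(lfsr_a - lfsr_b)) < 0.03
        assert np.corrcoef(lfsr_a, lfsr_b)[0, 1] > 0.98


class TestLfsr:
    def test_direct_count_examples(self):
        draws = counts.PosteriorDraws(
            proteins=["A", "B", "C"],
            blocks=["b1"],
            beta=np.array(
                [[-1.0, 1.0, 0.0], [0.0, 2.0, 0.0], [2.0, 3.0, 0.0], [3.0, 0.5, 0.0]]
            ),
            z=np.array([[1, 1, 0]] * 4),
            alpha=None,
            sigma2=np.ones((4, 1)),
            tau2=np.ones(4),
            pi0=np.full(4, 0.5),
            seed=0,
            n_iter=4,
            burn_in=0,
            thin=1,
            alpha_acceptance=0.4,
        )
        res = compute_lfsr(draws)
        lfsr = dict(zip(res.table.protein_id, res.table.lfsr))
        assert lfsr["A"] == pytest.approx(0.5)  # draws (-1, 0, 2, 3)
        assert lfsr["B"] == 0.0  # all positive
        assert lfsr["C"] == 1.0  # all spike zeros
        assert res.selected == ["A", "B"] or res.selected == ["B"]
        # threshold is inclusive: lfsr exactly 0.2 selects
        res2 = compute_lfsr(draws, threshold=0.5)
        assert "A" in res2.selected

    def test_global_rate_is_mean_of_selected(self):
        rng = np.random.default_rng(18)
        beta = rng.normal(1.0, 1.0, size=(200, 10))
        draws = counts.PosteriorDraws(
            proteins=[f"P{i}" for i in range(10)],
            blocks=["b"],
            beta=beta,
            z=np.ones_like(beta, dtype=int),
            alpha=None,
            sigma2=np.ones((200, 1)),
            tau2=np.ones(200),
            pi0=np.full(200, 0.5),
            seed=0,
            n_iter=200,
            burn_in=0,
            thin=1,
            alpha_acceptance=0.4,
        )
        res = compute_lfsr(draws)
        if res.selected:
            sel = res.table[res.table.selected]
            assert res.global_false_sign_rate == pytest.approx(sel.lfsr.mean())
            assert res.global_false_sign_rate <= res.threshold

    def test_mean_lfsr_nonincreasing_in_effect_size(self):
        """Scaling bait counts upward cannot raise the expected lfsr."""
        base = np.array([[[4, 4]], [[3, 3]], [[5, 5]]])
        mean_lfsr = []
        for scale in (1.0, 2.0, 4.0):
            vals = []
            for rep in range(40):
                rng = np.random.default_rng(100 + rep)
                y = base.copy()
                y[0, 0, 1] = rng.poisson(4.0 * scale)
                table = make_table(y)
                draws = run_mcmc(table, n_iter=400, burn_in=200, seed=rep)
                vals.append(compute_lfsr(draws).table["lfsr"].iloc[0])
            mean_lfsr.append(np.mean(vals))
        assert mean_lfsr[0] >= mean_lfsr[1] - 0.02
        assert mean_lfsr[1] >= mean_lfsr[2] - 0.02
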