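"""Multi-regime OU likelihood and reversible-jump shift detection."""

import math

import numpy as np
import pytest
from scipy import stats

from linkage_evo import (
    OUParams,
    Phylogeny,
    Shift,
    ShiftConfiguration,
    bm_loglik,
    gelman_r,
    ou_loglik,
    rjmcmc_shifts,
    summarize_shifts,
)
from linkage_evo.errors import InsufficientSamples, InvalidBurnin
from linkage_evo.ou import ou_cov, ou_mean
from linkage_evo.shifts import ShiftPosterior
from linkage_evo.simulate import simulate_ou_with_shifts, simulate_tree

NO_SHIFTS = ShiftConfiguration(())


def _single_shift_pp_oracle(y, tree, n_grid=12):
    """Deterministic per-branch shift probabilities, truncated at one shift.

    Uses the same priors as the sampler: truncated Poisson(1) on the
    shift count, uniform branch and position, N(mean y, (2 sd y)^2) on
    each optimum, half-Cauchy on alpha and sigma2.  The optima are
    marginalised exactly (the OU mean is linear in them); alpha, sigma2
    and the position are integrated on log-spaced / uniform grids.
    """
    from scipy import linalg as sla

    depths = tree.tip_depths()
    C = tree.vcv()
    bt = tree.branch_table()
    T = float(depths.max())
    n = len(y)
    B = bt.n_branches
    pm, psd = float(np.mean(y)), 2.0 * float(np.std(y))
    a_scale, s_scale = 2.0 / T, float(np.var(y)) / T

    alphas = np.exp(np.linspace(np.log(0.05), np.log(40.0), n_grid))
    sig2s = np.exp(np.linspace(np.log(0.02), np.log(20.0), n_grid))
    wa = np.gradient(np.log(alphas))
    ws = np.gradient(np.log(sig2s))

    def log_half_cauchy(x, s):
        return math.log(2.0 / (math.pi * s)) - math.log1p((x / s) ** 2)

    lm0, lmb = [], [[] for _ in range(B)]
    for ia, a in enumerate(alphas):
        for isg, s2 in enumerate(sig2s):
            V = ou_cov(C, depths, a, s2)
            L = sla.cholesky(V, lower=True)
            logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
            yw = sla.solve_triangular(L, y, lower=True)
            lw = (log_half_cauchy(a, a_scale) + math.log(a) + math.log(wa[ia])
                  + log_half_cauchy(s2, s_scale) + math.log(s2) + math.log(ws[isg]))

            def marginal(F):
                # y ~ N(F theta, V), theta ~ N(pm 1, psd^2 I), via Woodbury
                Fw = sla.solve_triangular(L, F, lower=True)
                G = Fw.T @ Fw
                r = yw - Fw @ np.full(F.shape[1], pm)
                sol = np.linalg.solve(np.eye(F.shape[1]) + psd ** 2 * G, Fw.T @ r)
                quad = float(r @ r) - psd ** 2 * float(r @ Fw @ sol)
                ld = logdet + np.linalg.slogdet(
                    np.eye(F.shape[1]) + psd ** 2 * G)[1]
                return -0.5 * (n * math.log(2.0 * math.pi) + ld + quad)

            lm0.append(lw + marginal(np.ones((n, 1))))
            for b in range(B):
                vals = []
                for pos in (0.25, 0.75):
                    ts = bt.t_start[b] + pos * (bt.t_end[b] - bt.t_start[b])
                    w = np.where(bt.tip_mask[b],
                                 -np.expm1(-a * (depths - ts)), 0.0)
                    vals.append(marginal(np.column_stack([1.0 - w, w])))
                m = max(vals)
                lmb[b].append(lw + m + math.log(np.mean(np.exp(np.array(vals) - m))))

    def lse(v):
        v = np.array(v)
        m = v.max()
        return m + math.log(np.sum(np.exp(v - m)))

    lM0 = lse(lm0)
    lMb = [lse(x) for x in lmb]
    pk = np.array([1.0 / math.factorial(k) for k in range(10)])
    pk /= pk.sum()
    terms = [math.log(pk[0]) + lM0] + [math.log(pk[1] / B) + m for m in lMb]
    Z = lse(terms)
    return np.array([math.exp(math.log(pk[1] / B) + m - Z) for m in lMb])


class TestOULoglik:
    def test_bm_limit_small_alpha(self):
        """With one regime and alpha -> 0 the OU likelihood tends to BM."""
        tree = simulate_tree(40, seed=1)
        rng = np.random.default_rng(2)
        y = rng.standard_normal(40)
        sigma2 = 0.7
        alpha = 1e-6 / tree.depth()
        # BM likelihood at the same (profiled-out) mean: centre y first
        theta = float(np.mean(y))
        ll_ou = ou_loglik(y, tree, NO_SHIFTS,
                          OUParams(alpha=alpha, sigma2=sigma2, theta_base=theta))
        # BM counterpart with the mean fixed at theta
        C = tree.vcv()
        ll_bm = stats.multivariate_normal.logpdf(y, mean=np.full(40, theta),
                                                 cov=sigma2 * C)
        assert abs(ll_ou - ll_bm) < 1e-4

    def test_two_tip_closed_form(self):
        """Hand-computed mean/variance for a cherry with one shift."""
        tree = Phylogeny.from_newick("(A:1,B:1);")
        alpha, sigma2, th0, th1 = 1.3, 0.8, 0.2, 1.7
        bt = tree.branch_table()
        branch_a = int(np.where(bt.tip_mask[:, tree.tip_labels.index("A")])[0][0])
        config = ShiftConfiguration((Shift(branch_a, 0.5, th1),))
        params = OUParams(alpha=alpha, sigma2=sigma2, theta_base=th0)
        y = np.array([0.9, -0.1])
        got = ou_loglik(y, tree, config, params)

        # independent symbolic evaluation of the same model
        v = sigma2 / (2 * alpha) * (1 - math.exp(-2 * alpha * 1.0))
        mean_a = th0 + (th1 - th0) * (1 - math.exp(-alpha * 0.5))
        mean_b = th0
        means = {"A": mean_a, "B": mean_b}
        want = sum(
            stats.norm.logpdf(y[i], loc=means[lab], scale=math.sqrt(v))
            for i, lab in enumerate(tree.tip_labels)
        )
        assert abs(got - want) < 1e-12

    def test_stationarity_large_alpha(self):
        """For alpha*T >> 1 every tip expectation approaches its regime theta."""
        tree = simulate_tree(30, seed=3)
        depths = tree.tip_depths()
        bt = tree.branch_table()
        params = OUParams(alpha=20.0, sigma2=1.0, theta_base=-1.0)
        mean = ou_mean(depths, bt, NO_SHIFTS, params)
        assert np.allclose(mean, -1.0)
        # one ancient shift: tips below it are pulled to the new optimum
        deep = int(np.argmax((~bt.is_terminal) * bt.tip_mask.sum(axis=1)
                             * (bt.tip_mask.sum(axis=1) < 15)))
        config = ShiftConfiguration((Shift(deep, 0.0, 2.0),))
        mean = ou_mean(depths, bt, config, params)
        below = bt.tip_mask[deep]
        gap = np.exp(-params.alpha * (depths[below] - bt.t_start[deep])) * 3.0
        assert np.all(np.abs(mean[below] - 2.0) <= gap + 1e-12)
        assert np.allclose(mean[~below], -1.0)

    def test_cov_matches_bm_limit_elementwise(self):
        tree = simulate_tree(20, seed=4)
        C = tree.vcv()
        V = ou_cov(C, tree.tip_depths(), alpha=1e-12, sigma2=0.5)
        assert np.allclose(V, 0.5 * C, rtol=1e-6)

    def test_nested_shifts_telescoping(self):
        """A shift overridden by a tipward shift leaves only the nearest
        regime's pull at stationarity."""
        tree = simulate_tree(30, seed=5)
        bt = tree.branch_table()
        depths = tree.tip_depths()
        sizes = bt.tip_mask.sum(axis=1)
        outer = int(np.argmax((~bt.is_terminal) * sizes * (sizes < 15)))
        inner_candidates = np.where(
            (bt.tip_mask[outer] @ bt.tip_mask.T > 0)
            & (np.arange(bt.n_branches) != outer)
            & (sizes < sizes[outer]))[0]
        inner = int(inner_candidates[0])
        params = OUParams(alpha=50.0, sigma2=1.0, theta_base=0.0)
        config = ShiftConfiguration((Shift(outer, 0.0, 5.0), Shift(inner, 0.9, -3.0)))
        mean = ou_mean(depths, bt, config, params)
        below_inner = bt.tip_mask[inner]
        assert np.allclose(mean[below_inner], -3.0, atol=1e-2)


class TestGelmanR:
    def test_identical_chains(self):
        x = np.linspace(0, 1, 500)
        assert abs(gelman_r(np.stack([x, x])) - 1.0) < 1e-6

    def test_same_distribution_near_one(self):
        rng = np.random.default_rng(6)
        chains = rng.standard_normal((2, 10_000))
        assert abs(gelman_r(chains) - 1.0) < 0.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(7)
        chains = np.stack([rng.standard_normal(500), 10.0 + rng.standard_normal(500)])
        assert gelman_r(chains) > 1.1

    def test_insufficient_samples(self):
        with pytest.raises(InsufficientSamples):
            gelman_r(np.zeros((2, 10)))
        with pytest.raises(InsufficientSamples):
            gelman_r(np.zeros((1, 500)))


class TestSummarizeShifts:
    def _post(self, pp, after=None, before=None):
        B = len(pp)
        return ShiftPosterior(
            branch_pp=np.array(pp),
            theta_after_mean=np.array(after if after is not None else [np.nan] * B),
            theta_before_mean=np.array(before if before is not None else [np.nan] * B),
            shift_count_freq=np.zeros(B + 1),
            traces=[], gelman_r={}, n_generations=0, burnin_fraction=0.3,
            n_branches=B, n_tips=0, n_samples_post_burnin=0,
        )

    def test_below_threshold_empty(self):
        table = summarize_shifts(self._post([0.1, 0.4, 0.5]))
        assert table.empty

    def test_single_supported_branch(self):
        table = summarize_shifts(
            self._post([0.1, 0.88, 0.2], after=[np.nan, 1.5, np.nan],
                       before=[np.nan, 0.5, np.nan]))
        assert list(table["branch"]) == [1]
        assert table.loc[0, "pp"] == pytest.approx(0.88)
        assert table.loc[0, "direction"] == 1


class TestRJMCMC:
    def test_invalid_burnin_rejected(self):
        tree = simulate_tree(10, seed=8)
        with pytest.raises(InvalidBurnin):
            rjmcmc_shifts(np.zeros(10), tree, n_generations=100, burnin=1.5)

    def test_small_tree_warns(self):
        tree = simulate_tree(10, seed=9)
        with pytest.warns(UserWarning, match="fewer than 50"):
            rjmcmc_shifts(np.zeros(10), tree, n_generations=200, chains=1,
                          prior_only=True)

    def test_prior_only_recovers_stated_prior(self):
        """With the likelihood disabled the sampler reproduces its prior:
        truncated-Poisson shift counts and uniform branch probabilities."""
        tree = simulate_tree(101, seed=1)
        post = rjmcmc_shifts(np.zeros(101), tree, n_generations=300_000,
                             chains=2, seed=3, prior_only=True, thin=100,
                             burnin=0.1)
        B = post.n_branches
        n = post.n_samples_post_burnin
        # shift-count distribution: Poisson(1) truncated at B
        pk = np.array([1.0 / math.factorial(k) for k in range(20)])
        pk /= pk.sum()
        obs = np.array([post.shift_count_freq[0], post.shift_count_freq[1],
                        post.shift_count_freq[2], post.shift_count_freq[3:].sum()])
        exp = np.array([pk[0], pk[1], pk[2], pk[3:].sum()])
        _, p = stats.chisquare(obs * n, exp * n)
        assert p > 0.01
        # per-branch probability uniform within Monte-Carlo error
        pp = post.branch_pp
        mean_pp = pp.mean()
        assert np.isclose(mean_pp, post.shift_count_freq @ np.arange(B + 1) / B)
        assert pp.std() / mean_pp < 0.5
        assert pp.max() < 3.0 * mean_pp

    def test_recovers_single_deep_shift(self):
        """A 3-stationary-SD optimum shift on a deep branch of a 101-tip
        tree is assigned high posterior probability at that branch."""
        tree = simulate_tree(101, seed=1)
        bt = tree.branch_table()
        sizes = bt.tip_mask.sum(axis=1)
        branch = int(np.where((~bt.is_terminal) & (sizes >= 15) & (sizes <= 35))[0][0])
        alpha, sigma2 = 2.0, 1.0
        sd_stat = math.sqrt(sigma2 / (2 * alpha))
        table = simulate_ou_with_shifts(
            tree, [(branch, 0.5, 3 * sd_stat)], alpha=alpha, sigma2=sigma2,
            theta_base=0.0, seed=5)
        y = table.values(["trait"]).ravel()
        post = rjmcmc_shifts(y, tree, n_generations=100_000, chains=2, seed=7)
        neighborhood = {branch, int(bt.parent[branch])} | {
            int(b) for b in np.where(bt.parent == branch)[0]}
        assert max(post.branch_pp[list(neighborhood)]) > 0.5
        for key, r in post.gelman_r.items():
            assert r < 1.1, f"chain disagreement on {key}: R={r:.3f}"

    def test_no_shift_data_yields_no_support(self):
        tree = simulate_tree(101, seed=2)
        table = simulate_ou_with_shifts(tree, [], alpha=2.0, sigma2=1.0,
                                        theta_base=0.0, seed=11)
        y = table.values(["trait"]).ravel()
        post = rjmcmc_shifts(y, tree, n_generations=60_000, chains=2, seed=13)
        assert np.sum(post.branch_pp > 0.5) == 0

    def test_branch_pp_matches_quadrature_oracle(self):
        """Posterior shift probabilities agree with a deterministic oracle.

        For models with at most one shift the posterior is computable
        without MCMC: the optima enter the OU mean linearly, so they
        marginalise analytically under their normal prior, and alpha,
        sigma2 and the shift position are integrated by quadrature over
        their priors.  The sampler's per-branch probabilities (which also
        visit multi-shift configurations) should track this truncated
        oracle closely when the data support at most one shift.
        """
        tree = simulate_tree(40, seed=21)
        bt = tree.branch_table()
        sizes = bt.tip_mask.sum(axis=1)
        branch = int(np.where((~bt.is_terminal) & (sizes >= 8) & (sizes <= 16))[0][0])
        table = simulate_ou_with_shifts(tree, [(branch, 0.5, 2.5)], alpha=3.0,
                                        sigma2=1.0, theta_base=0.0, seed=22)
        y = table.values(["trait"]).ravel()
        pp_oracle = _single_shift_pp_oracle(y, tree)
        # cap the sampler at one shift so both sides target the same
        # (zero-or-one-shift) model space
        with pytest.warns(UserWarning, match="fewer than 50"):
            post = rjmcmc_shifts(y, tree, n_generations=200_000, chains=2,
                                 seed=23, max_shifts=1)
        assert int(np.argmax(pp_oracle)) == int(np.argmax(post.branch_pp))
        assert abs(pp_oracle[branch] - post.branch_pp[branch]) < 0.1

    def test_simulator_and_likelihood_share_model(self):
        """Round trip: data simulated at known parameters has higher
        likelihood there than at perturbed optima."""
        tree = simulate_tree(60, seed=14)
        bt = tree.branch_table()
        sizes = bt.tip_mask.sum(axis=1)
        branch = int(np.argmax((~bt.is_terminal) * sizes * (sizes <= 20)))
        params = OUParams(alpha=3.0, sigma2=1.0, theta_base=0.0)
        config = ShiftConfiguration((Shift(branch, 0.5, 2.0),))
        wins = 0
        for rep in range(20):
            table = simulate_ou_with_shifts(tree, [(branch, 0.5, 2.0)],
                                            alpha=3.0, sigma2=1.0, seed=100 + rep)
            y = table.values(["trait"]).ravel()
            ll_true = ou_loglik(y, tree, config, params)
            worse = ShiftConfiguration((Shift(branch, 0.5, 2.0 + 2.0),))
            ll_pert = ou_loglik(y, tree, worse, params)
            wins += ll_true > ll_pert
        assert wins >= 18
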