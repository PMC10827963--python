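"""Hierarchical Bayesian latent-trait estimation of MPT models.

Model: participant ``i``'s yes-count in category ``c`` is binomial with
probability given by the MPT category probability at ``theta_i =
Phi(z_i)``, where the probit-scale vectors ``z_i ~ MVN(mu, Sigma)`` describe
population heterogeneity. Priors: ``mu_p ~ Normal(0, 1)`` on the probit
scale and ``Sigma ~ Inverse-Wishart(k + 1, I)``, the conjugate analogue of
the scaled-Wishart prior used by standard latent-trait MPT tooling.

Sampling is Metropolis-within-Gibbs: the individual ``z_i`` are updated by
adaptive component-wise random-walk Metropolis (vectorised across
participants), while ``mu | z, Sigma`` (multivariate normal) and
``Sigma | z, mu`` (inverse-Wishart) are exact conjugate Gibbs draws.
Convergence is summarised by split-R-hat and bulk effective sample size on
the group-level locations, computed with ArviZ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import norm, wishart

from .model import MptModel, build_dual_recollection_model
from .simulate import ResponseDataset

__all__ = [
    "PosteriorSummary",
    "fit_latent_trait",
    "posterior_predictive_check",
    "group_contrast_draws",
]


@dataclass
class PosteriorSummary:
    """Posterior draws and probability-scale summaries of a latent-trait fit."""

    parameter_names: tuple[str, ...]
    participants: tuple[str, ...]
    group_means: dict[str, float]
    group_sds: dict[str, float]
    bci_95: dict[str, tuple[float, float]]
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    flags: tuple[str, ...]
    draws: dict[str, np.ndarray]  # mu/phi_mu: (chains, draws, k); theta: (chains, draws, n, k)
    model: MptModel
    n_chains: int
    n_warmup: int
    n_draws: int
    seed: int
    ppc: dict | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def individual_means(self) -> np.ndarray:
        """Posterior-mean individual parameters, shape (participants, k)."""
        return self.draws["theta"].mean(axis=(0, 1))

    def phi_mu_draws(self, parameter: str) -> np.ndarray:
        """Flat (chains x draws) vector of Phi(mu_p) draws."""
        j = self.parameter_names.index(parameter)
        return self.draws["phi_mu"][:, :, j].reshape(-1)

    def to_inference_data(self):
        import arviz as az

        return az.from_dict(
            posterior={
                "mu": self.draws["mu"],
                "phi_mu": self.draws["phi_mu"],
                "sigma_diag": self.draws["sigma_diag"],
            },
            coords={"parameter": list(self.parameter_names)},
            dims={"mu": ["parameter"], "phi_mu": ["parameter"], "sigma_diag": ["parameter"]},
        )

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.parameter_names:
            lo, hi = self.bci_95[p]
            rows.append(
                {
                    "parameter": p,
                    "mean": self.group_means[p],
                    "sd": self.group_sds[p],
                    "bci_lower": lo,
                    "bci_upper": hi,
                    "rhat": self.rhat[p],
                    "ess": self.ess[p],
                }
            )
        return pd.DataFrame(rows)

    def draws_frame(self) -> pd.DataFrame:
        """Flat CSV-ready export of the group-level draws."""
        chains, draws, k = self.draws["phi_mu"].shape
        records = {
            "chain": np.repeat(np.arange(chains), draws),
            "draw": np.tile(np.arange(draws), chains),
        }
        for j, p in enumerate(self.parameter_names):
            records[f"phi_mu_{p}"] = self.draws["phi_mu"][:, :, j].reshape(-1)
        return pd.DataFrame(records)


def _run_chain(model, y, n, seed, n_warmup, n_draws, mu_prior_var=1.0):
    """One MCMC chain; returns (mu, sigma, theta) retained draws."""
    rng = np.random.default_rng(seed)
    P, _ = y.shape
    k = model.n_parameters
    eye = np.eye(k)

    def loglik_rows(z: np.ndarray) -> np.ndarray:
        p = np.clip(model.p_yes(ndtr(z)), 1e-12, 1 - 1e-12)
        return (y * np.log(p) + (n - y) * np.log1p(-p)).sum(axis=1)

    # initial state: crude probit of smoothed group rates via mu = 0
    mu = rng.normal(0.0, 0.1, size=k)
    z = mu + rng.normal(0.0, 0.1, size=(P, k))
    sigma = eye * 0.25
    sigma_inv = np.linalg.inv(sigma)
    scales = np.full((P, k), 0.4)
    shift_scales = np.full(k, 0.2)
    rescale_scales = np.full(k, 0.3)
    joint_scale = 1.0
    joint_cov = eye * 0.01
    mu_mean = np.zeros(k)
    mu_m2 = np.zeros((k, k))
    mu_count = 0
    cur_ll = loglik_rows(z)

    mu_out = np.empty((n_draws, k))
    sigma_out = np.empty((n_draws, k, k))
    theta_out = np.empty((n_draws, P, k))

    for t in range(n_warmup + n_draws):
        # --- individual probit-scale parameters, componentwise Metropolis
        dev = z - mu
        for j in range(k):
            step = rng.normal(0.0, scales[:, j])
            prop = z.copy()
            prop[:, j] += step
            ll_new = loglik_rows(prop)
            # prior quadratic-form change for a single-component move
            dq = 2.0 * step * (dev @ sigma_inv[j]) + step**2 * sigma_inv[j, j]
            log_r = ll_new - cur_ll - 0.5 * dq
            accept = np.log(rng.uniform(size=P)) < log_r
            z[accept, j] = prop[accept, j]
            dev[accept, j] += step[accept]
            cur_ll[accept] = ll_new[accept]
            if t < n_warmup:
                gamma = min(0.2, 2.0 / np.sqrt(t + 1.0))
                scales[:, j] *= np.exp(gamma * (accept.astype(float) - 0.44))

        # --- translation move: shift mu_j and every z_ij together, keeping
        # the deviations fixed; essential for group-level mixing when the
        # per-participant likelihoods are weak relative to the prior
        for j in range(k):
            eps = rng.normal(0.0, shift_scales[j])
            prop = z.copy()
            prop[:, j] += eps
            ll_new = loglik_rows(prop)
            mu_j_new = mu[j] + eps
            log_r = (ll_new - cur_ll).sum() - 0.5 * (mu_j_new**2 - mu[j] ** 2) / mu_prior_var
            if np.log(rng.uniform()) < log_r:
                z = prop
                mu = mu.copy()
                mu[j] = mu_j_new
                cur_ll = ll_new
                accepted = 1.0
            else:
                accepted = 0.0
            if t < n_warmup:
                gamma = min(0.2, 2.0 / np.sqrt(t + 1.0))
                shift_scales[j] *= np.exp(gamma * (accepted - 0.3))

        # --- rescale move: contract/expand the deviations of one component,
        # traversing the funnel between the group-level spread and the
        # individual displacements of weakly identified parameters
        for j in range(k):
            s = rng.normal(0.0, rescale_scales[j])
            c = np.exp(s)
            dev = z - mu
            step = (c - 1.0) * dev[:, j]
            prop = z.copy()
            prop[:, j] += step
            ll_new = loglik_rows(prop)
            dq = 2.0 * step * (dev @ sigma_inv[j]) + step**2 * sigma_inv[j, j]
            log_r = (ll_new - cur_ll).sum() - 0.5 * dq.sum() + P * s
            accepted = float(np.log(rng.uniform()) < log_r)
            if accepted:
                z = prop
                cur_ll = ll_new
            if t < n_warmup:
                gamma = min(0.2, 2.0 / np.sqrt(t + 1.0))
                rescale_scales[j] *= np.exp(gamma * (accepted - 0.3))

        # --- joint translation with a proposal covariance adapted to the
        # posterior correlations of mu (e.g. familiarity trading off against
        # the either-question bias)
        if t > 50:
            try:
                chol = np.linalg.cholesky(joint_cov + 1e-8 * eye)
                eps = joint_scale * (chol @ rng.normal(size=k))
            except np.linalg.LinAlgError:
                eps = joint_scale * rng.normal(size=k) * 0.1
            prop = z + eps
            ll_new = loglik_rows(prop)
            mu_new = mu + eps
            log_r = (ll_new - cur_ll).sum() - 0.5 * (mu_new @ mu_new - mu @ mu) / mu_prior_var
            accepted = float(np.log(rng.uniform()) < log_r)
            if accepted:
                z = prop
                mu = mu_new
                cur_ll = ll_new
            if t < n_warmup:
                gamma = min(0.2, 2.0 / np.sqrt(t + 1.0))
                joint_scale *= np.exp(gamma * (accepted - 0.23))
        if t < n_warmup:
            # running moments of mu for the joint proposal covariance
            mu_count += 1
            delta_mu = mu - mu_mean
            mu_mean += delta_mu / mu_count
            mu_m2 += np.outer(delta_mu, mu - mu_mean)
            if mu_count > 2 * k:
                joint_cov = mu_m2 / (mu_count - 1)

        # --- group location, conjugate normal draw
        prec = eye / mu_prior_var + P * sigma_inv
        cov = np.linalg.inv(prec)
        mean = cov @ (sigma_inv @ z.sum(axis=0))
        mu = rng.multivariate_normal(mean, cov, method="svd")

        # --- covariance, conjugate inverse-Wishart draw
        dev = z - mu
        scale = np.linalg.inv(eye + dev.T @ dev)
        sigma_inv = wishart.rvs(df=k + 1 + P, scale=scale, random_state=rng)
        sigma = np.linalg.inv(sigma_inv)

        if t >= n_warmup:
            i = t - n_warmup
            mu_out[i] = mu
            sigma_out[i] = sigma
            theta_out[i] = ndtr(z)

    return mu_out, sigma_out, theta_out


def fit_latent_trait(
    data: ResponseDataset,
    model: MptModel | None = None,
    seed: int = 0,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_draws: int = 1000,
    rhat_threshold: float = 1.05,
    ess_threshold: float = 400.0,
) -> PosteriorSummary:
    """Sample the latent-trait posterior for a response dataset.

    A non-converged fit (any group-level split-R-hat above
    ``rhat_threshold``) is returned with ``converged=False`` and an entry in
    ``flags`` — never silently.
    """
    import arviz as az

    if model is None:
        model = build_dual_recollection_model(data.design)
    if data.n_participants < 2:
        raise ValueError("latent-trait estimation needs at least 2 participants")
    y, n = data.count_matrices(model.categories)
    k = model.n_parameters

    chain_seeds = np.random.SeedSequence(seed).spawn(n_chains)
    mu_draws, sigma_draws, theta_draws = [], [], []
    for cs in chain_seeds:
        mu_c, sigma_c, theta_c = _run_chain(model, y, n, cs, n_warmup, n_draws)
        mu_draws.append(mu_c)
        sigma_draws.append(sigma_c)
        theta_draws.append(theta_c)
    mu_draws = np.stack(mu_draws)  # (chains, draws, k)
    sigma_draws = np.stack(sigma_draws)
    theta_draws = np.stack(theta_draws)
    phi_mu = norm.cdf(mu_draws)
    sigma_diag = np.einsum("cdkk->cdk", sigma_draws)

    idata = az.from_dict(
        posterior={"mu": mu_draws},
        coords={"parameter": list(model.parameter_names)},
        dims={"mu": ["parameter"]},
    )
    rhat_arr = az.rhat(idata)["mu"].to_numpy()
    ess_arr = az.ess(idata)["mu"].to_numpy()
    rhat = dict(zip(model.parameter_names, map(float, rhat_arr)))
    ess = dict(zip(model.parameter_names, map(float, ess_arr)))

    flags = []
    converged = bool(np.all(rhat_arr < rhat_threshold))
    if not converged:
        worst = max(rhat, key=rhat.get)
        flags.append(f"non-convergence: R-hat({worst}) = {rhat[worst]:.3f} > {rhat_threshold}")
    if np.any(ess_arr < ess_threshold):
        worst = min(ess, key=ess.get)
        flags.append(f"low effective sample size: ESS({worst}) = {ess[worst]:.0f} < {ess_threshold:.0f}")

    flat = phi_mu.reshape(-1, k)
    lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
    summary = PosteriorSummary(
        parameter_names=model.parameter_names,
        participants=tuple(map(str, data.participants)),
        group_means=dict(zip(model.parameter_names, map(float, flat.mean(axis=0)))),
        group_sds=dict(zip(model.parameter_names, map(float, flat.std(axis=0, ddof=1)))),
        bci_95={p: (float(lo[j]), float(hi[j])) for j, p in enumerate(model.parameter_names)},
        rhat=rhat,
        ess=ess,
        converged=converged,
        flags=tuple(flags),
        draws={
            "mu": mu_draws,
            "phi_mu": phi_mu,
            "sigma_diag": sigma_diag,
            "sigma": sigma_draws,
            "theta": theta_draws,
        },
        model=model,
        n_chains=n_chains,
        n_warmup=n_warmup,
        n_draws=n_draws,
        seed=seed,
    )
    return summary


# ---------------------------------------------------------------------------
# posterior-predictive fit statistics
# ---------------------------------------------------------------------------


def posterior_predictive_check(
    posterior: PosteriorSummary,
    data: ResponseDataset,
    n_rep: int = 500,
    seed: int = 0,
) -> dict:
    """T1/T2 posterior-predictive p-values.

    T1 is a Pearson chi-square distance between observed and expected
    category *mean frequencies* (averaged over participants, yes- and
    no-cells both included); T2 is the summed squared deviation between the
    observed and the expected across-participant covariance matrix of the
    category frequencies. For each retained posterior draw a replicate
    dataset is simulated from the individual-level parameters; the p-value
    is the fraction of draws in which the replicate statistic is at least as
    large as the observed one.
    """
    model = posterior.model
    y, n = data.count_matrices(model.categories)
    theta = posterior.draws["theta"].reshape(-1, *posterior.draws["theta"].shape[2:])
    total = theta.shape[0]
    warnings = []
    if total < n_rep:
        warnings.append(f"only {total} retained draws available (< {n_rep}); using all")
        idx = np.arange(total)
    else:
        idx = np.linspace(0, total - 1, n_rep).astype(int)
    theta = theta[idx]  # (D, P, k)
    rng = np.random.default_rng(seed)

    p = np.clip(model.p_yes(theta), 1e-12, 1 - 1e-12)  # (D, P, C)
    e = n * p
    y_rep = rng.binomial(n[None, :, :], p)

    # T1: Pearson distance on mean frequencies (yes and no cells)
    def t1_stat(obs_counts, expected):
        o_yes = obs_counts.mean(axis=-2)
        o_no = (n - obs_counts).mean(axis=-2)
        e_yes = expected.mean(axis=-2)
        e_no = (n - expected).mean(axis=-2)
        return ((o_yes - e_yes) ** 2 / e_yes + (o_no - e_no) ** 2 / e_no).sum(axis=-1)

    t1_obs = t1_stat(y[None, :, :], e)
    t1_rep = t1_stat(y_rep, e)
    t1_p = float(np.mean(t1_rep >= t1_obs))

    # T2: squared distance between across-participant covariance matrices
    s_obs = np.cov(y.T)
    iu = np.triu_indices(y.shape[1])

    def cov_distance(sample_cov, expected_cov):
        d = sample_cov - expected_cov
        return (d[iu] ** 2).sum()

    t2_obs = np.empty(len(idx))
    t2_rep = np.empty(len(idx))
    for d in range(len(idx)):
        binom_var = np.diag((n * p[d] * (1 - p[d])).mean(axis=0))
        s_exp = np.cov(e[d].T) + binom_var
        t2_obs[d] = cov_distance(s_obs, s_exp)
        t2_rep[d] = cov_distance(np.cov(y_rep[d].T), s_exp)
    t2_p = float(np.mean(t2_rep >= t2_obs))

    report = {"T1_p": t1_p, "T2_p": t2_p, "n_draws": int(len(idx)), "warnings": warnings}
    posterior.ppc = report
    return report


def group_contrast_draws(
    posterior: PosteriorSummary,
    parameter_a: str,
    parameter_b: str | None = None,
    posterior_b: PosteriorSummary | None = None,
) -> np.ndarray:
    """Per-draw differences of group-level probability-scale parameters.

    Within one fit, draws of ``Phi(mu_a) - Phi(mu_b)`` are differenced
    draw-by-draw. Across two independent fits (between-subject contrasts)
    draws are paired by index, which requires equal retained draw counts.
    """
    a = posterior.phi_mu_draws(parameter_a)
    if posterior_b is None:
        if parameter_b is None:
            raise ValueError("need parameter_b or posterior_b for a contrast")
        b = posterior.phi_mu_draws(parameter_b)
    else:
        b = posterior_b.phi_mu_draws(parameter_b or parameter_a)
        if len(a) != len(b):
            raise ValueError(
                f"draw-count mismatch between fits ({len(a)} vs {len(b)}); cannot pair draws"
            )
    return a - b
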