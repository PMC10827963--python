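"""Maximum-likelihood estimation of MPT parameters.

Per-participant (or aggregated) yes/no counts are modelled as independent
binomials per (probe, item class) cell with success probabilities given by
the model's category probabilities. The likelihood is maximised over an
unconstrained probit transform of the parameters with seeded multi-start
optimisation, because MPT likelihoods can be multimodal near the boundary of
the parameter space.

Individual fits on few trials are intentionally noisy: no shrinkage toward
group means is applied, so that downstream Bayes-factor tests receive
genuinely independent per-participant estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, norm

from .model import MptModel, ParameterVector
from .simulate import ResponseDataset

__all__ = ["FitResult", "fit_ml", "goodness_of_fit", "fit_dataset"]

_EPS = 1e-6  # boundary guard on the probability scale


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    estimates: ParameterVector
    log_likelihood: float
    g2: float
    df: int
    p_value: float | None
    converged: bool
    n_starts_used: int
    model: MptModel
    standard_errors: dict[str, float] | None = None
    hessian_singular: bool = False
    at_boundary: tuple[str, ...] = ()
    messages: tuple[str, ...] = field(default_factory=tuple)


def _counts_arrays(counts: pd.DataFrame, model: MptModel) -> tuple[np.ndarray, np.ndarray]:
    """Align a counts table with the model's category order."""
    grouped = counts.groupby(["probe", "item_class"], sort=False)[["n_yes", "n_total"]].sum()
    y = np.zeros(len(model.categories))
    n = np.zeros(len(model.categories))
    for i, key in enumerate(model.categories):
        if key not in grouped.index:
            raise ValueError(f"no counts for tree {key[0]}|{key[1]}")
        y[i], n[i] = grouped.loc[key, "n_yes"], grouped.loc[key, "n_total"]
    empty = [f"{q}|{c}" for (q, c), tot in zip(model.categories, n) if tot == 0]
    if empty:
        raise ValueError(f"empty cells for trees: {', '.join(empty)}")
    return y, n


def _binomial_loglik(p: np.ndarray, y: np.ndarray, n: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (n - y) * np.log1p(-p)))


def fit_ml(
    counts: pd.DataFrame,
    model: MptModel,
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    compute_se: bool = True,
) -> FitResult:
    """Maximise the product-binomial likelihood over theta in [0, 1]^k.

    ``counts`` is a long table with columns ``probe, item_class, n_yes,
    n_total`` covering every tree of the model (a participant slice of a
    :class:`~dualrec.simulate.ResponseDataset`, or aggregated counts).
    """
    y, n = _counts_arrays(counts, model)
    k = model.n_parameters

    def negll(z: np.ndarray) -> float:
        return -_binomial_loglik(model.p_yes(norm.cdf(z)), y, n)

    rng = np.random.default_rng(seed)
    starts = [np.zeros(k)] + [rng.normal(0.0, 1.0, size=k) for _ in range(max(0, n_starts - 1))]
    best = None
    n_ok = 0
    for z0 in starts:
        res = optimize.minimize(negll, z0, method="L-BFGS-B", options={"ftol": tol, "gtol": 1e-10})
        n_ok += int(res.success)
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    # high-precision polish of the best optimum (multistart uses the cheaper
    # default tolerances; large counts need a near-exact stationary point)
    polished = optimize.minimize(
        negll, best.x, method="L-BFGS-B", jac="3-point",
        options={"ftol": 1e-15, "gtol": 1e-12},
    )
    if polished.fun <= best.fun:
        best = polished

    theta_hat = np.clip(norm.cdf(best.x), _EPS, 1 - _EPS)
    at_boundary = tuple(
        name
        for name, v in zip(model.parameter_names, theta_hat)
        if v <= _EPS or v >= 1 - _EPS
    )
    estimates = ParameterVector(zip(model.parameter_names, theta_hat))
    loglik = _binomial_loglik(model.p_yes(theta_hat), y, n)
    g2, df, p_value = _g2(model, theta_hat, y, n)

    standard_errors = None
    hessian_singular = False
    messages = []
    if compute_se:
        standard_errors, hessian_singular = _observed_information_se(model, theta_hat, y, n)
        if hessian_singular:
            messages.append("observed information singular; standard errors unavailable")
    if n_ok == 0:
        messages.append("no optimiser start reported formal convergence")
    return FitResult(
        estimates=estimates,
        log_likelihood=loglik,
        g2=g2,
        df=df,
        p_value=p_value,
        converged=n_ok > 0,
        n_starts_used=len(starts),
        model=model,
        standard_errors=standard_errors,
        hessian_singular=hessian_singular,
        at_boundary=at_boundary,
        messages=tuple(messages),
    )


def _g2(model: MptModel, theta: np.ndarray, y: np.ndarray, n: np.ndarray):
    p = np.clip(model.p_yes(theta), 1e-12, 1 - 1e-12)
    exp_yes, exp_no = n * p, n * (1 - p)
    obs_yes, obs_no = y, n - y

    def term(obs, exp):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = obs * np.log(obs / exp)
        return np.where(obs > 0, t, 0.0)

    g2 = float(2.0 * (term(obs_yes, exp_yes).sum() + term(obs_no, exp_no).sum()))
    g2 = max(g2, 0.0)
    df = len(model.categories) - model.n_parameters
    p_value = float(chi2.sf(g2, df)) if df > 0 else None
    return g2, df, p_value


def goodness_of_fit(fit: FitResult, counts: pd.DataFrame) -> tuple[float, int, float | None]:
    """G2 deviance, degrees of freedom and chi-square upper-tail p-value.

    With ``df <= 0`` (saturated or over-parameterised model) the p-value is
    reported as ``None``.
    """
    y, n = _counts_arrays(counts, fit.model)
    theta = fit.estimates.as_array(fit.model.parameter_names)
    return _g2(fit.model, theta, y, n)


def _observed_information_se(model: MptModel, theta: np.ndarray, y: np.ndarray, n: np.ndarray):
    """SEs from the inverse observed information on the probability scale."""
    k = len(theta)
    h = 1e-5

    def ll(t):
        return _binomial_loglik(model.p_yes(np.clip(t, 1e-9, 1 - 1e-9)), y, n)

    hess = np.empty((k, k))
    f0 = ll(theta)
    for i in range(k):
        for j in range(i, k):
            ti = theta.copy()
            if i == j:
                ti[i] += h
                up = ll(ti)
                ti[i] -= 2 * h
                dn = ll(ti)
                hess[i, i] = (up - 2 * f0 + dn) / h**2
            else:
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[[i, j]] += h
                tpm[i] += h
                tpm[j] -= h
                tmp[i] -= h
                tmp[j] += h
                tmm[[i, j]] -= h
                hess[i, j] = hess[j, i] = (ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm)) / (4 * h**2)
    info = -hess
    try:
        cov = np.linalg.inv(info)
        variances = np.diag(cov)
        if np.any(variances <= 0) or not np.all(np.isfinite(variances)):
            return None, True
        return dict(zip(model.parameter_names, np.sqrt(variances))), False
    except np.linalg.LinAlgError:
        return None, True


def fit_dataset(
    dataset: ResponseDataset,
    model: MptModel,
    n_starts: int = 10,
    seed: int = 0,
    compute_se: bool = True,
) -> pd.DataFrame:
    """Fit every participant independently; one row per participant.

    The returned frame has columns ``participant``, one ``est_<param>`` and
    ``se_<param>`` per parameter, plus ``log_likelihood, G2, df, p_value,
    converged``. This is the exact input format of the batch Bayes-factor
    runner in :mod:`dualrec.stats`.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for pid in dataset.participants:
        fit = fit_ml(
            dataset.participant_counts(pid),
            model,
            n_starts=n_starts,
            seed=int(rng.integers(0, 2**31 - 1)),
            compute_se=compute_se,
        )
        row: dict = {"participant": pid}
        for name in model.parameter_names:
            row[f"est_{name}"] = fit.estimates[name]
            if fit.standard_errors is not None:
                row[f"se_{name}"] = fit.standard_errors[name]
            else:
                row[f"se_{name}"] = np.nan
        row.update(
            log_likelihood=fit.log_likelihood,
            G2=fit.g2,
            df=fit.df,
            p_value=fit.p_value,
            converged=fit.converged,
        )
        rows.append(row)
    return pd.DataFrame(rows)
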