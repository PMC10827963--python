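"""Descriptive measures, posterior contrast decisions and default-prior
Bayes factors.

The Bayes-factor tests mirror the standard default-prior toolkit for
two-condition comparisons: the JZS t-test (Cauchy prior with scale
``r = 1/sqrt(2)`` on the standardised effect size, marginal likelihood by
adaptive quadrature) and rank-based analogues (Wilcoxon signed-rank and
Mann-Whitney/rank-sum) computed by latent-normal data augmentation with a
Savage-Dickey density ratio at zero effect.

Evidence labels follow the conventional thresholds: a Bayes factor above 10
is strong and between 3 and 10 moderate evidence for the alternative;
symmetrically, below 0.1 strong and between 0.1 and 1/3 moderate evidence
for the null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import cauchy, mannwhitneyu, nct, norm, rankdata
from scipy.stats import t as t_dist

__all__ = [
    "ContrastResult",
    "BayesFactorResult",
    "corrected_acceptance_rate",
    "contrast_decision",
    "jzs_ttest_bf",
    "rank_bf",
    "evidence_label",
    "run_bf_tests",
]

DEFAULT_CAUCHY_SCALE = 1.0 / math.sqrt(2.0)


# ---------------------------------------------------------------------------
# descriptive measures and contrast decisions
# ---------------------------------------------------------------------------


def corrected_acceptance_rate(target_yes: float, distractor_yes: float) -> float:
    """CAR: P(yes | target) minus P(yes | distractor); guessing-corrected accuracy."""
    for name, v in (("target_yes", target_yes), ("distractor_yes", distractor_yes)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be a rate in [0, 1], got {v}")
    return float(target_yes) - float(distractor_yes)


@dataclass(frozen=True)
class ContrastResult:
    """Posterior mean, central 95% interval and substantiality of a contrast."""

    mean_diff: float
    bci_95: tuple[float, float]
    substantial: bool
    n_draws: int
    warnings: tuple[str, ...] = ()


def contrast_decision(diff_draws: np.ndarray) -> ContrastResult:
    """Summarise posterior difference draws; 'substantial' iff the central
    95% credible interval excludes zero."""
    draws = np.asarray(diff_draws, dtype=float).ravel()
    warnings = ()
    if draws.size < 500:
        warnings = (f"only {draws.size} draws (< 500); interval estimate unstable",)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    substantial = bool(lo > 0.0 or hi < 0.0)
    return ContrastResult(float(draws.mean()), (float(lo), float(hi)), substantial, draws.size, warnings)


# ---------------------------------------------------------------------------
# evidence labels
# ---------------------------------------------------------------------------

_LABELS = ("strong H0", "moderate H0", "weak H0", "weak H1", "moderate H1", "strong H1")


def evidence_label(bf: float) -> str:
    """Categorical evidence label for a Bayes factor (alternative over null).

    Boundaries: > 10 strong H1, [3, 10] moderate H1, (1, 3) weak H1,
    [1/3, 1] weak H0, (0.1, 1/3) moderate H0, <= 0.1 strong H0.
    """
    if not np.isfinite(bf) or bf <= 0:
        raise ValueError(f"Bayes factor must be a positive finite number, got {bf}")
    if bf > 10:
        return "strong H1"
    if bf >= 3:
        return "moderate H1"
    if bf > 1:
        return "weak H1"
    if bf >= 1 / 3:
        return "weak H0"
    if bf > 0.1:
        return "moderate H0"
    return "strong H0"


@dataclass(frozen=True)
class BayesFactorResult:
    """A default-prior Bayes factor with its companion test statistic."""

    bf: float
    direction: str  # "two-sided" | "greater" | "less"
    statistic: float
    statistic_name: str
    n: tuple[int, ...]
    evidence: str
    extra: dict = field(default_factory=dict)

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf


# ---------------------------------------------------------------------------
# JZS t-test Bayes factor
# ---------------------------------------------------------------------------


def _t_statistic(a, b=None, paired=False):
    a = np.asarray(a, dtype=float)
    if b is not None and paired:
        b = np.asarray(b, dtype=float)
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        a, b = a - b, None
    if b is None:
        n = len(a)
        if n < 2:
            raise ValueError("need at least 2 observations")
        sd = a.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance; t statistic undefined")
        return a.mean() / (sd / math.sqrt(n)), n - 1, float(n), (n,)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 observations per group")
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance; t statistic undefined")
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, n1 + n2 - 2, n1 * n2 / (n1 + n2), (n1, n2)


def _jzs_bf_from_t(t: float, df: int, n_eff: float, direction: str, r: float) -> float:
    """Marginal-likelihood ratio of the JZS alternative over the point null."""
    sqrt_n = math.sqrt(n_eff)
    log_null = t_dist.logpdf(t, df)
    # scale the integrand by the largest log-likelihood among candidate
    # effect sizes so the quadrature stays in floating-point range
    ref = max(float(nct.logpdf(t, df, d * sqrt_n)) for d in (0.0, t / sqrt_n)) if df > 0 else log_null

    def integrand(delta):
        return math.exp(float(nct.logpdf(t, df, delta * sqrt_n)) - ref) * cauchy.pdf(delta, 0.0, r)

    if direction == "two-sided":
        mass, _ = integrate.quad(integrand, -np.inf, 0.0, epsrel=1e-8, epsabs=0.0)
        mass2, _ = integrate.quad(integrand, 0.0, np.inf, epsrel=1e-8, epsabs=0.0)
        mass += mass2
    elif direction == "greater":
        mass, _ = integrate.quad(integrand, 0.0, np.inf, epsrel=1e-8, epsabs=0.0)
        mass *= 2.0  # half-Cauchy prior on the positive effects
    elif direction == "less":
        mass, _ = integrate.quad(integrand, -np.inf, 0.0, epsrel=1e-8, epsabs=0.0)
        mass *= 2.0
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return mass * math.exp(ref - log_null)


def jzs_ttest_bf(
    sample_a,
    sample_b=None,
    paired: bool = False,
    direction: str = "two-sided",
    cauchy_scale: float = DEFAULT_CAUCHY_SCALE,
) -> BayesFactorResult:
    """Default-prior (JZS) Bayesian t test.

    One-sample when ``sample_b`` is None; paired when ``paired=True``;
    independent two-sample otherwise. Directional variants (BF+0 / BF-0)
    truncate the Cauchy effect-size prior to the stated direction.
    """
    t, df, n_eff, ns = _t_statistic(sample_a, sample_b, paired)
    bf = _jzs_bf_from_t(t, df, n_eff, direction, cauchy_scale)
    return BayesFactorResult(
        bf=float(bf),
        direction=direction,
        statistic=float(t),
        statistic_name="t",
        n=ns,
        evidence=evidence_label(bf),
        extra={"df": df, "cauchy_scale": cauchy_scale},
    )


# ---------------------------------------------------------------------------
# rank-based Bayes factors via latent-normal data augmentation
# ---------------------------------------------------------------------------


def _truncnorm_draw(rng, mean, lo, hi):
    """Vectorised inverse-CDF truncated normal draw with unit SD."""
    a = norm.cdf(lo - mean)
    b = norm.cdf(hi - mean)
    u = a + rng.uniform(size=np.shape(mean)) * np.clip(b - a, 1e-15, None)
    return mean + norm.ppf(np.clip(u, 1e-15, 1 - 1e-15))


def _sample_delta(rng, like_mean, like_var, r, grid_size=1024):
    """Draw delta from N(like_mean, like_var) x Cauchy(0, r) via grid
    inverse-CDF; also return the normalised density at 0 and P(delta > 0)."""
    sd = math.sqrt(like_var)
    lo = min(-6 * r, like_mean - 8 * sd, -0.5)
    hi = max(6 * r, like_mean + 8 * sd, 0.5)
    grid = np.linspace(lo, hi, grid_size)
    logpost = norm.logpdf(grid, like_mean, sd) + cauchy.logpdf(grid, 0.0, r)
    logpost -= logpost.max()
    dens = np.exp(logpost)
    z_norm = np.trapezoid(dens, grid)
    dens /= z_norm
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
    cdf /= cdf[-1]
    delta = float(np.interp(rng.uniform(), cdf, grid))
    dens0 = float(np.interp(0.0, grid, dens))
    p_pos = float(1.0 - np.interp(0.0, grid, cdf))
    return delta, dens0, p_pos


def _bf_from_gibbs(dens0_mean, p_pos_mean, direction, r):
    bf10 = cauchy.pdf(0.0, 0.0, r) / dens0_mean  # Savage-Dickey at delta = 0
    if direction == "two-sided":
        return bf10
    if direction == "greater":
        return bf10 * p_pos_mean / 0.5
    if direction == "less":
        return bf10 * (1.0 - p_pos_mean) / 0.5
    raise ValueError(f"unknown direction {direction!r}")


def _signed_rank_W(d: np.ndarray) -> float:
    """Sum of the mid-ranks of |d| over positive differences (zeros dropped)."""
    ranks = rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def rank_bf(
    sample_a,
    sample_b=None,
    paired: bool = False,
    direction: str = "two-sided",
    cauchy_scale: float = DEFAULT_CAUCHY_SCALE,
    n_samples: int = 2000,
    n_burn: int = 500,
    seed: int = 0,
) -> BayesFactorResult:
    """Bayes factor for the Wilcoxon signed-rank / Mann-Whitney rank-sum test.

    Latent continuous values consistent with the observed ranks are Gibbs
    sampled (truncated normals between rank neighbours, alternating
    odd/even positions); the standardised effect delta gets a Cauchy(0, r)
    prior and the Bayes factor is the Savage-Dickey density ratio at zero,
    Rao-Blackwellised over the Gibbs draws. One-sample and paired data use
    the signed-rank formulation, two independent samples the rank-sum one.
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(sample_a, dtype=float)
    if sample_b is not None and paired:
        b = np.asarray(sample_b, dtype=float)
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        a, sample_b = a - b, None

    if sample_b is None:
        d = a[a != 0.0]  # signed-rank convention: zero differences dropped
        if d.size < 2 or np.all(d == d[0]):
            raise ValueError("all-tied or degenerate data; rank test undefined")
        w_stat, w_name, ns = _signed_rank_W(d), "W", (len(a),)
        sampler = _SignedRankAugmentation(d)
    else:
        b = np.asarray(sample_b, dtype=float)
        if min(len(a), len(b)) < 2 or (np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]):
            raise ValueError("all-tied or degenerate data; rank test undefined")
        w_stat = float(mannwhitneyu(a, b, alternative="two-sided").statistic)
        w_name, ns = "W", (len(a), len(b))
        sampler = _RankSumAugmentation(a, b)

    delta = 0.0
    dens0_acc, p_pos_acc, kept = 0.0, 0.0, 0
    for it in range(n_burn + n_samples):
        sampler.update_latent(rng, delta)
        like_mean, like_var = sampler.delta_likelihood()
        delta, dens0, p_pos = _sample_delta(rng, like_mean, like_var, cauchy_scale)
        if it >= n_burn:
            dens0_acc += dens0
            p_pos_acc += p_pos
            kept += 1
    bf = _bf_from_gibbs(dens0_acc / kept, p_pos_acc / kept, direction, cauchy_scale)
    return BayesFactorResult(
        bf=float(bf),
        direction=direction,
        statistic=w_stat,
        statistic_name=w_name,
        n=ns,
        evidence=evidence_label(bf),
        extra={"cauchy_scale": cauchy_scale, "n_samples": n_samples},
    )


class _SignedRankAugmentation:
    """Latent z ~ N(delta, 1) sharing the signs and |.|-order of the data."""

    def __init__(self, d: np.ndarray):
        self.n = d.size
        self.order = np.argsort(np.abs(d), kind="stable")
        self.signs = np.sign(d)[self.order]
        # initial latent values: normal scores of the (signed) ranks
        scores = (np.arange(self.n) + 1.0) / (self.n + 1.0)
        self.zabs = np.abs(norm.ppf(0.5 + scores / 2.0))
        self.z = self.signs * self.zabs

    def update_latent(self, rng, delta):
        for parity in (0, 1):
            idx = np.arange(parity, self.n, 2)
            lo_abs = np.where(idx > 0, self.zabs[np.maximum(idx - 1, 0)], 0.0)
            hi_abs = np.where(idx < self.n - 1, self.zabs[np.minimum(idx + 1, self.n - 1)], np.inf)
            sign = self.signs[idx]
            lo = np.where(sign > 0, lo_abs, -hi_abs)
            hi = np.where(sign > 0, hi_abs, -lo_abs)
            z_new = _truncnorm_draw(rng, np.full(idx.size, delta), lo, hi)
            self.z[idx] = z_new
            self.zabs[idx] = np.abs(z_new)

    def delta_likelihood(self):
        return float(self.z.mean()), 1.0 / self.n


class _RankSumAugmentation:
    """Latent z with group means -delta/2, +delta/2 sharing the pooled order."""

    def __init__(self, a: np.ndarray, b: np.ndarray):
        pooled = np.concatenate([a, b])
        groups = np.concatenate([np.zeros(len(a)), np.ones(len(b))])
        self.n1, self.n2 = len(a), len(b)
        self.n = pooled.size
        order = np.argsort(pooled, kind="stable")
        self.groups = groups[order]
        self.z = norm.ppf((np.arange(self.n) + 1.0) / (self.n + 1.0))

    def update_latent(self, rng, delta):
        # delta parameterises the (a - b) shift, matching the t-test direction
        means = np.where(self.groups == 0, delta / 2.0, -delta / 2.0)
        for parity in (0, 1):
            idx = np.arange(parity, self.n, 2)
            lo = np.where(idx > 0, self.z[np.maximum(idx - 1, 0)], -np.inf)
            hi = np.where(idx < self.n - 1, self.z[np.minimum(idx + 1, self.n - 1)], np.inf)
            self.z[idx] = _truncnorm_draw(rng, means[idx], lo, hi)

    def delta_likelihood(self):
        s1 = self.z[self.groups == 0].sum()
        s2 = self.z[self.groups == 1].sum()
        # quadratic in delta: precision (n1 + n2) / 4
        var = 4.0 / (self.n1 + self.n2)
        mean = (s1 - s2) * var / 2.0
        return float(mean), var


# ---------------------------------------------------------------------------
# batch runner over per-participant ML estimates
# ---------------------------------------------------------------------------


def run_bf_tests(
    estimates: pd.DataFrame,
    tests: list[dict],
    estimates_b: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run a list of Bayes-factor tests on per-participant estimate tables.

    ``estimates`` is the wide CSV emitted by :func:`dualrec.ml.fit_dataset`
    (columns ``est_<parameter>``). Each test dict names the contrast:
    ``{"name", "parameter_a", "parameter_b", "test": "t"|"rank",
    "paired": bool, "direction"}``. Paired tests compare two parameters
    within ``estimates``; independent tests compare ``parameter_a`` in
    ``estimates`` against ``parameter_b`` (default: the same parameter) in
    ``estimates_b``. The test choice is explicit input — no automatic
    normality screening is attempted.
    """
    rows = []
    for i, spec in enumerate(tests):
        test = spec.get("test", "t")
        direction = spec.get("direction", "two-sided")
        paired = bool(spec.get("paired", True))
        a = estimates[f"est_{spec['parameter_a']}"].to_numpy()
        if paired:
            b = estimates[f"est_{spec['parameter_b']}"].to_numpy()
        else:
            if estimates_b is None:
                raise ValueError("independent tests need estimates_b")
            b = estimates_b[f"est_{spec.get('parameter_b', spec['parameter_a'])}"].to_numpy()
        kwargs = dict(paired=paired, direction=direction)
        if test == "t":
            result = jzs_ttest_bf(a, b, **kwargs)
        elif test == "rank":
            result = rank_bf(a, b, seed=int(spec.get("seed", i)), **kwargs)
        else:
            raise ValueError(f"unknown test type {test!r}")
        rows.append(
            {
                "name": spec.get("name", f"test_{i}"),
                "parameter_a": spec["parameter_a"],
                "parameter_b": spec.get("parameter_b"),
                "test": test,
                "paired": paired,
                "direction": direction,
                "bf": result.bf,
                "statistic": result.statistic,
                "statistic_name": result.statistic_name,
                "evidence": result.evidence,
            }
        )
    return pd.DataFrame(rows)
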