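"""Two-arm design evaluation: Bayesian success rule and frequentist
operating characteristics.

The design randomizes n_t patients to treatment and n_c to control, with a
known per-observation sampling SD sigma and independent normal-mixture
priors on each arm's mean. Success is declared when the posterior
probability of a positive treatment effect delta = theta_c - theta_t
(control minus treatment mean change; on a worsening scale, positive delta
is benefit) strictly exceeds the threshold.

Frequentist operating characteristics sweep the true control mean theta_c
with theta_t = theta_c - delta: delta = 0 traces type I error, delta at the
clinically meaningful effect traces power. The default method integrates
the success region exactly by Gauss-Hermite quadrature over the control-arm
sample mean; seeded simulation provides an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .mixtures import GaussianSummary, NormalMixture, prob_difference_positive, update_posterior

__all__ = [
    "TwoArmDesign",
    "OCResult",
    "decide",
    "posterior_prob_positive",
    "critical_treatment_mean",
    "operating_characteristics",
    "freq_sample_size",
    "reduced_control_sizes",
    "freq_power",
]

DEFAULT_THETA_C_GRID = np.arange(5.0, 17.0 + 1e-9, 0.25)
_GH_NODES = 41


@dataclass(frozen=True)
class TwoArmDesign:
    """Trial geometry: arm sizes, known sampling SD, per-arm priors, and
    the posterior-probability success threshold."""

    n_t: int
    n_c: int
    sigma: float
    prior_t: NormalMixture
    prior_c: NormalMixture
    threshold: float = 0.975

    def __post_init__(self) -> None:
        if int(self.n_t) != self.n_t or self.n_t < 2:
            raise ValueError("n_t must be an integer >= 2")
        if int(self.n_c) != self.n_c or self.n_c < 2:
            raise ValueError("n_c must be an integer >= 2")
        if not (self.sigma > 0 and np.isfinite(self.sigma)):
            raise ValueError("sigma must be positive and finite")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly in (0, 1)")
        object.__setattr__(self, "n_t", int(self.n_t))
        object.__setattr__(self, "n_c", int(self.n_c))


@dataclass(frozen=True)
class OCResult:
    """Success probability along a grid of true control means at a fixed
    true effect delta; delta=0 curves are type I error, delta>0 power."""

    theta_c_grid: np.ndarray
    delta: float
    success_prob: np.ndarray
    method: str
    nsim: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        grid = np.asarray(self.theta_c_grid, dtype=float)
        prob = np.asarray(self.success_prob, dtype=float)
        if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("theta_c_grid must be 1-d, nonempty, strictly increasing")
        if prob.shape != grid.shape:
            raise ValueError("success_prob must align with theta_c_grid")
        if np.any(prob < -1e-12) or np.any(prob > 1 + 1e-12):
            raise ValueError("success probabilities must lie in [0, 1]")
        object.__setattr__(self, "theta_c_grid", grid)
        object.__setattr__(self, "success_prob", np.clip(prob, 0.0, 1.0))

    def max_success_prob(self) -> float:
        return float(np.max(self.success_prob))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"theta_c": self.theta_c_grid, "success_prob": self.success_prob}
        )


def posterior_prob_positive(design: TwoArmDesign, ybar_c: float, ybar_t: float) -> float:
    """P(delta > 0 | data): posterior probability that the control mean
    exceeds the treatment mean after conjugate updating of both arms."""
    post_c = update_posterior(design.prior_c, GaussianSummary(design.n_c, ybar_c, design.sigma))
    post_t = update_posterior(design.prior_t, GaussianSummary(design.n_t, ybar_t, design.sigma))
    return prob_difference_positive(post_c, post_t)


def decide(design: TwoArmDesign, ybar_c: float, ybar_t: float) -> bool:
    """Success rule: P(delta > 0 | data) strictly above the threshold."""
    return posterior_prob_positive(design, ybar_c, ybar_t) > design.threshold


def critical_treatment_mean(design: TwoArmDesign, ybar_c: float) -> float:
    """The treatment sample mean at which P(delta>0|data) equals the
    threshold; success holds exactly for ybar_t below it.

    P(delta>0) is strictly decreasing in ybar_t (the treatment posterior
    shifts up with the data), so the boundary is unique. The search starts
    from the vague-prior z-test boundary and expands the bracket
    geometrically.
    """
    z = stats.norm.ppf(design.threshold)
    guess = ybar_c - z * design.sigma * np.sqrt(1.0 / design.n_c + 1.0 / design.n_t)
    f = lambda t: posterior_prob_positive(design, ybar_c, t) - design.threshold
    half = max(design.sigma, 1.0)
    lo, hi = guess - half, guess + half
    for _ in range(60):
        flo, fhi = f(lo), f(hi)
        if not (np.isfinite(flo) and np.isfinite(fhi)):
            raise ArithmeticError("non-finite posterior probability during bracketing")
        if flo > 0.0 > fhi:  # f decreasing: success region is ybar_t < root
            return float(optimize.brentq(f, lo, hi, xtol=1e-10))
        half *= 2.0
        lo, hi = guess - half, guess + half
    raise ArithmeticError(
        "failed to bracket the decision boundary after 60 doublings (pathological prior?)"
    )


def _posterior_prob_positive_many(
    design: TwoArmDesign, ybar_c: np.ndarray, ybar_t: np.ndarray
) -> np.ndarray:
    """Vectorized P(delta>0|data) over paired arrays of arm means."""
    out = []
    for prior, n, ybar in (
        (design.prior_c, design.n_c, ybar_c),
        (design.prior_t, design.n_t, ybar_t),
    ):
        se2 = design.sigma**2 / n
        pv = prior.sds**2
        post_var = 1.0 / (1.0 / pv + 1.0 / se2)
        post_mean = post_var * (prior.means / pv + ybar[:, None] / se2)
        log_w = np.log(prior.weights) + stats.norm.logpdf(
            ybar[:, None], prior.means, np.sqrt(pv + se2)
        )
        log_w -= logsumexp(log_w, axis=1, keepdims=True)
        out.append((np.exp(log_w), post_mean, post_var))
    (wc, mc, vc), (wt, mt, vt) = out
    dm = mc[:, :, None] - mt[:, None, :]
    sd = np.sqrt(vc[:, None] + vt[None, :])
    w = wc[:, :, None] * wt[:, None, :]
    return np.sum(w * stats.norm.sf(0.0, loc=dm, scale=sd[None, :, :]), axis=(1, 2))


def operating_characteristics(
    design: TwoArmDesign,
    theta_c_grid=DEFAULT_THETA_C_GRID,
    delta: float = 0.0,
    method: str = "quadrature",
    nsim: int = 100_000,
    seed: int | None = None,
) -> OCResult:
    """Probability of declaring success at each true control mean, with the
    true treatment mean theta_t = theta_c - delta.

    quadrature: for each Gauss-Hermite node in the control sample-mean
    distribution, invert the decision boundary and accumulate the normal
    probability that the treatment sample mean falls below it. simulation:
    seeded trial replicates pushed through the success rule.
    """
    grid = np.asarray(theta_c_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("theta_c_grid must be nonempty")
    se_c = design.sigma / np.sqrt(design.n_c)
    se_t = design.sigma / np.sqrt(design.n_t)

    if method == "quadrature":
        nodes, weights = np.polynomial.hermite.hermgauss(_GH_NODES)
        probs = np.empty_like(grid)
        for i, theta_c in enumerate(grid):
            theta_t = theta_c - delta
            ybar_c = theta_c + np.sqrt(2.0) * se_c * nodes
            bounds = np.array([critical_treatment_mean(design, y) for y in ybar_c])
            if not np.all(np.isfinite(bounds)):
                raise ArithmeticError(f"non-finite decision boundary at theta_c={theta_c}")
            probs[i] = np.sum(weights * stats.norm.cdf((bounds - theta_t) / se_t)) / np.sqrt(
                np.pi
            )
        return OCResult(grid, delta, probs, "quadrature")

    if method == "simulation":
        if nsim < 1000:
            raise ValueError("nsim must be >= 1000 for simulation")
        rng = np.random.default_rng(seed)
        probs = np.empty_like(grid)
        for i, theta_c in enumerate(grid):
            ybar_c = rng.normal(theta_c, se_c, size=nsim)
            ybar_t = rng.normal(theta_c - delta, se_t, size=nsim)
            p = _posterior_prob_positive_many(design, ybar_c, ybar_t)
            probs[i] = np.mean(p > design.threshold)
        return OCResult(grid, delta, probs, "simulation", nsim=nsim, seed=seed)

    raise ValueError("method must be 'quadrature' or 'simulation'")


def freq_sample_size(
    alpha_one_sided: float,
    power: float,
    delta: float,
    sigma: float,
    allocation_ratio: float = 1.0,
) -> tuple[int, int]:
    """Normal-approximation two-sample sizes for a one-sided z-test,
    per-arm ceilings, with allocation ratio r = n_t / n_c."""
    if not 0.0 < alpha_one_sided < 0.5:
        raise ValueError("alpha_one_sided must lie in (0, 0.5)")
    if not 0.5 <= power < 1.0:
        raise ValueError("power must lie in [0.5, 1)")
    if delta == 0:
        raise ValueError("delta must be nonzero")
    if sigma <= 0 or allocation_ratio <= 0:
        raise ValueError("sigma and allocation_ratio must be positive")
    z = stats.norm.ppf(1.0 - alpha_one_sided) + stats.norm.ppf(power)
    n_c = (1.0 + 1.0 / allocation_ratio) * sigma**2 * z**2 / delta**2
    n_t = allocation_ratio * n_c
    return int(np.ceil(n_t)), int(np.ceil(n_c))


def reduced_control_sizes(
    alpha_one_sided: float,
    power: float,
    delta: float,
    sigma: float,
    ratio: float = 2.0,
) -> tuple[int, int]:
    """Arm sizes for the external-control design: keep the treatment arm at
    the 1:1 frequentist benchmark and shrink the control arm by the
    randomization ratio, with the borrowed prior supplying the missing
    control information (e.g. 85/43 at 2:1 for the benchmark 85 per arm)."""
    if ratio < 1:
        raise ValueError("ratio must be >= 1 (treatment-favoring randomization)")
    n_per_arm, _ = freq_sample_size(alpha_one_sided, power, delta, sigma, 1.0)
    return n_per_arm, int(np.ceil(n_per_arm / ratio))


def freq_power(
    n_t: int, n_c: int, alpha_one_sided: float, delta: float, sigma: float
) -> float:
    """Power of the one-sided two-sample z-test at true effect delta."""
    if n_t < 1 or n_c < 1:
        raise ValueError("arm sizes must be positive")
    if not 0.0 < alpha_one_sided < 1.0:
        raise ValueError("alpha_one_sided must lie in (0, 1)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    se = sigma * np.sqrt(1.0 / n_t + 1.0 / n_c)
    return float(stats.norm.cdf(delta / se - stats.norm.ppf(1.0 - alpha_one_sided)))
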