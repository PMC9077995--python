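"""Exact algebra on finite normal mixtures.

The normal mixture is the universal prior/posterior representation here:
a meta-analytic-predictive (MAP) prior moment-matched to one component, its
robustified version (informative + vague component), and every conjugate
posterior under a known-variance normal likelihood all live in this family,
so trial decisions can be evaluated in closed form without simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

__all__ = [
    "NormalMixture",
    "GaussianSummary",
    "robustify",
    "update_posterior",
    "mixture_cdf",
    "mixture_quantile",
    "mixture_moments",
    "prob_difference_positive",
]

_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class NormalMixture:
    """Finite mixture of normal distributions sum_k w_k N(m_k, s_k^2).

    Weights must be positive and sum to one within 1e-12; use
    :meth:`from_unnormalized` when the weights are only proportional.
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        w = np.atleast_1d(np.asarray(self.weights, dtype=float))
        m = np.atleast_1d(np.asarray(self.means, dtype=float))
        s = np.atleast_1d(np.asarray(self.sds, dtype=float))
        if not (w.shape == m.shape == s.shape) or w.ndim != 1 or w.size < 1:
            raise ValueError("weights, means, sds must be 1-d sequences of equal length >= 1")
        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(m)) or not np.all(np.isfinite(s)):
            raise ValueError("mixture parameters must be finite")
        if np.any(w <= 0):
            raise ValueError("all mixture weights must be positive")
        if abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"mixture weights must sum to 1 within {_WEIGHT_TOL}; got {w.sum()!r}")
        if np.any(s <= 0):
            raise ValueError("all component sds must be positive")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "sds", s)

    @classmethod
    def from_unnormalized(
        cls, weights: np.ndarray, means: np.ndarray, sds: np.ndarray
    ) -> "NormalMixture":
        w = np.atleast_1d(np.asarray(weights, dtype=float))
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("unnormalized weights must have a positive finite sum")
        return cls(w / total, means, sds)

    @classmethod
    def single(cls, mean: float, sd: float) -> "NormalMixture":
        return cls(np.array([1.0]), np.array([float(mean)]), np.array([float(sd)]))

    def __len__(self) -> int:
        return self.weights.size

    # -- densities and probabilities ------------------------------------

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.sum(
            self.weights * stats.norm.pdf(x[..., None], self.means, self.sds), axis=-1
        )

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.sum(
            self.weights * stats.norm.cdf(x[..., None], self.means, self.sds), axis=-1
        )

    def quantile(self, p: float) -> float:
        """Inverse cdf by bracketed root-finding (Brent)."""
        if not 0.0 < p < 1.0:
            raise ValueError("quantile level p must lie strictly in (0, 1)")
        half = 12.0 * float(self.sds.max())
        center = self.mean()
        lo, hi = center - half, center + half
        # expand geometrically until the root is bracketed
        for _ in range(200):
            if self.cdf(lo) < p < self.cdf(hi):
                break
            half *= 2.0
            lo, hi = center - half, center + half
        else:  # pragma: no cover - unreachable for proper mixtures
            raise RuntimeError("failed to bracket mixture quantile")
        return float(optimize.brentq(lambda x: self.cdf(x) - p, lo, hi, xtol=1e-12))

    def mean(self) -> float:
        return float(np.sum(self.weights * self.means))

    def var(self) -> float:
        m = self.mean()
        return float(np.sum(self.weights * (self.sds**2 + self.means**2)) - m**2)

    def sd(self) -> float:
        return float(np.sqrt(max(self.var(), 0.0)))

    def moments(self) -> tuple[float, float]:
        return self.mean(), self.sd()

    def rvs(self, size: int, rng: np.random.Generator):
        comp = rng.choice(len(self), size=size, p=self.weights)
        return rng.normal(self.means[comp], self.sds[comp])

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalMixture":
        return cls(np.asarray(d["weights"]), np.asarray(d["means"]), np.asarray(d["sds"]))


@dataclass(frozen=True)
class GaussianSummary:
    """Sufficient summary of one arm: n observations with mean ybar,
    known per-observation sampling SD sigma."""

    n: int
    ybar: float
    sigma: float

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 1:
            raise ValueError("n must be a positive integer")
        if not np.isfinite(self.ybar):
            raise ValueError("ybar must be finite")
        if not (self.sigma > 0 and np.isfinite(self.sigma)):
            raise ValueError("sigma must be positive and finite")
        object.__setattr__(self, "n", int(self.n))

    @property
    def se(self) -> float:
        """Standard error of the arm mean, sigma / sqrt(n)."""
        return self.sigma / np.sqrt(self.n)


def robustify(
    prior: NormalMixture, vague_weight: float, vague_mean: float, vague_sd: float
) -> NormalMixture:
    """Append a vague component with the given weight, down-weighting the
    informative components by (1 - vague_weight).

    This is the robust-MAP construction: the vague component lets the
    posterior discount the historical information under prior-data conflict
    (dynamic borrowing).
    """
    if not 0.0 < vague_weight < 1.0:
        raise ValueError("vague_weight must lie strictly in (0, 1)")
    if vague_sd <= 0:
        raise ValueError("vague_sd must be positive")
    w = np.append(prior.weights * (1.0 - vague_weight), vague_weight)
    m = np.append(prior.means, float(vague_mean))
    s = np.append(prior.sds, float(vague_sd))
    return NormalMixture.from_unnormalized(w, m, s)


def update_posterior(prior: NormalMixture, data: GaussianSummary) -> NormalMixture:
    """Conjugate posterior of a normal mixture prior given ybar ~ N(theta, sigma^2/n).

    Component-wise normal-normal update; posterior weights are proportional
    to prior weight times the marginal likelihood of ybar under each
    component, computed in log space (log-sum-exp) so extreme prior-data
    conflict cannot underflow the informative component to exactly zero.
    """
    se2 = data.sigma**2 / data.n
    prior_var = prior.sds**2
    post_prec = 1.0 / prior_var + 1.0 / se2
    post_var = 1.0 / post_prec
    post_mean = post_var * (prior.means / prior_var + data.ybar / se2)
    log_w = np.log(prior.weights) + stats.norm.logpdf(
        data.ybar, prior.means, np.sqrt(prior_var + se2)
    )
    log_w -= logsumexp(log_w)
    return NormalMixture(np.exp(log_w), post_mean, np.sqrt(post_var))


def mixture_cdf(mix: NormalMixture, x: float) -> float:
    return float(mix.cdf(x))


def mixture_quantile(mix: NormalMixture, p: float) -> float:
    return mix.quantile(p)


def mixture_moments(mix: NormalMixture) -> tuple[float, float]:
    return mix.moments()


def prob_difference_positive(mix_c: NormalMixture, mix_t: NormalMixture) -> float:
    """P(theta_c - theta_t > 0) for independent mixture-distributed arms.

    The difference of independent normal mixtures is itself a mixture over
    component pairs, with means m_c - m_t and variances summed, so the
    probability is an exact weighted sum of normal tail probabilities.
    """
    dm = mix_c.means[:, None] - mix_t.means[None, :]
    sd = np.sqrt(mix_c.sds[:, None] ** 2 + mix_t.sds[None, :] ** 2)
    w = mix_c.weights[:, None] * mix_t.weights[None, :]
    return float(np.sum(w * stats.norm.sf(0.0, loc=dm, scale=sd)))
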