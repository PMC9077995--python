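"""Beta-binomial inference for rare-event rates.

Small trials often observe zero events for outcomes that matter for
risk-benefit assessment; zero observed events do not imply zero risk. With
a Beta(a, b) prior on the event probability and x events in n patients, the
posterior is Beta(a + x, b + n - x), and its upper quantile gives a
posterior upper bound on the rate — the Bayesian answer to the
zero-numerator problem (for x=0, n around 100 and a uniform prior this
roughly reproduces the 'rule of three' bound 3/n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EventData", "posterior_upper_bound", "zero_event_table"]

UNIFORM_PRIOR = (1.0, 1.0)
JEFFREYS_PRIOR = (0.5, 0.5)


@dataclass(frozen=True)
class EventData:
    """x events out of n patients, Beta(prior_a, prior_b) prior, and the
    posterior quantile level for the upper bound (e.g. 0.95)."""

    x: int
    n: int
    prior_a: float = 1.0
    prior_b: float = 1.0
    level: float = 0.95

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 1:
            raise ValueError("n must be a positive integer")
        if int(self.x) != self.x or not 0 <= self.x <= self.n:
            raise ValueError("x must be an integer with 0 <= x <= n")
        if self.prior_a <= 0 or self.prior_b <= 0:
            raise ValueError("Beta prior parameters must be positive")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie strictly in (0, 1)")
        object.__setattr__(self, "x", int(self.x))
        object.__setattr__(self, "n", int(self.n))


def posterior_upper_bound(data: EventData) -> float:
    """`level` quantile of the Beta(a + x, b + n - x) posterior."""
    return float(
        stats.beta.ppf(data.level, data.prior_a + data.x, data.prior_b + data.n - data.x)
    )


def zero_event_table(n_values, priors, level: float = 0.95) -> pd.DataFrame:
    """Posterior upper bounds for x=0 over a grid of sample sizes and
    priors; one row per n (sorted ascending), one column per prior."""
    n_values = sorted(int(n) for n in n_values)
    if not n_values or not priors:
        raise ValueError("n_values and priors must be nonempty")
    table = {"n": n_values}
    for a, b in priors:
        col = f"Beta({a:g},{b:g})"
        table[col] = [
            posterior_upper_bound(EventData(0, n, a, b, level)) for n in n_values
        ]
    return pd.DataFrame(table)
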