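"""Synthetic data: historical-trial sets from the hierarchical generative
model, and single seeded trial replicates.

The generator mirrors the model the MAP analysis assumes — true study
means drawn around a population mean with between-trial SD tau, observed
study means adding sampling noise sigma_obs/sqrt(n_j) — so recovery tests
probe the fit under exactly the conditions it postulates. What it does not
emulate: non-exchangeable studies, drifting populations, or reported
standard errors that misstate the sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design_oc import TwoArmDesign, decide
from .hierarchical_map import HistoricalStudy

__all__ = ["SyntheticSpec", "generate_historical", "simulate_trial"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Truth for one synthetic historical-trial set: population mean,
    between-trial SD, per-study sizes, per-observation sampling SD, seed."""

    mu_true: float
    tau_true: float
    study_sizes: tuple[int, ...]
    sigma_obs: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_true < 0:
            raise ValueError("tau_true must be non-negative")
        sizes = tuple(int(n) for n in self.study_sizes)
        if not sizes or any(n < 2 for n in sizes):
            raise ValueError("study_sizes must be nonempty with all sizes >= 2")
        if self.sigma_obs <= 0:
            raise ValueError("sigma_obs must be positive")
        object.__setattr__(self, "study_sizes", sizes)


def generate_historical(spec: SyntheticSpec) -> list[HistoricalStudy]:
    """Seeded draw of one historical-trial set:
    theta_j ~ N(mu_true, tau_true^2), ybar_j ~ N(theta_j, sigma_obs^2/n_j),
    with se_j reported as sigma_obs/sqrt(n_j)."""
    rng = np.random.default_rng(spec.seed)
    studies = []
    for j, n in enumerate(spec.study_sizes):
        theta_j = rng.normal(spec.mu_true, spec.tau_true)
        se_j = spec.sigma_obs / np.sqrt(n)
        ybar_j = rng.normal(theta_j, se_j)
        studies.append(HistoricalStudy(f"synthetic-{j + 1}", n, float(ybar_j), float(se_j)))
    return studies


def simulate_trial(
    design: TwoArmDesign, theta_c: float, theta_t: float, seed: int
) -> tuple[float, float, bool]:
    """One seeded trial replicate: arm sample means from
    N(theta, sigma^2/n) and the success decision applied to them."""
    rng = np.random.default_rng(seed)
    ybar_c = float(rng.normal(theta_c, design.sigma / np.sqrt(design.n_c)))
    ybar_t = float(rng.normal(theta_t, design.sigma / np.sqrt(design.n_t)))
    return ybar_c, ybar_t, decide(design, ybar_c, ybar_t)
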