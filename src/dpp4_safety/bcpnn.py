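"""BCPNN information component for disproportionality signal detection.

The information component (IC) measures how much more often a drug-event pair
is reported than expected under independence:

    IC = log2( p11 / (p1. * p.1) )

with Beta-Dirichlet conjugate priors on the joint and marginal reporting
probabilities (the WHO-UMC Bayesian Confidence Propagation Neural Network
model).  The closed-form posterior mean and variance of the IC admit a normal
approximation for the 95% credible interval; a pair is a signal of
disproportionate reporting (SDR) when the interval's lower bound IC025
exceeds zero.

The closed form is validated against :func:`mc_ic_oracle`, which samples the
three reporting probabilities from their exact Beta posteriors and evaluates
the IC per draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .spontaneous import ContingencyTable

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class BcpnnPrior:
    """Pseudo-counts of the conjugate priors.

    ``alpha1``/``beta1`` smooth the drug and event margins, ``alpha``/``beta``
    their totals, and ``gamma11`` the joint cell; the joint total ``gamma`` is
    derived from the table so that the prior IC is centred at independence.
    Defaults are the standard WHO-UMC parameterization.
    """

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha, self.beta, self.gamma11) <= 0:
            raise ValueError("all prior pseudo-counts must be strictly positive")


@dataclass(frozen=True)
class SignalResult:
    """Posterior IC moments, credible interval and the SDR decision."""

    expected_ic: float
    variance_ic: float
    ic_lower: float
    ic_upper: float
    is_sdr: bool
    n11: int

    def __post_init__(self) -> None:
        if not (self.ic_lower <= self.expected_ic <= self.ic_upper):
            raise ValueError("interval must bracket the expected IC")
        if self.is_sdr != (self.ic_lower > 0.0):
            raise ValueError("is_sdr must equal (ic_lower > 0)")


def _gamma_joint(n1dot, ndot1, ndotdot, prior: BcpnnPrior):
    return (
        prior.gamma11
        * (ndotdot + prior.alpha)
        * (ndotdot + prior.beta)
        / ((n1dot + prior.alpha1) * (ndot1 + prior.beta1))
    )


def ic_moments_arrays(n11, n1dot, ndot1, ndotdot, prior: BcpnnPrior = BcpnnPrior()):
    """Vectorized posterior E(IC) and V(IC); inputs broadcast as arrays.

    E(IC) = log2[(n11+g11)(N+a)(N+b) / ((N+g)(n1.+a1)(n.1+b1))] with
    g = g11 (N+a)(N+b) / ((n1.+a1)(n.1+b1)); V(IC) is the delta-method sum of
    the three Beta posterior variances on the natural-log scale divided by
    (ln 2)^2.
    """
    n11 = np.asarray(n11, dtype=float)
    n1dot = np.asarray(n1dot, dtype=float)
    ndot1 = np.asarray(ndot1, dtype=float)
    ndotdot = np.asarray(ndotdot, dtype=float)
    p = prior
    gamma = _gamma_joint(n1dot, ndot1, ndotdot, p)
    e_ic = np.log2(
        (n11 + p.gamma11)
        * (ndotdot + p.alpha)
        * (ndotdot + p.beta)
        / ((ndotdot + gamma) * (n1dot + p.alpha1) * (ndot1 + p.beta1))
    )
    v_ic = (
        (ndotdot - n11 + gamma - p.gamma11)
        / ((n11 + p.gamma11) * (1.0 + ndotdot + gamma))
        + (ndotdot - n1dot + p.alpha - p.alpha1)
        / ((n1dot + p.alpha1) * (1.0 + ndotdot + p.alpha))
        + (ndotdot - ndot1 + p.beta - p.beta1)
        / ((ndot1 + p.beta1) * (1.0 + ndotdot + p.beta))
    ) / _LN2**2
    return e_ic, v_ic


def ic_moments(table: ContingencyTable, prior: BcpnnPrior = BcpnnPrior()):
    """Closed-form posterior mean and variance (bits, bits^2) of the IC."""
    if table.ndotdot == 0:
        raise ValueError("degenerate table: no cases (n.. = 0)")
    e, v = ic_moments_arrays(table.n11, table.n1dot, table.ndot1, table.ndotdot, prior)
    return float(e), float(v)


def ic_credible_interval(expected_ic: float, variance_ic: float, level: float = 0.95):
    """Normal-approximation credible interval E +/- z(level) * sqrt(V)."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    if np.any(np.asarray(variance_ic) < 0.0):
        raise ValueError("variance must be non-negative")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(variance_ic)
    return expected_ic - half, expected_ic + half


def detect_signal(
    table: ContingencyTable,
    prior: BcpnnPrior = BcpnnPrior(),
    level: float = 0.95,
) -> SignalResult:
    """IC moments, credible interval, and the strict IC025 > 0 SDR criterion."""
    e, v = ic_moments(table, prior)
    lo, hi = ic_credible_interval(e, v, level)
    return SignalResult(
        expected_ic=e,
        variance_ic=v,
        ic_lower=lo,
        ic_upper=hi,
        is_sdr=lo > 0.0,
        n11=table.n11,
    )


def mc_ic_oracle(
    table: ContingencyTable,
    prior: BcpnnPrior = BcpnnPrior(),
    n_draws: int = 10**6,
    seed: int = 0,
):
    """Monte-Carlo validation oracle for the closed-form moments.

    Samples p11, p1., p.1 from their conjugate Beta posteriors,

        p11 ~ Beta(n11+g11, N-n11+g-g11)
        p1. ~ Beta(n1.+a1, N-n1.+a-a1)
        p.1 ~ Beta(n.1+b1, N-n.1+b-b1),

    evaluates IC = log2(p11/(p1. p.1)) per draw, and returns the empirical
    (mean, variance, 2.5th percentile, 97.5th percentile).
    """
    if n_draws < 10**4:
        raise ValueError("n_draws must be at least 10^4")
    p = prior
    n, n1, n2, n11 = table.ndotdot, table.n1dot, table.ndot1, table.n11
    gamma = _gamma_joint(n1, n2, n, p)
    rng = np.random.default_rng(seed)
    p11 = rng.beta(n11 + p.gamma11, n - n11 + gamma - p.gamma11, size=n_draws)
    p1d = rng.beta(n1 + p.alpha1, n - n1 + p.alpha - p.alpha1, size=n_draws)
    pd1 = rng.beta(n2 + p.beta1, n - n2 + p.beta - p.beta1, size=n_draws)
    ic = np.log2(p11 / (p1d * pd1))
    lo, hi = np.percentile(ic, [2.5, 97.5])
    return float(ic.mean()), float(ic.var(ddof=1)), float(lo), float(hi)
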