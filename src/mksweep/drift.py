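"""Null models for pure genetic drift: frequency-change bounds and loss
probabilities under the neutral Wright-Fisher process.

Two routes to the probability that an allele has been lost by generation
``t`` are provided: the exact finite-population Markov chain (binomial
resampling of 2N gene copies) and the diffusion-approximation series of
Kimura.  The two agree closely for large ``Ne``; the Markov chain is the
arbiter wherever published series variants differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import hyp2f1
from scipy.stats import binom

__all__ = [
    "DriftQuery",
    "LossResult",
    "wf_sd_bound",
    "wf_markov_loss_prob",
    "kimura_loss_prob",
    "ne_for_loss_prob",
    "years_to_generations",
    "GENERATIONS_PER_YEAR",
]

#: ~10 generations per year (egg to mature adult in about 36 days)
GENERATIONS_PER_YEAR = 10.0

#: largest 2N for which the dense transition matrix is built
MARKOV_SIZE_CAP = 20_000


def years_to_generations(years: float, per_year: float = GENERATIONS_PER_YEAR) -> float:
    return years * per_year


@dataclass(frozen=True)
class DriftQuery:
    """Inputs for a drift calculation.

    p0: initial allele frequency; t: elapsed generations; N: (effective)
    diploid population size; k_sd: number of standard deviations used by
    the frequency-change bound.
    """

    p0: float
    t: float
    N: float
    k_sd: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0 must be in [0, 1], got {self.p0}")
        if self.t < 0:
            raise ValueError("t must be >= 0")
        if self.N < 1:
            raise ValueError("N must be >= 1")


@dataclass(frozen=True)
class LossResult:
    prob_loss: float
    method: str
    #: number of series terms, or number of Markov states
    size: int
    converged: bool = True


def wf_sd_bound(q: DriftQuery) -> float:
    """k standard deviations of neutral drift in allele frequency.

    The variance of allele frequency after t generations of neutral
    Wright-Fisher drift from p0 is ``p0(1-p0)(1-exp(-t/2N))``; the bound
    returned is ``k_sd`` times its square root.
    """
    var = q.p0 * (1.0 - q.p0) * (1.0 - np.exp(-q.t / (2.0 * q.N)))
    return float(q.k_sd * np.sqrt(var))


def wf_markov_loss_prob(q: DriftQuery, size_cap: int = MARKOV_SIZE_CAP) -> LossResult:
    """Exact loss probability from the binomial Wright-Fisher chain.

    The allele starts at ``round(2N * p0)`` copies out of ``2N``; the chain
    has ``2N + 1`` states and the reported value is the probability mass
    absorbed at 0 copies after ``t`` generations.
    """
    if q.t < 1 or q.t != int(q.t):
        raise ValueError("Markov chain requires integer t >= 1")
    n = int(round(2 * q.N))
    if n > size_cap:
        raise ValueError(
            f"2N = {n} exceeds the transition-matrix cap ({size_cap}); "
            "use kimura_loss_prob for large populations"
        )
    k0 = int(round(n * q.p0))
    v = np.zeros(n + 1)
    v[k0] = 1.0
    ks = np.arange(n + 1)
    transition = binom.pmf(ks[None, :], n, (ks / n)[:, None])
    for _ in range(int(q.t)):
        v = v @ transition
    return LossResult(prob_loss=float(v[0]), method="markov-chain", size=n + 1)


def kimura_loss_prob(
    q: DriftQuery, term_tol: float = 1e-12, max_terms: int = 10_000
) -> LossResult:
    """Diffusion-approximation probability of allele loss by generation t.

    Kimura's eigenfunction expansion of the drift diffusion gives the
    probability mass absorbed at frequency 0 by time t as

        P_loss = q - sum_{i>=1} p q (2i+1) F(1-i, i+2; 2; p) e^{-i(i+1)t/4N}

    with ``q = 1 - p`` and F the Gauss hypergeometric function (here a
    polynomial, since its first argument is a non-positive integer).  The
    series tends to 0 as t -> 0 and to ``q`` (the eventual loss
    probability) as t -> infinity.
    """
    if not 0.0 < q.p0 < 1.0:
        raise ValueError("kimura_loss_prob requires 0 < p0 < 1")
    if q.t < 1:
        raise ValueError("t must be >= 1")
    p, t, N = q.p0, q.t, q.N
    qq = 1.0 - p
    total = 0.0
    converged = False
    i = 0
    for i in range(1, max_terms + 1):
        term = (
            p * qq * (2 * i + 1) * hyp2f1(1 - i, i + 2, 2, p)
            * np.exp(-i * (i + 1) * t / (4.0 * N))
        )
        total += term
        if abs(term) < term_tol and i > 5:
            converged = True
            break
    prob = float(min(1.0, max(0.0, qq - total)))
    if not converged:
        raise RuntimeError(
            f"Kimura series did not converge in {max_terms} terms "
            f"(last p0={p}, t={t}, N={N})"
        )
    return LossResult(prob_loss=prob, method="diffusion-series", size=i)


def ne_for_loss_prob(
    p0: float,
    t: float,
    target_prob: float,
    bracket: tuple[float, float] = (5.0, 1e6),
) -> float:
    """Effective population size at which loss probability equals the target.

    The loss probability is monotone decreasing in N, so the root of
    ``kimura_loss_prob(p0, N, t) = target_prob`` is found by bracketed
    search over N.
    """
    if not 0.0 < target_prob < 1.0:
        raise ValueError("target_prob must be in (0, 1)")

    def f(N: float) -> float:
        return kimura_loss_prob(DriftQuery(p0=p0, t=t, N=N)).prob_loss - target_prob

    lo, hi = bracket
    if f(lo) < 0 or f(hi) > 0:
        raise ValueError(
            f"target probability {target_prob} not attainable for N in {bracket}"
        )
    return float(brentq(f, lo, hi, xtol=1e-6))
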