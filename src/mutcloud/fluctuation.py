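"""Mutation-rate estimation from parallel-culture fluctuation assays.

Model class: Lea-Coulson / Mandelbrot-Sarkar-Sandri formulation of the
Luria-Delbrueck distribution — mutation events per culture Poisson with
mean ``m``, each founding a resistant clone whose final size follows
``P(size = k) = 1 / (k (k + 1))`` — with full plating, no phenotypic lag
and no differential mutant fitness.  Partial plating is supported as a
binomial thinning of clone sizes.  The per-culture mutant-count pmf obeys
the standard recursion

    p_0 = exp(-m);  p_k = (m / k) * sum_{i=0}^{k-1} p_i / (k - i + 1).

The per-bp and genomic rates follow the reporter-gene scaling
``mu_bp = mu_rif / C`` and ``U = L * mu_rif / C`` with ``C`` the number of
distinct resistance-conferring single-nucleotide changes in the reporter
(default 71) and ``L`` the genome length (default 4,641,652 bp).

Likelihoods truncate the heavy-tailed pmf at ``k_cap``; counts above the
cap enter as a right-censored tail term, so jackpot cultures are handled
without computing an O(k^2) recursion out to extreme counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ld_pmf",
    "ld_log_likelihood",
    "estimate_mu",
    "drake_genomic_rate",
    "fold_change_summary",
    "MutationRateEstimate",
    "DEFAULT_CORRECTION",
    "DEFAULT_GENOME_LENGTH",
]

DEFAULT_CORRECTION = 71
DEFAULT_GENOME_LENGTH = 4_641_652
_CHI2_95_HALF = stats.chi2.ppf(0.95, df=1) / 2.0  # 1.9207... profile-CI drop


def _clone_size_pmf(k_max: int, plating_fraction: float = 1.0) -> np.ndarray:
    """pmf q[0..k_max] of the plated size of a single mutant clone.

    Full plating: q_k = 1/(k (k+1)) for k >= 1 (q_0 = 0).  Partial plating
    thins each clone binomially; the underlying clone-size sum is truncated
    where its contribution to counts <= k_max is negligible.
    """
    q = np.zeros(k_max + 1)
    if plating_fraction >= 1.0:
        k = np.arange(1, k_max + 1)
        q[1:] = 1.0 / (k * (k + 1.0))
        return q
    # clones much larger than k_max / fraction almost surely plate > k_max
    cap = max(1000, int(50 * (k_max + 1) / plating_fraction))
    sizes = np.arange(1, cap + 1)
    weights = 1.0 / (sizes * (sizes + 1.0))
    for j in range(k_max + 1):
        q[j] = float(np.sum(weights * stats.binom.pmf(j, sizes, plating_fraction)))
    return q


def ld_pmf(m: float, k_max: int, plating_fraction: float = 1.0) -> np.ndarray:
    """Luria-Delbrueck mutant-count probabilities for counts 0..k_max."""
    if m < 0:
        raise ValueError(f"m must be >= 0, got {m}")
    if k_max < 0:
        raise ValueError("k_max must be >= 0")
    if not 0 < plating_fraction <= 1:
        raise ValueError("plating_fraction must be in (0, 1]")
    q = _clone_size_pmf(k_max, plating_fraction)
    # compound-Poisson (Panjer) recursion; q_0 > 0 only under partial plating
    p = np.zeros(k_max + 1)
    p[0] = math.exp(-m * (1.0 - q[0]))
    j = np.arange(k_max + 1)
    jq = j * q
    for k in range(1, k_max + 1):
        p[k] = (m / k) * float(np.dot(jq[1 : k + 1], p[k - 1 :: -1]))
    return p


def ld_log_likelihood(
    m: float, counts: np.ndarray, k_cap: int = 512, plating_fraction: float = 1.0
) -> float:
    """Log-likelihood of i.i.d. mutant counts; counts > k_cap right-censored."""
    counts = np.asarray(counts, dtype=int)
    k_top = int(min(counts.max(initial=0), k_cap))
    p = ld_pmf(m, k_top, plating_fraction)
    ll = 0.0
    uncensored = counts[counts <= k_cap]
    if uncensored.size:
        probs = p[uncensored]
        if np.any(probs <= 0):
            return -np.inf
        ll += float(np.sum(np.log(probs)))
    n_censored = int((counts > k_cap).sum())
    if n_censored:
        tail = max(1.0 - float(p.sum()), 1e-300)
        ll += n_censored * math.log(tail)
    return ll


@dataclass
class MutationRateEstimate:
    """Fluctuation-assay estimate with profile-likelihood 95% CI on mu_rif."""

    m_hat: float
    mu_rif: float
    ci_low: float
    ci_high: float
    mu_bp: float
    U: float
    C: int
    L: int
    n_cultures: int
    mean_n_final: float


def estimate_mu(
    experiment: pd.DataFrame,
    plating_fraction: float = 1.0,
    C: int = DEFAULT_CORRECTION,
    L: int = DEFAULT_GENOME_LENGTH,
    k_cap: int = 512,
) -> MutationRateEstimate:
    """Maximum-likelihood mutation rate from a fluctuation experiment.

    ``experiment`` needs columns ``mutant_count`` and ``n_final``.  The
    marker rate per cell division is ``mu = m_hat / mean(n_final)``; the
    95% CI comes from the profile likelihood (drop of chi2_1(0.95)/2).
    All-zero counts give the boundary MLE m = 0 with a one-sided upper bound.
    """
    counts = np.asarray(experiment["mutant_count"], dtype=int)
    n_final = np.asarray(experiment["n_final"], dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 cultures")
    if np.any(counts < 0):
        raise ValueError("mutant counts must be >= 0")
    if np.any(~np.isfinite(n_final)) or np.any(n_final <= 0):
        raise ValueError("n_final must be positive and finite for every culture")
    n = counts.size
    mean_nt = float(n_final.mean())

    def nll(m: float) -> float:
        return -ld_log_likelihood(m, counts, k_cap, plating_fraction)

    if counts.max() == 0:
        # L(m) = exp(-n m): boundary MLE with one-sided profile upper bound
        m_hat, lo = 0.0, 0.0
        hi = _CHI2_95_HALF / n
    else:
        upper = max(50.0, 5.0 * float(np.minimum(counts, k_cap).mean()))
        res = optimize.minimize_scalar(
            nll, bounds=(1e-8, upper), method="bounded",
            options={"xatol": 1e-8},
        )
        m_hat = float(res.x)
        target = -float(res.fun) - _CHI2_95_HALF

        def profile(m: float) -> float:
            return ld_log_likelihood(m, counts, k_cap, plating_fraction) - target

        lo = 0.0
        if profile(1e-10) < 0:
            lo = float(optimize.brentq(profile, 1e-10, m_hat))
        hi_bracket = m_hat * 2 + 1
        while profile(hi_bracket) > 0:
            hi_bracket *= 2
            if hi_bracket > 1e8:  # pragma: no cover - pathological data
                raise RuntimeError("profile upper bound did not bracket")
        hi = float(optimize.brentq(profile, m_hat, hi_bracket))

    # thinned-clone pmf already accounts for plating, so m_hat estimates the
    # true number of mutation events per culture
    scale = 1.0 / mean_nt
    mu = m_hat * scale
    mu_bp, U = drake_genomic_rate(mu, C=C, L=L)
    return MutationRateEstimate(
        m_hat=m_hat,
        mu_rif=mu,
        ci_low=lo * scale,
        ci_high=hi * scale,
        mu_bp=mu_bp,
        U=U,
        C=C,
        L=L,
        n_cultures=n,
        mean_n_final=mean_nt,
    )


def drake_genomic_rate(
    mu_rif: float, C: int = DEFAULT_CORRECTION, L: int = DEFAULT_GENOME_LENGTH
) -> tuple[float, float]:
    """Scale a reporter-gene rate to (per-bp rate, genomic rate)."""
    if mu_rif < 0:
        raise ValueError("mu_rif must be >= 0")
    if C <= 0 or L <= 0:
        raise ValueError("C and L must be positive")
    mu_bp = mu_rif / C
    return mu_bp, L * mu_bp


def fold_change_summary(
    evolved: MutationRateEstimate, ancestor: MutationRateEstimate
) -> float:
    """Evolved mutation rate as a percentage of the ancestral rate."""
    if ancestor.mu_rif == 0:
        raise ValueError("ancestral mutation rate is zero; fold change undefined")
    return 100.0 * evolved.mu_rif / ancestor.mu_rif
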