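"""Tissue-level donor mixture estimation.

The quantity of interest is p_C, the fraction of a tissue's informative
transcript pool contributed by donor C (the L2/L3 cell layers); p_O = 1 - p_C
is the L1 (donor O) contribution.  Three estimators are provided because a
printed donor percentage can be either a share of SNP sites or a share of
reads:

``site_share``
    p_C = (#C_ONLY + sum over BOTH sites of (1 - f_O)) / #informative sites.
    BOTH sites contribute fractionally through their read evidence rather
    than a flat 1/2, so deeply covered shared sites inform the estimate.

``read_fraction``
    p_C = sum n_C / sum (n_O + n_C): the pooled donor-C allele frequency.

``binomial_mle``
    Maximum-likelihood estimate under an allele-miscall error model: each
    informative read reports the C allele with probability
    q(p) = p(1 - eps) + (1 - p) eps, so site i contributes
    Binomial(n_C,i | n_i, q(p)) to the likelihood.  The likelihood depends
    on the counts only through their pooled sums; the maximizer is located
    by a 1001-point grid followed by golden-section refinement (the
    likelihood is unimodal in p).  At eps = 0 the closed form
    p = sum n_C / sum n is returned exactly.

Bootstrap percentile confidence intervals resample *sites* with
replacement, treating sites as the independent units.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, xlogy

from .errors import ConfigurationError, EstimationError
from .origin import (BOTH, C_ONLY, O_ONLY, AlleleCounts, OriginCall,
                     OriginThresholds, classify_counts)

__all__ = [
    "CompositionEstimate",
    "estimate_site_share",
    "estimate_read_fraction",
    "estimate_binomial_mle",
    "bootstrap_ci",
    "METHODS",
]

logger = logging.getLogger(__name__)

METHODS = ("site_share", "read_fraction", "binomial_mle")

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0  # 1/phi
_GRID_POINTS = 1001
_GOLDEN_TOL = 1e-9  # bracket width at termination (beats the 1e-6 contract)


@dataclass(frozen=True)
class CompositionEstimate:
    """A donor-mixture point estimate with optional bootstrap CI."""

    p_C: float
    method: str
    n_sites_used: int
    ci_low: float | None = None
    ci_high: float | None = None
    loglik: float | None = None
    epsilon: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_C <= 1.0):
            raise EstimationError(f"p_C = {self.p_C} outside [0, 1]")
        if self.method not in METHODS:
            raise ConfigurationError(f"unknown method {self.method!r}")

    @property
    def p_O(self) -> float:
        return 1.0 - self.p_C


# ---------------------------------------------------------------------------
# Point estimators
# ---------------------------------------------------------------------------

def _site_weights(calls: list[OriginCall]) -> np.ndarray:
    """Per-call donor-C contribution; NaN marks uninformative calls."""
    w = np.full(len(calls), np.nan)
    for i, call in enumerate(calls):
        if call.category == C_ONLY:
            w[i] = 1.0
        elif call.category == O_ONLY:
            w[i] = 0.0
        elif call.category == BOTH:
            w[i] = 1.0 - call.f_O
    return w


def estimate_site_share(calls: list[OriginCall]) -> CompositionEstimate:
    """Donor-C share of informative diagnostic sites."""
    w = _site_weights(calls)
    informative = ~np.isnan(w)
    n_used = int(informative.sum())
    if n_used == 0:
        raise EstimationError("no informative origin calls")
    return CompositionEstimate(p_C=float(w[informative].mean()),
                               method="site_share", n_sites_used=n_used)


def _count_arrays(counts: list[AlleleCounts]) -> tuple[np.ndarray, np.ndarray]:
    n_c = np.array([c.n_C for c in counts], dtype=np.int64)
    n = np.array([c.n for c in counts], dtype=np.int64)
    return n_c, n


def estimate_read_fraction(counts: list[AlleleCounts]) -> CompositionEstimate:
    """Pooled donor-C allele frequency over all informative reads."""
    n_c, n = _count_arrays(counts)
    total = int(n.sum())
    if total == 0:
        raise EstimationError("zero informative reads")
    return CompositionEstimate(p_C=float(n_c.sum() / total),
                               method="read_fraction",
                               n_sites_used=int((n > 0).sum()))


def _pooled_loglik_kernel(q: float | np.ndarray, s_c: float, s_n: float):
    """Log-likelihood in q, dropping the count-dependent binomial constant."""
    return xlogy(s_c, q) + xlogy(s_n - s_c, 1.0 - q)


def _q_of_p(p, eps: float):
    return p * (1.0 - eps) + (1.0 - p) * eps


def _golden_section_max(f, lo: float, hi: float, tol: float) -> float:
    """Golden-section search for the maximum of a unimodal f on [lo, hi]."""
    a, b = lo, hi
    h = b - a
    c = b - _INVPHI * h
    d = a + _INVPHI * h
    fc, fd = f(c), f(d)
    while h > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            h = b - a
            c = b - _INVPHI * h
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            h = b - a
            d = a + _INVPHI * h
            fd = f(d)
    return 0.5 * (a + b)


def _mle_pooled(s_c: float, s_n: float, eps: float) -> tuple[float, float]:
    """Maximize the pooled binomial log-likelihood over p in [0, 1].

    Returns (p_hat, kernel loglik at p_hat).  The eps = 0 closed form
    p = s_c / s_n is returned exactly, never via the optimizer.
    """
    if eps == 0.0:
        p_hat = s_c / s_n
        return p_hat, float(_pooled_loglik_kernel(p_hat, s_c, s_n))

    def g(p):
        return float(_pooled_loglik_kernel(_q_of_p(p, eps), s_c, s_n))

    grid = np.linspace(0.0, 1.0, _GRID_POINTS)
    vals = _pooled_loglik_kernel(_q_of_p(grid, eps), s_c, s_n)
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, _GRID_POINTS - 1)]
    p_hat = _golden_section_max(g, float(lo), float(hi), _GOLDEN_TOL)
    # endpoint check: the bracket midpoint can never beat a boundary optimum
    best = max(((g(p), p) for p in (p_hat, 0.0, 1.0)), key=lambda t: t[0])
    return best[1], best[0]


def estimate_binomial_mle(counts: list[AlleleCounts],
                          epsilon: float = 0.005) -> CompositionEstimate:
    """Error-aware maximum-likelihood estimate of the donor-C mixture
    proportion.  ``loglik`` is the full maximized log-likelihood including
    the binomial coefficients."""
    if not (0.0 <= epsilon < 0.5):
        raise ConfigurationError(f"epsilon = {epsilon} outside [0, 0.5)")
    n_c, n = _count_arrays(counts)
    if int(n.sum()) == 0:
        raise EstimationError("all-zero informative depths")
    s_c, s_n = float(n_c.sum()), float(n.sum())
    p_hat, kernel = _mle_pooled(s_c, s_n, epsilon)
    const = float(np.sum(gammaln(n + 1) - gammaln(n_c + 1) - gammaln(n - n_c + 1)))
    return CompositionEstimate(
        p_C=float(np.clip(p_hat, 0.0, 1.0)),
        method="binomial_mle",
        n_sites_used=int((n > 0).sum()),
        loglik=kernel + const,
        epsilon=epsilon,
    )


# ---------------------------------------------------------------------------
# Bootstrap percentile confidence intervals
# ---------------------------------------------------------------------------

def _replicate_estimates_site_share(w: np.ndarray, idx: np.ndarray) -> np.ndarray:
    res = w[idx]  # (B, n)
    with np.errstate(invalid="ignore"):
        return np.nanmean(res, axis=1)


def bootstrap_ci(
    counts: list[AlleleCounts],
    estimator: str = "site_share",
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    epsilon: float = 0.005,
    thresholds: OriginThresholds = OriginThresholds(),
    exhaustive: bool = False,
) -> tuple[float, float]:
    """Percentile bootstrap interval for an estimator, resampling sites.

    Degenerate resamples (zero informative reads, or for ``site_share``
    zero informative calls) are redrawn; the redraw count is logged.  With
    ``exhaustive=True`` every ordered resample is enumerated instead of
    drawn (only feasible for a handful of sites) and ``B``/``seed`` are
    ignored.
    """
    if B < 1:
        raise ConfigurationError("B must be >= 1")
    if not (0.0 < level < 1.0):
        raise ConfigurationError("level must be in (0, 1)")
    if estimator not in METHODS:
        raise ConfigurationError(f"unknown estimator {estimator!r}")
    n_sites = len(counts)
    if n_sites < 2:
        raise EstimationError("bootstrap needs >= 2 sites")

    if estimator == "site_share":
        w = _site_weights(classify_counts(counts, thresholds))
        per_site = (w,)
    else:
        n_c, n = _count_arrays(counts)
        per_site = (n_c.astype(float), n.astype(float))

    def estimates_for(idx: np.ndarray) -> np.ndarray:
        if estimator == "site_share":
            return _replicate_estimates_site_share(per_site[0], idx)
        s_c = per_site[0][idx].sum(axis=1)
        s_n = per_site[1][idx].sum(axis=1)
        out = np.full(len(idx), np.nan)
        for j, (sc, sn) in enumerate(zip(s_c, s_n)):
            if sn > 0:
                if estimator == "read_fraction":
                    out[j] = sc / sn
                else:
                    out[j] = _mle_pooled(float(sc), float(sn), epsilon)[0]
        return out

    if exhaustive:
        if n_sites > 8:
            raise ConfigurationError("exhaustive bootstrap limited to <= 8 sites")
        idx = np.array(list(itertools.product(range(n_sites), repeat=n_sites)),
                       dtype=np.intp)
        reps = estimates_for(idx)
        reps = reps[~np.isnan(reps)]
        if reps.size == 0:
            raise EstimationError("all exhaustive resamples degenerate")
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n_sites, size=(B, n_sites))
        reps = estimates_for(idx)
        n_redraws = 0
        bad = np.isnan(reps)
        while bad.any():
            n_redraws += int(bad.sum())
            if n_redraws > 100 * B:
                raise EstimationError(
                    "bootstrap: resamples persistently degenerate")
            idx_new = rng.integers(0, n_sites, size=(int(bad.sum()), n_sites))
            reps[bad] = estimates_for(idx_new)
            bad = np.isnan(reps)
        if n_redraws:
            logger.info("bootstrap_ci: redrew %d degenerate resamples", n_redraws)

    alpha = 1.0 - level
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)
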