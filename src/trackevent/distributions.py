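"""Exact count-distribution machinery for multi-event lesion statistics.

A single track produces lesions in one of several categories; the number
of tracks hitting a region is Poisson distributed.  The number of lesions
per category is therefore a compound-Poisson (multinomial-mixture)
variable.  This module provides the exact finite-support arithmetic for
these distributions: multinomial conditionals, Poisson mixtures and their
factorisation into independent Poisson marginals, n-fold convolutions
weighted by the track-number distribution, independent binomial thinning
(used both for repair, keep = 1 - R, and for the ionization-cluster to
double-strand-break conversion, keep = p_d), and diagnostics against the
Poisson/independence null.

All distributions are truncated to a finite support with an explicit
``tail_mass`` bookkeeping the remainder; convolutions are exact direct
summations on the truncated supports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

__all__ = [
    "CountDistribution",
    "BivariateCountDistribution",
    "EventProbabilities",
    "multinomial_conditional",
    "poisson_mixture",
    "poisson_mixture_three",
    "thin_bivariate",
    "multi_event_mixture",
    "independence_ratio",
    "poisson_reference",
]

_NORM_TOL = 1e-9
DEFAULT_TAIL_TOL = 1e-12


def _check_norm(total: float, tail: float) -> None:
    if abs(total + tail - 1.0) > _NORM_TOL:
        raise ValueError(
            f"masses + tail_mass = {total + tail} deviates from 1 by more "
            f"than {_NORM_TOL}"
        )


@dataclass(frozen=True)
class CountDistribution:
    """Probability masses over counts 0..K with explicit tail mass."""

    masses: np.ndarray
    tail_mass: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "masses", m)
        if m.ndim != 1:
            raise ValueError("masses must be one-dimensional")
        if (m < -1e-15).any() or self.tail_mass < -1e-15:
            raise ValueError("negative probability mass")
        _check_norm(float(m.sum()), self.tail_mass)

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.masses.size)

    def mean(self) -> float:
        return float(self.support @ self.masses)

    def variance(self) -> float:
        mu = self.mean()
        return float(((self.support - mu) ** 2) @ self.masses)

    def overdispersion(self) -> float:
        """Variance-to-mean ratio (1 for a Poisson distribution)."""
        mu = self.mean()
        if mu == 0.0:
            raise ValueError("overdispersion undefined for zero-mean distribution")
        return self.variance() / mu


@dataclass(frozen=True)
class BivariateCountDistribution:
    """Joint probability masses over pairs of counts (0..K1, 0..K2)."""

    masses: np.ndarray
    tail_mass: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "masses", m)
        if m.ndim != 2:
            raise ValueError("masses must be two-dimensional")
        if (m < -1e-15).any() or self.tail_mass < -1e-15:
            raise ValueError("negative probability mass")
        _check_norm(float(m.sum()), self.tail_mass)

    def marginal(self, axis: int) -> CountDistribution:
        """Marginal distribution of the count indexed along ``axis``."""
        other = 1 - axis
        return CountDistribution(self.masses.sum(axis=other), self.tail_mass)

    def mean(self) -> tuple[float, float]:
        return (self.marginal(0).mean(), self.marginal(1).mean())


@dataclass(frozen=True)
class EventProbabilities:
    """Per-track category probabilities.

    Three-category model: nonlethal ``p0``, sublethal ``p1``, lethal
    ``p2plus`` (``p0 = 1 - p1 - p2plus``).  Four-category model adds
    potentially lethal ``p2`` and definitely lethal ``p3plus``; set
    either ``p2plus`` or the pair (``p2``, ``p3plus``), not both.
    """

    p1: float
    p2plus: float | None = None
    p2: float | None = None
    p3plus: float | None = None

    def __post_init__(self) -> None:
        four = self.p2 is not None or self.p3plus is not None
        if four and self.p2plus is not None:
            raise ValueError("give either p2plus or (p2, p3plus), not both")
        if four and (self.p2 is None or self.p3plus is None):
            raise ValueError("four-category model needs both p2 and p3plus")
        for v in self.active:
            if not 0.0 <= v <= 1.0:
                raise ValueError("category probabilities must lie in [0, 1]")
        if sum(self.active) > 1.0 + 1e-12:
            raise ValueError("category probabilities must sum to at most 1")

    @property
    def active(self) -> tuple[float, ...]:
        """Non-null category probabilities, excluding p0."""
        if self.p2 is not None:
            return (self.p1, self.p2, self.p3plus)
        return (self.p1, self.p2plus if self.p2plus is not None else 0.0)

    @property
    def p0(self) -> float:
        return 1.0 - sum(self.active)


def multinomial_conditional(n: int, probs: EventProbabilities) -> np.ndarray:
    """Joint pmf of the category counts given exactly ``n`` tracks.

    Returns an array of shape ``(n+1,) * m`` for ``m`` active categories;
    entry ``[n1, n2, ...]`` is the multinomial probability that the
    categories occur ``n1, n2, ...`` times among the ``n`` tracks (the
    remainder being nonlethal).  Entries with ``n1 + n2 + ... > n`` are 0.
    """
    if n < 0 or int(n) != n:
        raise ValueError("n must be a non-negative integer")
    n = int(n)
    active = probs.active
    m = len(active)
    out = np.zeros((n + 1,) * m)
    p = np.array(active + (probs.p0,))
    # enumerate compositions via meshgrid and scipy's multinomial pmf
    grids = np.meshgrid(*[np.arange(n + 1)] * m, indexing="ij")
    counts = np.stack([g.ravel() for g in grids], axis=1)
    rest = n - counts.sum(axis=1)
    ok = rest >= 0
    x = np.column_stack([counts[ok], rest[ok]])
    out.ravel()[np.flatnonzero(ok)] = stats.multinomial.pmf(x, n=n, p=p)
    return out


def _poisson_weights(n_t: float, tol: float) -> np.ndarray:
    """Poisson(n_t) pmf truncated when the cumulative weight >= 1 - tol."""
    if n_t < 0:
        raise ValueError("n_t must be non-negative")
    if not 0.0 < tol < 1.0:
        raise ValueError("tolerance must be in (0, 1)")
    n_max = int(stats.poisson.ppf(1.0 - tol, n_t)) + 1 if n_t > 0 else 0
    return stats.poisson.pmf(np.arange(n_max + 1), n_t)


def poisson_mixture(
    n_t: float, probs: EventProbabilities, tol: float = 1e-10
) -> BivariateCountDistribution:
    """Mixture sum_n Pois(n; n_t) * multinomial(n) over two categories.

    The result factorises into independent Poisson marginals with means
    ``n_t * p_i``; the mixture is computed by explicit summation (the
    factorisation is available as a cross-check, not assumed).
    """
    if len(probs.active) != 2:
        raise ValueError("poisson_mixture expects the three-category model")
    w = _poisson_weights(n_t, tol)
    size = w.size  # counts cannot exceed the track number
    acc = np.zeros((size, size))
    for n, wn in enumerate(w):
        cond = multinomial_conditional(n, probs)
        acc[: n + 1, : n + 1] += wn * cond
    return BivariateCountDistribution(acc, tail_mass=max(0.0, 1.0 - w.sum()))


def poisson_mixture_three(
    n_t: float, probs: EventProbabilities, tol: float = 1e-10
) -> np.ndarray:
    """Trivariate analogue for the four-category model.

    Returns the joint pmf array over (n1, n2, n3plus); it equals the
    product of three Poisson marginals with means ``n_t * p_i``.
    """
    if len(probs.active) != 3:
        raise ValueError("poisson_mixture_three expects the four-category model")
    w = _poisson_weights(n_t, tol)
    size = w.size
    acc = np.zeros((size, size, size))
    for n, wn in enumerate(w):
        cond = multinomial_conditional(n, probs)
        acc[: n + 1, : n + 1, : n + 1] += wn * cond
    return acc


def _binomial_kernel(n_max: int, keep: float) -> np.ndarray:
    """Matrix A with A[k, n] = Binomial(k | n, keep) for 0 <= k, n <= n_max."""
    k = np.arange(n_max + 1)[:, None]
    n = np.arange(n_max + 1)[None, :]
    return stats.binom.pmf(k, n, keep)


def thin_bivariate(
    dist: BivariateCountDistribution, keep1: float, keep2: float
) -> BivariateCountDistribution:
    """Independent binomial thinning of both counts.

    Each of the ``n1`` first-kind and ``n2`` second-kind entities survives
    independently with probability ``keep1`` / ``keep2``.  Repair thinning
    uses ``keep = 1 - R``; conversion of ionization clusters to DSBs uses
    ``keep = p_d``.  Thinning preserves independence of the marginals and
    maps Poisson marginals to Poisson marginals with scaled means.
    """
    for keep in (keep1, keep2):
        if not 0.0 <= keep <= 1.0:
            raise ValueError("keep probabilities must lie in [0, 1]")
    k1, k2 = dist.masses.shape
    a = _binomial_kernel(k1 - 1, keep1)
    b = _binomial_kernel(k2 - 1, keep2)
    return BivariateCountDistribution(a @ dist.masses @ b.T, dist.tail_mass)


def multi_event_mixture(
    single_event: BivariateCountDistribution,
    n_t: float,
    tol: float = 1e-10,
) -> BivariateCountDistribution:
    """Compound-Poisson multi-event distribution.

    Weighted sum of n-fold convolutions of the single-event distribution,
    with Poisson(n_t) weights for the number of tracks:
    ``P_multi = sum_n Pois(n; n_t) * P_single^(*n)``.  Convolutions are
    exact direct summations on the truncated supports.
    """
    w = _poisson_weights(n_t, tol)
    k1, k2 = single_event.masses.shape
    n_max = w.size - 1
    out = np.zeros((n_max * (k1 - 1) + 1, n_max * (k2 - 1) + 1))
    cur = np.ones((1, 1))  # zero tracks: point mass at (0, 0)
    out[:1, :1] += w[0] * cur
    for n in range(1, n_max + 1):
        cur = signal.convolve2d(cur, single_event.masses)
        out[: cur.shape[0], : cur.shape[1]] += w[n] * cur
    tail = max(0.0, 1.0 - w.sum()) + single_event.tail_mass
    # trim all-but-negligible trailing rows/columns for compactness
    keep1 = int(np.max(np.nonzero(out.sum(axis=1) > 0)[0])) + 1
    keep2 = int(np.max(np.nonzero(out.sum(axis=0) > 0)[0])) + 1
    trimmed = out[:keep1, :keep2]
    tail += float(out.sum() - trimmed.sum())
    return BivariateCountDistribution(trimmed, tail_mass=tail)


def independence_ratio(
    dist: BivariateCountDistribution, floor: float | None = None
) -> np.ma.MaskedArray:
    """Ratio of the joint pmf to the product of its marginals.

    Element (i, j) is ``P(i, j) / (P1(i) P2(j))``; cells where the product
    of marginals falls below ``floor`` are masked (default floor: 1e-6 of
    the maximum joint mass).  Ratios of 1 everywhere indicate statistical
    independence of the two counts.
    """
    if floor is None:
        floor = 1e-6 * float(dist.masses.max())
    if floor <= 0:
        raise ValueError("floor must be positive")
    m1 = dist.masses.sum(axis=1)[:, None]
    m2 = dist.masses.sum(axis=0)[None, :]
    prod = m1 * m2
    mask = prod < floor
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mask, np.nan, dist.masses / np.where(mask, 1.0, prod))
    return np.ma.MaskedArray(ratio, mask=mask)


def poisson_reference(
    dist: CountDistribution, omit_zero: bool = True
) -> tuple[CountDistribution, float]:
    """Matched Poisson reference and overdispersion index.

    The reference Poisson parameter is the mean of ``dist``; with
    ``omit_zero=True`` the mean is computed over the zero-truncated
    distribution (counts >= 1, renormalised), matching the convention of
    comparing scored frequency spectra against a Poisson of the same mean
    with the empty bin left out.  The overdispersion index is the
    variance-to-mean ratio of the full distribution.
    """
    total = float(dist.masses.sum())
    if total <= 0:
        raise ValueError("distribution has no mass")
    if omit_zero:
        pos = dist.masses[1:]
        norm = float(pos.sum())
        if norm <= 0:
            raise ValueError("all mass at zero; omit_zero reference undefined")
        lam = float(np.arange(1, dist.masses.size) @ pos) / norm
    else:
        lam = dist.mean()
    k = np.arange(dist.masses.size)
    pmf = stats.poisson.pmf(k, lam)
    ref = CountDistribution(pmf, tail_mass=max(0.0, 1.0 - pmf.sum()))
    return ref, dist.overdispersion()
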