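"""Closed-form cell-survival models of the track-event / RAMN family.

The models describe the surviving fraction of cells after a dose ``D`` of
ionizing radiation in terms of per-track probabilities of inducing lethal
and sublethal lesions.  A cell is hit by a Poisson-distributed number of
tracks; each track independently produces a nonlethal, sublethal or lethal
event.  Survival requires no lethal event and at most one sublethal event
(one isolated DNA double-strand break is assumed to be repaired).

Two parameterisations are used throughout:

* ``p``/``q``: expected numbers of lethal/sublethal events per unit dose
  (Gy^-1), giving ``S = (1 + qD) exp(-(p+q)D)``.
* RAMN: ``N`` cluster volumes (CVs) per cell, ``n_t`` mean tracks per cell
  cross-section, per-track probabilities ``p_SL``/``p_CL`` of a single or
  clustered lesion in one CV.

Repair variants extend the basic form with a repair probability ``R``
applied to cells holding exactly one lethal event or exactly two sublethal
events (and, in the four-category model, distinguishing potentially lethal
from definitely lethal events via a fourth rate ``p'``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SurvivalParameters",
    "RAMNParameters",
    "survival_basic",
    "survival_from_track_probs",
    "survival_ramn",
    "survival_critical_cvs",
    "quadratic_unity_dose",
    "survival_repair_consistent",
    "survival_repair_four_category",
    "survival_repair_threshold",
    "survival_curve",
]

#: n_t * p_SL above which the large-N exponential approximation is dubious.
APPROX_VALIDITY_LIMIT = 0.5


@dataclass(frozen=True)
class SurvivalParameters:
    """Rates per dose and dose for the p/q family of models.

    Parameters
    ----------
    p : float
        Lethal-event rate per dose (Gy^-1).
    q : float
        Sublethal-event rate per dose (Gy^-1).
    dose : float
        Absorbed dose (Gy).
    p_prime : float, optional
        Potentially-lethal-event rate per dose (Gy^-1); only used by the
        four-category repair model.  Defaults to ``p`` (no definitely
        lethal single-track events).
    repair : float
        Repair probability R in [0, 1].
    """

    p: float
    q: float
    dose: float
    p_prime: float | None = None
    repair: float = 0.0

    def __post_init__(self) -> None:
        if self.p < 0 or self.q < 0:
            raise ValueError("event rates p, q must be non-negative")
        if self.p_prime is not None and self.p_prime < 0:
            raise ValueError("p_prime must be non-negative")
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if not 0.0 <= self.repair <= 1.0:
            raise ValueError("repair probability must lie in [0, 1]")


@dataclass(frozen=True)
class RAMNParameters:
    """Parameters of the nanodosimetry-based radiation action model.

    ``n_cv`` is the number of cluster volumes per cell, ``n_t`` the mean
    number of tracks per cell cross-section, and ``p_sl``/``p_cl`` the
    per-track probabilities of inducing a single or clustered lesion in
    one CV.  ``sigma`` is the cross-section-like scale factor (nm^2 as
    configured); ``r1``/``r2plus`` are repair probabilities of single and
    clustered lesions.
    """

    n_cv: int
    n_t: float
    p_sl: float
    p_cl: float
    sigma: float | None = None
    r1: float = 0.0
    r2plus: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cv < 1 or int(self.n_cv) != self.n_cv:
            raise ValueError("n_cv must be an integer >= 1")
        if self.n_t < 0:
            raise ValueError("n_t must be non-negative")
        for name in ("p_sl", "p_cl", "r1", "r2plus"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def persistence(self) -> float:
        """Ratio (1-R1)/(1-R2+) of non-repair probabilities."""
        if self.r2plus >= 1.0:
            raise ValueError("persistence undefined for r2plus >= 1")
        return (1.0 - self.r1) / (1.0 - self.r2plus)


def survival_basic(params: SurvivalParameters) -> float:
    """Basic survival fraction ``(1 + qD) exp(-(p+q)D)``."""
    qd = params.q * params.dose
    return (1.0 + qd) * math.exp(-(params.p + params.q) * params.dose)


def survival_from_track_probs(n_t: float, p1: float, p2plus: float) -> float:
    """Survival from the mean track number and per-track probabilities.

    ``S = (1 + n_t p1) exp(-n_t (p1 + p2+))`` — survival means at most one
    sublethal and no lethal event among the Poisson(n_t) tracks.
    """
    if n_t < 0:
        raise ValueError("n_t must be non-negative")
    if p1 < 0 or p2plus < 0 or p1 + p2plus > 1.0 + 1e-12:
        raise ValueError("p1, p2plus must be non-negative with p1 + p2plus <= 1")
    return (1.0 + n_t * p1) * math.exp(-n_t * (p1 + p2plus))


def survival_ramn(params: RAMNParameters) -> float:
    """RAMN survival ``(1 + N n_t p_SL) exp(-N n_t (p_SL + p_CL))``.

    Equivalent to :func:`survival_from_track_probs` with the per-track
    probabilities scaled by the number of cluster volumes.
    """
    mu_sl = params.n_cv * params.n_t * params.p_sl
    mu_cl = params.n_cv * params.n_t * params.p_cl
    if not (math.isfinite(mu_sl) and math.isfinite(mu_cl)):
        raise ValueError("N * n_t * (p_SL + p_CL) must be finite")
    return (1.0 + mu_sl) * math.exp(-(mu_sl + mu_cl))


def survival_critical_cvs(params: RAMNParameters, mode: str = "exact") -> float:
    """Survival when every one of N critical CVs must stay undamaged.

    exact:  ``(1 + n_t p_SL)^N exp(-N n_t (p_SL + p_CL))`` evaluated in
    log space (``N log1p``) to stay finite for large N.

    approx: ``exp(-pD - (qD)^2 / (2N))`` with ``pD = N n_t p_CL`` and
    ``qD = N n_t p_SL`` (second-order expansion of the logarithm of the
    prefactor).
    """
    x = params.n_t * params.p_sl
    mu = params.n_cv * params.n_t * (params.p_sl + params.p_cl)
    if mode == "exact":
        return math.exp(params.n_cv * math.log1p(x) - mu)
    if mode == "approx":
        qd = params.n_cv * x
        pd = params.n_cv * params.n_t * params.p_cl
        if qd > APPROX_VALIDITY_LIMIT:
            warnings.warn(
                "large-N approximation dubious for N*n_t*p_SL > "
                f"{APPROX_VALIDITY_LIMIT}", stacklevel=2,
            )
        return math.exp(-pd - qd * qd / (2.0 * params.n_cv))
    raise ValueError(f"mode must be 'exact' or 'approx', got {mode!r}")


def quadratic_unity_dose(n_cv: float, q: float) -> float:
    """Dose at which the quadratic term ``(qD)^2/(2N)`` equals one.

    Closed form ``sqrt(2 N) / q``; gauges where the critical-CV survival
    approximation departs from a pure exponential.
    """
    if n_cv < 1:
        raise ValueError("n_cv must be >= 1")
    if q <= 0:
        raise ValueError("q must be positive")
    return math.sqrt(2.0 * n_cv) / q


def survival_repair_consistent(params: SurvivalParameters) -> float:
    """Repair-consistent survival.

    Cells with exactly one lethal event or exactly two sublethal events
    (and nothing else) are rescued with probability R:
    ``S = (1 + qD + R[pD + (qD)^2/2]) exp(-(p+q)D)``.
    """
    d = params.dose
    qd, pd, r = params.q * d, params.p * d, params.repair
    return (1.0 + qd + r * (pd + qd * qd / 2.0)) * math.exp(-(pd + qd))


def survival_repair_four_category(params: SurvivalParameters) -> float:
    """Four-category repair model (nonlethal / sublethal / potentially
    lethal / definitely lethal single-track events).

    Only potentially lethal events (rate ``p'``) are candidates for
    repair: ``S = (1 + qD + R[p'D + (qD)^2/2]) exp(-(p+q)D)``.  With
    ``p' = p`` this collapses to :func:`survival_repair_consistent`.
    """
    d = params.dose
    p_prime = params.p if params.p_prime is None else params.p_prime
    qd, pd, ppd, r = params.q * d, params.p * d, p_prime * d, params.repair
    return (1.0 + qd + r * (ppd + qd * qd / 2.0)) * math.exp(-(pd + qd))


def survival_repair_threshold(params: SurvivalParameters) -> float:
    """Threshold repair: whenever more than one DSB is present, all damage
    is repaired with probability R.

    ``S' = S0 + R (1 - S0)`` where S0 is the basic survival — the first
    term is the probability of at most one DSB, the bracket the
    probability of more than one.
    """
    s0 = survival_basic(params)
    return s0 + params.repair * (1.0 - s0)


_MODELS = {
    "basic": survival_basic,
    "repair-mixed": survival_repair_consistent,
    "repair-4cat": survival_repair_four_category,
    "repair-threshold": survival_repair_threshold,
}


def survival_curve(model: str, params, doses: np.ndarray) -> np.ndarray:
    """Evaluate a named survival model on a dose grid.

    ``params`` is a :class:`SurvivalParameters` (its ``dose`` field is
    ignored) for the p/q family, or a :class:`RAMNParameters` for the
    ``ramn``/``critical`` models, where the dose axis scales ``n_t``
    linearly (``n_t`` is taken to be the value at 1 Gy).
    """
    doses = np.asarray(doses, dtype=float)
    out = np.empty_like(doses)
    if model in _MODELS:
        fn = _MODELS[model]
        for i, d in enumerate(doses.ravel()):
            out.ravel()[i] = fn(
                SurvivalParameters(params.p, params.q, float(d),
                                   params.p_prime, params.repair)
            )
        return out
    if model in ("ramn", "critical"):
        for i, d in enumerate(doses.ravel()):
            scaled = RAMNParameters(params.n_cv, params.n_t * float(d),
                                    params.p_sl, params.p_cl, params.sigma,
                                    params.r1, params.r2plus)
            out.ravel()[i] = (survival_ramn(scaled) if model == "ramn"
                              else survival_critical_cvs(scaled))
        return out
    raise ValueError(f"unknown survival model {model!r}")
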