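"""Impact-parameter (annulus) fluence averaging and lesion probabilities.

A nanometric target (basic interaction volume, BIV, or cluster volume,
CV) can be damaged not only by tracks traversing it but also by tracks
passing at impact parameters of tens to hundreds of nm (the penumbra of
secondary electrons).  Per-track probabilities at a given fluence are
therefore fluence averages of conditional probabilities over the impact
parameter, evaluated here on concentric annuli whose radii are integer
multiples of a base radius ``R_L`` (annulus 1 being the traversal disc).

The module also provides the track-count-per-area relation
``n_t = (dose / mass stopping power) * area`` for broad parallel beams,
the corrected conditional single/clustered-lesion probabilities for a CV
containing ``n`` BIVs, and the mean persistent lesion frequencies after
repair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AnnulusGrid",
    "ImpactProfile",
    "FluenceModel",
    "LesionProbabilityInputs",
    "annulus_grid",
    "annulus_contributions",
    "fluence_average",
    "fluence_per_nm2",
    "tracks_through_area",
    "site_multiplicity_probs",
    "conditional_lesion_probs",
    "mean_persistent_lesions",
    "sphere_volume_ratio",
    "total_site_count",
]

#: J per MeV; converts mass stopping power (MeV cm^2/g) to Gy cm^2.
_MEV_TO_JOULE = 1.602176634e-13
#: nm^2 per cm^2.
_CM2_TO_NM2 = 1.0e14


@dataclass(frozen=True)
class AnnulusGrid:
    """Concentric annuli with edges at 0, R_L, 2 R_L, ..., k_max R_L (nm).

    Annulus k (1-based) spans radii [(k-1) R_L, k R_L]; annulus 1 is the
    disc of traversing tracks.  Areas are pi R_L^2 (2k - 1).
    """

    r_l: float
    k_max: int

    def __post_init__(self) -> None:
        if self.r_l <= 0:
            raise ValueError("R_L must be positive")
        if self.k_max < 1 or int(self.k_max) != self.k_max:
            raise ValueError("k_max must be an integer >= 1")

    @property
    def edges(self) -> np.ndarray:
        return self.r_l * np.arange(self.k_max + 1)

    @property
    def outer_radius(self) -> float:
        return self.r_l * self.k_max

    @property
    def areas(self) -> np.ndarray:
        """Annulus areas pi R_L^2 (2k - 1), k = 1..k_max (nm^2)."""
        k = np.arange(1, self.k_max + 1)
        return np.pi * self.r_l**2 * (2 * k - 1)

    @property
    def total_area(self) -> float:
        return float(np.pi * self.outer_radius**2)


@dataclass(frozen=True)
class ImpactProfile:
    """Conditional probability (or mean count) versus impact parameter."""

    radii: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "radii", r)
        object.__setattr__(self, "values", v)
        if r.ndim != 1 or r.shape != v.shape:
            raise ValueError("radii and values must be matching 1-D arrays")
        if (r < 0).any() or (np.diff(r) <= 0).any():
            raise ValueError("radii must be non-negative and strictly increasing")
        if (v < 0).any():
            raise ValueError("profile values must be non-negative")

    def __call__(self, r: np.ndarray) -> np.ndarray:
        """Linear interpolation; constant extrapolation at the inner end."""
        return np.interp(r, self.radii, self.values)


@dataclass(frozen=True)
class FluenceModel:
    """Uniform broad-beam fluence derived from dose and stopping power."""

    dose: float
    mass_stopping_power: float
    area: float | None = None

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if self.mass_stopping_power <= 0:
            raise ValueError("mass stopping power must be positive")

    @property
    def fluence(self) -> float:
        """Tracks per nm^2."""
        return fluence_per_nm2(self.dose, self.mass_stopping_power)


@dataclass(frozen=True)
class LesionProbabilityInputs:
    """Inputs for the conditional single/clustered-lesion probabilities.

    ``f2``: probability of >= 2 ionizations in a BIV given a track
    interacts with it; ``n_biv``: BIVs traversed by a track intersecting
    the CV; ``n_t``: mean tracks through the reference cross-section
    (small compared to 1, interpreted as an interaction probability).
    """

    f2: float
    n_biv: int
    n_t: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f2 <= 1.0:
            raise ValueError("F2 must lie in [0, 1]")
        if self.n_biv < 1 or int(self.n_biv) != self.n_biv:
            raise ValueError("n_biv must be an integer >= 1")
        if self.n_t < 0:
            raise ValueError("n_t must be non-negative")


def annulus_grid(r_l: float, k_max: int) -> AnnulusGrid:
    """Grid of k_max annuli with outer radius k_max * R_L."""
    return AnnulusGrid(r_l, k_max)


def _annulus_integrals(
    profile: ImpactProfile, grid: AnnulusGrid, subdivisions: int = 32
) -> np.ndarray:
    """Per-annulus integrals of profile(r) * 2 pi r dr (midpoint rule)."""
    if profile.radii[-1] < grid.outer_radius - 1e-9:
        raise ValueError(
            "profile domain ends at "
            f"{profile.radii[-1]} nm, short of the grid outer radius "
            f"{grid.outer_radius} nm"
        )
    edges = grid.edges
    out = np.empty(grid.k_max)
    for k in range(grid.k_max):
        sub = np.linspace(edges[k], edges[k + 1], subdivisions + 1)
        mid = 0.5 * (sub[:-1] + sub[1:])
        dr = np.diff(sub)
        out[k] = float(np.sum(profile(mid) * 2.0 * np.pi * mid * dr))
    return out


def annulus_contributions(
    profile: ImpactProfile, grid: AnnulusGrid, subdivisions: int = 32
) -> tuple[np.ndarray, np.ndarray]:
    """Relative and cumulative per-annulus contributions to the total.

    Contribution of annulus k is proportional to the integral of
    ``profile(r) * 2 pi r dr`` over the annulus; the returned relative
    contributions sum to 1 and the cumulative sums are monotone.
    """
    integrals = _annulus_integrals(profile, grid, subdivisions)
    total = integrals.sum()
    if total <= 0:
        raise ValueError("profile integrates to zero over the grid")
    rel = integrals / total
    return rel, np.cumsum(rel)


def fluence_average(
    profile: ImpactProfile,
    grid: AnnulusGrid,
    fluence: float,
    subdivisions: int = 32,
) -> tuple[float, float]:
    """Per-track probability and total probability at a given fluence.

    total = fluence * integral of profile(r) 2 pi r dr over the grid disc;
    the per-track probability divides out the mean track number
    ``n_t = fluence * (grid area)`` and is fluence-independent.
    """
    if fluence < 0:
        raise ValueError("fluence must be non-negative")
    integral = float(_annulus_integrals(profile, grid, subdivisions).sum())
    per_track = integral / grid.total_area
    return per_track, fluence * integral


def fluence_per_nm2(dose_gy: float, mass_stopping_power: float) -> float:
    """Broad-beam fluence (tracks / nm^2) = dose / mass stopping power.

    ``mass_stopping_power`` in MeV cm^2/g; unit conversion handled here.
    """
    if mass_stopping_power <= 0:
        raise ValueError("mass stopping power must be positive")
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    # (S/rho) in Gy cm^2: MeV cm^2/g * (J/MeV) * (1000 g/kg)
    gy_cm2 = mass_stopping_power * _MEV_TO_JOULE * 1e3
    return dose_gy / gy_cm2 / _CM2_TO_NM2


def tracks_through_area(
    dose_gy: float, mass_stopping_power: float, area_nm2: float
) -> float:
    """Mean number of tracks through an area (nm^2) at a given dose."""
    if area_nm2 < 0:
        raise ValueError("area must be non-negative")
    return fluence_per_nm2(dose_gy, mass_stopping_power) * area_nm2


def site_multiplicity_probs(
    mean_counts: np.ndarray,
    grid: AnnulusGrid,
    fluence: float,
    method: str = "poisson",
    n_sites: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-annulus probabilities of exactly one / two or more damaged sites.

    ``mean_counts[k]`` is the mean number of sites in the CV receiving an
    ionization cluster per single track through annulus k+1.  At the given
    fluence the multi-event mean is ``mu_k = (fluence * annulus area) *
    mean_counts[k]``; under Poisson statistics ``p1 = mu e^-mu`` and
    ``p2plus = 1 - (1 + mu) e^-mu``.  The binomial alternative distributes
    the mean over ``n_sites`` sites and agrees with Poisson to O(mu/n).
    """
    mean_counts = np.asarray(mean_counts, dtype=float)
    if mean_counts.shape != (grid.k_max,):
        raise ValueError("need one mean count per annulus")
    if (mean_counts < 0).any():
        raise ValueError("mean counts must be non-negative")
    mu = fluence * grid.areas * mean_counts
    if method == "poisson":
        p1 = mu * np.exp(-mu)
        p2plus = 1.0 - (1.0 + mu) * np.exp(-mu)
    elif method == "binomial":
        if n_sites is None or n_sites < 1:
            raise ValueError("binomial method needs n_sites >= 1")
        p = mu / n_sites
        if (p > 1).any():
            raise ValueError("mu exceeds n_sites; binomial model invalid")
        p0 = (1.0 - p) ** n_sites
        p1 = n_sites * p * (1.0 - p) ** (n_sites - 1)
        p2plus = 1.0 - p0 - p1
    else:
        raise ValueError(f"method must be 'poisson' or 'binomial', got {method!r}")
    return p1, p2plus


def conditional_lesion_probs(
    inp: LesionProbabilityInputs, mode: str = "exact"
) -> tuple[float, float]:
    """Conditional per-track single/clustered-lesion probabilities in a CV.

    exact:
        ``P_SL = F2 n (1 - n_t F2)^(n-1)``
        ``P_CL = [1 - (1 - n_t F2)^n] / n_t - P_SL``
    approx (first order in ``n_t``, as conventionally printed):
        ``P_SL = F2 n``,  ``P_CL = n_t n (n - 1) F2^2``.

    Note the exact P_CL expands to ``(n(n-1)/2) n_t F2^2`` at leading
    order — half the printed approximation; the exact form is the
    default and authoritative.
    """
    f2, n, n_t = inp.f2, inp.n_biv, inp.n_t
    if n_t * f2 >= 1.0:
        raise ValueError("requires n_t * F2 < 1")
    if mode == "exact":
        x = n_t * f2
        p_sl = f2 * n * (1.0 - x) ** (n - 1)
        # [1 - (1-x)^n]/n_t - P_SL = P(Binomial(n, x) >= 2)/n_t, evaluated
        # via the regularised tail to avoid catastrophic cancellation
        p_cl = 0.0 if n_t == 0.0 else float(stats.binom.sf(1, n, x)) / n_t
        return p_sl, p_cl
    if mode == "approx":
        return f2 * n, n_t * n * (n - 1) * f2 * f2
    raise ValueError(f"mode must be 'exact' or 'approx', got {mode!r}")


def mean_persistent_lesions(
    fluence: float,
    sigma: float,
    p_sl: float,
    p_cl: float,
    r1: float,
    r2plus: float,
) -> tuple[float, float]:
    """Mean persistent single and clustered lesions after repair.

    ``mean SL = (1 - R1) phi sigma P_SL``;
    ``mean CL = (1 - R2+) phi sigma P_CL``.
    """
    for name, v in (("r1", r1), ("r2plus", r2plus), ("p_sl", p_sl), ("p_cl", p_cl)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    return (1.0 - r1) * fluence * sigma * p_sl, (1.0 - r2plus) * fluence * sigma * p_cl


def sphere_volume_ratio(d_small: float, d_large: float) -> float:
    """Volume fraction (d_small / d_large)^3 of two spheres."""
    if d_small <= 0 or d_large <= 0:
        raise ValueError("diameters must be positive")
    return (d_small / d_large) ** 3


def total_site_count(sites_per_chromosome: float, n_chromosomes: float) -> float:
    """Total critical sites: sites per chromosome times chromosome count."""
    if sites_per_chromosome <= 0 or n_chromosomes <= 0:
        raise ValueError("counts must be positive")
    return sites_per_chromosome * n_chromosomes
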