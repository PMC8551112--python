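"""Seeded generators of synthetic ionization point clouds and profiles.

Real proton track structures (from condensed-history / track-structure
Monte Carlo codes) are spatially correlated point clouds: a dense core of
ionizations along the primary trajectory, secondary-electron branches
depositing compact blobs of ionizations at their track ends, and a
penumbra reaching radial distances of hundreds of nm.  The generators
here emulate those shape statistics with a transparent stochastic model
so that every scoring and statistics stage of the package is testable
without external simulation data.  They are NOT calibrated to physical
cross sections; the shipped "densely ionizing" and "sparsely ionizing"
parameter sets are synthetic stand-ins for low- and high-energy protons.

Model per track (axis +z):

* primary ionizations: Poisson process of rate ``lambda_primary`` per nm
  along [0, track_length];
* each primary ionization spawns a geometric number (mean
  ``secondary_yield``) of secondary-electron branches;
* each branch deposits a Gaussian blob (std ``end_blob_sigma``) of
  Poisson(``end_cluster_size_mean``) ionizations centred at a radial
  displacement drawn from a mixture of an exponential core
  (scale ``radial_core_scale``) and a bounded power-law tail
  (probability ``tail_fraction``, exponent ``tail_exponent``, cut off at
  ``tail_cutoff``), isotropic in azimuth, in the plane of the primary
  ionization.

An uncorrelated homogeneous "gas" of ionizations serves as the null
model for independence diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fluence import ImpactProfile

__all__ = [
    "TrackModelParams",
    "GasModelParams",
    "DENSE",
    "SPARSE",
    "generate_track",
    "generate_tracks",
    "generate_gas",
    "parametric_f2_profile",
    "radial_displacement_cdf",
]


@dataclass(frozen=True)
class TrackModelParams:
    """Shape parameters of the synthetic track model (lengths in nm)."""

    lambda_primary: float = 0.3
    secondary_yield: float = 1.0
    radial_core_scale: float = 3.0
    tail_fraction: float = 0.15
    tail_exponent: float = 1.5
    tail_cutoff: float = 500.0
    end_cluster_size_mean: float = 3.0
    end_blob_sigma: float = 1.5
    track_length: float = 650.0

    def __post_init__(self) -> None:
        for name in ("lambda_primary", "secondary_yield", "radial_core_scale",
                     "tail_exponent", "end_cluster_size_mean", "end_blob_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.tail_fraction <= 1.0:
            raise ValueError("tail_fraction must lie in [0, 1]")
        if self.track_length <= 0:
            raise ValueError("track_length must be positive")
        if self.tail_cutoff <= self.radial_core_scale:
            raise ValueError("tail_cutoff must exceed radial_core_scale")

    @property
    def mean_ionizations(self) -> float:
        """Expected total ionizations per track."""
        return self.track_length * self.lambda_primary * (
            1.0 + self.secondary_yield * self.end_cluster_size_mean
        )


#: Stand-in for a densely ionizing (low-energy) proton. Synthetic; not
#: calibrated to cross sections.
DENSE = TrackModelParams(
    lambda_primary=0.5, secondary_yield=1.5, radial_core_scale=2.5,
    tail_fraction=0.12, tail_exponent=1.5, tail_cutoff=500.0,
    end_cluster_size_mean=4.0, end_blob_sigma=1.2, track_length=650.0,
)

#: Stand-in for a sparsely ionizing (high-energy) proton. Synthetic.
SPARSE = TrackModelParams(
    lambda_primary=0.08, secondary_yield=1.0, radial_core_scale=4.0,
    tail_fraction=0.25, tail_exponent=1.2, tail_cutoff=500.0,
    end_cluster_size_mean=3.0, end_blob_sigma=1.5, track_length=650.0,
)

PRESETS = {"dense": DENSE, "sparse": SPARSE}


@dataclass(frozen=True)
class GasModelParams:
    """Homogeneous Poisson ionization gas in a box or cylinder (nm)."""

    density: float
    shape: str = "box"
    extent: tuple[float, float, float] = (100.0, 100.0, 100.0)

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be non-negative")
        if self.shape not in ("box", "cylinder"):
            raise ValueError("shape must be 'box' or 'cylinder'")

    @property
    def volume(self) -> float:
        if self.shape == "box":
            return float(np.prod(self.extent))
        radius, _, length = self.extent
        return float(np.pi * radius**2 * length)


def _sample_radial(params: TrackModelParams, n: int, rng: np.random.Generator
                   ) -> np.ndarray:
    """Radial displacements from the core/tail mixture."""
    tail = rng.random(n) < params.tail_fraction
    r = np.empty(n)
    n_core = int(np.sum(~tail))
    r[~tail] = rng.exponential(params.radial_core_scale, n_core)
    n_tail = n - n_core
    if n_tail:
        # bounded Pareto on [core scale, cutoff] via inverse CDF
        rmin, rmax, g = params.radial_core_scale, params.tail_cutoff, params.tail_exponent
        u = rng.random(n_tail)
        r[tail] = rmin * (1.0 - u * (1.0 - (rmin / rmax) ** g)) ** (-1.0 / g)
    return r


def radial_displacement_cdf(params: TrackModelParams, r: np.ndarray) -> np.ndarray:
    """CDF of the branch radial-displacement mixture (for distribution tests)."""
    r = np.asarray(r, dtype=float)
    core = 1.0 - np.exp(-r / params.radial_core_scale)
    rmin, rmax, g = params.radial_core_scale, params.tail_cutoff, params.tail_exponent
    with np.errstate(divide="ignore"):
        pareto = (1.0 - (rmin / np.maximum(r, rmin)) ** g) / (1.0 - (rmin / rmax) ** g)
    pareto = np.clip(pareto, 0.0, 1.0)
    return (1.0 - params.tail_fraction) * core + params.tail_fraction * pareto


def generate_track(
    params: TrackModelParams,
    rng: np.random.Generator | int,
    track_id: int = 0,
) -> pd.DataFrame:
    """One synthetic track as a table (track_id, x_nm, y_nm, z_nm).

    Deterministic for a given seed / generator state.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_primary = rng.poisson(params.lambda_primary * params.track_length)
    z_primary = np.sort(rng.uniform(0.0, params.track_length, n_primary))
    pts = [np.column_stack([np.zeros(n_primary), np.zeros(n_primary), z_primary])]
    if params.secondary_yield > 0 and n_primary:
        # geometric on {0, 1, ...} with mean = secondary_yield
        p_geo = 1.0 / (1.0 + params.secondary_yield)
        n_branches = rng.geometric(p_geo, n_primary) - 1
        total = int(n_branches.sum())
        if total:
            z0 = np.repeat(z_primary, n_branches)
            r = _sample_radial(params, total, rng)
            phi = rng.uniform(0.0, 2.0 * np.pi, total)
            centers = np.column_stack([r * np.cos(phi), r * np.sin(phi), z0])
            blob_n = rng.poisson(params.end_cluster_size_mean, total)
            m = int(blob_n.sum())
            if m:
                blob_centers = np.repeat(centers, blob_n, axis=0)
                jitter = rng.normal(0.0, params.end_blob_sigma, (m, 3))
                pts.append(blob_centers + jitter)
    xyz = np.concatenate(pts, axis=0) if pts else np.zeros((0, 3))
    return pd.DataFrame(
        {"track_id": track_id, "x_nm": xyz[:, 0], "y_nm": xyz[:, 1],
         "z_nm": xyz[:, 2]}
    )


def generate_tracks(
    params: TrackModelParams, n_tracks: int, seed: int
) -> pd.DataFrame:
    """Ensemble of ``n_tracks`` independent tracks, one seed stream."""
    if n_tracks < 0:
        raise ValueError("n_tracks must be non-negative")
    rng = np.random.default_rng(seed)
    frames = [generate_track(params, rng, track_id=t) for t in range(n_tracks)]
    if not frames:
        return pd.DataFrame(columns=["track_id", "x_nm", "y_nm", "z_nm"])
    return pd.concat(frames, ignore_index=True)


def generate_gas(
    params: GasModelParams, rng: np.random.Generator | int
) -> np.ndarray:
    """Homogeneous Poisson point process in the region; (n, 3) array (nm).

    Box: centred at the origin with side lengths ``extent``.  Cylinder:
    axis +z through the origin, ``extent = (radius, unused, length)``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = rng.poisson(params.density * params.volume)
    if params.shape == "box":
        ext = np.asarray(params.extent)
        return rng.uniform(-ext / 2.0, ext / 2.0, (n, 3))
    radius, _, length = params.extent
    r = radius * np.sqrt(rng.random(n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    z = rng.uniform(-length / 2.0, length / 2.0, n)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def parametric_f2_profile(
    f0: float,
    r_plateau: float,
    tail_exponent: float,
    cutoff: float,
    n_points: int = 512,
) -> ImpactProfile:
    """Plateau-plus-power-law impact-parameter profile.

    ``F2(r) = F0`` for ``r <= r_plateau``, then
    ``F0 (r_plateau / r)^tail_exponent`` up to ``cutoff`` and 0 beyond —
    a monotone stand-in for simulated cluster probabilities versus
    impact parameter.
    """
    if not 0.0 <= f0 <= 1.0:
        raise ValueError("F0 must lie in [0, 1]")
    if tail_exponent < 0:
        raise ValueError("tail exponent must be non-negative")
    if r_plateau <= 0 or cutoff <= r_plateau:
        raise ValueError("need 0 < r_plateau < cutoff")
    radii = np.unique(np.concatenate([
        np.linspace(0.0, r_plateau, max(2, n_points // 8)),
        np.geomspace(r_plateau, cutoff, n_points),
        [cutoff * (1 + 1e-9)],
    ]))
    values = np.where(
        radii <= r_plateau,
        f0,
        f0 * (r_plateau / np.maximum(radii, r_plateau)) ** tail_exponent,
    )
    values[radii > cutoff] = 0.0
    return ImpactProfile(radii, values)
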