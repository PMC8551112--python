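"""Two-pass FCC Wigner-Seitz scoring of ionization clusters.

Space is segmented into the Wigner-Seitz cells (rhombic dodecahedra) of a
face-centred cubic Bravais lattice — a full, gap-free tiling whose cells
approximate spheres.  The lattice constant is chosen so that the cell
volume equals that of a sphere of prescribed diameter, ``a^3/4 = pi
d^3/6``.

Pass 1 scores ionizations per BIV-sized cell; cells with at least two
ionizations hold an ionization cluster (IC), positioned at the centroid
of the ionizations in the cell.  Pass 2 scores ICs per CV-sized cell.
Spherical regions of interest (ROIs) are then tiled deterministically
over impact parameters around the track axis to build single-event
bivariate distributions of (CVs with exactly one IC, CVs with two or
more ICs).

Nearest-site assignment uses the exact decoder for the FCC (D3
checkerboard) lattice: scale to half-lattice-constant units, round to
the nearest integer vector, and if the coordinate sum is odd flip the
coordinate with the largest rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LatticeSpec",
    "ClusterSizeDistribution",
    "ROISpec",
    "lattice_from_diameter",
    "assign_points",
    "site_positions",
    "sites_in_box",
    "score_ics",
    "score_cvs",
    "roi_single_event",
    "cluster_size_cdf",
    "dsb_given_ic",
]

#: a = LATTICE_FACTOR * d_equiv solves a^3/4 = pi d^3/6.
LATTICE_FACTOR = (2.0 * np.pi / 3.0) ** (1.0 / 3.0)


@dataclass(frozen=True)
class LatticeSpec:
    """Axis-aligned FCC lattice with Wigner-Seitz cells of sphere-equivalent
    diameter ``d_equiv`` (nm)."""

    d_equiv: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.d_equiv <= 0:
            raise ValueError("equivalent diameter must be positive")

    @property
    def a(self) -> float:
        """Conventional cubic lattice constant (nm)."""
        return LATTICE_FACTOR * self.d_equiv

    @property
    def cell_volume(self) -> float:
        """Wigner-Seitz cell volume a^3/4 = pi d^3/6 (nm^3)."""
        return self.a**3 / 4.0


def lattice_from_diameter(
    d_equiv: float, origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
) -> LatticeSpec:
    """Lattice whose Wigner-Seitz cell volume matches a sphere of ``d_equiv``."""
    return LatticeSpec(d_equiv, origin)


def assign_points(points: np.ndarray, lattice: LatticeSpec) -> np.ndarray:
    """Map each point to its nearest FCC site (Wigner-Seitz membership).

    Returns integer site indices of shape (n, 3) in units of a/2 (index
    sums are even).  Exact nearest-site decoding; equidistant points are
    resolved deterministically by the rounding/flip rule.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[-1] != 3:
        raise ValueError("points must have shape (n, 3)")
    if not np.isfinite(pts).all():
        raise ValueError("point coordinates must be finite")
    u = (pts - np.asarray(lattice.origin)) / (lattice.a / 2.0)
    f = np.rint(u)
    odd = (f.sum(axis=1).astype(np.int64) % 2) != 0
    if odd.any():
        err = u[odd] - f[odd]
        worst = np.argmax(np.abs(err), axis=1)
        rows = np.arange(err.shape[0])
        step = np.where(err[rows, worst] >= 0, 1.0, -1.0)
        f[np.flatnonzero(odd), worst] += step
    return f.astype(np.int64)


def site_positions(cells: np.ndarray, lattice: LatticeSpec) -> np.ndarray:
    """Cartesian positions (nm) of FCC sites given their integer indices."""
    return np.asarray(cells, dtype=float) * (lattice.a / 2.0) + np.asarray(
        lattice.origin
    )


def sites_in_box(
    lattice: LatticeSpec, lo: np.ndarray, hi: np.ndarray
) -> np.ndarray:
    """Integer indices of all FCC sites whose positions lie in [lo, hi]^3."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    h = lattice.a / 2.0
    ranges = [
        np.arange(int(np.ceil((lo[i] - lattice.origin[i]) / h)),
                  int(np.floor((hi[i] - lattice.origin[i]) / h)) + 1)
        for i in range(3)
    ]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    even = (grid.sum(axis=1) % 2) == 0
    return grid[even].astype(np.int64)


def score_ics(
    points: np.ndarray, lattice_biv: LatticeSpec, min_ions: int = 2
) -> pd.DataFrame:
    """Pass 1: ionization clusters per BIV-sized Wigner-Seitz cell.

    Returns one row per cell containing at least ``min_ions`` ionizations,
    with columns ``i, j, k`` (site index), ``x, y, z`` (centroid of the
    ionizations in the cell, nm) and ``size`` (ionization count).
    """
    if min_ions < 2:
        raise ValueError("an ionization cluster needs min_ions >= 2")
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if pts.shape[0] == 0:
        return pd.DataFrame(columns=["i", "j", "k", "x", "y", "z", "size"])
    cells = assign_points(pts, lattice_biv)
    df = pd.DataFrame(
        {
            "i": cells[:, 0], "j": cells[:, 1], "k": cells[:, 2],
            "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
        }
    )
    agg = df.groupby(["i", "j", "k"], sort=True).agg(
        x=("x", "mean"), y=("y", "mean"), z=("z", "mean"), size=("x", "size")
    )
    agg = agg[agg["size"] >= min_ions].reset_index()
    return agg


def score_cvs(ic_positions: np.ndarray, lattice_cv: LatticeSpec) -> pd.DataFrame:
    """Pass 2: ionization-cluster counts per CV-sized Wigner-Seitz cell.

    ``ic_positions`` is an (n, 3) array of IC centroids (nm).  Returns one
    row per occupied CV cell with site index ``i, j, k``, site position
    ``x, y, z`` (nm) and ``n_ic``.
    """
    pos = np.asarray(ic_positions, dtype=float).reshape(-1, 3)
    if pos.shape[0] == 0:
        return pd.DataFrame(columns=["i", "j", "k", "x", "y", "z", "n_ic"])
    cells = assign_points(pos, lattice_cv)
    uniq, counts = np.unique(cells, axis=0, return_counts=True)
    xyz = site_positions(uniq, lattice_cv)
    return pd.DataFrame(
        {
            "i": uniq[:, 0], "j": uniq[:, 1], "k": uniq[:, 2],
            "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
            "n_ic": counts,
        }
    )


@dataclass(frozen=True)
class ROISpec:
    """Spherical ROI tiling around the track axis.

    Placements tile radial bins of width ``radial_bin_width`` (default
    ``r_roi``) from the axis out to ``max_radius`` (default 5 r_roi),
    with ``n_sectors`` azimuthal sectors per off-axis bin; each placement
    is weighted by the cross-sectional area of its sector.  The first
    ``head_trim`` nm and the distal ``tail_trim`` nm of the track are
    excluded.
    """

    r_roi: float
    radial_bin_width: float | None = None
    n_sectors: int = 8
    max_radius: float | None = None
    head_trim: float = 100.0
    tail_trim: float = 50.0

    def __post_init__(self) -> None:
        if self.r_roi <= 0:
            raise ValueError("ROI radius must be positive")
        if self.head_trim < 0 or self.tail_trim < 0:
            raise ValueError("trims must be non-negative")
        if self.n_sectors < 1:
            raise ValueError("need at least one azimuthal sector")
        if self.bin_width <= 0:
            raise ValueError("radial bin width must be positive")
        if self.placement_radius < self.r_roi:
            raise ValueError("max placement radius must be >= ROI radius")

    @property
    def bin_width(self) -> float:
        return self.radial_bin_width if self.radial_bin_width is not None else self.r_roi

    @property
    def placement_radius(self) -> float:
        return self.max_radius if self.max_radius is not None else 5.0 * self.r_roi

    def placements(self) -> tuple[np.ndarray, np.ndarray]:
        """Placement offsets (x, y) and area weights.

        The innermost bin is a disc sampled by one on-axis placement; each
        further bin contributes ``n_sectors`` placements at the bin-centre
        radius, equally spaced in azimuth, weighted by sector area.
        """
        w = self.bin_width
        n_bins = int(np.round(self.placement_radius / w))
        offs = [(0.0, 0.0)]
        weights = [np.pi * w**2]
        for k in range(2, n_bins + 1):
            r = (k - 0.5) * w
            sector_area = np.pi * w**2 * (2 * k - 1) / self.n_sectors
            for s in range(self.n_sectors):
                phi = 2.0 * np.pi * (s + 0.5) / self.n_sectors
                offs.append((r * np.cos(phi), r * np.sin(phi)))
                weights.append(sector_area)
        return np.asarray(offs), np.asarray(weights)


def roi_single_event(
    cv_tables: list[pd.DataFrame],
    z_ranges: list[tuple[float, float]],
    roi: ROISpec,
):
    """Single-event bivariate distribution of damaged CV counts per ROI.

    For each track (CV table from :func:`score_cvs` plus the z extent of
    the track), the ROI sphere is placed at the middle of the usable
    (trimmed) track length at each tiled radial offset; the counts of CVs
    with exactly one IC and with two or more ICs inside the sphere are
    recorded.  The pooled bivariate pmf weights each placement by its
    sector cross-sectional area.

    Returns ``(pooled, placements)`` where ``pooled`` is a
    :class:`~trackevent.distributions.BivariateCountDistribution` and
    ``placements`` a data frame with one row per (track, placement).
    """
    from .distributions import BivariateCountDistribution

    if len(cv_tables) != len(z_ranges):
        raise ValueError("need one z range per CV table")
    offs, weights = roi.placements()
    rows = []
    for t, (cv, (zmin, zmax)) in enumerate(zip(cv_tables, z_ranges)):
        z_lo = zmin + roi.head_trim
        z_hi = zmax - roi.tail_trim
        if z_hi - z_lo < 2.0 * roi.r_roi:
            raise ValueError(
                "usable track length shorter than the ROI diameter"
            )
        zc = 0.5 * (z_lo + z_hi)
        if len(cv):
            pos = cv[["x", "y", "z"]].to_numpy()
            n_ic = cv["n_ic"].to_numpy()
        else:
            pos = np.zeros((0, 3))
            n_ic = np.zeros(0, dtype=int)
        for p, (ox, oy) in enumerate(offs):
            center = np.array([ox, oy, zc])
            if len(pos):
                inside = np.sum((pos - center) ** 2, axis=1) <= roi.r_roi**2
                n1 = int(np.sum(inside & (n_ic == 1)))
                n2 = int(np.sum(inside & (n_ic >= 2)))
            else:
                n1 = n2 = 0
            rows.append((t, p, ox, oy, n1, n2, weights[p]))
    placements = pd.DataFrame(
        rows, columns=["track", "placement", "off_x", "off_y",
                       "n_single", "n_multi", "weight"]
    )
    k1 = int(placements["n_single"].max()) + 1
    k2 = int(placements["n_multi"].max()) + 1
    masses = np.zeros((k1, k2))
    np.add.at(
        masses,
        (placements["n_single"].to_numpy(), placements["n_multi"].to_numpy()),
        placements["weight"].to_numpy(),
    )
    masses /= masses.sum()
    return BivariateCountDistribution(masses), placements


@dataclass(frozen=True)
class ClusterSizeDistribution:
    """Cumulative cluster-size probabilities F_k = P(size >= k), k >= 1."""

    f: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "f", f)
        if f.ndim != 1 or f.size < 2:
            raise ValueError("need cumulative probabilities F_1, F_2, ...")
        if f[0] > 1.0 + 1e-12 or (f < -1e-15).any() or (np.diff(f) > 1e-12).any():
            raise ValueError("F_k must be non-increasing and within [0, 1]")

    @property
    def f2(self) -> float:
        return float(self.f[1])


def cluster_size_cdf(sizes: np.ndarray) -> ClusterSizeDistribution:
    """Empirical F_k = fraction of occupied cells with >= k ionizations."""
    sizes = np.asarray(sizes, dtype=int)
    if sizes.size == 0 or (sizes < 1).any():
        raise ValueError("need at least one cell with a positive count")
    kmax = int(sizes.max())
    f = np.array([(sizes >= k).mean() for k in range(1, kmax + 1)])
    if f.size < 2:
        f = np.append(f, 0.0)
    return ClusterSizeDistribution(f)


def dsb_given_ic(f: ClusterSizeDistribution) -> float:
    """Conditional probability that an ionization cluster forms a DSB.

    Each of the k ionizations in a cluster independently strikes one of
    the two DNA strands with probability 1/2; a DSB needs both strands
    hit.  Summing over the cluster-size spectrum:
    ``P(DSB | IC) = (1/F2) sum_{k>=2} F_k / 2^(k-1)``, always in [1/2, 1).
    """
    if f.f2 <= 0:
        raise ValueError("F2 must be positive")
    k = np.arange(2, f.f.size + 1)
    return float(np.sum(f.f[1:] / 2.0 ** (k - 1))) / f.f2
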