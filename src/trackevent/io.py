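"""Table I/O: track tables, pmf tables and impact-parameter profiles.

All formats are headered TSV.  Track tables carry one ionization per row
(``track_id  x_nm  y_nm  z_nm``); univariate pmfs ``count  probability``;
bivariate pmfs ``count1  count2  probability`` in row-major order;
profiles ``r_nm  value``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .distributions import BivariateCountDistribution, CountDistribution
from .fluence import ImpactProfile

__all__ = [
    "read_track_table",
    "write_track_table",
    "read_pmf",
    "write_pmf",
    "read_bivariate_pmf",
    "write_bivariate_pmf",
    "read_profile",
    "write_profile",
]

TRACK_COLUMNS = ["track_id", "x_nm", "y_nm", "z_nm"]


class TrackTableError(ValueError):
    """Raised for malformed track tables, naming the offending line."""


def read_track_table(path: str | Path) -> pd.DataFrame:
    """Read a track table, validating columns and coordinate values.

    Returns a data frame sorted by ``track_id`` with numeric coordinates
    in nm; raises :class:`TrackTableError` naming the first bad line.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackTableError(f"{path}: missing columns {missing}")
    out = pd.DataFrame()
    out["track_id"] = df["track_id"]
    for col in TRACK_COLUMNS[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise TrackTableError(
                f"{path}: non-numeric or missing {col} at line {line}"
            )
        if not np.isfinite(vals.to_numpy()).all():
            line = int(np.flatnonzero(~np.isfinite(vals.to_numpy()))[0]) + 2
            raise TrackTableError(f"{path}: non-finite {col} at line {line}")
        out[col] = vals.astype(float)
    return out.sort_values("track_id", kind="stable").reset_index(drop=True)


def write_track_table(df: pd.DataFrame, path: str | Path) -> None:
    df[TRACK_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pmf(path: str | Path) -> CountDistribution:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["count", "probability"]:
        raise ValueError(f"{path}: expected header 'count\tprobability'")
    counts = df["count"].to_numpy(dtype=int)
    masses = np.zeros(int(counts.max()) + 1 if len(counts) else 1)
    masses[counts] = df["probability"].to_numpy(dtype=float)
    return CountDistribution(masses, tail_mass=max(0.0, 1.0 - masses.sum()))


def write_pmf(dist: CountDistribution, path: str | Path) -> None:
    pd.DataFrame(
        {"count": dist.support, "probability": dist.masses}
    ).to_csv(path, sep="\t", index=False)


def read_bivariate_pmf(path: str | Path) -> BivariateCountDistribution:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:3]) != ["count1", "count2", "probability"]:
        raise ValueError(
            f"{path}: expected header 'count1\tcount2\tprobability'"
        )
    c1 = df["count1"].to_numpy(dtype=int)
    c2 = df["count2"].to_numpy(dtype=int)
    masses = np.zeros((int(c1.max()) + 1, int(c2.max()) + 1))
    masses[c1, c2] = df["probability"].to_numpy(dtype=float)
    return BivariateCountDistribution(
        masses, tail_mass=max(0.0, 1.0 - masses.sum())
    )


def write_bivariate_pmf(dist: BivariateCountDistribution, path: str | Path) -> None:
    k1, k2 = dist.masses.shape
    i1, i2 = np.meshgrid(np.arange(k1), np.arange(k2), indexing="ij")
    pd.DataFrame(
        {
            "count1": i1.ravel(),
            "count2": i2.ravel(),
            "probability": dist.masses.ravel(),
        }
    ).to_csv(path, sep="\t", index=False)


def read_profile(path: str | Path) -> ImpactProfile:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["r_nm", "value"]:
        raise ValueError(f"{path}: expected header 'r_nm\tvalue'")
    return ImpactProfile(df["r_nm"].to_numpy(float), df["value"].to_numpy(float))


def write_profile(profile: ImpactProfile, path: str | Path) -> None:
    pd.DataFrame({"r_nm": profile.radii, "value": profile.values}).to_csv(
        path, sep="\t", index=False
    )
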