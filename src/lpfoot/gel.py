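"""SDS-PAGE standard-curve calibration.

Band migration on a denaturing gel is, over the useful range, linear in
log10(molecular mass).  A ladder of known masses is fit by ordinary least
squares of log10(mass, kDa) on migration distance; an unknown band's mass is
then read off the fitted line.  Migration is the predictor because that is
what an analyst measures for an unknown band.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .proteins import MEAN_RESIDUE_MASS, TaggedConstruct


class CalibrationError(ValueError):
    """Raised when a ladder cannot be fit."""


@dataclass(frozen=True)
class LadderBand:
    mass: float  # daltons
    migration: float  # distance units (mm or pixels)

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("ladder band mass must be positive")
        if self.migration < 0:
            raise ValueError("migration distance must be >= 0")


@dataclass(frozen=True)
class StandardCurve:
    """Fitted log10(mass in kDa) = slope * migration + intercept."""

    slope: float
    intercept: float
    r_squared: float | None
    n_bands: int
    migration_min: float
    migration_max: float


@dataclass(frozen=True)
class MassEstimate:
    mass: float  # daltons
    extrapolated: bool

    def __float__(self) -> float:
        return self.mass


def fit_standard_curve(bands: Sequence[LadderBand]) -> StandardCurve:
    """OLS of log10(mass, kDa) on migration distance.

    With exactly two bands the fit is exact and r_squared is not reported.
    """
    if len(bands) < 2:
        raise CalibrationError(f"need >= 2 ladder bands, got {len(bands)}")
    mig = np.array([b.migration for b in bands], dtype=float)
    logm = np.log10(np.array([b.mass for b in bands], dtype=float) / 1e3)
    for m in np.unique(mig):
        vals = logm[mig == m]
        if vals.size > 1 and not np.allclose(vals, vals[0]):
            raise CalibrationError(f"duplicate migration {m} with different masses")
    if np.unique(mig).size < 2:
        raise CalibrationError("ladder bands must span at least two distinct migrations")
    fit = stats.linregress(mig, logm)
    r2 = float(fit.rvalue**2) if len(bands) >= 3 else None
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        n_bands=len(bands),
        migration_min=float(mig.min()),
        migration_max=float(mig.max()),
    )


def estimate_mass(curve: StandardCurve, migration: float) -> MassEstimate:
    """Mass in daltons at a migration distance; flags extrapolation."""
    log_kda = curve.slope * migration + curve.intercept
    extrapolated = not (curve.migration_min <= migration <= curve.migration_max)
    return MassEstimate(mass=float(10.0**log_kda * 1e3), extrapolated=extrapolated)


def predict_migration(curve: StandardCurve, mass: float) -> float:
    """Inverse of :func:`estimate_mass`; used by the gel simulator."""
    if curve.slope == 0:
        raise CalibrationError("flat standard curve has no inverse")
    return (np.log10(mass / 1e3) - curve.intercept) / curve.slope


def mass_to_length(
    mass: float,
    construct: TaggedConstruct | None = None,
    retained_tags: Iterable[str] = (),
    mean_residue_mass: float = MEAN_RESIDUE_MASS,
) -> int:
    """Residue count for a band mass after subtracting retained tag masses."""
    tag_mass = 0.0
    for side in retained_tags:
        if construct is None:
            raise ValueError("retained_tags given without a construct")
        tag = construct.n_tag if side == "N" else construct.c_tag if side == "C" else None
        if tag is None:
            raise ValueError(f"construct has no {side!r} tag")
        tag_mass += tag.mass
    if mass <= tag_mass:
        raise ValueError(
            f"band smaller than tag: mass {mass:.0f} Da <= retained tag mass {tag_mass:.0f} Da"
        )
    return int(round((mass - tag_mass) / mean_residue_mass))


# ---------------------------------------------------------------------------
# tab-separated I/O
#
# Ladder and band tables share one schema:
#   gel_id  lane  band_id  migration  mass_kda
# with either migration or mass_kda possibly empty (not both).

TABLE_COLUMNS = ["gel_id", "lane", "band_id", "migration", "mass_kda"]


def read_band_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gel_id": str, "lane": str, "band_id": str})
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"band table {path} missing columns {sorted(missing)}")
    both_empty = df["migration"].isna() & df["mass_kda"].isna()
    if both_empty.any():
        raise ValueError(f"band table {path}: rows with neither migration nor mass_kda")
    return df


def ladder_from_table(df: pd.DataFrame, gel_id: str | None = None) -> list[LadderBand]:
    if gel_id is not None:
        df = df[df["gel_id"] == gel_id]
    return [
        LadderBand(mass=row.mass_kda * 1e3, migration=row.migration)
        for row in df.itertuples()
    ]


def write_band_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=TABLE_COLUMNS, lineterminator="\n")
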