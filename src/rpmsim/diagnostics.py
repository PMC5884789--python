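"""Orientation-density diagnostics on the unit sphere.

How uniformly a simulator visits orientations is the property that separates
a good randomization algorithm from a poor one. This module bins the
sample-frame gravity direction into an equal-area partition of the sphere
(polar bands × azimuthal sectors, with band boundaries equally spaced in
cos θ), accumulates residence *time* per cell, and normalizes so that a
density of 1 everywhere is the uniform distribution. It also produces the
analytic expected density of the prolate-spheroid target law for
observed-vs-expected comparison, and summary uniformity metrics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EmptyTraceError, InvalidArgumentError
from .kinematics import GravityTrace
from .spheroid import SpheroidSpec

__all__ = [
    "EqualAreaPartition",
    "DensityMap",
    "UniformityMetrics",
    "equal_area_partition",
    "residence_density",
    "density_from_directions",
    "expected_spheroid_density",
    "uniformity_metrics",
    "chi_square_gof",
]

_AREA_TOL = 1e-9


@dataclass(frozen=True)
class EqualAreaPartition:
    """Equal-area band/sector partition of the unit sphere.

    ``cos_edges`` are the n_bands+1 polar-band boundaries, equally spaced on
    [-1, 1]; band i spans cos θ in [cos_edges[i], cos_edges[i+1]] and is cut
    into ``sectors[i]`` equal azimuthal cells. Cells are indexed band-major.
    """

    cos_edges: np.ndarray
    sectors: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "cos_edges", np.asarray(self.cos_edges, dtype=float))
        object.__setattr__(self, "sectors", np.asarray(self.sectors, dtype=int))
        areas = self.cell_areas()
        if np.max(areas) - np.min(areas) > _AREA_TOL:
            raise InvalidArgumentError(
                "sector rule does not produce equal-area cells; with equally "
                "spaced cos(theta) bands every band needs the same sector count"
            )

    @property
    def n_bands(self) -> int:
        return int(self.sectors.size)

    @property
    def n_cells(self) -> int:
        return int(self.sectors.sum())

    @property
    def band_offsets(self) -> np.ndarray:
        """First flat cell index of each band."""
        return np.concatenate([[0], np.cumsum(self.sectors)[:-1]])

    def cell_areas(self) -> np.ndarray:
        """Solid angle of every cell (flat, band-major order)."""
        band_area = 2.0 * np.pi * np.diff(self.cos_edges)
        return np.repeat(band_area / self.sectors, self.sectors)

    def cell_bounds(self) -> pd.DataFrame:
        """Cell bounds as polar/azimuth angles in radians (band-major order)."""
        rows = []
        for i in range(self.n_bands):
            c_lo, c_hi = self.cos_edges[i], self.cos_edges[i + 1]
            th_lo, th_hi = math.acos(min(c_hi, 1.0)), math.acos(max(c_lo, -1.0))
            k = self.sectors[i]
            width = 2.0 * np.pi / k
            for j in range(k):
                rows.append((th_lo, th_hi, j * width, (j + 1) * width))
        return pd.DataFrame(rows, columns=["band_lo", "band_hi", "az_lo", "az_hi"])

    def assign(self, directions: np.ndarray) -> np.ndarray:
        """Flat cell index of each unit direction (vectorized)."""
        u = np.asarray(directions, dtype=float)
        c = np.clip(u[:, 2], -1.0, 1.0)
        nb = self.n_bands
        band = np.minimum((np.searchsorted(self.cos_edges, c, side="right") - 1), nb - 1)
        band = np.maximum(band, 0)
        az = np.mod(np.arctan2(u[:, 1], u[:, 0]), 2.0 * np.pi)
        k = self.sectors[band]
        sector = np.minimum((az / (2.0 * np.pi) * k).astype(int), k - 1)
        return self.band_offsets[band] + sector


@dataclass
class DensityMap:
    """Normalized residence density over an equal-area partition.

    ``density`` is residence time per unit solid angle divided by the
    uniform expectation, so the area-weighted mean is 1 and 1 everywhere
    means perfectly uniform visiting. ``residence`` keeps the raw per-cell
    residence times (seconds, or probability mass for analytic maps).
    """

    partition: EqualAreaPartition
    residence: np.ndarray
    total_time: float

    def __post_init__(self) -> None:
        self.residence = np.asarray(self.residence, dtype=float)
        if self.residence.shape != (self.partition.n_cells,):
            raise InvalidArgumentError("one residence value per cell required")
        if self.total_time <= 0:
            raise InvalidArgumentError("total time must be positive")

    @property
    def density(self) -> np.ndarray:
        areas = self.partition.cell_areas()
        return (self.residence / self.total_time) / (areas / (4.0 * np.pi))

    def to_dataframe(self) -> pd.DataFrame:
        df = self.partition.cell_bounds()
        df["density"] = self.density
        return df

    def to_csv(self, path) -> None:
        """CSV with header ``band_lo,band_hi,az_lo,az_hi,density`` (radians)."""
        self.to_dataframe().to_csv(path, index=False)

    def to_json_report(self, path=None) -> dict:
        m = uniformity_metrics(self)
        report = {
            "n_cells": self.partition.n_cells,
            "total_time": self.total_time,
            "cv": m.cv,
            "min_density": m.min_density,
            "max_density": m.max_density,
            "chi_square": m.chi_square,
            "chi_square_dof": m.dof,
            "chi_square_p_uniform": m.p_value,
        }
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(report, fh, indent=2)
        return report


@dataclass(frozen=True)
class UniformityMetrics:
    """Descriptive uniformity summary of a density map."""

    cv: float
    min_density: float
    max_density: float
    chi_square: float
    dof: int
    p_value: float


def equal_area_partition(n_bands: int = 10, cells_per_band: int = 10) -> EqualAreaPartition:
    """Build the equal-area band/sector partition (default 10 × 10 = 100 cells).

    Band boundaries are equally spaced in cos θ (equal band areas);
    ``cells_per_band`` azimuthal sectors per band then make every cell's
    solid angle exactly 4π / (n_bands · cells_per_band).
    """
    if n_bands < 1:
        raise InvalidArgumentError("need at least one band")
    if cells_per_band < 1:
        raise InvalidArgumentError("need at least one sector per band")
    edges = np.linspace(-1.0, 1.0, n_bands + 1)
    return EqualAreaPartition(cos_edges=edges, sectors=np.full(n_bands, cells_per_band))


def residence_density(trace: GravityTrace, partition: EqualAreaPartition) -> DensityMap:
    """Residence-time density of a gravity trace over the partition.

    Each sample carries a trapezoidal time weight (half of its two adjacent
    intervals), so the per-cell residence times sum exactly to the trace
    duration and non-uniform time steps are handled.
    """
    if len(trace) == 0:
        raise EmptyTraceError("cannot bin an empty trace")
    if len(trace) == 1 or trace.duration == 0:
        weights = np.ones(len(trace))
        total = float(weights.sum())
    else:
        dt = np.diff(trace.t)
        weights = np.zeros(len(trace))
        weights[:-1] += dt / 2.0
        weights[1:] += dt / 2.0
        total = trace.duration
    idx = partition.assign(trace.u)
    residence = np.bincount(idx, weights=weights, minlength=partition.n_cells)
    return DensityMap(partition=partition, residence=residence, total_time=total)


def density_from_directions(
    directions: np.ndarray, partition: EqualAreaPartition
) -> DensityMap:
    """Density map of i.i.d. direction draws (equal weight per draw)."""
    u = np.asarray(directions, dtype=float)
    if u.ndim != 2 or u.shape[1] != 3 or u.shape[0] == 0:
        raise InvalidArgumentError("directions must be a non-empty (n, 3) array")
    idx = partition.assign(u)
    residence = np.bincount(idx, minlength=partition.n_cells).astype(float)
    return DensityMap(partition=partition, residence=residence, total_time=float(u.shape[0]))


def _axial_cdf_antiderivative(e: float, z: np.ndarray) -> np.ndarray:
    """Antiderivative of sqrt(1 - e² z²): closed form of the band mass."""
    z = np.asarray(z, dtype=float)
    if e == 0.0:
        return z
    return 0.5 * (z * np.sqrt(1.0 - (e * z) ** 2) + np.arcsin(e * z) / e)


def expected_spheroid_density(
    spec: SpheroidSpec, partition: EqualAreaPartition
) -> DensityMap:
    """Analytic residence density of the spheroid target law over the partition.

    Integrates the same axial density the sampler draws from
    (∝ sqrt(1 - e² z²)), mapped through the focus→surface direction, so the
    sampler's empirical map must converge to this one. The partition is
    polar about the z axis, so the spheroid's symmetry axis must be ±z.
    """
    axis_z = spec.symmetry_axis[2]
    if abs(abs(axis_z) - 1.0) > 1e-9:
        raise InvalidArgumentError(
            "analytic density requires the symmetry axis aligned with ±z"
        )
    sign = 1.0 if axis_z > 0 else -1.0
    e = spec.eccentricity
    norm = _axial_cdf_antiderivative(e, 1.0) - _axial_cdf_antiderivative(e, -1.0)
    masses = np.empty(partition.n_cells)
    flat = 0
    for i in range(partition.n_bands):
        c_lo, c_hi = partition.cos_edges[i], partition.cos_edges[i + 1]
        # axial direction component a = u · axis for u in this band
        a_lo, a_hi = sorted((sign * c_lo, sign * c_hi))
        # invert a(z) = (e - z)/(1 - e z): a decreasing in z
        z_hi = (e - a_lo) / (1.0 - e * a_lo)
        z_lo = (e - a_hi) / (1.0 - e * a_hi)
        band_mass = (
            _axial_cdf_antiderivative(e, z_hi) - _axial_cdf_antiderivative(e, z_lo)
        ) / norm
        k = partition.sectors[i]
        masses[flat : flat + k] = band_mass / k  # azimuth is uniform
        flat += k
    return DensityMap(partition=partition, residence=masses, total_time=1.0)


def uniformity_metrics(dmap: DensityMap) -> UniformityMetrics:
    """Coefficient of variation, extremes and chi-square-vs-uniform of a map.

    Cells have equal area, so the CV is the plain standard deviation of the
    density values (their mean is 1 by construction). The chi-square
    statistic compares per-cell residence against the equal expectation; for
    time-weighted maps it is descriptive, for count maps it is the Pearson
    goodness-of-fit statistic.
    """
    d = dmap.density
    n = dmap.partition.n_cells
    expected = dmap.total_time / n
    chi2 = float(np.sum((dmap.residence - expected) ** 2 / expected))
    dof = n - 1
    return UniformityMetrics(
        cv=float(np.std(d)),
        min_density=float(np.min(d)),
        max_density=float(np.max(d)),
        chi_square=chi2,
        dof=dof,
        p_value=float(stats.chi2.sf(chi2, dof)),
    )


def chi_square_gof(counts: np.ndarray, expected_probs: np.ndarray) -> tuple[float, float]:
    """Pearson goodness-of-fit of observed counts against expected cell masses."""
    counts = np.asarray(counts, dtype=float)
    expected = np.asarray(expected_probs, dtype=float) * counts.sum()
    stat, p = stats.chisquare(counts, expected)
    return float(stat), float(p)
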