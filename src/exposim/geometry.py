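"""Study-area geometry and the distance-decay spatial correlation model.

The simulated study area is a 50 km x 50 km square divided into a 10 x 10
lattice of 5 km x 5 km grid-squares, grouped into 4 regions of 5 x 5 grids
(25 km x 25 km blocks). Between-grid correlation of daily pollutant
concentrations decays linearly with an *effective* distance D: for two
distinct grids D = d + 2.13/d where d is the centre-to-centre distance in
km (an approximation to the mean distance between two uniform points, one
in each square), and within a single 5 km square D = 2.6 km (the mean
distance between two uniform points in the square). Multiplying the
resulting correlation matrix by the observed monitor within-site variance
yields the spatial covariance matrix Omega used to draw daily fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "URBAN_OZONE_CORRELATION",
    "UNIT_SQUARE_MEAN_DISTANCE",
    "GridLayout",
    "DistanceModel",
    "CorrelationModel",
    "SpatialCovariance",
    "effective_distance",
    "correlation_at_distance",
    "build_covariance",
    "mean_point_distance_oracle",
]

#: Mean distance between two independent uniform points in the unit square
#: (closed form: (2 + sqrt(2) + 5 asinh(1)) / 15).
UNIT_SQUARE_MEAN_DISTANCE = (2.0 + np.sqrt(2.0) + 5.0 * np.arcsinh(1.0)) / 15.0


@dataclass(frozen=True)
class GridLayout:
    """Square lattice of grid-squares grouped into rectangular regions."""

    grid_side_km: float = 5.0
    n_grid_rows: int = 10
    n_grid_cols: int = 10
    region_rows: int = 2
    region_cols: int = 2

    def __post_init__(self) -> None:
        if self.n_grid_rows % self.region_rows or self.n_grid_cols % self.region_cols:
            raise ValueError("region tiling must divide the grid lattice evenly")

    @property
    def n_grids(self) -> int:
        return self.n_grid_rows * self.n_grid_cols

    @property
    def n_regions(self) -> int:
        return self.region_rows * self.region_cols

    @property
    def grids_per_region(self) -> int:
        return self.n_grids // self.n_regions

    @property
    def grid_centres(self) -> np.ndarray:
        """(n_grids, 2) array of (easting_km, northing_km) grid centres."""
        half = self.grid_side_km / 2.0
        cols = half + self.grid_side_km * np.arange(self.n_grid_cols)
        rows = half + self.grid_side_km * np.arange(self.n_grid_rows)
        ee, nn = np.meshgrid(cols, rows)
        return np.column_stack([ee.ravel(), nn.ravel()])

    @property
    def region_of_grid(self) -> np.ndarray:
        """(n_grids,) array mapping grid index -> region index (row-major)."""
        rows_per = self.n_grid_rows // self.region_rows
        cols_per = self.n_grid_cols // self.region_cols
        idx = np.arange(self.n_grids)
        r, c = divmod(idx, self.n_grid_cols)
        return (r // rows_per) * self.region_cols + (c // cols_per)

    def grids_in_region(self, region: int) -> np.ndarray:
        return np.flatnonzero(self.region_of_grid == region)


@dataclass(frozen=True)
class DistanceModel:
    """Effective-distance model D = d + between_adjustment/d (D_within for d=0)."""

    within_square_D_km: float = 2.6
    between_adjustment_km2: float = 2.13

    def __post_init__(self) -> None:
        if self.within_square_D_km <= 0 or self.between_adjustment_km2 <= 0:
            raise ValueError("distance-model constants must be positive")


@dataclass(frozen=True)
class CorrelationModel:
    """Linear distance-decay correlation E(P) = intercept + slope_per_km * D."""

    intercept: float
    slope_per_km: float

    def __post_init__(self) -> None:
        if not 0.0 < self.intercept <= 1.0:
            raise ValueError("intercept must lie in (0, 1]")


#: Fitted urban-background ozone decay: E(P) = 0.93031 - 0.00080 D.
URBAN_OZONE_CORRELATION = CorrelationModel(intercept=0.93031, slope_per_km=-0.00080)


@dataclass
class SpatialCovariance:
    """Between-grid correlation and covariance matrices for daily fields."""

    correlation_matrix: np.ndarray
    covariance_matrix: np.ndarray
    within_grid_true_variance: float
    monitor_within_variance: float
    pd_repaired: bool = False
    _factor: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_grids(self) -> int:
        return self.covariance_matrix.shape[0]

    @property
    def factor(self) -> np.ndarray:
        """Symmetric factor L with L @ L.T = Omega, computed once and cached.

        Uses an eigendecomposition rather than Cholesky so that exactly
        singular (PSD) matrices - e.g. the perfect-correlation limit -
        remain sampleable.
        """
        if self._factor is None:
            vals, vecs = np.linalg.eigh(self.covariance_matrix)
            vals = np.clip(vals, 0.0, None)
            self._factor = vecs * np.sqrt(vals)
        return self._factor

    def to_csv(self, path, which: str = "covariance") -> None:
        """Export the correlation or covariance matrix as a labelled CSV."""
        import pandas as pd

        mat = self.covariance_matrix if which == "covariance" else self.correlation_matrix
        labels = [f"grid_{i}" for i in range(self.n_grids)]
        pd.DataFrame(mat, index=labels, columns=labels).to_csv(path)


def effective_distance(grid_a: int, grid_b: int, layout: GridLayout, dm: DistanceModel) -> float:
    """Effective distance D (km) between two grid-squares of ``layout``.

    Same grid: the within-square constant. Distinct grids: d + adj/d with d
    the Euclidean centre-to-centre distance (requires d >= 1 km; the lattice
    guarantees d >= grid_side_km for distinct grids).
    """
    n = layout.n_grids
    for g in (grid_a, grid_b):
        if not 0 <= g < n:
            raise IndexError(f"grid index {g} outside 0..{n - 1}")
    if grid_a == grid_b:
        return dm.within_square_D_km
    centres = layout.grid_centres
    d = float(np.linalg.norm(centres[grid_a] - centres[grid_b]))
    if d < 1.0:
        raise ValueError("between-grid adjustment d + adj/d is unreliable below 1 km")
    return d + dm.between_adjustment_km2 / d


def correlation_at_distance(D, cm: CorrelationModel):
    """Evaluate the linear decay model at effective distance D (km).

    Values are clamped into [-1, 1]; clamping triggers a warning because it
    means the linear model is being extrapolated outside its valid range.
    Accepts scalars or arrays.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("distance must be non-negative")
    rho = cm.intercept + cm.slope_per_km * D
    if np.any(rho > 1.0) or np.any(rho < -1.0):
        warnings.warn(
            "distance-decay correlation clamped into [-1, 1]; the linear "
            "model is extrapolated beyond its valid range",
            stacklevel=2,
        )
        rho = np.clip(rho, -1.0, 1.0)
    return float(rho) if rho.ndim == 0 else rho


def _effective_distance_matrix(layout: GridLayout, dm: DistanceModel) -> np.ndarray:
    centres = layout.grid_centres
    diff = centres[:, None, :] - centres[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    off = ~np.eye(layout.n_grids, dtype=bool)
    if np.any(d[off] < 1.0):
        raise ValueError("distinct grid centres closer than 1 km are unsupported")
    D = np.full_like(d, dm.within_square_D_km)
    D[off] = d[off] + dm.between_adjustment_km2 / d[off]
    return D


def build_covariance(
    layout: GridLayout,
    dm: DistanceModel,
    cm: CorrelationModel,
    monitor_within_variance: float,
    repair_tolerance: float = 1e-3,
) -> SpatialCovariance:
    """Assemble the spatial covariance Omega = rho(D) * monitor variance.

    Every element, including the diagonal, is the decay correlation at the
    effective distance times the observed monitor within-site variance; the
    common diagonal value is the implied "true" within-grid variance (the
    monitor variance with instrument/location error removed).

    A linear-in-distance correlation matrix is not automatically positive
    semi-definite. If Omega has negative eigenvalues they are clipped to a
    small positive floor and the matrix reassembled with its diagonal
    re-equalised; a repair that moves any correlation by more than
    ``repair_tolerance`` raises, since the sampled process would then no
    longer follow the stated model.
    """
    if monitor_within_variance <= 0:
        raise ValueError("monitor_within_variance must be positive")
    D = _effective_distance_matrix(layout, dm)
    corr = np.asarray(correlation_at_distance(D, cm))
    omega = corr * monitor_within_variance
    sigma_w2 = float(omega[0, 0])

    vals = np.linalg.eigvalsh(omega)
    repaired = False
    tol = 1e-10 * float(vals[-1])
    if vals[0] < -tol:
        repaired = True
        vals, vecs = np.linalg.eigh(omega)
        floor = max(1e-12 * float(vals[-1]), 0.0)
        vals = np.clip(vals, floor, None)
        fixed = (vecs * vals) @ vecs.T
        fixed = (fixed + fixed.T) / 2.0
        # re-equalise the diagonal back to sigma_w2 (rescale to correlation form)
        d = np.sqrt(np.diag(fixed))
        fixed = fixed / np.outer(d, d) * sigma_w2
        shift = np.max(np.abs(fixed - omega)) / monitor_within_variance
        if shift > repair_tolerance:
            raise ValueError(
                f"positive-definiteness repair moved a correlation by {shift:.2e} "
                f"(> {repair_tolerance}); the correlation model is invalid for "
                "this geometry"
            )
        omega = fixed
        corr = omega / monitor_within_variance
    elif vals[0] < 0.0:
        # negligible negative eigenvalues: flag as repaired, factor() clips them
        repaired = True

    return SpatialCovariance(
        correlation_matrix=corr,
        covariance_matrix=omega,
        within_grid_true_variance=sigma_w2,
        monitor_within_variance=monitor_within_variance,
        pd_repaired=repaired,
    )


def mean_point_distance_oracle(
    square_side_km: float,
    offset_km: float = 0.0,
    n_draws: int = 1_000_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo mean distance between uniform points in two offset squares.

    Draws one point uniformly in each of two axis-aligned squares of side
    ``square_side_km`` whose centres are ``offset_km`` apart along one axis
    (offset 0 = the same square). This is the simulation behind the
    within-square constant D ~= 2.6 km for 5 km squares and validates the
    d + 2.13/d between-square approximation.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if square_side_km < 0 or offset_km < 0:
        raise ValueError("lengths must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = rng.uniform(0.0, square_side_km, size=(n_draws, 2))
    q = rng.uniform(0.0, square_side_km, size=(n_draws, 2))
    q[:, 0] += offset_km
    return float(np.mean(np.hypot(*(p - q).T)))
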