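"""Closed-form attenuation predictions and error-variance decomposition.

For additive error with grid fixed effects absorbing constant offsets, the
large-sample slope of regressing on a surrogate W in place of the truth X*
is beta * cov(X*, W)/var(W). Two surrogates admit closed forms:

* grid-specific CTM data: attenuation factor cov(X*, Z)/var(Z);
* a single monitor per region assigned to all n grids: averaging the slope
  over the n target grids and a uniformly placed monitor grid m gives

      (sigma_w^2 + (n-1) rho_bar V) / (n (sigma_w^2 + sigma_err^2))

  where V is the monitor within-site variance scaling the covariance
  matrix, sigma_w^2 its diagonal, rho_bar the mean distance-decay
  correlation over ordered within-region grid pairs, and sigma_err the
  instrument/location error SD.

The model-minus-truth error variance splits exactly into a classical-like
component CC = var(Z) - cov(Z, X*) (noise in Z beyond its shared signal
with X*, which attenuates) and a Berkson-like component
BC = var(X*) - cov(Z, X*) (smoothness of Z relative to X*, which mainly
costs power): CC + BC = var(Z - X*).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import (
    CorrelationModel,
    DistanceModel,
    GridLayout,
    correlation_at_distance,
    effective_distance,
)

__all__ = [
    "TheoryInputs",
    "DecompositionResult",
    "mean_within_region_correlation",
    "attenuation_factor_ctm",
    "attenuation_factor_single_monitor",
    "decompose_error",
]


@dataclass(frozen=True)
class TheoryInputs:
    """Variance/covariance inputs to the closed-form predictions."""

    cov_xz: float
    var_z: float
    var_xstar: float
    monitor_within_variance: float = np.nan
    sigma_err: float = np.nan
    rho_bar: float = np.nan
    n_grids_per_region: int = 25
    true_beta: float = np.nan

    def __post_init__(self) -> None:
        if self.var_z <= 0 or self.var_xstar <= 0:
            raise ValueError("variances must be positive")


@dataclass(frozen=True)
class DecompositionResult:
    """Classical-like / Berkson-like split of var(Z - X*)."""

    CC: float
    BC: float

    @property
    def total(self) -> float:
        return self.CC + self.BC

    @property
    def cc_share(self) -> float:
        return self.CC / self.total

    @property
    def bc_share(self) -> float:
        return self.BC / self.total


def mean_within_region_correlation(
    layout: GridLayout, dm: DistanceModel, cm: CorrelationModel, region: int = 0
) -> float:
    """Mean decay correlation over ordered pairs of distinct grids in a region.

    Under the homogeneous design every region gives the same value, so the
    first region is used by default.
    """
    grids = layout.grids_in_region(region)
    vals = [
        correlation_at_distance(effective_distance(i, m, layout, dm), cm)
        for i in grids
        for m in grids
        if i != m
    ]
    return float(np.mean(vals))


def attenuation_factor_ctm(inputs: TheoryInputs) -> float:
    """Large-sample slope factor cov(X*, Z)/var(Z) for grid-specific CTM data.

    Equals the reliability ratio var(X*)/var(Z) when the error is purely
    classical (cov = var(X*)); equals 1 when cov = var(Z) (pure Berkson).
    A factor above 1 (cov > var(Z)) means inflation, not attenuation, and
    is flagged with a warning.
    """
    factor = inputs.cov_xz / inputs.var_z
    if factor > 1.0:
        warnings.warn(
            "cov(X*, Z) exceeds var(Z): the surrogate inflates rather than "
            "attenuates the slope",
            stacklevel=2,
        )
    return factor


def attenuation_factor_single_monitor(inputs: TheoryInputs) -> float:
    """Placement-averaged slope factor for the one-monitor-per-region design.

    Every grid i of an n-grid region receives the monitor series
    X_m = X*_m + E_m from a uniformly chosen grid m. The slope of grid i's
    regression component is cov(X*_i, X_m)/var(X_m); averaging over i and m
    gives the closed form documented in the module docstring. Requires
    monitor_within_variance, sigma_err and rho_bar to be set.
    """
    n = inputs.n_grids_per_region
    if n < 2:
        raise ValueError("need at least 2 grids per region")
    for name in ("monitor_within_variance", "sigma_err", "rho_bar"):
        if not np.isfinite(getattr(inputs, name)):
            raise ValueError(f"{name} must be set for the single-monitor prediction")
    if not 0.0 < inputs.rho_bar <= 1.0:
        raise ValueError("rho_bar must lie in (0, 1]")
    num = inputs.var_xstar + (n - 1) * inputs.rho_bar * inputs.monitor_within_variance
    den = n * (inputs.var_xstar + inputs.sigma_err**2)
    return num / den


def decompose_error(inputs: TheoryInputs) -> DecompositionResult:
    """CC = var(Z) - cov(Z, X*); BC = var(X*) - cov(Z, X*); CC + BC = var(Z - X*)."""
    return DecompositionResult(
        CC=inputs.var_z - inputs.cov_xz,
        BC=inputs.var_xstar - inputs.cov_xz,
    )
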