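"""Surrogate exposure panels: monitor error, CTM emulation, regional averages.

Monitor series add pure classical error X = X* + N(0, sigma_err^2)
(instrument imprecision plus monitor-location error). Chemistry-transport
model (CTM) output is emulated from the truth by the linear projection

    Z = c_i + mu_i + lambda (X* - mu_i) + Delta,
    lambda = cov(X*, Z) / var(X*),   Delta ~ N(0, var(Z) - lambda^2 var(X*))

which reproduces a target mean bias c_i, variance var(Z) and covariance
cov(X*, Z), mixing classical-like and Berkson-like error. Regional-average
surrogates assign the mean of l sampled monitor series to every grid of a
25 km region. Proportional-error analyses back-transform log-scale panels
with exp(.) before averaging or regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GridLayout
from .truth import TrueField

__all__ = [
    "MonitorErrorSpec",
    "CtmSpec",
    "SurrogatePanel",
    "add_classical_error",
    "emulate_ctm_series",
    "sample_monitor_grids",
    "regional_average",
    "back_transform",
]


@dataclass(frozen=True)
class MonitorErrorSpec:
    """SD of the additive instrument/location error on the simulation scale."""

    sigma_err: float

    def __post_init__(self) -> None:
        if self.sigma_err < 0:
            raise ValueError("sigma_err must be >= 0")


@dataclass(frozen=True)
class CtmSpec:
    """Targets for the emulated CTM channel.

    cov_xz, var_z and var_xstar pin the projection slope and residual
    variance; bias_c is the common mean offset c (CTM minus truth); in
    proportional mode the grid-specific offsets are drawn as
    c_i = c + N(0, sigma_diff^2) once per grid per replicate.
    """

    cov_xz: float
    var_z: float
    var_xstar: float
    bias_c: float = 0.0
    sigma_diff: float = 0.0

    def __post_init__(self) -> None:
        if self.var_z <= 0 or self.var_xstar <= 0:
            raise ValueError("variances must be positive")
        if self.residual_variance < -1e-12 * self.var_z:
            raise ValueError(
                "negative residual variance: require "
                "var_z >= cov_xz^2 / var_xstar (implied corr(X*, Z) <= 1)"
            )
        if self.sigma_diff < 0:
            raise ValueError("sigma_diff must be >= 0")

    @property
    def slope(self) -> float:
        """Projection slope lambda = cov(X*, Z) / var(X*)."""
        return self.cov_xz / self.var_xstar

    @property
    def residual_variance(self) -> float:
        """var(Z) - cov(X*, Z)^2 / var(X*), the variance of Delta."""
        return self.var_z - self.cov_xz**2 / self.var_xstar

    @property
    def implied_correlation(self) -> float:
        return self.cov_xz / np.sqrt(self.var_xstar * self.var_z)


@dataclass
class SurrogatePanel:
    """Exposure series as fed to the regression, with provenance.

    provenance is one of ``true_field``, ``monitor_grid``,
    ``regional_average(l)`` or ``ctm``; ``scale`` records whether the panel
    is still on the simulation (possibly log) scale or has been
    back-transformed with exp(.).
    """

    values: np.ndarray                       # (n_days, n_grids)
    provenance: str
    monitor_grids_used: list[np.ndarray] | None = None
    scale: str = "simulation_scale"          # | "back_transformed"

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("surrogate panel contains non-finite values")
        if self.scale not in ("simulation_scale", "back_transformed"):
            raise ValueError(f"unknown scale {self.scale!r}")

    def to_long_csv(self, path) -> None:
        import pandas as pd

        n_grids = self.values.shape[1]
        days, grids = np.divmod(np.arange(self.values.size), n_grids)
        pd.DataFrame(
            {
                "day": days + 1,
                "grid": grids,
                "value": self.values.ravel(),
                "provenance": self.provenance,
            }
        ).to_csv(path, index=False)


def add_classical_error(
    field: TrueField, spec: MonitorErrorSpec, rng: np.random.Generator
) -> SurrogatePanel:
    """Monitor panel X = X* + E with i.i.d. E ~ N(0, sigma_err^2)."""
    noise = spec.sigma_err * rng.standard_normal(field.values.shape)
    return SurrogatePanel(values=field.values + noise, provenance="monitor_grid")


def emulate_ctm_series(
    field: TrueField,
    spec: CtmSpec,
    mode: str = "additive",
    rng: np.random.Generator | None = None,
) -> SurrogatePanel:
    """Emulate a CTM exposure panel from the true field.

    Additive mode uses a common bias c for every grid (grid fixed effects
    absorb it in the regression). Proportional mode draws grid-specific
    biases c_i = c + N(0, sigma_diff^2), held constant over days, and
    back-transforms the panel with exp(.) since the analysis is on the
    natural scale.
    """
    if mode not in ("additive", "proportional"):
        raise ValueError("mode must be 'additive' or 'proportional'")
    if rng is None:
        raise ValueError("an rng is required")
    n_days, n_grids = field.values.shape
    if mode == "additive":
        c_i = np.full(n_grids, spec.bias_c)
    else:
        c_i = spec.bias_c + spec.sigma_diff * rng.standard_normal(n_grids)
    resid_sd = np.sqrt(max(spec.residual_variance, 0.0))
    delta = resid_sd * rng.standard_normal((n_days, n_grids))
    centred = field.values - field.grid_means
    z = c_i + field.grid_means + spec.slope * centred + delta
    panel = SurrogatePanel(values=z, provenance="ctm")
    if mode == "proportional":
        panel = back_transform(panel)
    return panel


def sample_monitor_grids(
    layout: GridLayout, l: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Sample l monitor grids uniformly without replacement from each region."""
    if not 1 <= l <= layout.grids_per_region:
        raise ValueError(f"l must be in 1..{layout.grids_per_region}")
    return [
        np.sort(rng.choice(layout.grids_in_region(j), size=l, replace=False))
        for j in range(layout.n_regions)
    ]


def regional_average(
    panel: SurrogatePanel, selection: list[np.ndarray], layout: GridLayout
) -> SurrogatePanel:
    """Replace each region's columns by the mean of its selected monitor series.

    The daily mean W_j = (1/l) sum of the selected monitor series is
    assigned to all grids of region j, so within a region every column of
    the result is identical. For proportional-error analyses the input
    panel must already be back-transformed (averaging happens on the
    natural scale).
    """
    if panel.provenance != "monitor_grid":
        raise ValueError("regional averages are built from monitor panels")
    if len(selection) != layout.n_regions or any(len(s) == 0 for s in selection):
        raise ValueError("need a non-empty monitor selection for every region")
    out = np.empty_like(panel.values)
    for j, sel in enumerate(selection):
        w = panel.values[:, sel].mean(axis=1)
        out[:, layout.grids_in_region(j)] = w[:, None]
    l = len(selection[0])
    return SurrogatePanel(
        values=out,
        provenance=f"regional_average({l})",
        monitor_grids_used=[np.asarray(s) for s in selection],
        scale=panel.scale,
    )


def back_transform(panel: SurrogatePanel) -> SurrogatePanel:
    """Elementwise exp(.), log scale -> natural scale; refuses to run twice."""
    if panel.scale != "simulation_scale":
        raise ValueError("panel is already back-transformed")
    return SurrogatePanel(
        values=np.exp(panel.values),
        provenance=panel.provenance,
        monitor_grids_used=panel.monitor_grids_used,
        scale="back_transformed",
    )
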