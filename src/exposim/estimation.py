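"""Poisson regression with grid fixed effects, and replicate summaries.

The health model is log E(Y_it) = a_i + beta * w_it with one intercept per
grid (no global intercept) and a single exposure slope. Because the
intercepts have the closed-form profile solution

    a_i(beta) = log( sum_t y_it / sum_t exp(beta * w_it) ),

the slope is found by Newton iteration on the one-dimensional profile
likelihood; the Wald standard error comes from the beta block of the full
model's observed information (equal to the profile information for this
model), so the result is identical to a dummy-variable GLM fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import SurrogatePanel
from .truth import MortalityPanel

__all__ = [
    "PoissonFixedEffects",
    "FitResult",
    "ScenarioSummary",
    "fit_poisson_fixed_effects",
    "wald_interval",
    "summarize_replicates",
]


@dataclass
class FitResult:
    """Slope estimate and Wald SE from one fixed-effects Poisson fit."""

    beta_hat: float
    se_beta: float
    converged: bool
    n_iterations: int
    n_grids_dropped: int = 0

    def summary(self) -> str:
        lines = [
            "Poisson fixed-effects regression",
            "================================",
            f"  beta_hat     {self.beta_hat: .7g}",
            f"  se(beta)     {self.se_beta: .7g}",
            f"  z            {self.beta_hat / self.se_beta: .4g}",
            f"  converged    {self.converged} ({self.n_iterations} iterations)",
        ]
        if self.n_grids_dropped:
            lines.append(f"  grids dropped (all-zero counts): {self.n_grids_dropped}")
        return "\n".join(lines)


class PoissonFixedEffects:
    """Model object for the grid-fixed-effects Poisson regression.

    Parameters
    ----------
    counts : MortalityPanel or (n_days, n_grids) integer array
    exposure : SurrogatePanel or (n_days, n_grids) float array

    Grids whose counts are all zero have intercept -inf; they carry no
    information about beta and are dropped with a warning count recorded on
    the results object.
    """

    def __init__(self, counts, exposure):
        y = counts.counts if isinstance(counts, MortalityPanel) else np.asarray(counts)
        w = exposure.values if isinstance(exposure, SurrogatePanel) else np.asarray(exposure)
        if y.shape != w.shape:
            raise ValueError(f"counts {y.shape} and exposure {w.shape} differ in shape")
        if not np.isfinite(w).all():
            raise ValueError("exposure contains missing/non-finite values")
        self._all_zero = y.sum(axis=0) == 0
        self.n_grids_dropped = int(self._all_zero.sum())
        keep = ~self._all_zero
        self.y = np.asarray(y, dtype=float)[:, keep]
        self.w = np.asarray(w, dtype=float)[:, keep]
        if self.y.shape[1] == 0:
            raise ValueError("all grids have zero counts; nothing to fit")
        # slope identified only through within-grid exposure variation
        if float(self.w.var(axis=0).sum()) == 0.0:
            raise ValueError(
                "exposure is constant within every grid: the slope is "
                "collinear with the grid fixed effects"
            )

    def _score_info(self, beta: float) -> tuple[float, float]:
        # per-grid softmax weights p_it = exp(b w) / sum_t exp(b w),
        # stabilised by subtracting the per-grid max
        bw = beta * self.w
        bw -= bw.max(axis=0)
        e = np.exp(bw)
        denom = e.sum(axis=0)
        p = e / denom
        ysum = self.y.sum(axis=0)
        m1 = (p * self.w).sum(axis=0)
        m2 = (p * self.w**2).sum(axis=0)
        score = float((self.y * self.w).sum() - (ysum * m1).sum())
        info = float((ysum * (m2 - m1**2)).sum())
        return score, info

    def fit(self, start: float = 0.0, tol: float = 1e-10, max_iter: int = 50) -> FitResult:
        """Newton iteration on the profile likelihood for beta."""
        beta = float(start)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            score, info = self._score_info(beta)
            if info <= 0:
                break
            step = score / info
            # dampen absurd first steps from poor scaling
            if abs(step) > 10 * (1 + abs(beta)):
                step = np.sign(step) * 10 * (1 + abs(beta))
            beta += step
            if abs(step) <= tol * (1 + abs(beta)):
                converged = True
                break
        _, info = self._score_info(beta)
        se = float(1.0 / np.sqrt(info)) if info > 0 else np.nan
        return FitResult(
            beta_hat=beta,
            se_beta=se,
            converged=converged and np.isfinite(se),
            n_iterations=it,
            n_grids_dropped=self.n_grids_dropped,
        )


def fit_poisson_fixed_effects(counts, exposure) -> FitResult:
    """Convenience wrapper: build the model and fit it."""
    return PoissonFixedEffects(counts, exposure).fit()


def wald_interval(fit: FitResult, level: float = 0.95) -> tuple[float, float]:
    """Two-sided Wald confidence interval beta_hat +/- z * SE."""
    if not fit.converged:
        raise ValueError("confidence interval requested for a non-converged fit")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return fit.beta_hat - z * fit.se_beta, fit.beta_hat + z * fit.se_beta


@dataclass
class ScenarioSummary:
    """Across-replicate summary of one exposure scenario."""

    scenario: str
    n_reps: int
    mean_beta_hat: float
    mean_se: float
    coverage_pct: float
    power_pct: float
    mc_se_of_mean_beta: float
    sd_beta_hat: float
    n_nonconverged: int = 0


def summarize_replicates(
    fits: list[FitResult], true_beta: float, scenario: str = ""
) -> ScenarioSummary:
    """Mean estimate/SE, 95% coverage and 5%-level power across replicates.

    Coverage is the percentage of replicates whose 95% Wald interval
    contains ``true_beta``; power is the percentage with two-sided Wald
    p < 0.05. Non-converged fits are excluded and counted.
    """
    good = [f for f in fits if f.converged]
    n_bad = len(fits) - len(good)
    if not good:
        raise ValueError("no converged fits to summarize")
    beta = np.array([f.beta_hat for f in good])
    se = np.array([f.se_beta for f in good])
    z = stats.norm.ppf(0.975)
    covered = np.abs(beta - true_beta) <= z * se
    significant = np.abs(beta / se) > z
    return ScenarioSummary(
        scenario=scenario,
        n_reps=len(good),
        mean_beta_hat=float(beta.mean()),
        mean_se=float(se.mean()),
        coverage_pct=float(100.0 * covered.mean()),
        power_pct=float(100.0 * significant.mean()),
        mc_se_of_mean_beta=float(beta.std(ddof=1) / np.sqrt(len(good)))
        if len(good) > 1
        else np.nan,
        sd_beta_hat=float(beta.std(ddof=1)) if len(good) > 1 else np.nan,
        n_nonconverged=n_bad,
    )
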