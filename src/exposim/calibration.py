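"""Calibration of simulation parameters from paired monitor/CTM site data.

Given daily monitor and chemistry-transport-model (CTM) series at a set of
monitoring sites, this module computes the summary statistics that feed
the simulation (site-mean and within-site variability by site type, the
monitor-CTM covariance/correlation and mean bias), fits the linear decay
of between-site correlation with distance, and derives the implied
instrument/location error SD from the within-square correlation: if the
correlation extrapolated to the mean within-square distance is read as the
reliability ratio var(X*)/var(X), then

    sigma_err = sqrt( (1 - rho(D_within)) * monitor within-site variance ).

A seeded synthetic fixture generator emulates a national monitoring
network (sites scattered over an area, distance-decaying between-site
correlation, instrument noise, a linearly coupled biased CTM channel,
optional missingness) so the whole estimation chain can be exercised
without observational data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CtmSpec
from .geometry import CorrelationModel, DistanceModel, correlation_at_distance

__all__ = [
    "SitePairSeries",
    "SiteTypeSummary",
    "CalibrationSummary",
    "DistanceDecayFit",
    "summarize_sites",
    "pairwise_standardized_correlations",
    "fit_distance_decay",
    "estimate_instrument_error",
    "generate_site_fixtures",
    "read_sites_csv",
    "write_sites_csv",
]

SITE_CSV_COLUMNS = [
    "site_id", "site_type", "easting_km", "northing_km",
    "date", "monitor_value", "ctm_value",
]


@dataclass
class SitePairSeries:
    """Paired daily monitor/CTM series at one monitoring site.

    ``records`` is a DataFrame with columns date, monitor_value, ctm_value;
    either value may be missing (NaN). Dates must be unique.
    """

    site_id: str
    site_type: str                  # "urban" | "rural"
    easting_km: float
    northing_km: float
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if self.site_type not in ("urban", "rural"):
            raise ValueError("site_type must be 'urban' or 'rural'")
        if self.records["date"].duplicated().any():
            raise ValueError(f"site {self.site_id}: duplicate dates")

    @property
    def paired(self) -> pd.DataFrame:
        """Records where both channels are present."""
        return self.records.dropna(subset=["monitor_value", "ctm_value"])

    @property
    def n_paired_days(self) -> int:
        return len(self.paired)


@dataclass
class SiteTypeSummary:
    """Cross-site averages for one site type (urban or rural)."""

    site_type: str
    n_sites: int
    total_days: int
    mean_of_site_means_monitor: float
    sd_of_site_means_monitor: float
    mean_of_site_means_ctm: float
    sd_of_site_means_ctm: float
    mean_within_sd_monitor: float
    sd_within_sd_monitor: float
    mean_within_sd_ctm: float
    sd_within_sd_ctm: float
    mean_covariance: float
    mean_correlation: float
    mean_corr_monitor_with_diff: float
    mean_corr_ctm_with_diff: float
    mean_of_mean_diff: float
    sd_of_mean_diff: float


@dataclass
class CalibrationSummary:
    """Per-site-type summaries plus the count of excluded (short) sites."""

    by_type: dict[str, SiteTypeSummary]
    n_sites_excluded: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.by_type.values()])


def _site_stats(site: SitePairSeries) -> dict:
    p = site.paired
    mon = p["monitor_value"].to_numpy()
    ctm = p["ctm_value"].to_numpy()
    diff = ctm - mon
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.nan
        if mon.std(ddof=1) > 0 and ctm.std(ddof=1) > 0:
            corr = float(np.corrcoef(mon, ctm)[0, 1])
        corr_mon_diff = corr_ctm_diff = np.nan
        if diff.std(ddof=1) > 0:
            if mon.std(ddof=1) > 0:
                corr_mon_diff = float(np.corrcoef(mon, diff)[0, 1])
            if ctm.std(ddof=1) > 0:
                corr_ctm_diff = float(np.corrcoef(ctm, diff)[0, 1])
    return {
        "n_days": len(p),
        "mean_monitor": float(mon.mean()),
        "mean_ctm": float(ctm.mean()),
        "sd_monitor": float(mon.std(ddof=1)),
        "sd_ctm": float(ctm.std(ddof=1)),
        "covariance": float(np.cov(mon, ctm, ddof=1)[0, 1]),
        "correlation": corr,
        "corr_monitor_diff": corr_mon_diff,
        "corr_ctm_diff": corr_ctm_diff,
        "mean_diff": float(diff.mean()),
    }


def summarize_sites(sites: list[SitePairSeries], min_days: int = 364) -> CalibrationSummary:
    """Cross-site summary statistics per site type.

    Sites with fewer than ``min_days`` paired days are excluded (counted).
    Per-site statistics use paired days only; undefined correlations (zero
    variance) are reported missing and skipped in cross-site averages.
    """
    kept = [s for s in sites if s.n_paired_days >= min_days]
    n_excluded = len(sites) - len(kept)
    if n_excluded:
        warnings.warn(
            f"{n_excluded} site(s) excluded with fewer than {min_days} paired days",
            stacklevel=2,
        )
    by_type: dict[str, SiteTypeSummary] = {}
    for stype in ("urban", "rural"):
        group = [s for s in kept if s.site_type == stype]
        if not group:
            warnings.warn(f"no {stype} sites after filtering; stratum omitted", stacklevel=2)
            continue
        stats = pd.DataFrame([_site_stats(s) for s in group])
        sd = lambda col: float(stats[col].std(ddof=1)) if len(group) > 1 else np.nan
        by_type[stype] = SiteTypeSummary(
            site_type=stype,
            n_sites=len(group),
            total_days=int(stats["n_days"].sum()),
            mean_of_site_means_monitor=float(stats["mean_monitor"].mean()),
            sd_of_site_means_monitor=sd("mean_monitor"),
            mean_of_site_means_ctm=float(stats["mean_ctm"].mean()),
            sd_of_site_means_ctm=sd("mean_ctm"),
            mean_within_sd_monitor=float(stats["sd_monitor"].mean()),
            sd_within_sd_monitor=sd("sd_monitor"),
            mean_within_sd_ctm=float(stats["sd_ctm"].mean()),
            sd_within_sd_ctm=sd("sd_ctm"),
            mean_covariance=float(stats["covariance"].mean()),
            mean_correlation=float(stats["correlation"].mean(skipna=True)),
            mean_corr_monitor_with_diff=float(stats["corr_monitor_diff"].mean(skipna=True)),
            mean_corr_ctm_with_diff=float(stats["corr_ctm_diff"].mean(skipna=True)),
            mean_of_mean_diff=float(stats["mean_diff"].mean()),
            sd_of_mean_diff=sd("mean_diff"),
        )
    return CalibrationSummary(by_type=by_type, n_sites_excluded=n_excluded)


def pairwise_standardized_correlations(
    sites: list[SitePairSeries], min_paired: int = 364
) -> pd.DataFrame:
    """Between-site correlations of standardized monitor series vs distance.

    Monitor series are standardized within site (subtract the site mean,
    divide by the site SD, over that site's paired days). For every pair of
    same-type sites with at least ``min_paired`` overlapping days the
    Pearson correlation over the overlap and the Euclidean distance are
    returned (columns: site_a, site_b, site_type, distance_km, pearson_r,
    n_days). Pairs below the threshold are omitted; sites with zero
    within-site SD are skipped with a warning.
    """
    std_series: dict[str, pd.Series] = {}
    usable: list[SitePairSeries] = []
    for s in sites:
        p = s.paired
        mon = p["monitor_value"]
        if len(p) < 2 or mon.std(ddof=1) == 0:
            warnings.warn(f"site {s.site_id}: zero monitor variance, skipped", stacklevel=2)
            continue
        std_series[s.site_id] = pd.Series(
            ((mon - mon.mean()) / mon.std(ddof=1)).to_numpy(), index=p["date"].to_numpy()
        )
        usable.append(s)

    rows = []
    for i, a in enumerate(usable):
        for b in usable[i + 1:]:
            if a.site_type != b.site_type:
                continue
            sa, sb = std_series[a.site_id], std_series[b.site_id]
            common = sa.index.intersection(sb.index)
            if len(common) < min_paired:
                continue
            r = float(np.corrcoef(sa.loc[common], sb.loc[common])[0, 1])
            dist = float(np.hypot(a.easting_km - b.easting_km, a.northing_km - b.northing_km))
            rows.append(
                {
                    "site_a": a.site_id,
                    "site_b": b.site_id,
                    "site_type": a.site_type,
                    "distance_km": dist,
                    "pearson_r": r,
                    "n_days": int(len(common)),
                }
            )
    return pd.DataFrame(rows, columns=["site_a", "site_b", "site_type",
                                       "distance_km", "pearson_r", "n_days"])


@dataclass
class DistanceDecayFit:
    """OLS fit of between-site correlation on distance."""

    intercept: float
    slope_per_km: float
    r_squared: float
    n_pairs: int
    quadratic_coef: float | None = None
    r_squared_gain: float | None = None

    def predict(self, distance_km: float) -> float:
        r = self.intercept + self.slope_per_km * distance_km
        if self.quadratic_coef is not None:
            r += self.quadratic_coef * distance_km**2
        return r

    def to_correlation_model(self) -> CorrelationModel:
        return CorrelationModel(intercept=self.intercept, slope_per_km=self.slope_per_km)


def fit_distance_decay(pairs, include_quadratic: bool = False) -> DistanceDecayFit:
    """OLS of pairwise correlation on distance (optionally + distance^2).

    ``pairs`` is the DataFrame from :func:`pairwise_standardized_correlations`
    or any sequence of (distance_km, pearson_r) pairs. With the quadratic
    flag the linear coefficients reported are still those of the *linear*
    fit; the quadratic term is a diagnostic whose R^2 gain is reported.
    """
    if isinstance(pairs, pd.DataFrame):
        d = pairs["distance_km"].to_numpy(dtype=float)
        r = pairs["pearson_r"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(pairs), dtype=float)
        d, r = arr[:, 0], arr[:, 1]
    n = len(d)
    if n < (3 if include_quadratic else 2):
        raise ValueError("not enough pairs for the requested fit")
    if np.ptp(d) == 0:
        raise ValueError("degenerate design: all distances equal")

    def ols_r2(X):
        coef, *_ = np.linalg.lstsq(X, r, rcond=None)
        resid = r - X @ coef
        tss = float(((r - r.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 0.0
        return coef, r2

    coef, r2 = ols_r2(np.column_stack([np.ones(n), d]))
    quad = gain = None
    if include_quadratic:
        qcoef, qr2 = ols_r2(np.column_stack([np.ones(n), d, d**2]))
        quad, gain = float(qcoef[2]), qr2 - r2
    return DistanceDecayFit(
        intercept=float(coef[0]),
        slope_per_km=float(coef[1]),
        r_squared=r2,
        n_pairs=n,
        quadratic_coef=quad,
        r_squared_gain=gain,
    )


def estimate_instrument_error(
    fit: DistanceDecayFit | CorrelationModel,
    dm: DistanceModel,
    monitor_within_variance: float,
) -> float:
    """Instrument/location error SD implied by the within-square correlation.

    The decay fit evaluated at the mean within-square distance D_within is
    interpreted as the reliability ratio var(X*)/var(X) of the monitor
    channel, so sigma_err^2 = (1 - rho(D_within)) * monitor variance.
    """
    D = dm.within_square_D_km
    if isinstance(fit, CorrelationModel):
        rho = correlation_at_distance(D, fit)
    else:
        rho = fit.predict(D)
    if not 0.0 < rho <= 1.0:
        raise ValueError(
            f"correlation at the within-square distance is {rho:.4f}, "
            "outside (0, 1]: cannot be read as a reliability ratio"
        )
    return float(np.sqrt((1.0 - rho) * monitor_within_variance))


def generate_site_fixtures(
    n_urban: int,
    n_rural: int,
    area_km: float,
    correlation: CorrelationModel,
    site_mean: float,
    site_mean_sd: float,
    within_site_sd: float,
    sigma_err: float,
    ctm: CtmSpec | None = None,
    n_days: int = 1095,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    start_date: str = "2003-01-01",
) -> list[SitePairSeries]:
    """Synthetic stand-in for a paired monitor/CTM network dataset.

    Sites are placed uniformly in an ``area_km`` square. ``correlation``
    describes the decay of *observed monitor* correlations with raw
    between-site distance; the latent true series are drawn MVN with the
    correspondingly inflated correlations (divided by the reliability ratio
    (within_site_sd^2 - sigma_err^2)/within_site_sd^2, capped at 1), so that
    adding N(0, sigma_err^2) instrument noise reproduces the stated decay.
    The CTM channel follows the linear-projection emulation with bias; a
    ``missing_rate`` knocks out each channel-day independently. Urban and
    rural strata share the generating parameters; fully seeded.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    var_mon = within_site_sd**2
    var_true = var_mon - sigma_err**2
    if var_true <= 0:
        raise ValueError("sigma_err^2 must be smaller than the within-site variance")
    reliability = var_true / var_mon

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sites = n_urban + n_rural
    coords = rng.uniform(0.0, area_km, size=(n_sites, 2))
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))

    corr_obs = np.asarray(correlation_at_distance(dist, correlation))
    corr_true = np.minimum(corr_obs / reliability, 1.0)
    np.fill_diagonal(corr_true, 1.0)
    cov_true = corr_true * var_true
    vals, vecs = np.linalg.eigh(cov_true)
    if vals[0] < -1e-8 * vals[-1]:
        warnings.warn("site covariance repaired by eigenvalue clipping", stacklevel=2)
    factor = vecs * np.sqrt(np.clip(vals, 0.0, None))

    means = site_mean + site_mean_sd * rng.standard_normal(n_sites)
    truth = means + rng.standard_normal((n_days, n_sites)) @ factor.T
    monitor = truth + sigma_err * rng.standard_normal((n_days, n_sites))
    if ctm is not None:
        resid_sd = np.sqrt(max(ctm.residual_variance, 0.0))
        ctm_vals = (
            ctm.bias_c + means + ctm.slope * (truth - means)
            + resid_sd * rng.standard_normal((n_days, n_sites))
        )
    else:
        ctm_vals = truth.copy()

    if missing_rate > 0:
        monitor[rng.random((n_days, n_sites)) < missing_rate] = np.nan
        ctm_vals[rng.random((n_days, n_sites)) < missing_rate] = np.nan

    dates = pd.date_range(start_date, periods=n_days, freq="D")
    sites = []
    for k in range(n_sites):
        stype = "urban" if k < n_urban else "rural"
        sites.append(
            SitePairSeries(
                site_id=f"{stype[0].upper()}{k:03d}",
                site_type=stype,
                easting_km=float(coords[k, 0]),
                northing_km=float(coords[k, 1]),
                records=pd.DataFrame(
                    {
                        "date": dates,
                        "monitor_value": monitor[:, k],
                        "ctm_value": ctm_vals[:, k],
                    }
                ),
            )
        )
    return sites


def write_sites_csv(sites: list[SitePairSeries], path) -> None:
    frames = []
    for s in sites:
        df = s.records.copy()
        df.insert(0, "site_id", s.site_id)
        df.insert(1, "site_type", s.site_type)
        df.insert(2, "easting_km", s.easting_km)
        df.insert(3, "northing_km", s.northing_km)
        frames.append(df)
    pd.concat(frames, ignore_index=True)[SITE_CSV_COLUMNS].to_csv(path, index=False)


def read_sites_csv(path) -> list[SitePairSeries]:
    df = pd.read_csv(path, parse_dates=["date"])
    missing = set(SITE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site CSV missing columns: {sorted(missing)}")
    sites = []
    for sid, g in df.groupby("site_id", sort=True):
        sites.append(
            SitePairSeries(
                site_id=str(sid),
                site_type=str(g["site_type"].iloc[0]),
                easting_km=float(g["easting_km"].iloc[0]),
                northing_km=float(g["northing_km"].iloc[0]),
                records=g[["date", "monitor_value", "ctm_value"]].reset_index(drop=True),
            )
        )
    return sites
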