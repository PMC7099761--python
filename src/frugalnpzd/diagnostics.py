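"""Analysis surface: nutrient ratios, limitation statistics, DCM, skill.

All diagnostics operate on the run datasets produced by
:func:`frugalnpzd.simulate.run`.  "Surface" means the mean over the top
10 m of the column; climatological months are calendar-month bins of a
365-day year over the post-spin-up record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import xarray as xr

from .ecosystem import EcosystemParams
from .stoichiometry import StoichiometryPolicy, p_to_n_ratio

SURFACE_DEPTH = 10.0  # m

_MONTH_EDGES = np.cumsum([0, 31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
MONTH_NAMES = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")


class TwinContractError(ValueError):
    """Two runs offered as twins do not share forcing or grid."""


def _policy_from(ds: xr.Dataset) -> StoichiometryPolicy:
    mode = ds.attrs["stoichiometry"]
    return (StoichiometryPolicy.redfield() if mode == "redfield"
            else StoichiometryPolicy.lof())


def _params_from(ds: xr.Dataset) -> EcosystemParams:
    cfg = json.loads(ds.attrs["config"])
    return EcosystemParams.from_dict(cfg["params"])


def _post_spinup(ds: xr.Dataset, window=None) -> xr.Dataset:
    if window is not None:
        return ds.sel(time=slice(*window))
    return ds.sel(time=slice(float(ds.attrs.get("spinup_days", 0)), None))


def surface_mean(da: xr.DataArray, depth: float = SURFACE_DEPTH) -> xr.DataArray:
    """Mean over layers whose centers lie within the top ``depth`` m."""
    sel = da.sel(z=da.z[da.z <= depth])
    if sel.z.size == 0:
        sel = da.isel(z=[0])
    return sel.mean("z")


def month_of(time_days: np.ndarray) -> np.ndarray:
    """Calendar month (1-12) of each model time in a 365-day year."""
    doy = np.asarray(time_days) % 365
    return np.searchsorted(_MONTH_EDGES, doy, side="right").clip(1, 12)


# ---------------------------------------------------------------------------
# limitation statistics


@dataclass
class LimitationClimatology:
    """Phosphate-limitation statistics of one run's surface layer."""

    definition: str
    percent_p_limited: float
    per_pft_percent: dict
    monthly: pd.DataFrame  # month, frac_p_limited, limiting


def _surface_limitation_indicators(ds: xr.Dataset, window=None):
    """Per-PFT boolean P-limited indicators and biomass weights at the
    surface for every saved timestep."""
    sub = _post_spinup(ds, window)
    policy = _policy_from(ds)
    params = _params_from(ds)
    din = surface_mean(sub["nh4"] + sub["no3"]).values
    po4 = surface_mean(sub["po4"]).values
    ratio = np.asarray(p_to_n_ratio(policy, po4), float)
    inds, weights = [], []
    for i, pft in enumerate(params.pfts):
        a = pft.alpha_nutrient
        nl = din**2 / (a**2 + din**2)
        half = ratio * a
        pl = po4**2 / (half**2 + po4**2)
        inds.append(pl < nl)
        weights.append(surface_mean(sub["phyto_n"].isel(pft=i)).values)
    return np.array(inds), np.array(weights), sub["time"].values


def limitation_stats(ds: xr.Dataset, definition: str = "biomass_weighted",
                     window=None) -> LimitationClimatology:
    """Percent of time the surface is phosphate limited, plus the
    monthly climatology of the limiting nutrient.

    ``definition`` selects how per-type outcomes are aggregated to one
    verdict per timestep: ``biomass_weighted`` (P-limited when the
    biomass-weighted P-limited fraction exceeds 1/2) or ``any_pft``
    (P-limited when any type is).
    """
    if definition not in ("biomass_weighted", "any_pft"):
        raise ValueError(f"unknown limitation definition {definition!r}")
    inds, weights, time = _surface_limitation_indicators(ds, window)
    if definition == "any_pft":
        p_lim = inds.any(axis=0)
    else:
        wsum = weights.sum(axis=0)
        frac = np.where(wsum > 0, (inds * weights).sum(axis=0) / (wsum + 1e-300),
                        inds.mean(axis=0))
        p_lim = frac > 0.5
    params = _params_from(ds)
    per_pft = {p.name: 100.0 * float(inds[i].mean())
               for i, p in enumerate(params.pfts)}
    months = month_of(time)
    rows = []
    for m in range(1, 13):
        sel = months == m
        frac_m = float(p_lim[sel].mean()) if sel.any() else np.nan
        rows.append({
            "month": MONTH_NAMES[m - 1],
            "frac_p_limited": frac_m,
            "limiting": "phosphorus" if frac_m >= 0.5 else "nitrogen",
        })
    return LimitationClimatology(
        definition=definition,
        percent_p_limited=100.0 * float(p_lim.mean()),
        per_pft_percent=per_pft,
        monthly=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# nutrient-ratio fields


def np_fields(ds: xr.Dataset) -> xr.Dataset:
    """Time x depth N:P of water (nitrate:phosphate) and of organic
    matter (summed organic N over summed organic P ledgers).

    Undefined ratios (zero denominator) are NaN sentinels.
    """
    no3, po4 = ds["no3"], ds["po4"]
    npw = xr.where(po4 > 0, no3 / po4.where(po4 > 0), np.nan)
    org_n = ds["phyto_n"].sum("pft") + ds["zoo_n"] + ds["det_n"]
    org_p = ds["phyto_p"].sum("pft") + ds["zoo_p"] + ds["det_p"]
    npom = xr.where(org_p > 0, org_n / org_p.where(org_p > 0), np.nan)
    out = xr.Dataset({"np_water": npw, "np_om": npom})
    out["np_water"].attrs["long_name"] = "inorganic nitrate:phosphate of seawater"
    out["np_om"].attrs["long_name"] = "molar N:P of organic matter"
    return out


def np_om_chl_correlation(ds: xr.Dataset, window=None) -> float:
    """Sign-carrying Pearson correlation between surface organic-matter
    N:P and surface chlorophyll over the post-spin-up record."""
    sub = _post_spinup(ds, window)
    ratios = np_fields(sub)
    x = surface_mean(ratios["np_om"]).values
    y = surface_mean(sub["chl"]).values
    ok = np.isfinite(x) & np.isfinite(y)
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


# ---------------------------------------------------------------------------
# twin anomalies


@dataclass
class AnomalyReport:
    """Difference statistics between twin runs (b minus a)."""

    field: str
    mean_bias: float                 # surface mean of (b - a)
    profile: np.ndarray              # per-layer time-mean difference
    z: np.ndarray
    difference: xr.DataArray         # full (time, z) field


def anomaly(run_a: xr.Dataset, run_b: xr.Dataset, field: str = "chl",
            window=None, check_twin: bool = True) -> AnomalyReport:
    """b - a difference of one field between twin runs.

    Twin identity (same forcing content and grid) is verified from run
    metadata unless ``check_twin`` is disabled.
    """
    if check_twin:
        if run_a.attrs.get("forcing_sha256") != run_b.attrs.get("forcing_sha256"):
            raise TwinContractError("runs do not share forcing (hash mismatch)")
        if not np.array_equal(run_a["z"].values, run_b["z"].values):
            raise TwinContractError("runs do not share a vertical grid")
    a = _post_spinup(run_a, window)[field]
    b = _post_spinup(run_b, window)[field]
    diff = b - a
    if "z" in diff.dims:
        bias = float(surface_mean(diff).mean("time"))
        profile = diff.mean("time").values
        z = run_a["z"].values
    else:
        bias = float(diff.mean())
        profile = np.array([bias])
        z = np.array([0.0])
    return AnomalyReport(field=field, mean_bias=bias, profile=profile,
                         z=z, difference=diff)


# ---------------------------------------------------------------------------
# skill statistics


@dataclass
class SkillReport:
    """Taylor-diagram statistics of a model field against a reference."""

    mean_bias: float
    correlation: float
    std_ratio: float          # sigma_model / sigma_reference
    sigma_model: float
    sigma_reference: float
    centered_rms: float
    relative_error: float     # mean(|ref - model|) / mean(ref)
    n: int

    def taylor_identity_residual(self) -> float:
        """cRMS^2 - (sm^2 + sr^2 - 2 sm sr rho); zero up to rounding."""
        return (self.centered_rms**2
                - (self.sigma_model**2 + self.sigma_reference**2
                   - 2 * self.sigma_model * self.sigma_reference
                   * self.correlation))


def skill(model, reference) -> SkillReport:
    """Compute bias, correlation, standard-deviation ratio, centered RMS
    difference and relative error, pairwise-complete over NaNs."""
    m = np.asarray(getattr(model, "values", model), float).ravel()
    r = np.asarray(getattr(reference, "values", reference), float).ravel()
    if m.shape != r.shape:
        raise ValueError("model and reference must have matching shapes")
    ok = np.isfinite(m) & np.isfinite(r)
    m, r = m[ok], r[ok]
    if m.size < 2:
        raise ValueError("need at least two paired finite values")
    mm, rm = m.mean(), r.mean()
    sm, sr = m.std(), r.std()
    ma, ra = m - mm, r - rm
    corr = float(np.mean(ma * ra) / (sm * sr)) if sm > 0 and sr > 0 else np.nan
    crms = float(np.sqrt(np.mean((ma - ra) ** 2)))
    rel = float(np.mean(np.abs(r - m)) / rm) if rm != 0 else np.nan
    return SkillReport(
        mean_bias=float(mm - rm), correlation=corr,
        std_ratio=float(sm / sr) if sr > 0 else np.nan,
        sigma_model=float(sm), sigma_reference=float(sr),
        centered_rms=crms, relative_error=rel, n=int(m.size),
    )


# ---------------------------------------------------------------------------
# deep chlorophyll maximum


@dataclass
class DcmMetrics:
    present: bool
    depth: Optional[float]       # m; None when absent
    intensity: Optional[float]   # mg Chl m^-3 at the maximum
    surface_chl: float
    mld_mean: float


DEFAULT_SUMMER_WINDOW = (152.0, 273.0)  # days of year: June-September


def dcm_from_profile(z, chl_profile, mld: float) -> DcmMetrics:
    """Locate a subsurface chlorophyll maximum in one profile.

    The maximum must lie below the mixed layer and exceed the surface
    value, otherwise the profile is flagged surface-intensified (no
    DCM).  Equal maxima report the shallower depth.
    """
    z = np.asarray(z, float)
    c = np.asarray(chl_profile, float)
    idx = int(np.argmax(c))  # first occurrence = shallower on ties
    surface = float(c[0])
    depth = float(z[idx])
    present = depth > mld and c[idx] > surface
    return DcmMetrics(
        present=bool(present),
        depth=depth if present else None,
        intensity=float(c[idx]) if present else None,
        surface_chl=surface,
        mld_mean=float(mld),
    )


def dcm(ds: xr.Dataset, season_window: Tuple[float, float] = DEFAULT_SUMMER_WINDOW,
        window=None) -> DcmMetrics:
    """DCM depth and intensity from the summer-mean post-spin-up profile.

    ``season_window`` selects days of year (default June-September, the
    stratified season); the profile is averaged over those days in every
    analysed year.
    """
    sub = _post_spinup(ds, window)
    doy = sub["time"].values % 365
    lo, hi = season_window
    sel = (doy >= lo) & (doy <= hi)
    if not sel.any():
        raise ValueError("season window contains no saved timesteps")
    prof = sub["chl"].isel(time=np.flatnonzero(sel)).mean("time").values
    mld_mean = float(sub["mld"].isel(time=np.flatnonzero(sel)).mean())
    return dcm_from_profile(sub["z"].values, prof, mld_mean)


# ---------------------------------------------------------------------------
# tabular export


def monthly_climatology(ds: xr.Dataset, field: str = "chl",
                        window=None) -> pd.DataFrame:
    """Calendar-month surface climatology of one field."""
    sub = _post_spinup(ds, window)
    series = surface_mean(sub[field]) if "z" in sub[field].dims else sub[field]
    months = month_of(sub["time"].values)
    df = pd.DataFrame({"month_num": months, field: series.values})
    out = df.groupby("month_num")[field].mean().reset_index()
    out["month"] = [MONTH_NAMES[m - 1] for m in out["month_num"]]
    return out[["month", field]]
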