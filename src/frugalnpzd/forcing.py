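"""Synthetic physical forcing for the water column.

Fabricates the seasonal environment the ecosystem runs in — mixed-layer
depth, surface photosynthetically available radiation (PAR), sea-surface
temperature, a two-regime vertical diffusivity profile, and deep
nutrient reservoirs — as smooth annual cycles with optional seeded red
noise.  Two open-sea presets emulate the contrasting nutrient regimes of
the western and eastern Mediterranean (a N-richer, P-moderate "site A"
and a strongly P-depleted "site B"), plus a river-influenced preset with
a high-N:P surface nutrient source for perturbation experiments.

Nutrients reach the column by vertical diffusion against a deep
reservoir restored below a set depth, standing in for the advective
renewal a full circulation model would provide.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, replace
from typing import Optional

import numpy as np

DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class RiverSource:
    """Surface boundary nutrient flux, mmol m^-2 d^-1."""

    no3_flux: float
    po4_flux: float


@dataclass(frozen=True)
class ScenarioPreset:
    """Scenario constants: deep reservoirs, seasonal-cycle parameters.

    Deep nutrient concentrations are the initialization constants of the
    two open-sea regimes (site A: NO3 8.0, PO4 0.44; site B: NO3 4.6,
    PO4 0.16, all mmol m^-3).
    """

    name: str
    deep_no3: float
    deep_po4: float
    surface_no3: float
    surface_nh4: float
    surface_po4: float
    mld_min: float = 15.0            # m, summer stratification
    mld_max: float = 250.0           # m, winter mixing
    mld_peak_day: float = 45.0       # day of year of deepest mixing
    mld_shape: float = 4.0           # sharpens the winter-mixing season
    par_min: float = 25.0            # W m^-2, daily-mean winter PAR
    par_max: float = 105.0           # W m^-2, summer
    sst_min: float = 13.5            # degC
    sst_max: float = 25.0
    deep_temp: float = 13.5          # degC below the seasonal thermocline
    kz_mixed: float = 100.0          # m^2 d^-1 inside the mixed layer
    kz_background: float = 0.3       # m^2 d^-1 below it
    kz_transition: float = 5.0       # m, width of the mixed-layer base
    attenuation_kw: float = 0.045    # m^-1, clear-water light extinction
    attenuation_kchl: float = 0.03   # m^2 (mg Chl)^-1, self-shading
    restore_depth: float = 200.0     # m, top of the deep-reservoir zone
    restore_timescale: float = 30.0  # d
    river: Optional[RiverSource] = None

    def to_dict(self) -> dict:
        return asdict(self)


SITE_A = ScenarioPreset(
    name="siteA", deep_no3=8.0, deep_po4=0.44,
    surface_no3=0.5, surface_nh4=0.05, surface_po4=0.05,
    mld_min=15.0, mld_max=250.0, par_min=25.0, par_max=105.0,
    sst_min=13.0, sst_max=25.0, deep_temp=13.0, attenuation_kw=0.045,
)

SITE_B = ScenarioPreset(
    name="siteB", deep_no3=4.6, deep_po4=0.16,
    surface_no3=0.1, surface_nh4=0.02, surface_po4=0.01,
    mld_min=15.0, mld_max=130.0, par_min=30.0, par_max=115.0,
    sst_min=16.0, sst_max=27.0, deep_temp=14.0, attenuation_kw=0.035,
)

ADRIATIC_RIVER = ScenarioPreset(
    name="adriatic_river", deep_no3=5.0, deep_po4=0.2,
    surface_no3=1.0, surface_nh4=0.1, surface_po4=0.04,
    mld_min=12.0, mld_max=100.0, par_min=22.0, par_max=100.0,
    sst_min=11.0, sst_max=26.0, deep_temp=12.0, attenuation_kw=0.08,
    river=RiverSource(no3_flux=1.2, po4_flux=0.025),
)

PRESETS = {p.name: p for p in (SITE_A, SITE_B, ADRIATIC_RIVER)}


def get_preset(name: str) -> ScenarioPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario preset {name!r}; available: "
            + ", ".join(sorted(PRESETS))
        ) from None


def scale_boundary_source(preset: ScenarioPreset, no3_factor: float,
                          po4_factor: float) -> ScenarioPreset:
    """Scale the river-like boundary nutrient fluxes of a preset.

    Supports the x5 nutrient-load perturbation experiments; a preset
    without a river source is returned unchanged only for identity
    factors, otherwise it is an error.
    """
    if preset.river is None:
        if no3_factor == 1.0 and po4_factor == 1.0:
            return preset
        raise ValueError(f"preset {preset.name!r} has no boundary source to scale")
    river = RiverSource(no3_flux=preset.river.no3_flux * no3_factor,
                        po4_flux=preset.river.po4_flux * po4_factor)
    return replace(preset, river=river)


@dataclass(frozen=True)
class ForcingSeries:
    """Daily forcing arrays plus the diffusivity field on a grid.

    ``kz`` has shape (n_days, n_interfaces) when built for a grid,
    giving the vertical diffusivity at layer interfaces.
    """

    preset: ScenarioPreset
    time: np.ndarray          # days, daily resolution
    mld: np.ndarray           # m
    surface_par: np.ndarray   # W m^-2
    sst: np.ndarray           # degC
    kz: Optional[np.ndarray]  # m^2 d^-1, (nt, nz+1); None for box forcing
    seed: int

    def sha256(self) -> str:
        """Hash of the forcing content — the twin-run identity stamp."""
        h = hashlib.sha256()
        for arr in (self.time, self.mld, self.surface_par, self.sst):
            h.update(np.ascontiguousarray(arr).tobytes())
        if self.kz is not None:
            h.update(np.ascontiguousarray(self.kz).tobytes())
        h.update(repr(sorted(self.preset.to_dict().items())).encode())
        return h.hexdigest()


def _seasonal(t: np.ndarray, lo: float, hi: float, peak_day: float,
              shape: float = 1.0) -> np.ndarray:
    """Cosine annual cycle in [lo, hi] peaking at ``peak_day``.

    ``shape`` > 1 sharpens the peak (narrow deep-mixing season) while
    preserving the extremes and the 365-day period.
    """
    w = 0.5 * (1.0 + np.cos(2.0 * np.pi * (t - peak_day) / DAYS_PER_YEAR))
    return lo + (hi - lo) * w**shape


def _red_noise(rng: np.random.Generator, n: int, amplitude: float,
               timescale: float = 10.0) -> np.ndarray:
    """AR(1) noise with unit marginal std scaled by ``amplitude``."""
    if amplitude == 0.0:
        return np.zeros(n)
    phi = np.exp(-1.0 / timescale)
    eps = rng.standard_normal(n) * np.sqrt(1.0 - phi**2)
    out = np.empty(n)
    out[0] = rng.standard_normal()
    for i in range(1, n):
        out[i] = phi * out[i - 1] + eps[i]
    return amplitude * out


def mixed_layer_depth(preset: ScenarioPreset, t) -> np.ndarray:
    return _seasonal(np.asarray(t, float), preset.mld_min, preset.mld_max,
                     preset.mld_peak_day, preset.mld_shape)


def surface_par(preset: ScenarioPreset, t) -> np.ndarray:
    # peak at the summer solstice
    return _seasonal(np.asarray(t, float), preset.par_min, preset.par_max, 172.0)


def sea_surface_temp(preset: ScenarioPreset, t) -> np.ndarray:
    # SST lags insolation by about a month
    return _seasonal(np.asarray(t, float), preset.sst_min, preset.sst_max, 215.0)


def diffusivity_profile(preset: ScenarioPreset, mld, z_interfaces) -> np.ndarray:
    """kz at layer interfaces: mixed-layer value above the MLD, background
    below, blended over ``kz_transition`` metres."""
    mld = np.atleast_1d(np.asarray(mld, float))[:, None]
    z = np.asarray(z_interfaces, float)[None, :]
    blend = 0.5 * (1.0 + np.tanh((mld - z) / preset.kz_transition))
    kz = preset.kz_background + (preset.kz_mixed - preset.kz_background) * blend
    return kz


def temperature_profile(preset: ScenarioPreset, sst, mld, z_centers) -> np.ndarray:
    """Uniform SST in the mixed layer, relaxing to the deep temperature
    over a 50 m scale below it."""
    sst = np.atleast_1d(np.asarray(sst, float))[:, None]
    mld = np.atleast_1d(np.asarray(mld, float))[:, None]
    z = np.asarray(z_centers, float)[None, :]
    below = np.maximum(z - mld, 0.0)
    return preset.deep_temp + (sst - preset.deep_temp) * np.exp(-below / 50.0)


def make_forcing(preset, years: int, seed: int,
                 z_interfaces=None,
                 noise_mld: float = 0.0,
                 noise_par: float = 0.0) -> ForcingSeries:
    """Build the daily forcing series for ``years`` annual cycles.

    Pure and deterministic: the same (preset, years, seed, noise)
    arguments yield bit-identical arrays.  With zero noise amplitudes
    the series are exact sinusoids.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if years < 1:
        raise ValueError("years must be >= 1")
    nt = years * DAYS_PER_YEAR + 1
    t = np.arange(nt, dtype=float)
    rng = np.random.default_rng(seed)
    mld = mixed_layer_depth(preset, t)
    par = surface_par(preset, t)
    if noise_mld or noise_par:
        mld = np.clip(mld * (1.0 + _red_noise(rng, nt, noise_mld)),
                      preset.mld_min, preset.mld_max)
        par = np.clip(par * (1.0 + _red_noise(rng, nt, noise_par)),
                      0.0, None)
    sst = sea_surface_temp(preset, t)
    kz = None
    if z_interfaces is not None:
        kz = diffusivity_profile(preset, mld, z_interfaces)
    return ForcingSeries(preset=preset, time=t, mld=mld, surface_par=par,
                         sst=sst, kz=kz, seed=seed)
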