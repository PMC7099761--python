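"""Time integration of the ecosystem in a 0-D box or a 1-D column.

The update is operator-split per time step:

1. biological tendencies, explicit Euler with demand capping
   (:func:`frugalnpzd.ecosystem.step_biology`);
2. vertical diffusion, backward-Euler tridiagonal solve in flux form
   (exactly mass conserving with no-flux boundaries), plus restoring of
   NO3/PO4 toward the deep reservoir below ``restore_depth``;
3. upwind sinking of phytoplankton and detritus (material reaching the
   bottom layer stays there and remineralizes).

Every external exchange — nitrogen fixation, deep restoring, river
boundary fluxes — is accumulated in a depth-integrated ledger so that
the change of total N and total P over any window equals the summed
ledgers to rounding precision, which the tests audit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
import xarray as xr
from scipy.linalg import solve_banded

from . import __version__
from .ecosystem import (EcosystemParams, EcosystemState, PFT_NAMES,
                        chlorophyll, default_params, step_biology)
from .forcing import (DAYS_PER_YEAR, ForcingSeries, ScenarioPreset,
                      get_preset, make_forcing, temperature_profile)
from .stoichiometry import StoichiometryPolicy


@dataclass(frozen=True)
class Grid:
    """Vertical grid: contiguous layer edges from the surface down (m)."""

    edges: tuple
    mode: str = "column"

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, float)
        if e[0] != 0.0 or np.any(np.diff(e) <= 0):
            raise ValueError("layer edges must increase strictly from 0")
        if self.mode not in ("box", "column"):
            raise ValueError("grid mode must be 'box' or 'column'")
        if self.mode == "box" and len(e) != 2:
            raise ValueError("box mode is a single layer")

    @classmethod
    def box(cls, depth: float = 20.0) -> "Grid":
        return cls(edges=(0.0, depth), mode="box")

    @classmethod
    def column(cls, depth: float = 250.0, n_layers: int = 25) -> "Grid":
        return cls(edges=tuple(np.linspace(0.0, depth, n_layers + 1)), mode="column")

    @property
    def nz(self) -> int:
        return len(self.edges) - 1

    @property
    def dz(self) -> np.ndarray:
        return np.diff(np.asarray(self.edges, float))

    @property
    def z_centers(self) -> np.ndarray:
        e = np.asarray(self.edges, float)
        return 0.5 * (e[:-1] + e[1:])

    @property
    def z_interfaces(self) -> np.ndarray:
        return np.asarray(self.edges, float)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run bit-identically."""

    scenario: Union[str, ScenarioPreset] = "siteA"
    stoichiometry: str = "lof"          # 'redfield' | 'lof'
    years: int = 8
    spinup_years: int = 1
    dt: float = 0.05                    # days
    save_interval: float = 1.0          # days
    grid: Optional[Grid] = None         # default: 25-layer, 250 m column
    seed: int = 0
    params: Optional[EcosystemParams] = None
    nitrogen_fixation: bool = True
    noise_mld: float = 0.0
    noise_par: float = 0.0

    def resolve(self) -> "RunConfig":
        out = replace(self)
        if isinstance(out.scenario, str):
            out.scenario = get_preset(out.scenario)
        if out.grid is None:
            out.grid = Grid.column()
        if out.params is None:
            out.params = default_params()
        return out

    def to_json(self) -> str:
        cfg = self.resolve()
        d = {
            "scenario": cfg.scenario.to_dict(),
            "stoichiometry": cfg.stoichiometry,
            "years": cfg.years,
            "spinup_years": cfg.spinup_years,
            "dt": cfg.dt,
            "save_interval": cfg.save_interval,
            "grid": {"edges": list(cfg.grid.edges), "mode": cfg.grid.mode},
            "seed": cfg.seed,
            "params": cfg.params.to_dict(),
            "nitrogen_fixation": cfg.nitrogen_fixation,
            "noise_mld": cfg.noise_mld,
            "noise_par": cfg.noise_par,
        }
        return json.dumps(d, sort_keys=True)


_MAX_BIO_RATE = 4.0  # d^-1, conservative bound on any single process rate


def _stability_check(config: RunConfig) -> None:
    dt, grid = config.dt, config.grid
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt * _MAX_BIO_RATE > 1.0:
        raise ValueError(
            f"dt={dt} d violates the explicit-biology stability bound "
            f"dt * {_MAX_BIO_RATE} <= 1"
        )
    ws = [p.sinking_speed for p in config.params.pfts] + [config.params.detritus_sinking]
    cfl = max(ws) * dt / grid.dz.min()
    if cfl > 1.0:
        raise ValueError(f"sinking CFL {cfl:.3f} > 1; reduce dt or sinking speed")


def _diffusion_matrix(kz_if: np.ndarray, dz: np.ndarray, dt: float) -> np.ndarray:
    """Banded backward-Euler matrix for flux-form vertical diffusion."""
    nz = dz.size
    z_mid = np.cumsum(dz) - 0.5 * dz
    h = np.diff(z_mid)  # center-to-center distances
    k_in = kz_if[1:-1]  # interior interface diffusivities
    lower = np.zeros(nz)
    upper = np.zeros(nz)
    lower[1:] = -dt * k_in / (dz[1:] * h)
    upper[:-1] = -dt * k_in / (dz[:-1] * h)
    diag = 1.0 - lower - upper
    ab = np.zeros((3, nz))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    return ab


def _sinking(arr: np.ndarray, w: float, dz: np.ndarray, dt: float) -> None:
    """Explicit upwind downward advection, in place; closed bottom."""
    if w == 0.0:
        return
    flux = w * arr[..., :-1]  # through interior interfaces
    arr[..., :-1] -= dt * flux / dz[:-1]
    arr[..., 1:] += dt * flux / dz[1:]


def run(config: RunConfig) -> xr.Dataset:
    """Integrate one simulation and return its gridded result.

    The returned dataset carries time x depth arrays of every state
    pool plus chlorophyll, the forcing actually used, cumulative
    external-flux ledgers, and full provenance (configuration JSON,
    seed, forcing hash, package version) in its attributes.
    """
    cfg = config.resolve()
    _stability_check(cfg)
    grid: Grid = cfg.grid
    preset: ScenarioPreset = cfg.scenario
    params: EcosystemParams = cfg.params
    policy = (StoichiometryPolicy.redfield() if cfg.stoichiometry == "redfield"
              else StoichiometryPolicy.lof())
    column = grid.mode == "column"

    forcing = make_forcing(preset, cfg.years, cfg.seed,
                           z_interfaces=grid.z_interfaces if column else None,
                           noise_mld=cfg.noise_mld, noise_par=cfg.noise_par)

    dz = grid.dz
    z = grid.z_centers
    nz = grid.nz

    # initial nutrient profiles: linear ramp from surface values to the
    # deep reservoir at the restoring depth
    ramp = np.clip(z / preset.restore_depth, 0.0, 1.0)
    no3_0 = preset.surface_no3 + (preset.deep_no3 - preset.surface_no3) * ramp
    po4_0 = preset.surface_po4 + (preset.deep_po4 - preset.surface_po4) * ramp
    state = EcosystemState.initial(nz, no3_0, preset.surface_nh4, po4_0)

    n_steps = int(round(cfg.years * DAYS_PER_YEAR / cfg.dt))
    save_every = max(1, int(round(cfg.save_interval / cfg.dt)))
    n_save = n_steps // save_every + 1

    restore_w = np.clip((z - preset.restore_depth) / 25.0, 0.0, 1.0) if column else np.zeros(nz)
    attenuation_kw = preset.attenuation_kw
    attenuation_kchl = preset.attenuation_kchl

    ledgers = {k: 0.0 for k in
               ("fixed_n", "restore_n", "restore_p", "river_n", "river_p")}

    # output buffers
    out = {name: np.empty((n_save,) + getattr(state, name).shape)
           for name in EcosystemState.POOL_NAMES}
    out["chl"] = np.empty((n_save, nz))
    saved_t = np.empty(n_save)
    saved_forcing = {k: np.empty(n_save) for k in ("mld", "surface_par", "sst")}
    saved_ledgers = {k: np.empty(n_save) for k in ledgers}
    saved_totals = {"total_n": np.empty(n_save), "total_p": np.empty(n_save)}

    def save(idx: int, t: float, f_mld, f_par, f_sst) -> None:
        for name in EcosystemState.POOL_NAMES:
            out[name][idx] = getattr(state, name)
        out["chl"][idx] = chlorophyll(state, params.chl_to_n)
        saved_t[idx] = t
        saved_forcing["mld"][idx] = f_mld
        saved_forcing["surface_par"][idx] = f_par
        saved_forcing["sst"][idx] = f_sst
        for k, v in ledgers.items():
            saved_ledgers[k][idx] = v
        saved_totals["total_n"][idx] = state.total_nitrogen(dz)
        saved_totals["total_p"][idx] = state.total_phosphorus(dz)

    ft, fm, fp, fs = forcing.time, forcing.mld, forcing.surface_par, forcing.sst
    river = preset.river
    tau = preset.restore_timescale
    isave = 0
    save(isave, 0.0, fm[0], fp[0], fs[0])
    isave += 1

    for n in range(1, n_steps + 1):
        t = n * cfg.dt
        # linear interpolation of the daily forcing
        d = min(int(t), ft.size - 2)
        frac = t - d
        mld = fm[d] + frac * (fm[d + 1] - fm[d])
        par0 = fp[d] + frac * (fp[d + 1] - fp[d])
        sst = fs[d] + frac * (fs[d + 1] - fs[d])

        temp = temperature_profile(preset, sst, mld, z)[0] if column else np.full(nz, sst)

        # light profile with self-shading, evaluated at layer centers
        chl = chlorophyll(state, params.chl_to_n)
        k_layer = attenuation_kw + attenuation_kchl * chl
        tau_edges = np.concatenate(([0.0], np.cumsum(k_layer * dz)))
        par = par0 * np.exp(-(tau_edges[:-1] + 0.5 * k_layer * dz))

        fix_rate = step_biology(state, par, temp, cfg.dt, policy, params,
                                fixation=cfg.nitrogen_fixation)
        ledgers["fixed_n"] += cfg.dt * float(np.sum(fix_rate * dz))

        if column:
            kz_t = forcing.kz[d] + frac * (forcing.kz[d + 1] - forcing.kz[d])
            ab = _diffusion_matrix(kz_t, dz, cfg.dt)
            tracers = [state.phyto_n[i] for i in range(state.phyto_n.shape[0])]
            tracers += [state.phyto_p[i] for i in range(state.phyto_p.shape[0])]
            tracers += [state.zoo_n, state.zoo_p, state.det_n, state.det_p,
                        state.no3, state.nh4, state.po4]
            x = np.stack(tracers, axis=1)
            x = solve_banded((1, 1), ab, x)
            npft = state.phyto_n.shape[0]
            state.phyto_n[:] = x[:, :npft].T
            state.phyto_p[:] = x[:, npft:2 * npft].T
            (state.zoo_n[:], state.zoo_p[:], state.det_n[:], state.det_p[:],
             state.no3[:], state.nh4[:], state.po4[:]) = x[:, 2 * npft:].T

            # deep-reservoir restoring (stands in for advective renewal)
            dn = cfg.dt * restore_w * (preset.deep_no3 - state.no3) / tau
            dp = cfg.dt * restore_w * (preset.deep_po4 - state.po4) / tau
            state.no3 += dn
            state.po4 += dp
            ledgers["restore_n"] += float(np.sum(dn * dz))
            ledgers["restore_p"] += float(np.sum(dp * dz))

            for i, pft in enumerate(params.pfts):
                _sinking(state.phyto_n[i], pft.sinking_speed, dz, cfg.dt)
                _sinking(state.phyto_p[i], pft.sinking_speed, dz, cfg.dt)
            _sinking(state.det_n, params.detritus_sinking, dz, cfg.dt)
            _sinking(state.det_p, params.detritus_sinking, dz, cfg.dt)

            if river is not None:
                state.no3[0] += cfg.dt * river.no3_flux / dz[0]
                state.po4[0] += cfg.dt * river.po4_flux / dz[0]
                ledgers["river_n"] += cfg.dt * river.no3_flux
                ledgers["river_p"] += cfg.dt * river.po4_flux

        if not np.isfinite(state.min_pool()):
            raise FloatingPointError(
                f"non-finite state at step {n} (t={t:.3f} d); "
                f"pool minima: " + ", ".join(
                    f"{k}={float(getattr(state, k).min()):.3e}"
                    for k in EcosystemState.POOL_NAMES)
            )

        if n % save_every == 0:
            save(isave, t, mld, par0, sst)
            isave += 1

    coords = {
        "time": ("time", saved_t, {"units": "days since start"}),
        "z": ("z", z, {"units": "m", "positive": "down",
                        "long_name": "layer center depth"}),
        "pft": ("pft", np.array(PFT_NAMES, dtype="U16")),
    }
    data = {}
    for name in EcosystemState.POOL_NAMES:
        arr = out[name]
        if arr.ndim == 3:
            data[name] = (("time", "pft", "z"), arr.transpose(0, 1, 2),
                          {"units": "mmol m-3"})
        else:
            data[name] = (("time", "z"), arr, {"units": "mmol m-3"})
    data["chl"] = (("time", "z"), out["chl"], {"units": "mg m-3",
                   "long_name": "chlorophyll a"})
    for k, v in saved_forcing.items():
        data[k] = (("time",), v)
    for k, v in saved_ledgers.items():
        data[f"ledger_{k}"] = (("time",), v,
                               {"units": "mmol m-2", "long_name":
                                f"cumulative external {k} input"})
    for k, v in saved_totals.items():
        data[k] = (("time",), v, {"units": "mmol m-2"})
    data["dz"] = (("z",), dz, {"units": "m"})

    ds = xr.Dataset(data, coords=coords)
    ds.attrs.update({
        "config": cfg.to_json(),
        "scenario": preset.name,
        "stoichiometry": cfg.stoichiometry,
        "seed": cfg.seed,
        "spinup_days": cfg.spinup_years * DAYS_PER_YEAR,
        "forcing_sha256": forcing.sha256(),
        "params_preset": params.preset_name,
        "package_version": __version__,
    })
    return ds


def conservation_report(ds: xr.Dataset) -> dict:
    """Audit the ledger identity on a finished run.

    Returns the maximum relative deviation of the depth-integrated N and
    P budgets from their external-flux ledgers over the whole record.
    """
    n_ext = ds["ledger_fixed_n"] + ds["ledger_restore_n"] + ds["ledger_river_n"]
    p_ext = ds["ledger_restore_p"] + ds["ledger_river_p"]
    n_resid = (ds["total_n"] - ds["total_n"].isel(time=0)) - n_ext
    p_resid = (ds["total_p"] - ds["total_p"].isel(time=0)) - p_ext
    n0 = float(ds["total_n"].isel(time=0))
    p0 = float(ds["total_p"].isel(time=0))
    return {
        "n_drift_rel": float(np.abs(n_resid).max()) / n0,
        "p_drift_rel": float(np.abs(p_resid).max()) / p0,
    }


def save_netcdf(ds: xr.Dataset, path) -> None:
    """Write a run to NetCDF (classic format via the SciPy backend)."""
    ds.to_netcdf(path, engine="scipy")


def load_netcdf(path) -> xr.Dataset:
    # time is plain model days since the run start, not a calendar axis
    return xr.load_dataset(path, engine="scipy", decode_times=False)
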