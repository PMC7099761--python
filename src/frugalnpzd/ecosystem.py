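"""NPZD ecosystem process terms in nitrogen currency with a parallel P ledger.

Three phytoplankton functional types (diatom-like, flagellate-like,
cyanobacteria-like), one zooplankton compartment, detritus, and three
dissolved pools (NO3, NH4, PO4).  Every organic pool carries an explicit
phosphorus ledger alongside its nitrogen content so that variable-ratio
uptake remains exactly mass conservative: each unit of N fixed into
phytoplankton draws ``p_to_n(PO4)`` units of P from the phosphate pool,
and every downstream transfer (grazing, mortality, remineralization)
moves P in the donor pool's actual P:N ratio.

Nitrogen fixation by the cyanobacteria-like type is an external N source
tracked in its own ledger: the fixer's growth ignores the nitrogen
limitation factor, draws dissolved N while available, and books the
shortfall as fixed N.

All process functions are vectorized over layers (arrays of shape
``(n_layers,)`` or ``(n_pft, n_layers)``).
"""

from __future__ import annotations

import functools
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .stoichiometry import StoichiometryPolicy, p_to_n_ratio

_TINY = 1e-300

PFT_NAMES = ("diatom", "flagellate", "cyanobacteria")


@dataclass(frozen=True)
class PftParams:
    """Per-functional-type process parameters.

    mu_max
        Maximum growth rate, d^-1.  Zero is allowed and switches the
        type off entirely (used by the cyanobacteria-removal experiment).
    alpha_nutrient
        Nutrient half-saturation in nitrogen units, mmol N m^-3.
    light_halfsat
        Light half-saturation, W m^-2.
    q10
        Temperature sensitivity per 10 degC of the growth rate.
    sinking_speed
        Downward sinking of the cells, m d^-1.
    mortality_rate
        Linear mortality to detritus, d^-1.
    fixes_nitrogen
        Whether the type can supply its N demand by fixation.
    """

    name: str
    mu_max: float
    alpha_nutrient: float
    light_halfsat: float
    q10: float = 1.9
    sinking_speed: float = 0.0
    mortality_rate: float = 0.05
    fixes_nitrogen: bool = False

    def __post_init__(self) -> None:
        for attr in ("mu_max", "alpha_nutrient", "light_halfsat",
                     "sinking_speed", "mortality_rate"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.alpha_nutrient == 0 or self.light_halfsat == 0:
            raise ValueError("half-saturation constants must be positive")
        if self.fixes_nitrogen and self.name != "cyanobacteria":
            raise ValueError("only the cyanobacteria-like type fixes nitrogen")


@dataclass(frozen=True)
class ZooplanktonParams:
    max_grazing: float = 0.9        # d^-1
    grazing_halfsat: float = 0.5    # mmol N m^-3, Holling-II on total phyto N
    assimilation: float = 0.7       # dimensionless; rest goes to detritus
    excretion_rate: float = 0.08    # d^-1, to NH4 / PO4
    mortality_rate: float = 0.12    # d^-1, to detritus


@dataclass(frozen=True)
class RemineralizationParams:
    # Equal default N and P rates keep detrital P:N at the ratio of its
    # inputs; unequal rates are supported but decouple the pool ratios.
    detritus_n_rate: float = 0.05   # d^-1, det_n -> NH4
    detritus_p_rate: float = 0.05   # d^-1, det_p -> PO4
    nitrification_rate: float = 0.1  # d^-1, NH4 -> NO3


@dataclass(frozen=True)
class EcosystemParams:
    """Full biological parameter set; shipped presets are versioned."""

    pfts: tuple = ()
    zoo: ZooplanktonParams = field(default_factory=ZooplanktonParams)
    remin: RemineralizationParams = field(default_factory=RemineralizationParams)
    chl_to_n: float = 1.6            # mg Chl (mmol N)^-1
    reference_temp: float = 16.0     # degC for the Q10 factors
    q10_hetero: float = 2.0          # grazing / excretion / remineralization
    detritus_sinking: float = 3.0    # m d^-1
    preset_name: str = "custom"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EcosystemParams":
        d = dict(d)
        d["pfts"] = tuple(PftParams(**p) for p in d["pfts"])
        d["zoo"] = ZooplanktonParams(**d["zoo"])
        d["remin"] = RemineralizationParams(**d["remin"])
        return cls(**d)

    def with_pft(self, name: str, **changes) -> "EcosystemParams":
        """Return a copy with one functional type's parameters replaced."""
        pfts = tuple(
            replace(p, **changes) if p.name == name else p for p in self.pfts
        )
        if not any(p.name == name for p in self.pfts):
            raise ValueError(f"no functional type named {name!r}")
        return replace(self, pfts=pfts, preset_name=f"{self.preset_name}+mod")


def default_params() -> EcosystemParams:
    """The ``med-oligotrophic-v1`` preset.

    Magnitudes follow the ERGOM family of Baltic/Mediterranean NPZD
    models: a fast, sinking, light-hungry diatom; a slower flagellate
    able to grow on dim deep light (it builds the subsurface chlorophyll
    maximum); and a slow, warm-water cyanobacterium that can fix
    nitrogen.
    """
    return EcosystemParams(
        pfts=(
            PftParams("diatom", mu_max=1.8, alpha_nutrient=0.35,
                      light_halfsat=20.0, q10=1.9, sinking_speed=0.5,
                      mortality_rate=0.06),
            PftParams("flagellate", mu_max=1.1, alpha_nutrient=0.15,
                      light_halfsat=8.0, q10=1.9, sinking_speed=0.0,
                      mortality_rate=0.06),
            PftParams("cyanobacteria", mu_max=0.7, alpha_nutrient=0.10,
                      light_halfsat=25.0, q10=2.5, sinking_speed=0.0,
                      mortality_rate=0.06, fixes_nitrogen=True),
        ),
        preset_name="med-oligotrophic-v1",
    )


@dataclass
class EcosystemState:
    """Concentrations per layer (mmol m^-3); phyto arrays are (n_pft, nz)."""

    phyto_n: np.ndarray
    phyto_p: np.ndarray
    zoo_n: np.ndarray
    zoo_p: np.ndarray
    det_n: np.ndarray
    det_p: np.ndarray
    no3: np.ndarray
    nh4: np.ndarray
    po4: np.ndarray

    POOL_NAMES = ("phyto_n", "phyto_p", "zoo_n", "zoo_p",
                  "det_n", "det_p", "no3", "nh4", "po4")

    @classmethod
    def initial(cls, nz: int, no3, nh4, po4, n_pft: int = 3,
                seed_biomass: float = 0.01,
                seed_p_to_n: float = 1.0 / 16.0) -> "EcosystemState":
        """Uniform seed biomass over given nutrient profiles."""
        def prof(x):
            return np.broadcast_to(np.asarray(x, float), (nz,)).copy()

        pn = np.full((n_pft, nz), seed_biomass, float)
        return cls(
            phyto_n=pn,
            phyto_p=pn * seed_p_to_n,
            zoo_n=np.full(nz, seed_biomass),
            zoo_p=np.full(nz, seed_biomass * seed_p_to_n),
            det_n=np.zeros(nz),
            det_p=np.zeros(nz),
            no3=prof(no3), nh4=prof(nh4), po4=prof(po4),
        )

    @property
    def nz(self) -> int:
        return self.no3.shape[-1]

    def copy(self) -> "EcosystemState":
        return EcosystemState(**{k: getattr(self, k).copy()
                                 for k in self.POOL_NAMES})

    def total_nitrogen(self, dz) -> float:
        """Depth-integrated nitrogen, mmol N m^-2 (dz in m)."""
        dz = np.asarray(dz, float)
        col = self.phyto_n.sum(axis=0) + self.zoo_n + self.det_n + self.no3 + self.nh4
        return float(np.sum(col * dz))

    def total_phosphorus(self, dz) -> float:
        """Depth-integrated phosphorus, mmol P m^-2."""
        dz = np.asarray(dz, float)
        col = self.phyto_p.sum(axis=0) + self.zoo_p + self.det_p + self.po4
        return float(np.sum(col * dz))

    def min_pool(self) -> float:
        return min(float(getattr(self, k).min()) for k in self.POOL_NAMES)


def temperature_factor(temp, q10: float, reference_temp: float):
    """Exponential Q10 response, ``q10 ** ((T - Tref)/10)``."""
    return np.asarray(q10, float) ** ((np.asarray(temp, float) - reference_temp) / 10.0)


def light_limitation(par, halfsat: float):
    """Saturating (Monod) light response in [0, 1)."""
    par = np.maximum(np.asarray(par, float), 0.0)
    return par / (par + halfsat)


@functools.lru_cache(maxsize=32)
def _pft_arrays(params: EcosystemParams):
    p = params.pfts
    col = lambda attr: np.array([getattr(x, attr) for x in p])[:, None]
    return {
        "mu_max": col("mu_max"),
        "alpha": col("alpha_nutrient"),
        "light_halfsat": col("light_halfsat"),
        "q10": col("q10"),
        "mortality": col("mortality_rate"),
        "fixes": np.array([x.fixes_nitrogen for x in p])[:, None],
    }


def growth_fluxes(state: EcosystemState, par, temp,
                  policy: StoichiometryPolicy, params: EcosystemParams) -> dict:
    """Uncapped (raw) growth-related rates, all in mmol m^-3 d^-1.

    Growth of each type is mu_max * f_T * min(nlim, plim, llim) * biomass;
    the nitrogen factor is waived for a fixer.  Returns the limitation
    factors and the raw growth per type; demand allocation against the
    finite dissolved pools is done by :func:`step_biology`.
    """
    a = _pft_arrays(params)
    din = state.nh4 + state.no3
    nl = din**2 / (a["alpha"] ** 2 + din**2)
    ratio = np.asarray(p_to_n_ratio(policy, state.po4), float)
    half = a["alpha"] * ratio
    pl = state.po4**2 / (half**2 + state.po4**2)
    par_pos = np.maximum(np.asarray(par, float), 0.0)
    ll = par_pos / (par_pos + a["light_halfsat"])
    f_t = a["q10"] ** ((np.asarray(temp, float) - params.reference_temp) / 10.0)
    lim = np.where(a["fixes"], np.minimum(pl, ll), np.minimum(np.minimum(nl, pl), ll))
    growth = a["mu_max"] * f_t * lim * state.phyto_n
    return {"growth": growth, "nlim": nl, "plim": pl, "llim": ll,
            "p_to_n": ratio, "f_t": f_t}


def grazing_fluxes(state: EcosystemState, temp, params: EcosystemParams) -> dict:
    """Raw Holling-II grazing on total phytoplankton nitrogen.

    Grazing is partitioned across types in proportion to their biomass;
    P moves in each prey pool's actual P:N ratio.
    """
    z = params.zoo
    f_t = temperature_factor(temp, params.q10_hetero, params.reference_temp)
    ptot = state.phyto_n.sum(axis=0)
    total = z.max_grazing * f_t * ptot / (z.grazing_halfsat + ptot + _TINY) * state.zoo_n
    share = np.divide(state.phyto_n, ptot + _TINY)
    graze_n = total * share
    ratio = np.divide(state.phyto_p, state.phyto_n + _TINY)
    graze_p = graze_n * ratio
    return {"graze_n": graze_n, "graze_p": graze_p, "f_t": f_t}


def remineralization_fluxes(state: EcosystemState, temp,
                            params: EcosystemParams) -> dict:
    """Raw first-order remineralization and nitrification rates."""
    r = params.remin
    f_t = temperature_factor(temp, params.q10_hetero, params.reference_temp)
    return {
        "remin_n": r.detritus_n_rate * f_t * state.det_n,
        "remin_p": r.detritus_p_rate * f_t * state.det_p,
        "nitrif": r.nitrification_rate * f_t * state.nh4,
    }


def chlorophyll(state: EcosystemState, chl_to_n: float) -> np.ndarray:
    """Chlorophyll a per layer, mg Chl m^-3 = chl_to_n * total phyto N."""
    return chl_to_n * state.phyto_n.sum(axis=0)


def _sink_scale(pool: np.ndarray, demand: np.ndarray, dt: float) -> np.ndarray:
    """Factor scaling all sinks of a pool so dt * sinks <= pool."""
    need = dt * demand
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(need > pool, pool / (need + _TINY), 1.0)
    return np.clip(s, 0.0, 1.0)


def step_biology(state: EcosystemState, par, temp, dt: float,
                 policy: StoichiometryPolicy, params: EcosystemParams,
                 fixation: bool = True) -> np.ndarray:
    """Advance the biological terms one explicit Euler step, in place.

    Positivity is enforced by demand capping: when the combined sinks of
    a pool would overdraw it within ``dt``, all of that pool's sinks are
    scaled by available/demand, keeping every transfer paired and the
    N and P budgets exact.

    Returns the nitrogen-fixation rate per layer (mmol N m^-3 d^-1)
    actually applied during this step, for the external-source ledger.
    """
    g = growth_fluxes(state, par, temp, policy, params)
    a = _pft_arrays(params)
    ratio = g["p_to_n"]

    # --- phosphate cap scales growth itself (P is obligatory) ---------
    g0 = g["growth"]
    p_demand = g0.sum(axis=0) * ratio
    s_p = _sink_scale(state.po4, p_demand, dt)
    g1 = g0 * s_p

    # --- dissolved N allocation: NH4 preferred, overflow from NO3 -----
    remin = remineralization_fluxes(state, temp, params)
    d_tot = g1.sum(axis=0)
    s_nh4 = _sink_scale(state.nh4, d_tot + remin["nitrif"], dt)
    nh4_up = g1 * s_nh4
    nitrif = remin["nitrif"] * s_nh4
    residual = g1 - nh4_up
    s_no3 = _sink_scale(state.no3, residual.sum(axis=0), dt)
    no3_up = residual * s_no3
    shortfall = residual - no3_up
    fixes = a["fixes"]
    if not fixation:
        fixes = np.zeros_like(fixes)
    fix_n = np.where(fixes, shortfall, 0.0)
    growth = nh4_up + no3_up + fix_n
    p_up = growth * ratio  # <= P-cap allowance since growth <= g1

    # --- grazing and phytoplankton mortality, capped per type ---------
    gr = grazing_fluxes(state, temp, params)
    mort_n = a["mortality"] * state.phyto_n
    s_ph = _sink_scale(state.phyto_n, gr["graze_n"] + mort_n, dt)
    graze_n = gr["graze_n"] * s_ph
    mort_n = mort_n * s_ph
    pool_ratio = np.divide(state.phyto_p, state.phyto_n + _TINY)
    graze_p = graze_n * pool_ratio
    mort_p = mort_n * pool_ratio

    # --- zooplankton losses at the pool's own ratio --------------------
    z = params.zoo
    f_th = gr["f_t"]
    exc_n = z.excretion_rate * f_th * state.zoo_n
    zmort_n = z.mortality_rate * state.zoo_n
    exc_p = z.excretion_rate * f_th * state.zoo_p
    zmort_p = z.mortality_rate * state.zoo_p
    s_z = np.minimum(_sink_scale(state.zoo_n, exc_n + zmort_n, dt),
                     _sink_scale(state.zoo_p, exc_p + zmort_p, dt))
    exc_n, zmort_n, exc_p, zmort_p = (x * s_z for x in
                                      (exc_n, zmort_n, exc_p, zmort_p))

    # --- detritus remineralization, capped -----------------------------
    remin_n = remin["remin_n"] * _sink_scale(state.det_n, remin["remin_n"], dt)
    remin_p = remin["remin_p"] * _sink_scale(state.det_p, remin["remin_p"], dt)

    beta = z.assimilation
    graze_n_tot = graze_n.sum(axis=0)
    graze_p_tot = graze_p.sum(axis=0)

    state.phyto_n += dt * (growth - graze_n - mort_n)
    state.phyto_p += dt * (p_up - graze_p - mort_p)
    state.zoo_n += dt * (beta * graze_n_tot - exc_n - zmort_n)
    state.zoo_p += dt * (beta * graze_p_tot - exc_p - zmort_p)
    state.det_n += dt * ((1 - beta) * graze_n_tot + mort_n.sum(axis=0)
                         + zmort_n - remin_n)
    state.det_p += dt * ((1 - beta) * graze_p_tot + mort_p.sum(axis=0)
                         + zmort_p - remin_p)
    state.nh4 += dt * (remin_n + exc_n - nh4_up.sum(axis=0) - nitrif)
    state.no3 += dt * (nitrif - no3_up.sum(axis=0))
    state.po4 += dt * (remin_p + exc_p - p_up.sum(axis=0))

    # demand capping guarantees non-negativity up to rounding; clamp the
    # last few ulps so downstream sqrt/ratio code never sees -1e-20
    for name in EcosystemState.POOL_NAMES:
        arr = getattr(state, name)
        np.maximum(arr, 0.0, out=arr)

    return fix_n.sum(axis=0)
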