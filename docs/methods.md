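# Methods

## Model structure and assumptions

The ecosystem is a low-complexity NPZD model in nitrogen currency:
three phytoplankton functional types (diatom-like, flagellate-like,
cyanobacteria-like), one zooplankton compartment, one detritus pool,
and dissolved NO3, NH4 and PO4. Growth of type *i* is

```
G_i = mu_max,i * Q10_i^((T-16)/10) * min(nlim_i, plim_i, llim_i) * P_i
```

with `llim = PAR/(PAR + k_I)` and the squared Michaelis–Menten nutrient
factors given in the README. The Liebig minimum selects a single
limiting resource per type, position and time step; `nlim` and `plim`
both equal 0.5 exactly at their half-saturation points (`DIN = alpha`,
`PO4 = i·alpha`), which the tests exploit.

**Variable stoichiometry with exact budgets.** The uptake ratio `i`
(P:N of newly formed organic matter) is either 1/16 or the
phosphate-dependent frugal line `(6.9·PO4 + 6)/144`. Because `i` varies
in space and time, every organic pool (each phytoplankton type,
zooplankton, detritus) carries an explicit phosphorus ledger next to
its nitrogen content. All transfers move P at the donor pool's actual
P:N: grazing and mortality at the prey's ratio, zooplankton losses at
the zooplankton's own ratio, and detritus remineralizes N and P with
separate first-order rates. This makes variable-ratio uptake exactly
conservative, at the cost of three extra tracers; whether a simpler
model would let only uptake vary while organic pools stay Redfieldian
is ambiguous, and the full-ledger form is the conservative superset.
With the fixed 1/16 policy and equal detrital N/P rates (the default)
every organic pool's P:N is pinned to 1/16 for all time — the
degeneracy that distinguishes the two modes in regression tests. Under
the frugal policy each phytoplankton ratio stays inside the convex hull
of the uptake ratios experienced, i.e. inside [1/24, 1/16] wherever
ambient PO4 remains below the Redfield crossing 3/6.9 ≈ 0.435
mmol P m⁻³ (site B always does; site A's deep water, at 0.44, can push
the ratio marginally above 1/16, which is the intended physics of a
ratio line that crosses Redfield).

**Nitrogen uptake split and fixation.** The limitation term sums
NH4 + NO3; the split of realized uptake between the two pools is not
determined by it, so the model draws NH4 first and overflows to NO3
(the cheapest rule consistent with the summed term; configurable in
code). The cyanobacteria-like type ignores `nlim`; it draws dissolved N
like everyone else while it lasts, and whatever N demand remains is
supplied from an external "fixed nitrogen" ledger. Fixation is thus
active exactly when nitrogen would otherwise limit the fixer and is
capped by its growth demand. Removing the group ("negligible maximum
growth rate") is implemented as `mu_max = 0` exactly.

**Closure terms.** Grazing is Holling-II on total phytoplankton
nitrogen, partitioned by biomass; an assimilated fraction (0.7) goes to
zooplankton, the rest to detritus. Linear zooplankton excretion
(to NH4/PO4) and mortality (to detritus), linear phytoplankton
mortality, first-order remineralization and nitrification, all
heterotrophic rates sharing a Q10 of 2 about 16 °C. None of these
process forms is the object of study; they are the standard ERGOM-family
closures that give the stoichiometry scheme a realistic host.

## Default parameters (`med-oligotrophic-v1`)

| parameter | diatom | flagellate | cyanobacteria | units |
|---|---|---|---|---|
| mu_max | 1.8 | 1.1 | 0.7 | d⁻¹ |
| alpha (nutrient half-sat, N units) | 0.35 | 0.15 | 0.10 | mmol N m⁻³ |
| k_I (light half-sat) | 20 | 8 | 25 | W m⁻² |
| Q10 | 1.9 | 1.9 | 2.5 | – |
| sinking | 0.5 | 0 | 0 | m d⁻¹ |
| mortality | 0.06 | 0.06 | 0.06 | d⁻¹ |

Zooplankton: max grazing 0.9 d⁻¹, half-saturation 0.5 mmol N m⁻³,
assimilation 0.7, excretion 0.08 d⁻¹, mortality 0.12 d⁻¹. Detritus:
remineralization 0.05 d⁻¹ (N and P), sinking 3 m d⁻¹; nitrification
0.1 d⁻¹. Chlorophyll is diagnostic, `Chl = 1.6 × Σ phyto_N`
(mg Chl per mmol N, i.e. C:N ≈ 6.6 with C:Chl ≈ 50). These magnitudes
were chosen once for an oligotrophic-Mediterranean regime — a fast,
light-hungry, sinking diatom; a slow-light flagellate able to populate
the deep chlorophyll maximum; a warm-water fixer — and are shipped as a
named preset; every run embeds the full parameter set and configuration
JSON in its output attributes.

## Synthetic forcing: what it emulates and what it does not

The forcing generator fabricates smooth annual cycles: mixed-layer
depth (sharpened cosine, winter maximum around mid-February), surface
PAR (cosine peaking at the solstice), SST (lagging a month), a
two-regime diffusivity (100 m² d⁻¹ inside the mixed layer, 0.3 m² d⁻¹
below, tanh-blended over 5 m), exponential light attenuation with
chlorophyll self-shading, and deep NO3/PO4 reservoirs restored below
200 m on a 30-day timescale, standing in for advective renewal.
Optional seeded AR(1) "weather" noise on MLD and PAR is off by default,
so the default forcing is the exact closed form. Two open-sea presets
set the contrast that drives the analysis: site A (deep NO3 8.0,
PO4 0.44 mmol m⁻³; winter mixing to 250 m) and site B (deep NO3 4.6,
PO4 0.16; winter mixing to 130 m; clearer water), plus a
river-influenced preset whose surface NO3/PO4 fluxes support the ×5
load-perturbation experiments. The generator reproduces the
*statistical structure* the analysis needs — seasonality, deep-winter /
shallow-summer stratification, contrasting deep N:P — not real
hydrography: no advection, convection events, interannual variability
or realistic coastlines. Passing tests therefore demonstrate the
stoichiometric mechanism under controlled seasonal forcing, not skill
against the real ocean.

## Numerics

Operator-split step, default `dt = 0.05` d: (1) explicit Euler biology
with *demand capping* — when the combined sinks of a pool would
overdraw it within one step, all sinks of that pool are scaled by
available/demand, so positivity is enforced by construction and every
transfer stays paired (budgets exact to rounding, measured drift
~10⁻¹⁴ relative over eight simulated years); (2) backward-Euler
vertical diffusion in flux form (tridiagonal solve, one banded solve
for all 13 tracers; exactly conservative with no-flux boundaries);
(3) explicit upwind sinking (CFL ≈ 0.015 at defaults; closed bottom so
material accumulates in the deepest layer and remineralizes there).
The explicit-biology stability bound (`dt × max rate ≤ 1`) and the
sinking CFL are asserted at startup. The scheme is first order in `dt`;
the convergence test integrates a 10-day box problem against a
`dt = 0.003125` d oracle and checks observed orders in (0.7, 1.5).
The 0.05 d default resolves the fastest default process (~2 d⁻¹) by a
factor 10 and makes an 8-year, 25-layer column run take tens of
seconds; box audits use 0.1 d, where conservation is independent of
step size by construction.

Grid: 250 m column in 25 uniform layers (the DCM depth range of
interest is 60–100 m); 0-D "box" mode is a single closed layer with no
transport, restoring or boundary fluxes — the conservation testbed.
Runs default to 8 years with the first year flagged as spin-up;
analysis windows in the diagnostics default to the post-spin-up record.
Test and acceptance runs use 4-year twins (one spin-up + three analysed
years), which is enough for stable climatological statistics at this
level of forcing idealization.

## Diagnostics conventions

"Surface" is the mean over layer centers in the top 10 m. Climatological
months are calendar-month bins of a 365-day year. N:P_water is
nitrate:phosphate (ammonium excluded, matching the water-ratio
convention); the limitation factors use NH4+NO3. Division by a zero
denominator in either ratio yields a NaN sentinel, never a silent
infinity. The per-timestep limitation verdict aggregates the three
types either biomass-weighted (default: P-limited when the weighted
P-limited fraction exceeds 1/2; months with fraction ≥ 1/2 are labelled
phosphorus) or as `any_pft`. Twin anomalies are defined LoF − RfR, and
the twin contract (identical forcing hash and grid) is verified from
run metadata before differencing. DCM detection takes the summer-mean
(June–September) profile, requires the maximum below the mean mixed
layer and above the surface value, and reports the shallower depth on
ties. Skill reports carry mean bias, Pearson correlation, standard
deviation ratio, centered RMS difference (which satisfies the Taylor
identity to ~10⁻¹⁶) and relative error `mean(|ref − model|)/mean(ref)`,
pairwise-complete over NaNs.

## Output format

Runs are xarray Datasets and serialize to classic NetCDF-3 through the
SciPy backend (no external NetCDF library needed); the time coordinate
is plain model days since the run start.

## Known limitations

* No carbon state variable: N:C is collapsed to a constant 144 ‰, so
  carbon-specific effects (photoacclimation, variable C:Chl) are out of
  reach; chlorophyll is a fixed multiple of phytoplankton nitrogen.
* One vertical column; lateral gradients, advection and real
  bathymetry are not represented, so basin-scale numbers produced by
  3-D systems are out of scope by design.
* The ammonium-first uptake rule, the single zooplankton closure and
  the equal detrital N/P remineralization rates are pragmatic choices,
  not results; each is configurable.
* With default forcing the co-limited site A flips almost entirely to
  nitrogen limitation under the frugal policy — the expected direction
  of the mechanism, but sharper than in nature, where lateral supply
  buffers the switch.
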