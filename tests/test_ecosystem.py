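"""Process-level tests of the NPZD tendencies and their bookkeeping."""

import numpy as np
import pytest

from frugalnpzd.ecosystem import (
    EcosystemState,
    chlorophyll,
    default_params,
    grazing_fluxes,
    growth_fluxes,
    remineralization_fluxes,
    step_biology,
)
from frugalnpzd.stoichiometry import StoichiometryPolicy, p_to_n_ratio

LOF = StoichiometryPolicy.lof()
RFR = StoichiometryPolicy.redfield()
PARAMS = default_params()
PAR = np.array([40.0])
TEMP = np.array([16.0])


def state_with(**overrides) -> EcosystemState:
    st = EcosystemState.initial(1, no3=2.0, nh4=0.3, po4=0.2, seed_biomass=0.1)
    for key, val in overrides.items():
        getattr(st, key)[:] = val
    return st


def totals(st: EcosystemState):
    return st.total_nitrogen([1.0]), st.total_phosphorus([1.0])


class TestGrowth:
    def test_zero_mu_max_removes_the_type(self):
        params = PARAMS.with_pft("cyanobacteria", mu_max=0.0)
        g = growth_fluxes(state_with(), PAR, TEMP, LOF, params)
        assert np.all(g["growth"][2] == 0.0)
        assert np.all(g["growth"][:2] > 0.0)

    def test_phosphate_starvation_stops_everyone(self):
        g = growth_fluxes(state_with(po4=0.0), PAR, TEMP, LOF, PARAMS)
        assert np.all(g["growth"] == 0.0)  # plim = 0 limits fixers too

    def test_lof_draws_less_phosphorus_at_low_po4(self):
        # same N growth demand, smaller P per N under the frugal ratio
        r_lof = p_to_n_ratio(LOF, 0.05)
        r_rfr = p_to_n_ratio(RFR, 0.05)
        assert r_lof == pytest.approx((6.9 * 0.05 + 6) / 144, rel=1e-14)
        assert r_lof < r_rfr
        st_a, st_b = state_with(po4=0.05), state_with(po4=0.05)
        step_biology(st_a, PAR, TEMP, 0.01, LOF, PARAMS)
        step_biology(st_b, PAR, TEMP, 0.01, RFR, PARAMS)
        drawn_lof = 0.05 - float(st_a.po4[0])
        drawn_rfr = 0.05 - float(st_b.po4[0])
        assert 0 < drawn_lof < drawn_rfr

    def test_fixer_waives_nitrogen_limitation(self):
        st = state_with(no3=0.0, nh4=0.0)
        g = growth_fluxes(st, PAR, TEMP, LOF, PARAMS)
        assert np.all(g["growth"][:2] == 0.0)   # non-fixers N-starved
        assert np.all(g["growth"][2] > 0.0)     # fixer grows on fixation

    def test_fixation_ledger_matches_nitrogen_gain(self):
        st = state_with(no3=0.0, nh4=0.0)
        n_before, _ = totals(st)
        fix = step_biology(st, PAR, TEMP, 0.05, LOF, PARAMS)
        n_after, _ = totals(st)
        assert n_after - n_before == pytest.approx(0.05 * float(fix.sum()),
                                                   rel=1e-12)
        assert float(fix.sum()) > 0

    def test_fixation_flag_off_suppresses_the_source(self):
        st = state_with(no3=0.0, nh4=0.0)
        fix = step_biology(st, PAR, TEMP, 0.05, LOF, PARAMS, fixation=False)
        assert np.all(fix == 0.0)


class TestGrazing:
    def test_no_prey_no_grazing(self):
        g = grazing_fluxes(state_with(phyto_n=0.0, phyto_p=0.0), TEMP, PARAMS)
        assert np.all(g["graze_n"] == 0.0) and np.all(g["graze_p"] == 0.0)

    def test_prey_ratio_preserved_in_transfer(self):
        # prey at organic N:P of 24 is grazed at exactly that ratio
        st = state_with()
        st.phyto_p[:] = st.phyto_n / 24.0
        g = grazing_fluxes(st, TEMP, PARAMS)
        mask = g["graze_n"] > 0
        assert np.allclose(g["graze_p"][mask] / g["graze_n"][mask], 1 / 24.0,
                           rtol=1e-12)

    def test_full_assimilation_leaves_no_grazing_detritus(self):
        from dataclasses import replace
        params = replace(PARAMS, zoo=replace(PARAMS.zoo, assimilation=1.0),
                         remin=replace(PARAMS.remin, detritus_n_rate=0.0,
                                       detritus_p_rate=0.0))
        # disable the other detritus sources
        for name in ("diatom", "flagellate", "cyanobacteria"):
            params = params.with_pft(name, mortality_rate=0.0)
        params = replace(params, zoo=replace(params.zoo, assimilation=1.0,
                                             mortality_rate=0.0))
        st = state_with(det_n=0.0, det_p=0.0)
        step_biology(st, PAR, TEMP, 0.05, LOF, params)
        assert np.all(st.det_n == 0.0) and np.all(st.det_p == 0.0)


class TestRemineralization:
    def test_no_detritus_no_ammonium_source(self):
        fl = remineralization_fluxes(state_with(det_n=0.0), TEMP, PARAMS)
        assert np.all(fl["remin_n"] == 0.0)

    def test_first_order_rate_at_reference_temp(self):
        fl = remineralization_fluxes(state_with(det_p=1.0), TEMP, PARAMS)
        assert fl["remin_p"][0] == pytest.approx(
            PARAMS.remin.detritus_p_rate, rel=1e-12)

    def test_closed_step_conserves_nitrogen_and_phosphorus(self):
        st = state_with(det_n=0.5, det_p=0.03)
        n0, p0 = totals(st)
        for _ in range(200):
            step_biology(st, PAR, TEMP, 0.05, LOF, PARAMS, fixation=False)
        n1, p1 = totals(st)
        assert n1 == pytest.approx(n0, rel=1e-12)
        assert p1 == pytest.approx(p0, rel=1e-12)


class TestChlorophyll:
    def test_zero_biomass(self):
        st = state_with(phyto_n=0.0)
        assert np.all(chlorophyll(st, 1.6) == 0.0)

    def test_linear_in_conversion_and_biomass(self):
        st = state_with()
        assert np.allclose(chlorophyll(st, 3.2), 2 * chlorophyll(st, 1.6))
        # sum phyto N = 0.3 here (3 types at 0.1)
        assert chlorophyll(st, 1.6)[0] == pytest.approx(0.48, rel=1e-12)


class TestPositivityAndRatios:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_pools_stay_nonnegative_under_random_states(self, seed):
        rng = np.random.default_rng(seed)
        st = EcosystemState.initial(5, no3=rng.uniform(0, 5, 5),
                                    nh4=rng.uniform(0, 1, 5),
                                    po4=rng.uniform(0, 0.5, 5))
        st.phyto_n[:] = rng.uniform(0, 2, st.phyto_n.shape)
        st.phyto_p[:] = st.phyto_n * rng.uniform(1 / 24, 1 / 16, st.phyto_n.shape)
        st.det_n[:] = rng.uniform(0, 1, 5)
        st.det_p[:] = st.det_n / 16
        par = rng.uniform(0, 120, 5)
        temp = rng.uniform(10, 28, 5)
        for _ in range(400):
            step_biology(st, par, temp, 0.2, LOF, PARAMS)
        assert st.min_pool() >= 0.0
        assert np.isfinite(st.min_pool())

    def test_redfield_keeps_every_organic_pool_at_sixteen(self):
        st = state_with(det_n=0.16, det_p=0.01)
        for _ in range(500):
            step_biology(st, PAR, TEMP, 0.1, RFR, PARAMS)
        for n_pool, p_pool in ((st.phyto_n, st.phyto_p), (st.zoo_n, st.zoo_p),
                               (st.det_n, st.det_p)):
            mask = n_pool > 1e-12
            assert np.allclose(p_pool[mask] / n_pool[mask], 1 / 16, rtol=1e-9)
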