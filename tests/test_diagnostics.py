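"""Diagnostics: limitation statistics, ratio fields, anomalies, skill, DCM."""

import numpy as np
import pytest
import xarray as xr

from frugalnpzd.diagnostics import (
    TwinContractError,
    anomaly,
    dcm,
    dcm_from_profile,
    limitation_stats,
    month_of,
    np_fields,
    np_om_chl_correlation,
    skill,
    surface_mean,
)
from frugalnpzd.simulate import RunConfig


def make_synthetic_run(no3, nh4, po4, stoich="redfield", nt=100, nz=4,
                       phyto=0.1, det_n=0.0, det_p=0.0) -> xr.Dataset:
    """Hand-built dataset with the layout of a finished run.

    Synthetic: exists only to drive diagnostics with known inputs.
    """
    time = np.arange(nt, dtype=float)
    z = 5.0 + 10.0 * np.arange(nz)
    shape = (nt, nz)

    def fld(x):
        return ("time", "z"), np.full(shape, float(x))

    def fld_t(x):
        arr = np.empty(shape)
        arr[:] = np.asarray(x, float).reshape(-1, 1)
        return ("time", "z"), arr

    pn = np.full((nt, 3, nz), phyto)
    ds = xr.Dataset(
        {
            "no3": fld_t(np.broadcast_to(no3, (nt,))),
            "nh4": fld_t(np.broadcast_to(nh4, (nt,))),
            "po4": fld_t(np.broadcast_to(po4, (nt,))),
            "phyto_n": (("time", "pft", "z"), pn),
            "phyto_p": (("time", "pft", "z"), pn / 16.0),
            "zoo_n": fld(0.0),
            "zoo_p": fld(0.0),
            "det_n": fld(det_n),
            "det_p": fld(det_p),
            "chl": fld(0.1),
            "mld": (("time",), np.full(nt, 20.0)),
            "dz": (("z",), np.full(nz, 10.0)),
        },
        coords={"time": time, "z": z,
                "pft": np.array(["diatom", "flagellate", "cyanobacteria"])},
    )
    ds.attrs.update({
        "config": RunConfig(stoichiometry=stoich).to_json(),
        "stoichiometry": stoich,
        "spinup_days": 0,
        "forcing_sha256": "synthetic",
        "seed": 0,
    })
    return ds


class TestLimitationStats:
    def test_permanent_phosphate_starvation(self):
        ds = make_synthetic_run(no3=1.0, nh4=0.1, po4=0.0)
        for definition in ("biomass_weighted", "any_pft"):
            assert limitation_stats(ds, definition).percent_p_limited == 100.0

    def test_phosphate_replete_nitrogen_scarce(self):
        ds = make_synthetic_run(no3=0.0, nh4=0.0, po4=5.0)
        assert limitation_stats(ds).percent_p_limited == 0.0

    def test_alternating_record_gives_fifty_percent(self):
        nt = 100
        po4 = np.where(np.arange(nt) % 2 == 0, 0.0, 5.0)
        no3 = np.where(np.arange(nt) % 2 == 0, 5.0, 0.0)
        ds = make_synthetic_run(no3=no3, nh4=0.0, po4=po4, nt=nt)
        stats = limitation_stats(ds)
        assert stats.percent_p_limited == pytest.approx(50.0)

    def test_monthly_modes_are_binary(self, column_twins):
        stats = limitation_stats(column_twins[("siteA", "lof")])
        assert set(stats.monthly["limiting"]) <= {"nitrogen", "phosphorus"}
        assert 0.0 <= stats.percent_p_limited <= 100.0

    def test_definitions_are_ordered_and_valid(self, column_twins):
        ds = column_twins[("siteA", "redfield")]
        weighted = limitation_stats(ds, "biomass_weighted").percent_p_limited
        any_pft = limitation_stats(ds, "any_pft").percent_p_limited
        # "any type P-limited" is a superset of the majority-vote verdict
        assert weighted <= any_pft + 1e-9
        assert 0.0 <= weighted <= 100.0

    def test_unknown_definition_rejected(self, column_twins):
        with pytest.raises(ValueError):
            limitation_stats(column_twins[("siteA", "lof")], "median")


class TestMonthMapping:
    def test_calendar_bins(self):
        assert list(month_of([0.5, 30.9, 31.0, 364.5])) == [1, 1, 2, 12]
        assert list(month_of([365.0 + 10])) == [1]


class TestNpFields:
    def test_redfield_run_is_degenerate_sixteen(self, box_runs_8y):
        ratios = np_fields(box_runs_8y[("redfield", False)])
        vals = ratios["np_om"].values
        assert np.allclose(vals[np.isfinite(vals)], 16.0, rtol=1e-9)

    def test_all_detritus_ratio(self):
        ds = make_synthetic_run(no3=1.0, nh4=0.0, po4=0.1, phyto=0.0,
                                det_n=2.4, det_p=0.1)
        assert np_fields(ds)["np_om"].values == pytest.approx(24.0)

    def test_water_ratio_sentinel(self):
        ds = make_synthetic_run(no3=1.6, nh4=0.0, po4=0.1)
        assert np.allclose(np_fields(ds)["np_water"].values, 16.0)
        ds0 = make_synthetic_run(no3=1.0, nh4=0.0, po4=0.0)
        assert np.isnan(np_fields(ds0)["np_water"].values).all()

    def test_om_chl_correlation_is_signed_and_negative_here(self, column_twins):
        # more frugal (high N:P) organic matter coincides with low
        # chlorophyll in the seasonal cycle, so the sign comes out negative
        corr = np_om_chl_correlation(column_twins[("siteA", "lof")])
        assert -1.0 <= corr <= 1.0
        assert corr < 0


class TestAnomaly:
    def test_self_comparison_is_zero(self, column_twins):
        ds = column_twins[("siteA", "lof")]
        rep = anomaly(ds, ds, "chl")
        assert rep.mean_bias == 0.0
        assert np.all(rep.profile == 0.0)

    def test_twin_contract_enforced(self, column_twins):
        a = column_twins[("siteA", "lof")]
        b = column_twins[("siteB", "lof")]
        with pytest.raises(TwinContractError):
            anomaly(a, b, "chl")

    def test_constant_offset_recovered(self, column_twins):
        a = column_twins[("siteA", "redfield")]
        b = a.copy(deep=True)
        b["chl"] = a["chl"] + 0.1
        rep = anomaly(a, b, "chl")
        assert rep.mean_bias == pytest.approx(0.1, rel=1e-9)


class TestSkill:
    def test_self_comparison_perfect(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.05, 1.0, 500)
        rep = skill(x, x)
        assert rep.mean_bias == 0.0
        assert rep.correlation == pytest.approx(1.0, abs=1e-12)
        assert rep.std_ratio == pytest.approx(1.0, abs=1e-12)
        assert rep.centered_rms == pytest.approx(0.0, abs=1e-12)
        assert rep.relative_error == 0.0

    def test_constant_offset(self):
        rng = np.random.default_rng(1)
        r = rng.uniform(0.1, 1.0, 300)
        rep = skill(r + 0.25, r)
        assert rep.mean_bias == pytest.approx(0.25, rel=1e-12)
        assert rep.correlation == pytest.approx(1.0, abs=1e-12)

    def test_doubled_zero_mean_reference(self):
        rng = np.random.default_rng(2)
        r = rng.standard_normal(400)
        r -= r.mean()
        rep = skill(2 * r, r)
        assert rep.correlation == pytest.approx(1.0, abs=1e-12)
        assert rep.std_ratio == pytest.approx(2.0, rel=1e-12)

    def test_taylor_identity_on_noisy_pair(self):
        rng = np.random.default_rng(3)
        r = rng.uniform(0.05, 0.6, 1000)
        m = r + 0.1 * rng.standard_normal(1000)
        rep = skill(m, r)
        assert abs(rep.taylor_identity_residual()) < 1e-12

    def test_nan_pairwise_masking(self):
        r = np.array([1.0, np.nan, 2.0, 3.0])
        m = np.array([1.5, 2.0, np.nan, 3.5])
        rep = skill(m, r)
        assert rep.n == 2

    def test_relative_error_definition(self):
        r = np.array([1.0, 2.0])
        m = np.array([0.5, 2.5])
        assert skill(m, r).relative_error == pytest.approx(
            (0.5 + 0.5) / 2 / 1.5)


class TestDcm:
    def test_fixture_peak_at_93_m(self):
        z = np.arange(5.0, 250.0, 10.0)
        profile = np.exp(-0.5 * ((z - 93.0) / 20.0) ** 2) * 0.3 + 0.02
        res = dcm_from_profile(z, profile, mld=15.0)
        assert res.present
        assert res.depth == pytest.approx(95.0, abs=5.0)  # nearest center
        assert res.intensity >= res.surface_chl

    def test_monotone_profile_has_no_dcm(self):
        z = np.arange(5.0, 105.0, 10.0)
        res = dcm_from_profile(z, np.linspace(1.0, 0.1, z.size), mld=15.0)
        assert not res.present and res.depth is None

    def test_tie_reports_shallower(self):
        z = np.array([5.0, 25.0, 45.0, 65.0])
        profile = np.array([0.1, 0.5, 0.5, 0.2])
        res = dcm_from_profile(z, profile, mld=10.0)
        assert res.depth == 25.0

    def test_summer_dcm_detected_in_runs(self, column_twins):
        for key in (("siteA", "lof"), ("siteB", "lof")):
            res = dcm(column_twins[key])
            assert res.present
            assert res.depth > res.mld_mean


def test_surface_mean_uses_top_ten_meters(column_twins):
    ds = column_twins[("siteA", "lof")]
    top = ds["chl"].isel(z=0)
    assert np.allclose(surface_mean(ds["chl"]).values, top.values)
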