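import math

import numpy as np
import pytest

from peatflux.accumulation import (
    AccumulationSeries,
    CoreProfile,
    CoreSlice,
    McErrorModel,
    bulk_density,
    car_series,
    carbon_inventory,
    carbon_inventory_stock,
    dust_flux_series,
    elemental_mar,
    par_series,
)

ZERO_ERR = McErrorModel(
    radius_err=0.0, thickness_err=0.0, mass_err=0.0, rate_rel_err=0.0, n_draws=1000
)


def _profile(n=1, rho=0.05, c=49.0, conc=None, conc_sd=None):
    slices = []
    for i in range(n):
        slices.append(
            CoreSlice(
                depth_top=float(i),
                thickness=1.0,
                dry_mass=rho * math.pi * 3.75**2,
                c_pct=c,
                element_conc=conc or {},
                element_conc_sd=conc_sd or {},
            )
        )
    return CoreProfile(slices=tuple(slices))


def test_bulk_density_arithmetic():
    sl = CoreSlice(depth_top=0, thickness=1.0, dry_mass=2.2089, corer_radius=3.75)
    assert bulk_density(sl) == pytest.approx(0.0500, abs=1e-4)


def test_bulk_density_zero_mass_is_zero():
    sl = CoreSlice(depth_top=0, thickness=1.0, dry_mass=0.0)
    assert bulk_density(sl) == 0.0


def test_zero_thickness_slice_is_invalid():
    with pytest.raises(ValueError):
        CoreSlice(depth_top=0, thickness=0.0, dry_mass=1.0)


def test_par_with_zero_errors_collapses_to_deterministic():
    par = par_series(_profile(rho=0.05), np.array([0.02]), ZERO_ERR, seed=0)
    for stat in (par.deterministic, par.mc_median, par.mc_q25, par.mc_q75):
        assert stat[0] == pytest.approx(10.0, rel=1e-12)


def test_par_units_on_unity_inputs():
    """rho [g/cm3] x s [cm/yr] x 1e4 = g m-2 yr-1: unity in, 1e4 out."""
    par = par_series(_profile(rho=1.0), np.array([1.0]), ZERO_ERR, seed=0)
    assert par.deterministic[0] == pytest.approx(1.0e4)


def test_par_mc_median_matches_deterministic_and_delta_method():
    err = McErrorModel(n_draws=200_000)
    rho, s = 0.05, 0.02
    prof = _profile(rho=rho)
    par = par_series(prof, np.array([s]), err, seed=1)
    det = par.deterministic[0]
    assert abs(par.mc_median[0] - det) / det < 0.005
    # first-order propagation: uniform half-width w has SD w/sqrt(3);
    # PAR = m/(pi r^2 h) * s * 1e4 with relative derivatives (1, -2, -1, 1)
    sl = prof.slices[0]
    rel_var = (
        (err.mass_err / math.sqrt(3) / sl.dry_mass) ** 2
        + (2 * err.radius_err / math.sqrt(3) / sl.corer_radius) ** 2
        + (err.thickness_err / math.sqrt(3) / sl.thickness) ** 2
        + (err.rate_rel_err / math.sqrt(3)) ** 2
    )
    expected_halfwidth = 0.6745 * det * math.sqrt(rel_var)
    observed_halfwidth = (par.mc_q75[0] - par.mc_q25[0]) / 2
    assert observed_halfwidth == pytest.approx(expected_halfwidth, rel=0.10)


def test_par_mc_converges_to_deterministic_as_errors_shrink():
    deviations = []
    for scale in (1.0, 0.3, 0.1):
        err = McErrorModel(
            radius_err=0.1 * scale,
            thickness_err=0.1 * scale,
            mass_err=0.002 * scale,
            rate_rel_err=0.05 * scale,
            n_draws=20_000,
        )
        par = par_series(_profile(rho=0.05), np.array([0.02]), err, seed=2)
        deviations.append(abs(par.mc_q75[0] - par.mc_q25[0]))
    assert deviations[0] > deviations[1] > deviations[2]


def test_car_scales_par_by_carbon_fraction():
    par = par_series(_profile(rho=0.05, c=49.0), np.array([0.02]), ZERO_ERR, seed=0)
    car = car_series(par, np.array([49.0]))
    assert car.deterministic[0] == pytest.approx(4.9)
    car0 = car_series(par, np.array([0.0]))
    assert car0.deterministic[0] == 0.0
    assert car0.mc_q75[0] == 0.0


def test_elemental_mar_deterministic_value():
    prof = _profile(rho=0.05, conc={"Al": 1000.0}, conc_sd={"Al": 0.0})
    # rho*s*1e4 = 100 g m-2 yr-1; 1000 ppm -> 0.1 g m-2 yr-1
    mar = elemental_mar(prof, np.array([0.2]), "Al", ZERO_ERR, seed=0)
    assert mar.deterministic[0] == pytest.approx(0.1)


def test_mar_with_zero_conc_sd_scales_par_quartiles_exactly():
    err = McErrorModel(n_draws=10_000)
    prof = _profile(rho=0.05, conc={"Al": 1000.0}, conc_sd={"Al": 0.0})
    par = par_series(prof, np.array([0.02]), err, seed=3)
    mar = elemental_mar(prof, np.array([0.02]), "Al", err, seed=3)
    # same seed -> same PAR sub-stream draws, so quartiles scale exactly
    factor = 1000.0 * 1e-6
    assert mar.mc_q25[0] == pytest.approx(par.mc_q25[0] * factor, rel=1e-12)
    assert mar.mc_q75[0] == pytest.approx(par.mc_q75[0] * factor, rel=1e-12)


def test_mar_missing_sd_falls_back_with_warning():
    prof = _profile(rho=0.05, conc={"Al": 1000.0})
    with pytest.warns(UserWarning, match="lacked Al SD"):
        mar = elemental_mar(prof, np.array([0.02]), "Al", McErrorModel(n_draws=1000), seed=0)
    assert mar.deterministic[0] > 0


def test_dust_flux_series_trivial_cases():
    par = par_series(_profile(rho=0.05, conc={"Al": 1000.0}, conc_sd={"Al": 0.0}),
                     np.array([0.02]), ZERO_ERR, seed=0)
    mar = AccumulationSeries(
        midpoint_age=par.midpoint_age,
        deterministic=np.array([0.0804]),
        mc_median=np.array([0.0804]),
        mc_q25=np.array([0.0804]),
        mc_q75=np.array([0.0804]),
        units="g m-2 yr-1",
        n_draws=1000,
        seed=0,
    )
    assert dust_flux_series(mar, 0.0804).deterministic[0] == pytest.approx(1.0)
    assert dust_flux_series(mar, 1.0).deterministic[0] == pytest.approx(0.0804)


def _car_series(values, ages_mid):
    v = np.asarray(values, float)
    return AccumulationSeries(
        midpoint_age=np.asarray(ages_mid, float),
        deterministic=v,
        mc_median=v,
        mc_q25=v,
        mc_q75=v,
        units="g C m-2 yr-1",
        n_draws=1000,
        seed=0,
    )


def test_carbon_inventory_rate_times_time():
    # constant 100 g C m-2 yr-1 over 10 yr on 1 m2 -> 1 kg C
    car = _car_series([100.0], [5.0])
    mass = carbon_inventory(car, np.array([0.0, 10.0]), (0.0, 10.0), 1.0)
    assert mass == pytest.approx(1000.0)


def test_carbon_inventory_is_additive_over_disjoint_intervals():
    ages = np.linspace(0.0, 100.0, 11)
    car = _car_series(np.linspace(50, 150, 10), 0.5 * (ages[:-1] + ages[1:]))
    whole = carbon_inventory(car, ages, (0.0, 100.0), 2.0)
    parts = carbon_inventory(car, ages, (0.0, 37.0), 2.0) + carbon_inventory(
        car, ages, (37.0, 100.0), 2.0
    )
    assert parts == pytest.approx(whole, rel=1e-9)


def test_carbon_inventory_empty_interval_raises():
    car = _car_series([100.0], [5.0])
    with pytest.raises(ValueError):
        carbon_inventory(car, np.array([0.0, 10.0]), (50.0, 60.0), 1.0)


def test_stock_and_flux_inventories_agree_on_consistent_core():
    """rate x time telescopes back to thickness x density x C%."""
    n = 20
    rho, s, c = 0.06, 0.05, 49.0
    prof = _profile(n=n, rho=rho, c=c)
    ages = np.arange(n + 1) / s  # exact chronology for constant rate
    par = par_series(prof, np.full(n, s), ZERO_ERR, seed=0)
    car = car_series(par, np.full(n, c))
    area = 1.0e6
    flux_based = carbon_inventory(car, ages, (0.0, ages[-1]), area)
    stock_based = carbon_inventory_stock(prof, ages, (0.0, ages[-1]), area)
    assert flux_based == pytest.approx(stock_based, rel=0.02)


def test_error_model_validation():
    with pytest.raises(ValueError):
        McErrorModel(radius_err=-0.1)
    with pytest.raises(ValueError):
        McErrorModel(n_draws=10)


def test_non_contiguous_profile_rejected():
    with pytest.raises(ValueError, match="contiguous"):
        CoreProfile(
            slices=(
                CoreSlice(depth_top=0.0, thickness=1.0, dry_mass=1.0),
                CoreSlice(depth_top=2.0, thickness=1.0, dry_mass=1.0),
            )
        )
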