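"""Simulator: dynamics closed forms, mass balance, noise model, gradients."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nitrosip import (
    GuildParams,
    SimConfig,
    SoilScenario,
    generate_dataset,
    simulate_dynamics,
    simulate_gradient,
    simulate_measurements,
)
from nitrosip.sip import normalize_profile, weighted_mean_density
from nitrosip.synthetic import lognormal_factors, true_labeled_fraction

from conftest import make_scenario


class TestDynamics:
    def test_no_flux_fixed_point(self):
        """Zero growth, zero mineralization, empty NH4 pool: nothing moves."""
        sc = make_scenario(
            mineralization_rate=0.0, initial_nh4=0.0,
            guilds=(GuildParams("AOA", 1e6, 0.0, 0.0),),
        )
        t = simulate_dynamics(sc, "native", SimConfig())
        for col in ("nh4", "nox", "ph", "abundance_AOA"):
            assert t[col].nunique() == 1

    def test_exponential_growth_closed_form(self):
        """Unlimited substrate, 0.1 d-1 for 30 d: final/initial = e^3."""
        sc = make_scenario(
            mineralization_rate=1000.0, initial_nh4=1e6, buffer_capacity=1e9,
            guilds=(GuildParams("AOA", 1e6, 0.1, 0.1, per_cell_activity=1e-6),),
        )
        t = simulate_dynamics(sc, "native", SimConfig())
        ratio = t.loc[30, "abundance_AOA"] / t.loc[0, "abundance_AOA"]
        assert ratio == pytest.approx(math.e**3, rel=1e-12)

    def test_ph_decline_tracks_buffering(self):
        """1 µg N g-1 d-1 oxidized against a 100 µg N g-1 pH-1 buffer for
        30 days lowers pH by exactly 0.30."""
        sc = make_scenario(
            mineralization_rate=1.0, initial_nh4=0.0, buffer_capacity=100.0,
            guilds=(GuildParams("AOA", 1e9, 0.0, 0.0, per_cell_activity=23.0),),
        )
        t = simulate_dynamics(sc, "native", SimConfig())
        assert t.loc[30, "ph"] - t.loc[0, "ph"] == pytest.approx(-0.30, abs=1e-9)
        assert t.loc[30, "nox"] - t.loc[0, "nox"] == pytest.approx(30.0, abs=1e-9)

    def test_growth_halts_under_ammonium_limitation(self):
        sc = make_scenario(
            mineralization_rate=0.0, initial_nh4=0.5,  # below the 1 µg N g-1 threshold
            guilds=(GuildParams("AOA", 1e6, 0.2, 0.2, per_cell_activity=1e-6),),
        )
        t = simulate_dynamics(sc, "native", SimConfig())
        assert t.loc[30, "abundance_AOA"] == t.loc[0, "abundance_AOA"]

    @pytest.mark.parametrize("field,value", [
        ("mineralization_rate", float("nan")),
        ("initial_nh4", float("inf")),
    ])
    def test_nonfinite_parameters_rejected_naming_field(self, field, value):
        with pytest.raises(ValueError, match=field):
            make_scenario(**{field: value})

    def test_nonfinite_growth_rate_rejected(self):
        with pytest.raises(ValueError, match="growth_rate_native"):
            GuildParams("AOA", 1e6, float("nan"), 0.0)

    @given(
        mineralization=st.floats(0, 10),
        nh4=st.floats(0, 100),
        rate=st.floats(-0.2, 0.2),
        abundance=st.floats(1e3, 1e9),
        activity=st.floats(0.1, 30.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_mass_balance_each_step(self, mineralization, nh4, rate, abundance, activity):
        """Δ(NH4 + NOx) per day equals the mineralization input exactly."""
        sc = make_scenario(
            mineralization_rate=mineralization, initial_nh4=nh4,
            guilds=(GuildParams("AOA", abundance, rate, rate, per_cell_activity=activity),),
        )
        t = simulate_dynamics(sc, "native", SimConfig())
        pool = t["nh4"] + t["nox"]
        assert np.allclose(np.diff(pool), mineralization, atol=1e-9)

    def test_labeled_fraction_bounded_by_autotroph_fraction(self):
        sc = make_scenario(
            mineralization_rate=100.0, initial_nh4=1e4, buffer_capacity=1e9,
            guilds=(GuildParams("AOA", 1e6, 0.1, 0.1, autotroph_fraction=0.6,
                                per_cell_activity=1e-6),),
        )
        t = simulate_dynamics(sc, "native", SimConfig())
        lf = true_labeled_fraction(t, "AOA", 30)
        assert 0 < lf <= 0.6
        # af x (net new copies / final copies) for uninterrupted growth
        expected = 0.6 * (1 - math.exp(-3))
        assert lf == pytest.approx(expected, rel=1e-9)


class TestMeasurements:
    def _tables(self, config):
        sc = make_scenario()
        traj = {("T", c): simulate_dynamics(sc, c, config) for c in ("native", "modified")}
        return simulate_measurements(traj, config)

    def test_zero_cv_measurements_equal_truth(self):
        config = SimConfig(seed=1, qpcr_cv=0.0, chem_cv=0.0)
        sc = make_scenario()
        traj = simulate_dynamics(sc, "native", config)
        chem, abund = simulate_measurements({("T", "native"): traj}, config)
        day30 = chem[chem.day == 30]
        assert np.allclose(day30.nox, traj.loc[30, "nox"])
        assert np.allclose(abund[abund.day == 30].copies, traj.loc[30, "abundance_AOA"])

    def test_noise_model_cv_recovered(self, rng):
        """Sample CV of the multiplicative noise matches the nominal 0.2."""
        draws = lognormal_factors(rng, 0.2, 3000)
        assert abs(draws.std(ddof=1) / draws.mean() - 0.2) < 0.02
        assert draws.mean() == pytest.approx(1.0, abs=0.02)

    def test_same_seed_identical_tables(self):
        config = SimConfig(seed=11)
        c1, a1 = self._tables(config)
        c2, a2 = self._tables(config)
        assert c1.to_csv(index=False) == c2.to_csv(index=False)
        assert a1.to_csv(index=False) == a2.to_csv(index=False)

    def test_day0_has_single_isotope_group(self):
        chem, _ = self._tables(SimConfig(seed=2))
        assert set(chem[chem.day == 0].isotope) == {"none"}
        assert set(chem[chem.day == 30].isotope) == {"12C", "13C"}


class TestGradient:
    def test_unlabeled_peak_at_gc_density(self, single_guild, noise_free_config):
        """GC 0.5 bands at 1.66 + 0.098 x 0.5 = 1.709 g ml-1."""
        prof = simulate_gradient(1e7, 0.0, single_guild, "12C", noise_free_config)
        peak = prof.loc[prof.copies.idxmax(), "buoyant_density"]
        width = 0.1 / 15
        assert abs(peak - 1.709) <= width / 2 + 1e-12

    def test_full_labeling_shifts_by_max_label_shift(self, single_guild, noise_free_config):
        p0 = normalize_profile(simulate_gradient(1e7, 0.0, single_guild, "13C", noise_free_config))
        p1 = normalize_profile(simulate_gradient(1e7, 1.0, single_guild, "13C", noise_free_config))
        shift = weighted_mean_density(p1) - weighted_mean_density(p0)
        assert shift == pytest.approx(0.036, abs=0.004)  # within binning error

    def test_gradient_conservation_before_noise(self, single_guild, noise_free_config):
        prof = simulate_gradient(3.7e6, 0.5, single_guild, "13C", noise_free_config)
        assert prof.copies.sum() == pytest.approx(3.7e6, rel=1e-6)

    def test_labeled_mass_matches_labeled_fraction(self, single_guild, noise_free_config):
        """40% labeled: the shifted component carries 40% of the mass."""
        prof = simulate_gradient(1e7, 0.4, single_guild, "13C", noise_free_config)
        # split at the midpoint between the two band centers
        mid = 1.709 + 0.018
        heavy = prof[prof.buoyant_density >= mid].copies.sum()
        assert heavy / prof.copies.sum() == pytest.approx(0.4, abs=0.03)

    def test_wmd_monotone_in_labeled_fraction(self, single_guild, noise_free_config):
        wmds = []
        for lf in np.linspace(0, 1, 11):
            p = normalize_profile(simulate_gradient(1e7, lf, single_guild, "13C", noise_free_config))
            wmds.append(weighted_mean_density(p))
        assert np.all(np.diff(wmds) >= -1e-12)

    def test_12c_never_labeled(self, single_guild, noise_free_config):
        a = simulate_gradient(1e7, 0.9, single_guild, "12C", noise_free_config)
        b = simulate_gradient(1e7, 0.0, single_guild, "12C", noise_free_config)
        assert np.allclose(a.copies, b.copies)

    def test_bad_labeled_fraction_rejected(self, single_guild, noise_free_config):
        with pytest.raises(ValueError, match="labeled_fraction"):
            simulate_gradient(1e7, 1.2, single_guild, "13C", noise_free_config)


class TestDataset:
    def test_default_design_row_arithmetic(self):
        from nitrosip import default_scenarios

        ds = generate_dataset(default_scenarios(), SimConfig(seed=5))
        chem = ds.chemistry
        # 5 soils x 2 pH x 2 isotopes x triplicate per day after day 0
        assert len(chem[chem.day == 30]) == 60
        assert len(chem[chem.day == 15]) == 60
        assert len(chem[chem.day == 0]) == 30  # day-0 triplicates only
        # gradient: day-30 microcosms x 3 guilds x 13 quantified fractions
        assert len(ds.gradient) == 60 * 3 * 13

    def test_minimal_design_counts(self):
        sc = make_scenario()
        cfg = SimConfig(seed=5, replicates=1, sample_days=(0, 30))
        ds = generate_dataset([sc], cfg)
        assert len(ds.chemistry) == 2 * (1 + 2)  # 2 conditions x (day0 + 2 isotopes)
        assert len(ds.abundance) == len(ds.chemistry) * 1  # one guild
        assert len(ds.gradient) == 2 * 2 * 1 * 13

    def test_duplicate_soil_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate soil_id"):
            generate_dataset([make_scenario(), make_scenario()], SimConfig())

    def test_truth_contributions_never_exceed_net_nox(self):
        """Per-guild oxidized N sums exactly to the NOx produced."""
        from nitrosip import closure_scenarios

        ds = generate_dataset(closure_scenarios()[:2], SimConfig(seed=5, qpcr_cv=0, chem_cv=0))
        for soil, conds in ds.truth["soils"].items():
            for cond, entry in conds.items():
                total = sum(g["oxidized_ug_n"] for g in entry["guilds"].values())
                assert total <= entry["net_nox"] + 1e-9
                assert total == pytest.approx(entry["net_nox"], abs=1e-6)

    def test_dataset_determinism(self):
        from nitrosip import default_scenarios

        a = generate_dataset(default_scenarios(), SimConfig(seed=9))
        b = generate_dataset(default_scenarios(), SimConfig(seed=9))
        for name in ("chemistry", "abundance", "gradient"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
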